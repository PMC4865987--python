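"""Small shared sequence helpers (reverse complement, reference access)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import pyfaidx

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ReferenceLike = Union[Mapping[str, str], pyfaidx.Fasta]


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def as_seq_dict(reference: Union[ReferenceLike, str, Path]) -> dict[str, str]:
    """Materialize a reference as {chrom: sequence} of uppercase strings.

    Accepts a FASTA path, a pyfaidx.Fasta, or an existing mapping. Panels
    here span a few Mb at most, so whole-genome strings are the fastest
    representation for the exact substring work the pipeline does.
    """
    if isinstance(reference, (str, Path)):
        reference = pyfaidx.Fasta(str(reference))
    if isinstance(reference, pyfaidx.Fasta):
        return {name: str(reference[name][:]).upper() for name in reference.keys()}
    return {k: v.upper() for k, v in reference.items()}


def write_fasta(seqs: Mapping[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
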