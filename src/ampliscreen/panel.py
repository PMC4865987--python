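"""Mutation-panel data model and I/O.

A carrier-screening panel is a list of known pathogenic mutations (SNVs,
small indels, and a few large rearrangements with characterized
breakpoints).  Distinct mutations can share a genomic position (two
different pathogenic alleles of the same nucleotide); for coverage
accounting these are collapsed into a single *target position*, so a panel
of 370 small mutations with two same-position allele pairs yields 368
targets.  Large rearrangements are not positional targets at all: they are
detected through chimeric *junction references* — the sequence across the
breakpoint that exists only in carrier genomes.

Coordinate conventions: panel TSV and VCF are 1-based; BED and all internal
interval arithmetic are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from ampliscreen.seq import ReferenceLike, as_seq_dict, revcomp

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Malformed panel content (parse or invariant violation)."""


class MutationClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    LARGE_REARRANGEMENT = "LARGE_REARRANGEMENT"


@dataclass(frozen=True)
class PanelMutation:
    """One targetable disease mutation.

    ``pos`` is the 1-based anchor base.  SNVs have single, differing
    ref/alt bases; indels share the anchor base (VCF-style left-anchored
    representation).  Large rearrangements carry ``breakpoints`` (deleted
    interval for deletions; insertion point repeated for insertions) and
    empty ref/alt alleles.
    """

    mutation_id: str
    gene: str
    disorder: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    mut_class: MutationClass
    breakpoints: Optional[tuple[int, int]] = None
    inserted_seq: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"{self.mutation_id}: pos must be >= 1, got {self.pos}")
        mc = self.mut_class
        ref, alt = self.ref_allele, self.alt_allele
        if mc is MutationClass.LARGE_REARRANGEMENT:
            if ref or alt:
                raise PanelError(f"{self.mutation_id}: rearrangement must have empty alleles")
            if self.breakpoints is None:
                raise PanelError(f"{self.mutation_id}: rearrangement requires breakpoints")
            b1, b2 = self.breakpoints
            if not (1 <= b1 <= b2):
                raise PanelError(f"{self.mutation_id}: invalid breakpoints {self.breakpoints}")
            if b1 == b2 and not self.inserted_seq:
                raise PanelError(f"{self.mutation_id}: insertion breakpoints need inserted_seq")
            return
        for name, allele in (("ref", ref), ("alt", alt)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise PanelError(f"{self.mutation_id}: invalid {name} allele {allele!r}")
        if mc is MutationClass.SNV:
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                raise PanelError(f"{self.mutation_id}: SNV requires single differing bases")
        elif mc is MutationClass.INS:
            if not (len(alt) > len(ref) == 1 and alt[0] == ref):
                raise PanelError(f"{self.mutation_id}: INS must extend the anchor base")
        elif mc is MutationClass.DEL:
            if not (len(ref) > len(alt) == 1 and ref[0] == alt):
                raise PanelError(f"{self.mutation_id}: DEL must contract to the anchor base")

    @property
    def is_rearrangement(self) -> bool:
        return self.mut_class is MutationClass.LARGE_REARRANGEMENT


@dataclass
class MutationPanel:
    """Ordered collection of panel mutations with unique ids."""

    mutations: list[PanelMutation]
    version: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.mutations:
            if m.mutation_id in seen:
                raise PanelError(f"duplicate mutation_id {m.mutation_id}")
            seen.add(m.mutation_id)
        self._by_id = {m.mutation_id: m for m in self.mutations}

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[PanelMutation]:
        return iter(self.mutations)

    def __getitem__(self, mutation_id: str) -> PanelMutation:
        return self._by_id[mutation_id]

    def __contains__(self, mutation_id: str) -> bool:
        return mutation_id in self._by_id

    @property
    def small_mutations(self) -> list[PanelMutation]:
        """SNVs and small indels (everything except large rearrangements)."""
        return [m for m in self.mutations if not m.is_rearrangement]

    @property
    def rearrangements(self) -> list[PanelMutation]:
        return [m for m in self.mutations if m.is_rearrangement]


@dataclass(frozen=True)
class TargetPosition:
    """A genomic position to capture; may host several alternative alleles."""

    target_id: str
    chrom: str
    pos: int
    mutation_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.mutation_ids:
            raise PanelError(f"{self.target_id}: target without member mutations")


@dataclass(frozen=True)
class JunctionReference:
    """Chimeric sequence across a rearrangement breakpoint.

    ``sequence`` exists only in carrier genomes; ``core_kmer`` is the exact
    substring (straddling the junction with at least ``min_anchor`` bases on
    each side) used for read matching, verified absent from the unmutated
    reference.
    """

    mutation_id: str
    sequence: str
    flank_len: int
    core_kmer: str


# ---------------------------------------------------------------------------
# Panel TSV I/O

_COLUMNS = [
    "mutation_id",
    "gene",
    "disorder",
    "chrom",
    "pos",
    "ref",
    "alt",
    "class",
    "breakpoint1",
    "breakpoint2",
    "inserted_seq",
    "label",
]


def load_panel(path: Union[str, Path], version: str = "", provenance: str = "") -> MutationPanel:
    """Parse a tab-separated panel file (header line starts with '#').

    Raises :class:`PanelError` naming the offending line for malformed rows,
    duplicate ids, invalid alleles, or an SNV with ref == alt.
    """
    path = Path(path)
    mutations: list[PanelMutation] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise PanelError(f"{path}: missing '#' header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_COLUMNS):
                raise PanelError(
                    f"{path}:{lineno}: expected {len(_COLUMNS)} columns, got {len(fields)}"
                )
            row = dict(zip(_COLUMNS, fields))
            try:
                mut_class = MutationClass(row["class"])
                breakpoints = None
                if row["breakpoint1"] != "." or row["breakpoint2"] != ".":
                    breakpoints = (int(row["breakpoint1"]), int(row["breakpoint2"]))
                mut = PanelMutation(
                    mutation_id=row["mutation_id"],
                    gene=row["gene"],
                    disorder=row["disorder"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref_allele="" if row["ref"] == "." else row["ref"],
                    alt_allele="" if row["alt"] == "." else row["alt"],
                    mut_class=mut_class,
                    breakpoints=breakpoints,
                    inserted_seq="" if row["inserted_seq"] == "." else row["inserted_seq"],
                    label=row["label"],
                )
            except (PanelError, ValueError) as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
            mutations.append(mut)
    if not mutations:
        log.warning("panel file %s contains no mutations", path)
    try:
        return MutationPanel(mutations, version=version, provenance=provenance or str(path))
    except PanelError as exc:
        raise PanelError(f"{path}: {exc}") from exc


def write_panel(panel: MutationPanel, path: Union[str, Path]) -> None:
    """Write a panel back to TSV; round-trips all fields bit-exactly."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for m in panel:
            b1, b2 = (str(m.breakpoints[0]), str(m.breakpoints[1])) if m.breakpoints else (".", ".")
            fh.write(
                "\t".join(
                    [
                        m.mutation_id,
                        m.gene,
                        m.disorder,
                        m.chrom,
                        str(m.pos),
                        m.ref_allele or ".",
                        m.alt_allele or ".",
                        m.mut_class.value,
                        b1,
                        b2,
                        m.inserted_seq or ".",
                        m.label,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Target collapsing

def collapse_targets(panel: MutationPanel) -> list[TargetPosition]:
    """Collapse co-located small mutations into unique target positions.

    Keys on (chrom, pos) only: two alternative alleles of the same
    nucleotide become one target listing both member mutations.  Large
    rearrangements are skipped (they are detected via junction references).
    Output order follows first appearance in the panel, so the operation is
    order-independent up to that stable ordering.
    """
    grouped: dict[tuple[str, int], list[str]] = {}
    for m in panel.small_mutations:
        grouped.setdefault((m.chrom, m.pos), []).append(m.mutation_id)
    return [
        TargetPosition(
            target_id=f"t_{chrom}_{pos}",
            chrom=chrom,
            pos=pos,
            mutation_ids=tuple(ids),
        )
        for (chrom, pos), ids in grouped.items()
    ]


def write_targets_bed(targets: Sequence[TargetPosition], path: Union[str, Path]) -> None:
    """Write targets as 6-column BED (0-based half-open single-base records)."""
    if not targets:
        raise PanelError("refusing to write an empty target BED")
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.pos - 1}\t{t.pos}\t{t.target_id}\t0\t+\n")


# ---------------------------------------------------------------------------
# Junction references

def build_junction_reference(
    mut: PanelMutation,
    reference: ReferenceLike,
    flank_len: int = 60,
    min_anchor: int = 20,
) -> JunctionReference:
    """Build the chimeric junction sequence for a large rearrangement.

    For a deletion of [b1, b2] (1-based inclusive) the sequence is the
    ``flank_len`` reference bases ending at b1-1 joined to the ``flank_len``
    bases starting at b2+1.  For an insertion at b (breakpoints (b, b)) it
    is left flank (ending at b) + inserted sequence + right flank (starting
    at b+1).  The core k-mer takes ``min_anchor`` bases on each side of the
    left-most junction point; its absence from the unmutated reference (both
    strands) is verified, since junction detection relies on exact matching.
    """
    if not mut.is_rearrangement:
        raise PanelError(f"{mut.mutation_id}: junction reference requires LARGE_REARRANGEMENT")
    genome = as_seq_dict(reference)
    chrom = genome[mut.chrom]
    b1, b2 = mut.breakpoints  # type: ignore[misc]
    if mut.inserted_seq and b1 == b2:
        left = chrom[b1 - flank_len : b1]  # ends at b1 (1-based inclusive)
        right = chrom[b1 : b1 + flank_len]
        sequence = left + mut.inserted_seq + right
    else:
        left = chrom[b1 - 1 - flank_len : b1 - 1]  # ends at b1-1
        right = chrom[b2 : b2 + flank_len]
        sequence = left + right
    if len(left) < flank_len or len(right) < flank_len:
        raise PanelError(f"{mut.mutation_id}: flanks of {flank_len} bp do not fit the chromosome")
    # Core k-mer straddles the junction at the end of the left flank.
    core = sequence[flank_len - min_anchor : flank_len + min_anchor]
    for name, seq in genome.items():
        if core in seq or revcomp(core) in seq:
            raise PanelError(
                f"{mut.mutation_id}: ambiguous junction — core k-mer occurs in reference {name}"
            )
    return JunctionReference(
        mutation_id=mut.mutation_id,
        sequence=sequence,
        flank_len=flank_len,
        core_kmer=core,
    )
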