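"""Multiplex-PCR pool assignment under amplicon compatibility constraints.

Primer pairs co-amplified in one microfluidic inlet must not interfere:
products must not overlap or sit closer than ``min_gap_bp`` on the same
chromosome (strictly less than the gap conflicts; an exact 5 kb separation
is allowed), pool members must have similar product lengths (each within
``size_tolerance`` of the pool's mean length) and a bounded GC spread, and
a pool holds at most ``max_pool_size`` primer pairs with at most
``max_pools`` inlets available on the chip.

Hard pairwise incompatibilities form a conflict graph; assignment is a
deterministic greedy first-fit colouring (largest conflict degree first,
then longest product, then lexical id) that re-checks the aggregate pool
constraints on every insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union


class PoolingError(ValueError):
    pass


@dataclass(frozen=True)
class Amplicon:
    """One primer pair's PCR product (0-based half-open interval)."""

    amplicon_id: str
    chrom: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str
    gc_fraction: float
    target_ids: tuple[str, ...] = ()
    is_junction: bool = False
    is_length_outlier: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PoolingError(f"{self.amplicon_id}: empty interval")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise PoolingError(f"{self.amplicon_id}: GC fraction outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PoolingParams:
    min_gap_bp: int = 5000
    size_tolerance: float = 0.20        # fraction of pool mean length
    gc_span_max: float = 15.0           # percentage points within a pool
    max_pool_size: int = 12
    max_pools: int = 48

    def __post_init__(self) -> None:
        if min(self.min_gap_bp, self.gc_span_max, self.max_pool_size, self.max_pools) <= 0:
            raise PoolingError("pooling parameters must be positive")
        if not 0 < self.size_tolerance < 1:
            raise PoolingError("size_tolerance must be in (0,1)")


OVERLAP = "OVERLAP"
PROXIMITY = "PROXIMITY"


@dataclass
class ConflictGraph:
    nodes: list[str]
    edges: dict[frozenset, str] = field(default_factory=dict)

    def conflict(self, a: str, b: str) -> Optional[str]:
        return self.edges.get(frozenset((a, b)))

    def degree(self, a: str) -> int:
        return sum(1 for e in self.edges if a in e)


@dataclass
class PoolingPlan:
    pools: list[list[str]]
    params: PoolingParams
    policy: str = "greedy first-fit; order = (degree desc, length desc, id asc)"

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def pool_of(self, amplicon_id: str) -> int:
        for i, pool in enumerate(self.pools):
            if amplicon_id in pool:
                return i
        raise KeyError(amplicon_id)


@dataclass(frozen=True)
class PoolingViolation:
    pool_index: int
    members: tuple[str, ...]
    reason: str
    detail: str


def build_conflict_graph(amplicons: Sequence[Amplicon], params: PoolingParams) -> ConflictGraph:
    """Edge (a,b) iff same chromosome and products overlap or gap < min_gap_bp."""
    graph = ConflictGraph(nodes=[a.amplicon_id for a in amplicons])
    by_chrom: dict[str, list[Amplicon]] = {}
    for a in amplicons:
        by_chrom.setdefault(a.chrom, []).append(a)
    for group in by_chrom.values():
        group = sorted(group, key=lambda a: (a.start, a.end))
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                gap = b.start - a.end
                if gap >= params.min_gap_bp:
                    break  # starts are sorted, so gap only grows
                reason = OVERLAP if a.end > b.start else PROXIMITY
                graph.edges[frozenset((a.amplicon_id, b.amplicon_id))] = reason
    return graph


def _pool_feasible(
    members: list[Amplicon], candidate: Amplicon, graph: ConflictGraph, params: PoolingParams
) -> bool:
    if len(members) + 1 > params.max_pool_size:
        return False
    for m in members:
        if graph.conflict(m.amplicon_id, candidate.amplicon_id):
            return False
    lengths = [m.length for m in members] + [candidate.length]
    mean = sum(lengths) / len(lengths)
    if any(abs(l - mean) > params.size_tolerance * mean for l in lengths):
        return False
    gcs = [m.gc_fraction for m in members] + [candidate.gc_fraction]
    if (max(gcs) - min(gcs)) * 100.0 > params.gc_span_max:
        return False
    return True


def assign_pools(
    amplicons: Sequence[Amplicon],
    graph: Optional[ConflictGraph] = None,
    params: PoolingParams = PoolingParams(),
) -> PoolingPlan:
    """Deterministic greedy pool assignment; raises on infeasibility.

    Amplicons are processed by (conflict degree desc, length desc, id asc)
    and placed into the first existing pool where all pool invariants —
    conflict-freedom, size cap, pool-mean length tolerance, GC span —
    still hold; otherwise a new pool opens.
    """
    if graph is None:
        graph = build_conflict_graph(amplicons, params)
    order = sorted(
        amplicons,
        key=lambda a: (-graph.degree(a.amplicon_id), -a.length, a.amplicon_id),
    )
    pools: list[list[Amplicon]] = []
    unplaceable: list[str] = []
    for a in order:
        for pool in pools:
            if _pool_feasible(pool, a, graph, params):
                pool.append(a)
                break
        else:
            if len(pools) >= params.max_pools:
                unplaceable.append(a.amplicon_id)
                continue
            pools.append([a])
    if unplaceable:
        raise PoolingError(
            f"infeasible: {len(unplaceable)} amplicons exceed max_pools={params.max_pools}: "
            + ",".join(unplaceable)
        )
    return PoolingPlan(pools=[[m.amplicon_id for m in pool] for pool in pools], params=params)


def validate_pooling(
    plan: PoolingPlan, amplicons: Sequence[Amplicon], params: Optional[PoolingParams] = None
) -> list[PoolingViolation]:
    """Exhaustively re-check every pool constraint; empty list iff valid."""
    params = params or plan.params
    by_id = {a.amplicon_id: a for a in amplicons}
    violations: list[PoolingViolation] = []
    seen: dict[str, int] = {}
    for i, pool in enumerate(plan.pools):
        members = []
        for aid in pool:
            if aid not in by_id:
                raise PoolingError(f"plan references unknown amplicon {aid}")
            if aid in seen:
                violations.append(
                    PoolingViolation(i, (aid,), "DUPLICATE", f"also in pool {seen[aid]}")
                )
            seen[aid] = i
            members.append(by_id[aid])
        if len(members) > params.max_pool_size:
            violations.append(
                PoolingViolation(i, tuple(pool), "POOL_SIZE", f"{len(members)} members")
            )
        for j, a in enumerate(members):
            for b in members[j + 1 :]:
                if a.chrom != b.chrom:
                    continue
                first, second = (a, b) if a.start <= b.start else (b, a)
                gap = second.start - first.end
                if first.end > second.start:
                    violations.append(
                        PoolingViolation(
                            i, (a.amplicon_id, b.amplicon_id), OVERLAP, "products overlap"
                        )
                    )
                elif gap < params.min_gap_bp:
                    violations.append(
                        PoolingViolation(
                            i, (a.amplicon_id, b.amplicon_id), PROXIMITY, f"gap {gap} bp"
                        )
                    )
        if members:
            mean = sum(m.length for m in members) / len(members)
            for m in members:
                if abs(m.length - mean) > params.size_tolerance * mean:
                    violations.append(
                        PoolingViolation(
                            i,
                            (m.amplicon_id,),
                            "SIZE_TOLERANCE",
                            f"length {m.length} vs pool mean {mean:.1f}",
                        )
                    )
            gcs = [m.gc_fraction for m in members]
            span = (max(gcs) - min(gcs)) * 100.0
            if span > params.gc_span_max:
                violations.append(
                    PoolingViolation(i, tuple(pool), "GC_SPAN", f"span {span:.1f} pp")
                )
    missing = set(by_id) - set(seen)
    for aid in sorted(missing):
        violations.append(PoolingViolation(-1, (aid,), "UNASSIGNED", "not in any pool"))
    if len(plan.pools) > params.max_pools:
        violations.append(
            PoolingViolation(-1, (), "POOL_COUNT", f"{len(plan.pools)} > {params.max_pools}")
        )
    return violations


# ---------------------------------------------------------------------------
# TSV I/O

def write_amplicons_tsv(amplicons: Iterable[Amplicon], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#amplicon_id\tchrom\tstart\tend\tfwd_primer\trev_primer\tgc_fraction\t"
            "target_ids\tis_junction\tis_length_outlier\n"
        )
        for a in amplicons:
            fh.write(
                f"{a.amplicon_id}\t{a.chrom}\t{a.start}\t{a.end}\t{a.fwd_primer}\t"
                f"{a.rev_primer}\t{a.gc_fraction:.6f}\t{','.join(a.target_ids) or '.'}\t"
                f"{int(a.is_junction)}\t{int(a.is_length_outlier)}\n"
            )


def load_amplicons_tsv(path: Union[str, Path]) -> list[Amplicon]:
    amplicons = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise PoolingError(f"{path}: missing header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            amplicons.append(
                Amplicon(
                    amplicon_id=f[0],
                    chrom=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    fwd_primer=f[4],
                    rev_primer=f[5],
                    gc_fraction=float(f[6]),
                    target_ids=tuple(f[7].split(",")) if f[7] != "." else (),
                    is_junction=bool(int(f[8])),
                    is_length_outlier=bool(int(f[9])),
                )
            )
    return amplicons


def write_pooling_tsv(plan: PoolingPlan, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#pool_id\tamplicon_id\n")
        for i, pool in enumerate(plan.pools):
            for aid in pool:
                fh.write(f"pool{i:02d}\t{aid}\n")
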