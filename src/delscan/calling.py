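"""Run-length deletion calling, border refinement, and gene intersection.

A large deletion is a block of at least ``min_low_run`` adjacent bins whose
normalized depth is <= ``low_fraction`` of the wild type; it is considered
finished only once at least ``min_high_run_to_terminate`` adjacent bins rise
above that threshold (or the chromosome ends).  Interior high runs shorter
than the termination run are absorbed into the call; the reported end is the
last low bin.  Masked bins are neutral: they extend neither the low nor the
high run, and sit inside a call when flanked by low bins.

Bin-resolution calls can then be refined against gene models with wild-type
capture coverage: the refined interval runs from the first to the last gene
whose own normalized coverage in the mutant is <= ``low_fraction``, and the
nearest covered genes on either side are reported as flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CallerParams, NormalizedCoverage

logger = logging.getLogger(__name__)

BACKGROUND_POLYMORPHISM = "background_polymorphism_suspect"


@dataclass
class DeletionCall:
    """A contiguous low-coverage block (0-based, half-open)."""

    line_id: str
    chromosome: str
    start: int
    end: int
    n_low_bins: int
    method: str = "bin"  # "bin" or "refined"
    flags: set = field(default_factory=set)
    flank_upstream: str | None = None  # nearest retained gene before the deletion
    flank_downstream: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty call [{self.start}, {self.end})")
        if self.method not in ("bin", "refined"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with an annotation-confidence grade and a flag for
    whether the wild-type line shows capture coverage over it."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    confidence: str = "high"  # "high" or "low"
    wildtype_covered: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")


class HomoeologyMap:
    """Symmetric gene-to-gene relation across subgenomes."""

    def __init__(self, pairs: Sequence[tuple[str, str]] = ()):
        self._partners: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        self._partners.setdefault(a, set()).add(b)
        self._partners.setdefault(b, set()).add(a)

    def related(self, a: str, b: str) -> bool:
        return b in self._partners.get(a, ())

    def partners(self, a: str) -> set[str]:
        return set(self._partners.get(a, ()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._partners.values()) // 2


def deletion_size(call: DeletionCall) -> int:
    """Size in bp: exactly end - start, for bin-resolution and refined calls."""
    return call.end - call.start


def find_low_blocks(
    values: Sequence[float],
    low_fraction: float,
    min_low_run: int,
    min_high_run: int,
) -> list[tuple[int, int, int]]:
    """Core run-rule scan on one chromosome's bin values.

    Returns (first_low_index, last_low_index, n_low_bins) triples in order.
    NaN values are neutral; runs are counted over non-NaN bins only.
    """
    # indices of unmasked bins, scanned left to right
    idx = [i for i, v in enumerate(values) if v == v]  # v == v filters NaN
    calls: list[tuple[int, int, int]] = []
    open_start = -1  # original index of first low bin of the open call
    last_low = -1
    n_low = 0
    low_run = 0
    high_run = 0
    pending: list[int] = []  # low bins seen in the current (not yet open) run
    for i in idx:
        if values[i] <= low_fraction:
            low_run += 1
            high_run = 0
            if open_start >= 0:
                last_low = i
                n_low += 1
            else:
                pending.append(i)
                if low_run >= min_low_run:
                    open_start = pending[0]
                    last_low = i
                    n_low = len(pending)
                    pending = []
        else:
            high_run += 1
            low_run = 0
            pending = []
            if open_start >= 0 and high_run >= min_high_run:
                calls.append((open_start, last_low, n_low))
                open_start = -1
                n_low = 0
    if open_start >= 0:  # chromosome end closes an open call
        calls.append((open_start, last_low, n_low))
    return calls


def call_deletions(cov: NormalizedCoverage, params: CallerParams) -> list[DeletionCall]:
    """Apply the run rules to a normalized profile, per chromosome.

    A call opens at the first bin of a run of >= ``min_low_run`` low bins and
    closes at the last low bin preceding a run of >= ``min_high_run_to_terminate``
    high bins (or the chromosome end).  Calls are returned per chromosome in
    coordinate order, with bin-boundary coordinates.
    """
    calls: list[DeletionCall] = []
    for chrom in cov.chromosomes():
        bins = cov.bins(chrom)
        blocks = find_low_blocks(
            bins["value"].tolist(),
            params.low_fraction,
            params.min_low_run,
            params.min_high_run_to_terminate,
        )
        for first, last, n_low in blocks:
            calls.append(
                DeletionCall(
                    line_id=cov.line_id,
                    chromosome=chrom,
                    start=int(bins["start"].iloc[first]),
                    end=int(bins["end"].iloc[last]),
                    n_low_bins=n_low,
                    method="bin",
                )
            )
    return calls


def flag_shared_calls(
    calls_by_line: Mapping[str, list[DeletionCall]],
) -> dict[str, list[DeletionCall]]:
    """Flag calls shared between independent lines as suspect alignment artifacts.

    Independent irradiation mutants should not share deletions; a call that
    overlaps (>= 1 bp, same chromosome) a call in another line is most likely
    a polymorphism between the background variety and the reference assembly
    causing read misalignment in every line.  Flagged, never removed.
    """
    lines = list(calls_by_line)
    if len(lines) < 2:
        logger.info("flag_shared_calls: single line, nothing to compare")
        return dict(calls_by_line)
    for i, li in enumerate(lines):
        for call in calls_by_line[li]:
            for lj in lines:
                if lj == li:
                    continue
                for other in calls_by_line[lj]:
                    if (
                        other.chromosome == call.chromosome
                        and call.start < other.end
                        and other.start < call.end
                    ):
                        call.flags.add(BACKGROUND_POLYMORPHISM)
                        other.flags.add(BACKGROUND_POLYMORPHISM)
    return dict(calls_by_line)


def refine_borders(
    call: DeletionCall,
    genes: Sequence[GeneModel],
    per_gene_value: Mapping[str, float],
    low_fraction: float = 0.1,
) -> DeletionCall:
    """Re-estimate the deletion extent from gene-level mutant coverage.

    Only genes with wild-type capture coverage on the call's chromosome are
    considered, sorted by coordinate.  The refined interval runs from the
    start of the first gene of the contiguous low-coverage (value <=
    ``low_fraction``) gene block intersecting the call to the end of its last
    gene; the nearest high-coverage genes on either side are reported as
    flanks.  If no low-coverage gene intersects the call, the bin-resolution
    call is returned unchanged.
    """
    cand = sorted(
        (g for g in genes if g.wildtype_covered and g.chromosome == call.chromosome),
        key=lambda g: (g.start, g.end),
    )
    if not cand:
        logger.info("refine_borders: no covered genes on %s; call unchanged", call.chromosome)
        return call
    low = [per_gene_value[g.gene_id] <= low_fraction for g in cand]
    inside = [
        i
        for i, g in enumerate(cand)
        if low[i] and g.start < call.end and call.start < g.end
    ]
    if not inside:
        logger.info(
            "refine_borders: no low-coverage gene inside %s:[%d, %d); call unchanged",
            call.chromosome,
            call.start,
            call.end,
        )
        return call
    first = inside[0]
    while first > 0 and low[first - 1]:
        first -= 1
    last = inside[-1]
    while last + 1 < len(cand) and low[last + 1]:
        last += 1
    return replace(
        call,
        start=cand[first].start,
        end=cand[last].end,
        method="refined",
        flank_upstream=cand[first - 1].gene_id if first > 0 else None,
        flank_downstream=cand[last + 1].gene_id if last + 1 < len(cand) else None,
        flags=set(call.flags),
    )


def gene_content(call: DeletionCall, genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Genes overlapping the call by >= 1 bp (half-open), each counted once."""
    return [g for g in genes if g.start < call.end and call.start < g.end]


def intersect_homoeologues(
    genesA: Sequence[GeneModel],
    genesB: Sequence[GeneModel],
    homoeology: HomoeologyMap,
) -> list[tuple[GeneModel, GeneModel]]:
    """Greedy one-to-one pairing of homoeologous genes across two gene lists.

    Genes are taken in coordinate order; each gene enters at most one pair
    (an A gene related to several B genes pairs with the first unused B gene
    by coordinate).
    """
    order_a = sorted(genesA, key=lambda g: (g.chromosome, g.start, g.end))
    order_b = sorted(genesB, key=lambda g: (g.chromosome, g.start, g.end))
    used_b: set[str] = set()
    pairs: list[tuple[GeneModel, GeneModel]] = []
    for a in order_a:
        for b in order_b:
            if b.gene_id in used_b:
                continue
            if homoeology.related(a.gene_id, b.gene_id):
                pairs.append((a, b))
                used_b.add(b.gene_id)
                break
    return pairs


def calls_to_frame(calls: Sequence[DeletionCall]) -> pd.DataFrame:
    """Tabular view mirroring the reported deletion table columns."""
    return pd.DataFrame(
        {
            "line_id": [c.line_id for c in calls],
            "chrom": [c.chromosome for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "size_bp": [c.size for c in calls],
            "n_low_bins": [c.n_low_bins for c in calls],
            "method": [c.method for c in calls],
            "flags": [";".join(sorted(c.flags)) for c in calls],
        }
    )
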