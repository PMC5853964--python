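"""Binned read-depth profiles and their normalization.

Exome-capture coverage is highly probe-dependent, so a mutant line's read
depth is only interpretable relative to a wild-type line captured with the
same probe set.  The workflow here is:

1. count retained alignments in fixed-width bins (default 1 Mb) along each
   chromosome (``bin_alignments``),
2. normalize each bin within-line (divide by the line's total retained reads)
   and then to the wild-type line (``normalize_coverage``),
3. optionally lift bins or calls from split "parts" pseudomolecules to
   full-chromosome coordinates (``lift_parts_to_full``).

All coordinates are 0-based, half-open ``[start, end)``.  Bins where the
wild-type count is zero (no capture probes) are masked with NaN rather than
set to zero, so they can never imitate a deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MASKED = float("nan")

COVERAGE_COLUMNS = ["chrom", "start", "end", "count"]
NORMALIZED_COLUMNS = ["chrom", "start", "end", "value"]


@dataclass(frozen=True)
class ReadPlacement:
    """A single placed read: chromosome, 0-based start, MAPQ, and a flag that
    is True only for primary alignments mapped in a proper pair."""

    chromosome: str
    position: int
    mapq: int
    proper_pair_and_primary: bool = True

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if self.mapq < 0:
            raise ValueError(f"negative MAPQ {self.mapq}")


@dataclass
class CallerParams:
    """Thresholds of the deletion-calling workflow.

    low_fraction
        A bin is "low" when its normalized value is <= this fraction of the
        wild type (default 0.1, i.e. <=10% of wild-type depth).
    min_low_run
        Minimum number of adjacent low bins to open a deletion (default 4).
    min_high_run_to_terminate
        Number of adjacent high bins required to close a deletion (default 4).
    mapq_min
        Minimum mapping quality for a read to be counted (default 30).
    bin_size
        Bin width in bp (default 1,000,000).
    smoothing_window
        Moving-average window used for plots only, never for calling.
    residual_in_deletion
        Residual capture fraction inside a deletion assumed by the synthetic
        generator (trace off-target signal), default 0.02.
    """

    low_fraction: float = 0.1
    min_low_run: int = 4
    min_high_run_to_terminate: int = 4
    mapq_min: int = 30
    bin_size: int = 1_000_000
    smoothing_window: int = 4
    residual_in_deletion: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.low_fraction < 1:
            raise ValueError("low_fraction must be in (0, 1)")
        if self.min_low_run < 1 or self.min_high_run_to_terminate < 1:
            raise ValueError("run lengths must be >= 1")
        if self.bin_size < 1:
            raise ValueError("bin_size must be positive")
        if not 0 <= self.residual_in_deletion < 1:
            raise ValueError("residual_in_deletion must be in [0, 1)")


@dataclass
class BinnedCoverage:
    """Per-bin raw read counts for one line.

    ``df`` has columns (chrom, start, end, count); bins are contiguous and
    non-overlapping within a chromosome, in coordinate order.  Only the final
    bin of a chromosome part may be shorter than ``bin_size``.
    """

    line_id: str
    bin_size: int
    df: pd.DataFrame
    total_reads: int = -1

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if self.total_reads < 0:
            self.total_reads = int(self.df["count"].sum())
        if (self.df["count"] < 0).any():
            raise ValueError("negative bin count")

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def counts(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "count"].to_numpy()


@dataclass
class NormalizedCoverage:
    """Per-bin mutant/wild-type depth ratios; NaN marks masked bins."""

    line_id: str
    reference_line_id: str
    bin_size: int
    df: pd.DataFrame  # chrom, start, end, value

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def values(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "value"].to_numpy()

    def bins(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom].reset_index(drop=True)


@dataclass
class PartsMap:
    """Mapping from split "parts" pseudomolecules to full chromosomes.

    Each row relates (part1_id, part2_id) -> full_id with the length of part 1
    in bp; part-2 coordinates shift by that length on lifting.
    """

    df: pd.DataFrame  # part1_id, part2_id, full_id, part1_length

    def __post_init__(self) -> None:
        if (self.df["part1_length"] <= 0).any():
            raise ValueError("part1_length must be positive")
        ids = pd.concat([self.df["part1_id"], self.df["part2_id"]])
        if ids.duplicated().any():
            raise ValueError("a part id maps to more than one full chromosome")

    def lookup(self, part_id: str) -> tuple[str, int]:
        """Return (full_id, offset) for a part id; offset is 0 for part 1."""
        hit = self.df[self.df["part1_id"] == part_id]
        if len(hit):
            return str(hit["full_id"].iloc[0]), 0
        hit = self.df[self.df["part2_id"] == part_id]
        if len(hit):
            return str(hit["full_id"].iloc[0]), int(hit["part1_length"].iloc[0])
        raise KeyError(f"unknown part id {part_id!r}")

    def split_point(self, full_id: str) -> tuple[str, str, int]:
        hit = self.df[self.df["full_id"] == full_id]
        if not len(hit):
            raise KeyError(f"unknown full chromosome {full_id!r}")
        row = hit.iloc[0]
        return str(row["part1_id"]), str(row["part2_id"]), int(row["part1_length"])


def make_bins(length: int, bin_size: int, offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges covering [0, length): full-width bins plus a short final bin.

    ``offset`` shifts all coordinates (used when expressing part-2 bins in
    full-chromosome coordinates).
    """
    if length <= 0:
        raise ValueError("chromosome length must be positive")
    n = math.ceil(length / bin_size)
    starts = np.arange(n, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, length)
    return starts + offset, ends + offset


def bin_alignments(
    placements: Iterable[ReadPlacement],
    params: CallerParams,
    chromosome_lengths: Mapping[str, int],
    line_id: str = "line",
) -> BinnedCoverage:
    """Count retained alignments in fixed-width bins by start position.

    A placement is retained when ``mapq >= params.mapq_min`` and it is a
    primary alignment in a proper pair; each retained placement increments
    exactly one bin, the half-open bin containing its start.  ``total_reads``
    is the retained count, so downstream normalization and filtering act on
    the same read universe.
    """
    counts: dict[str, np.ndarray] = {}
    n_bins = {
        chrom: math.ceil(length / params.bin_size)
        for chrom, length in chromosome_lengths.items()
    }
    total = 0
    for p in placements:
        if p.chromosome not in chromosome_lengths:
            raise KeyError(f"chromosome {p.chromosome!r} missing from length table")
        if p.position >= chromosome_lengths[p.chromosome]:
            raise ValueError(
                f"placement beyond chromosome end: {p.chromosome}:{p.position} "
                f">= {chromosome_lengths[p.chromosome]}"
            )
        if p.mapq < params.mapq_min or not p.proper_pair_and_primary:
            continue
        arr = counts.setdefault(p.chromosome, np.zeros(n_bins[p.chromosome], dtype=np.int64))
        arr[p.position // params.bin_size] += 1
        total += 1

    frames = []
    for chrom, length in chromosome_lengths.items():
        starts, ends = make_bins(length, params.bin_size)
        arr = counts.get(chrom, np.zeros(n_bins[chrom], dtype=np.int64))
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "count": arr})
        )
    df = pd.concat(frames, ignore_index=True)
    return BinnedCoverage(line_id=line_id, bin_size=params.bin_size, df=df, total_reads=total)


def _check_same_structure(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b):
        raise ValueError(f"bin structures differ in length: {len(a)} vs {len(b)}")
    same = (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy())
        & (a["start"].to_numpy() == b["start"].to_numpy())
        & (a["end"].to_numpy() == b["end"].to_numpy())
    )
    if not same.all():
        i = int(np.argmin(same))
        raise ValueError(
            "bin structures differ first at index "
            f"{i}: {a.iloc[i][['chrom', 'start', 'end']].tolist()} vs "
            f"{b.iloc[i][['chrom', 'start', 'end']].tolist()}"
        )


def normalize_coverage(mutant: BinnedCoverage, reference: BinnedCoverage) -> NormalizedCoverage:
    """Two-step normalization: within-line totals, then ratio to wild type.

    value = (mutant_count / mutant_total) / (reference_count / reference_total).
    Bins with reference count 0 are masked (NaN): there is no capture signal
    to compare against and they must not imitate deletions.
    """
    _check_same_structure(mutant.df, reference.df)
    if mutant.total_reads <= 0 or reference.total_reads <= 0:
        raise ValueError("both lines must have total_reads > 0")
    m = mutant.df["count"].to_numpy(dtype=float) / mutant.total_reads
    r = reference.df["count"].to_numpy(dtype=float) / reference.total_reads
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(r > 0, m / np.where(r > 0, r, 1.0), MASKED)
    df = mutant.df[["chrom", "start", "end"]].copy()
    df["value"] = value
    return NormalizedCoverage(
        line_id=mutant.line_id,
        reference_line_id=reference.line_id,
        bin_size=mutant.bin_size,
        df=df,
    )


def lift_parts_to_full(obj, parts: PartsMap, inverse: bool = False):
    """Convert coverage (or any chrom/start/end table) between parts and full
    pseudomolecule coordinates.

    Forward: part-1 coordinates are unchanged, part-2 coordinates shift by
    part1_length, and part-1's short terminal bin is retained, so bins on the
    second half sit at offsets from multiples of the bin size.  ``inverse``
    undoes the transform (lift is a bijection on coordinates).
    """
    if isinstance(obj, BinnedCoverage):
        df = _lift_df(obj.df, parts, inverse)
        return BinnedCoverage(obj.line_id, obj.bin_size, df, total_reads=obj.total_reads)
    if isinstance(obj, NormalizedCoverage):
        df = _lift_df(obj.df, parts, inverse)
        return NormalizedCoverage(obj.line_id, obj.reference_line_id, obj.bin_size, df)
    if isinstance(obj, pd.DataFrame):
        return _lift_df(obj, parts, inverse)
    raise TypeError(f"cannot lift object of type {type(obj).__name__}")


def _lift_df(df: pd.DataFrame, parts: PartsMap, inverse: bool) -> pd.DataFrame:
    if inverse:
        return _lift_df_inverse(df, parts)
    out = []
    for chrom in dict.fromkeys(df["chrom"]):
        sub = df[df["chrom"] == chrom].copy()
        try:
            full_id, offset = parts.lookup(str(chrom))
        except KeyError:
            out.append(sub)  # already a full chromosome (no parts entry)
            continue
        sub["chrom"] = full_id
        sub["start"] = sub["start"] + offset
        sub["end"] = sub["end"] + offset
        out.append(sub)
    merged = pd.concat(out, ignore_index=True)
    # keep original order within chromosome; part1 precedes part2 because its
    # lifted coordinates are smaller
    merged = merged.sort_values(
        ["chrom", "start"], kind="stable", key=lambda s: s
    ).reset_index(drop=True)
    return merged


def _lift_df_inverse(df: pd.DataFrame, parts: PartsMap) -> pd.DataFrame:
    out = []
    for chrom in dict.fromkeys(df["chrom"]):
        sub = df[df["chrom"] == chrom]
        try:
            p1, p2, split = parts.split_point(str(chrom))
        except KeyError:
            out.append(sub.copy())
            continue
        first = sub[sub["start"] < split].copy()
        second = sub[sub["start"] >= split].copy()
        first["chrom"] = p1
        second["chrom"] = p2
        second["start"] = second["start"] - split
        second["end"] = second["end"] - split
        out.extend([first, second])
    return pd.concat(out, ignore_index=True)


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Window-start-aligned moving average, for plotting only.

    Output length is ``len(values) - window + 1``; element i is the mean of
    inputs i..i+window-1.  Masked (NaN) bins are excluded from each window's
    mean; a window of only masked bins yields a masked output.
    """
    arr = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if arr.size < window:
        raise ValueError(f"sequence of length {arr.size} shorter than window {window}")
    n_out = arr.size - window + 1
    out = np.empty(n_out)
    for i in range(n_out):
        w = arr[i : i + window]
        good = ~np.isnan(w)
        out[i] = w[good].mean() if good.any() else MASKED
    return out
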