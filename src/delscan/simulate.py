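"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is deterministic given its seed and emits a machine-readable
truth table, so each downstream stage can be scored without re-deriving
truth.

The coverage generator emulates exome-capture depth: each bin has a capture
efficiency drawn once and shared between the mutant and wild-type lines
(probe-dependent enrichment), read counts are Poisson around the
efficiency-scaled mean, and bins inside a planted deletion retain a small
residual fraction of signal (trace off-target capture) rather than dropping
to exactly zero.  The granule generator renders filled discs in two
lognormal size classes whose mean areas sit near those measured for small
(~24 µm²) and large (~300 µm²) wheat starch granules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import GeneModel, HomoeologyMap
from .coverage import BinnedCoverage, CallerParams, PartsMap, make_bins
from .genotyping import Marker, MarkerObservation
from .granules import Micrograph


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: id, length (bp), and, when assembled as two "parts"
    scaffolds, the length of part 1."""

    id: str
    length: int
    part1_length: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.id}: length must be positive")
        if self.part1_length is not None and not 0 < self.part1_length < self.length:
            raise ValueError(f"{self.id}: part1_length outside (0, length)")


@dataclass
class GenomeSpec:
    """Chromosome layout plus the planted deletions of one mutant line
    (full-chromosome coordinates, 0-based half-open)."""

    chromosomes: list[ChromosomeSpec]
    deletions: list[tuple[str, int, int]] = field(default_factory=list)
    line_id: str = "mutant"

    def __post_init__(self) -> None:
        lengths = {c.id: c.length for c in self.chromosomes}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.deletions:
            if chrom not in lengths:
                raise ValueError(f"deletion on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= lengths[chrom]:
                raise ValueError(f"deletion [{start}, {end}) outside {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping deletions on {chrom}")

    def chromosome(self, chrom: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.id == chrom:
                return c
        raise KeyError(chrom)

    def deletions_on(self, chrom: str) -> list[tuple[int, int]]:
        return sorted((s, e) for c, s, e in self.deletions if c == chrom)


@dataclass
class CoverageSimParams:
    """Exome-capture depth model: mean_reads_per_bin is the expected count in
    a fully covered bin at efficiency 1; capture_efficiency_sd is the sigma
    of the shared per-bin lognormal efficiency; residual_in_deletion is the
    off-target fraction retained inside deletions."""

    mean_reads_per_bin: float = 100.0
    capture_efficiency_sd: float = 0.3
    residual_in_deletion: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_reads_per_bin <= 0:
            raise ValueError("mean_reads_per_bin must be positive")
        if self.capture_efficiency_sd < 0:
            raise ValueError("capture_efficiency_sd must be >= 0")
        if not 0 <= self.residual_in_deletion < 1:
            raise ValueError("residual_in_deletion must be in [0, 1)")


def bin_grid(spec: GenomeSpec, bin_size: int = 1_000_000) -> pd.DataFrame:
    """Full-coordinate bin grid honoring the parts structure: each part gets
    its own grid (short terminal bin), so part-2 bins sit at offsets from
    multiples of the bin size — exactly the grid produced by binning parts
    pseudomolecules and lifting."""
    frames = []
    for c in spec.chromosomes:
        if c.part1_length is None:
            starts, ends = make_bins(c.length, bin_size)
        else:
            s1, e1 = make_bins(c.part1_length, bin_size)
            s2, e2 = make_bins(c.length - c.part1_length, bin_size, offset=c.part1_length)
            starts = np.concatenate([s1, s2])
            ends = np.concatenate([e1, e2])
        frames.append(pd.DataFrame({"chrom": c.id, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def make_parts_map(spec: GenomeSpec) -> PartsMap:
    """PartsMap for the split chromosomes of a genome spec (ids get
    ``_part1``/``_part2`` suffixes)."""
    rows = [
        {
            "part1_id": f"{c.id}_part1",
            "part2_id": f"{c.id}_part2",
            "full_id": c.id,
            "part1_length": c.part1_length,
        }
        for c in spec.chromosomes
        if c.part1_length is not None
    ]
    if not rows:
        raise ValueError("no split chromosomes in spec")
    return PartsMap(pd.DataFrame(rows))


def _deleted_fraction(starts: np.ndarray, ends: np.ndarray, deletions) -> np.ndarray:
    """Per-bin fraction of the bin overlapped by planted deletions."""
    frac = np.zeros(len(starts))
    widths = (ends - starts).astype(float)
    for d_start, d_end in deletions:
        overlap = np.minimum(ends, d_end) - np.maximum(starts, d_start)
        frac += np.clip(overlap, 0, None) / widths
    return np.clip(frac, 0.0, 1.0)


def simulate_coverage_pair(
    spec: GenomeSpec,
    params: CoverageSimParams,
    bin_size: int = 1_000_000,
    wildtype_id: str = "wildtype",
    coordinates: str = "full",
) -> tuple[BinnedCoverage, BinnedCoverage, pd.DataFrame]:
    """Paired mutant / wild-type binned coverage with planted deletions.

    Per bin, one capture-efficiency factor e ~ lognormal(0, sd) is drawn and
    shared by both lines; the wild-type count is Poisson(mean x e) and the
    mutant count Poisson(mean x e x r), where r interpolates between 1
    (outside deletions) and ``residual_in_deletion`` (bin fully inside a
    deletion) by the overlapped fraction.  ``coordinates="parts"`` expresses
    the output on the parts pseudomolecules instead (split chromosomes get
    ``_part1``/``_part2`` ids).

    Returns (mutant, wildtype, truth) where truth lists the planted intervals.
    """
    rng = np.random.default_rng(params.seed)
    grid = bin_grid(spec, bin_size)
    n = len(grid)
    eff = rng.lognormal(mean=0.0, sigma=params.capture_efficiency_sd, size=n)
    lam = params.mean_reads_per_bin * eff

    frac = np.concatenate(
        [
            _deleted_fraction(
                grid.loc[grid["chrom"] == c.id, "start"].to_numpy(),
                grid.loc[grid["chrom"] == c.id, "end"].to_numpy(),
                spec.deletions_on(c.id),
            )
            for c in spec.chromosomes
        ]
    )
    r = 1.0 - frac * (1.0 - params.residual_in_deletion)
    wt_counts = rng.poisson(lam)
    mut_counts = rng.poisson(lam * r)

    wt_df = grid.copy()
    wt_df["count"] = wt_counts
    mut_df = grid.copy()
    mut_df["count"] = mut_counts
    wildtype = BinnedCoverage(line_id=wildtype_id, bin_size=bin_size, df=wt_df)
    mutant = BinnedCoverage(line_id=spec.line_id, bin_size=bin_size, df=mut_df)
    truth = pd.DataFrame(
        [{"line_id": spec.line_id, "chrom": c, "start": s, "end": e} for c, s, e in spec.deletions]
    )
    if coordinates == "parts":
        from .coverage import lift_parts_to_full

        parts = make_parts_map(spec)
        mutant = lift_parts_to_full(mutant, parts, inverse=True)
        wildtype = lift_parts_to_full(wildtype, parts, inverse=True)
    elif coordinates != "full":
        raise ValueError(f"unknown coordinate system {coordinates!r}")
    return mutant, wildtype, truth


def simulate_gene_models(
    spec: GenomeSpec,
    density: float = 1.0,
    homoeology_fraction: float = 0.0,
    seed: int = 0,
    paired_chromosomes: tuple[str, str] | None = None,
    gene_length: int = 3_000,
    residual_value: float = 0.0,
) -> tuple[list[GeneModel], HomoeologyMap, dict[str, float]]:
    """Random non-overlapping gene models with truth coverage values.

    ``density`` is genes per Mb.  When ``paired_chromosomes=(A, B)`` is
    given, a ``homoeology_fraction`` of the genes on A receive a homoeologue
    on B at the proportionally scaled position (identical position when the
    chromosomes have equal length); remaining genes on B are placed
    independently.  Truth coverage for each gene is 1 minus the deleted
    fraction of its extent (scaled down to ``residual_value`` inside planted
    deletions), i.e. a gene fully inside a deletion has value
    ``residual_value``.

    Returns (genes, homoeology map, per-gene truth coverage).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    homoeology = HomoeologyMap()

    def place(chrom: str, length: int, n: int, prefix: str) -> list[GeneModel]:
        starts = np.sort(rng.integers(0, max(1, length - gene_length), size=n))
        placed = []
        prev_end = -1
        for i, s in enumerate(starts):
            s = max(int(s), prev_end + 1)
            e = s + gene_length
            if e > length:
                break
            placed.append(GeneModel(f"{prefix}{i + 1:04d}", chrom, s, e))
            prev_end = e
        return placed

    pair_a, pair_b = paired_chromosomes if paired_chromosomes else (None, None)
    for c in spec.chromosomes:
        if c.id == pair_b and pair_a is not None:
            continue  # generated from its partner below
        n = round(c.length / 1e6 * density)
        chrom_genes = place(c.id, c.length, n, f"G{c.id}_")
        genes.extend(chrom_genes)
        if c.id == pair_a and pair_b is not None:
            partner = spec.chromosome(pair_b)
            ratio = partner.length / c.length
            n_paired = round(len(chrom_genes) * homoeology_fraction)
            paired_idx = rng.choice(len(chrom_genes), size=n_paired, replace=False)
            for j, gi in enumerate(sorted(paired_idx)):
                g = chrom_genes[gi]
                s = min(int(round(g.start * ratio)), partner.length - gene_length)
                b_gene = GeneModel(f"G{pair_b}_h{j + 1:04d}", pair_b, s, s + gene_length)
                genes.append(b_gene)
                homoeology.add(g.gene_id, b_gene.gene_id)
            # independent unpaired genes on the partner chromosome
            n_extra = round(partner.length / 1e6 * density) - n_paired
            if n_extra > 0:
                genes.extend(place(pair_b, partner.length, n_extra, f"G{pair_b}_u"))

    values: dict[str, float] = {}
    for g in genes:
        frac = _deleted_fraction(
            np.array([g.start]), np.array([g.end]), spec.deletions_on(g.chromosome)
        )[0]
        values[g.gene_id] = 1.0 - frac * (1.0 - residual_value)
    return genes, homoeology, values


def simulate_marker_table(
    spec: GenomeSpec,
    panel: list[Marker],
    chromosome: str,
    faint_rate: float = 0.0,
    seed: int = 0,
    plant_id: str = "plant1",
) -> list[MarkerObservation]:
    """Dominant-marker screen of one plant against the planted deletions.

    A marker is absent exactly when its position falls inside a planted
    deletion on the given chromosome; with probability ``faint_rate`` an
    absent marker is reported as a faint band instead (same putative-deletion
    interpretation, lower confidence).
    """
    rng = np.random.default_rng(seed)
    length = spec.chromosome(chromosome).length
    deletions = spec.deletions_on(chromosome)
    observations = []
    for m in panel:
        if m.position is None:
            raise ValueError(f"marker {m.marker_id} has no position")
        if not 0 <= m.position < length:
            raise ValueError(f"marker {m.marker_id} outside {chromosome}")
        deleted = any(s <= m.position < e for s, e in deletions)
        if deleted:
            call = "faint" if rng.random() < faint_rate else "absent"
        else:
            call = "present"
        observations.append(MarkerObservation(plant_id=plant_id, marker_id=m.marker_id, call=call))
    return observations


def simulate_granule_image(
    n_granules: int,
    small_fraction: float,
    small_diameter_dist: tuple[float, float] = (5.2, 0.25),  # lognormal median µm, sigma
    large_diameter_dist: tuple[float, float] = (18.4, 0.25),
    overlap_fraction: float = 0.0,
    scale: float = 0.5,  # µm per pixel
    seed: int = 0,
    canvas_shape: tuple[int, int] | None = None,
    image_id: str = "synthetic",
) -> tuple[Micrograph, pd.DataFrame]:
    """Render a synthetic micrograph of starch granules with known truth.

    Granules are filled dark discs on a light background (iodine-stained
    starch in bright field) with mild optical blur and Gaussian pixel noise.
    Exactly ``round(n_granules x small_fraction)`` granules are drawn from
    the small-diameter lognormal and the rest from the large one, so the
    planted composition is exact.  A fraction ``overlap_fraction`` of the
    granules is placed touching a previously placed granule (moderate
    overlap); all others are strictly separated.  Raises ValueError when the
    requested granules cannot be packed into the canvas.

    Returns (micrograph, truth) with per-granule center, diameter and class.
    """
    if not 0 <= small_fraction <= 1:
        raise ValueError("small_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_small = round(n_granules * small_fraction)
    diam_um = np.concatenate(
        [
            small_diameter_dist[0] * np.exp(rng.normal(0, small_diameter_dist[1], n_small)),
            large_diameter_dist[0] * np.exp(rng.normal(0, large_diameter_dist[1], n_granules - n_small)),
        ]
    )
    classes = np.array(["small"] * n_small + ["large"] * (n_granules - n_small))
    order = rng.permutation(n_granules)
    diam_um, classes = diam_um[order], classes[order]
    radii_px = diam_um / 2.0 / scale

    if canvas_shape is None:
        total_area = float(np.sum(np.pi * radii_px**2))
        side = int(np.ceil(np.sqrt(max(total_area, 1.0) / 0.18))) + 60
        canvas_shape = (side, side)
    h, w = canvas_shape

    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for i, r in enumerate(radii_px):
        if r + 2 >= min(h, w) / 2:
            raise ValueError("canvas too small for requested granules")
        touching = bool(centers) and rng.random() < overlap_fraction
        ok = False
        for _ in range(3000):
            if touching:
                j = rng.integers(len(centers))
                ang = rng.uniform(0, 2 * np.pi)
                d = (r + placed_r[j]) * rng.uniform(0.80, 0.95)
                y = centers[j][0] + d * np.sin(ang)
                x = centers[j][1] + d * np.cos(ang)
                partner = j
            else:
                y = rng.uniform(r + 2, h - r - 2)
                x = rng.uniform(r + 2, w - r - 2)
                partner = -1
            if not (r + 2 <= y <= h - r - 2 and r + 2 <= x <= w - r - 2):
                continue
            clear = True
            for k, ((cy, cx), cr) in enumerate(zip(centers, placed_r)):
                if k == partner:
                    continue
                if (cy - y) ** 2 + (cx - x) ** 2 < (r + cr + 2) ** 2:
                    clear = False
                    break
            if clear:
                centers.append((y, x))
                placed_r.append(float(r))
                ok = True
                break
        if not ok:
            raise ValueError(
                f"canvas too small: could not place granule {i + 1}/{n_granules}"
            )

    img = np.full((h, w), 200.0)
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx), r in zip(centers, placed_r):
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 70.0
    from scipy import ndimage as ndi

    img = ndi.gaussian_filter(img, sigma=0.8)
    img = img + rng.normal(0, 4.0, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "y_px": [c[0] for c in centers],
            "x_px": [c[1] for c in centers],
            "diameter_um": diam_um,
            "area_um2": np.pi * (diam_um / 2.0) ** 2,
            "class": classes,
        }
    )
    return Micrograph(pixels=img, scale=scale, image_id=image_id), truth
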