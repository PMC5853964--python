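"""Interpretation of dominant PCR-marker screens.

Two assay styles are supported: homoeologue-specific markers scored on
agarose gels as present / absent / faint, and a homoeologue-non-specific
multiplex marker whose per-genome products are separated by capillary
electrophoresis.  Both are dominant assays: a product can come from one or
two chromosome copies, so heterozygotes are indistinguishable from wild type
and only homozygous deletions are identifiable.

Marker panels are ordered along the chromosome arm; under the single-
contiguous-deletion assumption the set of deleted markers classifies each
plant into one of a small number of deletion-extent hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

CALLS = ("present", "absent", "faint")
PRODUCT_CALLS = ("present", "absent", "very_small")


@dataclass(frozen=True)
class Marker:
    """One PCR marker: its target subgenome ('A', 'B', 'D', or 'multiplex'),
    the chromosome arm, and its order along that arm."""

    marker_id: str
    genome_specificity: str
    chromosome_arm: str
    order_index: int
    expected_products: tuple[str, ...] = ()
    position: int | None = None  # bp, used by the synthetic screen generator


@dataclass(frozen=True)
class MarkerObservation:
    """One plant x marker gel call, or per-product calls for a multiplex assay."""

    plant_id: str
    marker_id: str
    call: str | None = None
    product_calls: Mapping[str, str] | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.call is not None and self.call.lower() not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class DeletionHypothesis:
    plant_id: str
    arm: str
    classification: str
    deleted_marker_ids: list[str] = field(default_factory=list)
    low_confidence_marker_ids: list[str] = field(default_factory=list)


def interpret_call(observation: MarkerObservation) -> bool:
    """True when the marker is putatively deleted.

    Absence of a PCR product indicates deletion of the target gene; a faint
    band (near absence) is also taken as a putative deletion, but flagged as
    low-confidence evidence.  Case is ignored, so 'Faint' and 'FAINT' are the
    same call.
    """
    if observation.call is None:
        raise ValueError(f"observation for {observation.marker_id} has no gel call")
    call = observation.call.lower()
    if call not in CALLS:
        raise ValueError(f"unknown call {observation.call!r}")
    return call in ("absent", "faint")


def infer_deletion_extent(
    panel: Sequence[Marker],
    observations: Sequence[MarkerObservation],
    anchor_marker: str,
) -> DeletionHypothesis:
    """Classify a plant's deletion extent from an ordered marker panel.

    The anchor marker is the panel's reference locus nearest the region of
    interest.  Under the assumption of a single contiguous deletion:

    - every marker deleted        -> ``spans_all_markers``
    - all deleted except anchor   -> ``distal_not_including_anchor``
    - only the anchor deleted     -> ``anchor_only``
    - none deleted                -> ``no_deletion``
    - other contiguous block      -> ``interstitial``
    - non-contiguous deletions    -> ``inconsistent`` (contiguity violated)

    Observation input order is irrelevant; the panel order governs contiguity.
    """
    ordered = sorted(panel, key=lambda m: m.order_index)
    obs_by_marker = {o.marker_id: o for o in observations}
    missing = [m.marker_id for m in ordered if m.marker_id not in obs_by_marker]
    if missing:
        raise ValueError(f"missing observation for marker(s): {', '.join(missing)}")
    if anchor_marker not in {m.marker_id for m in ordered}:
        raise ValueError(f"anchor marker {anchor_marker!r} not in panel")

    plant_ids = {o.plant_id for o in observations}
    if len(plant_ids) != 1:
        raise ValueError(f"observations span several plants: {sorted(plant_ids)}")
    (plant_id,) = plant_ids

    deleted_flags = [interpret_call(obs_by_marker[m.marker_id]) for m in ordered]
    deleted = [m.marker_id for m, d in zip(ordered, deleted_flags) if d]
    faint = [
        m.marker_id
        for m in ordered
        if obs_by_marker[m.marker_id].call.lower() == "faint"
    ]

    positions = [i for i, d in enumerate(deleted_flags) if d]
    contiguous = not positions or positions[-1] - positions[0] + 1 == len(positions)
    anchor_set = {anchor_marker}

    if not deleted:
        cls = "no_deletion"
    elif len(deleted) == len(ordered):
        cls = "spans_all_markers"
    elif set(deleted) == {m.marker_id for m in ordered} - anchor_set:
        cls = "distal_not_including_anchor"
    elif set(deleted) == anchor_set:
        cls = "anchor_only"
    elif contiguous:
        cls = "interstitial"
    else:
        cls = "inconsistent"

    return DeletionHypothesis(
        plant_id=plant_id,
        arm=ordered[0].chromosome_arm,
        classification=cls,
        deleted_marker_ids=deleted,
        low_confidence_marker_ids=faint,
    )


@dataclass
class MultiplexGenotype:
    plant_id: str
    genome_deleted: dict  # e.g. {"A": True, "B": False, "D": True}
    double_mutant: bool
    note: str = "homozygous states only (dominant marker)"


def classify_peaks(
    heights: Mapping[str, float], relative_threshold: float = 0.2
) -> dict[str, str]:
    """Convert capillary peak heights to per-product calls.

    A product is 'absent' at height 0 and 'very_small' when its height is
    below ``relative_threshold`` times the median of the nonzero peaks; the
    threshold is a stated convention for "very small relative to the others".
    """
    import statistics

    nonzero = [h for h in heights.values() if h > 0]
    median = statistics.median(nonzero) if nonzero else 0.0
    calls = {}
    for product, h in heights.items():
        if h <= 0:
            calls[product] = "absent"
        elif median > 0 and h < relative_threshold * median:
            calls[product] = "very_small"
        else:
            calls[product] = "present"
    return calls


def genotype_multiplex(
    observation: MarkerObservation,
    a_products: tuple[str, str] = ("A1", "A2"),
    b_product: str = "B",
    d_product: str = "D",
) -> MultiplexGenotype:
    """Per-genome deletion status from one multiplex observation.

    The A genome carries two copies of the target gene, so it is called
    deleted only when both A products are absent or very small; the B and D
    genomes each have a single product.  ``double_mutant`` is True when both
    the A and D genomes are deleted.  As a dominant assay this reports
    homozygous deletions only — no heterozygous state is ever emitted.
    """
    if observation.product_calls is None:
        raise ValueError("multiplex observation requires product_calls")
    calls = {k: v.lower() for k, v in observation.product_calls.items()}
    required = (*a_products, b_product, d_product)
    missing = [p for p in required if p not in calls]
    if missing:
        raise ValueError(f"missing product channel(s): {', '.join(missing)}")
    for product, c in calls.items():
        if c not in PRODUCT_CALLS:
            raise ValueError(f"unknown product call {c!r} for {product}")

    def gone(product: str) -> bool:
        return calls[product] in ("absent", "very_small")

    a_del = all(gone(p) for p in a_products)
    b_del = gone(b_product)
    d_del = gone(d_product)
    return MultiplexGenotype(
        plant_id=observation.plant_id,
        genome_deleted={"A": a_del, "B": b_del, "D": d_del},
        double_mutant=a_del and d_del,
    )
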