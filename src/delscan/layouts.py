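"""Published study layouts: deletion tables, marker panels, and screen calls.

These constants transcribe the study's printed inputs so the pipeline can be
exercised end-to-end without any external download: the bin-resolution
deletion intervals of mutant lines A1 and D4 (reported against the wheat
RefSeq v1.0 assembly), the dominant marker panels for chromosome arms 4AL
and 4DS, and the 19-plant screening table.

Chromosome lengths are the approximate RefSeq v1.0 pseudomolecule lengths;
where a deletion ends at a chromosome end the printed end coordinate fixes
the length exactly (1B: 689,851,870; 4B: 673,617,499).  Part-1 lengths of
the split "parts" scaffolds are chosen to reproduce the printed deletion
coordinates on the lifted bin grid: bins on the second half of a chromosome
are offset from 1 Mb multiples by part1_length mod 1 Mb (555,092 on 4A;
720,154 on 1B; 14,251 on 4B).
"""

from __future__ import annotations

from .genotyping import Marker, MarkerObservation
from .simulate import ChromosomeSpec, GenomeSpec

BIN_SIZE = 1_000_000

CHROMOSOMES = {
    "Chr1A": ChromosomeSpec("Chr1A", 594_102_056),
    "Chr1B": ChromosomeSpec("Chr1B", 689_851_870, part1_length=430_720_154),
    "Chr4A": ChromosomeSpec("Chr4A", 744_588_157, part1_length=445_555_092),
    "Chr4B": ChromosomeSpec("Chr4B", 673_617_499, part1_length=450_014_251),
    "Chr4D": ChromosomeSpec("Chr4D", 509_857_067),
    "Chr5D": ChromosomeSpec("Chr5D", 566_080_677),
    "Chr6A": ChromosomeSpec("Chr6A", 618_079_260),
    "Chr6B": ChromosomeSpec("Chr6B", 720_988_478),
    "Chr6D": ChromosomeSpec("Chr6D", 473_592_718),
    "Chr7A": ChromosomeSpec("Chr7A", 736_706_236),
}

# Bin-resolution deletion intervals (0-based half-open; size = end - start).
LINE_A1_DELETIONS = [
    ("Chr1B", 182_000_000, 190_000_000),
    ("Chr4A", 576_555_092, 600_555_092),
    ("Chr5D", 422_000_000, 440_000_000),
    ("Chr6A", 262_000_000, 274_000_000),
]

LINE_D4_DELETIONS = [
    ("Chr1A", 105_000_000, 110_000_000),
    ("Chr1B", 640_720_154, 689_851_870),
    ("Chr4B", 563_014_251, 673_617_499),
    ("Chr4D", 0, 21_000_000),
    ("Chr6D", 177_000_000, 181_000_000),
    ("Chr7A", 332_000_000, 336_000_000),
]

# Gene-refined intervals for the same deletions.
LINE_A1_REFINED = [
    ("Chr1B", 181_218_604, 190_284_536),
    ("Chr4A", 576_167_498, 601_039_825),
    ("Chr5D", 421_138_884, 441_103_787),
    ("Chr6A", 260_435_891, 276_294_537),
]

LINE_D4_REFINED = [
    ("Chr1A", 104_949_904, 110_279_278),
    ("Chr1B", 640_164_065, 689_851_870),
    ("Chr4B", 562_939_364, 673_617_499),
    ("Chr4D", 0, 21_516_171),
    ("Chr6D", 176_481_122, 181_405_837),
    ("Chr7A", 330_452_708, 336_755_079),
]

# Low-coverage artifact shared by independent mutants: a polymorphism between
# the background variety and the reference assembly misaligns reads on 6B
# near 260 Mb in every line; it is not an irradiation-induced deletion.
SHARED_6B_ARTIFACT = ("Chr6B", 258_000_000, 262_000_000)


def _spec(line_id: str, deletions, chroms=None) -> GenomeSpec:
    used = chroms or sorted({c for c, _, _ in deletions})
    return GenomeSpec(
        chromosomes=[CHROMOSOMES[c] for c in used],
        deletions=list(deletions),
        line_id=line_id,
    )


def line_a1_spec(include_6b_artifact: bool = False) -> GenomeSpec:
    dels = LINE_A1_DELETIONS + ([SHARED_6B_ARTIFACT] if include_6b_artifact else [])
    return _spec("A1", dels)


def line_d4_spec(include_6b_artifact: bool = False) -> GenomeSpec:
    dels = LINE_D4_DELETIONS + ([SHARED_6B_ARTIFACT] if include_6b_artifact else [])
    return _spec("D4", dels)


ANCHOR_MARKER = "4G"

# Markers ordered along each arm; positions (bp, full coordinates) are a
# synthetic convention for the screen generator: the 4AL distal markers sit
# inside the A1 group-4 deletion with 4G just outside it.
PANEL_4AL = [
    Marker("TC37b", "A", "4AL", 0, position=580_000_000),
    Marker("KT71", "A", "4AL", 1, position=585_000_000),
    Marker("TC30b", "A", "4AL", 2, position=590_000_000),
    Marker("TC34", "A", "4AL", 3, position=595_000_000),
    Marker("4G", "A", "4AL", 4, position=601_500_000),
]

PANEL_4DS = [
    Marker("TC37b", "D", "4DS", 0, position=5_000_000),
    Marker("KT71", "D", "4DS", 1, position=9_000_000),
    Marker("TC30b", "D", "4DS", 2, position=13_000_000),
    Marker("TC34", "D", "4DS", 3, position=17_000_000),
    Marker("4G", "D", "4DS", 4, position=20_500_000),
    Marker("4N5.5", "D", "4DS", 5, position=22_500_000),
]

KT71_MULTIPLEX = Marker(
    "KT71", "multiplex", "4AL/4BS/4DS", 0, expected_products=("A1", "A2", "B", "D")
)

# The published screening table: one row per plant, gel calls per marker.
# "NA" = no homoeologue exists on that genome; "ND" = not determined.
MARKER_ORDER = ["TC37b", "KT71", "TC30b", "TC34", "4G", "4N5.5"]

SCREEN_TABLE = [
    ("4AL", "A1", 1, ["-", "-", "-", "-", "+", "NA"]),
    ("4AL", "A1", 2, ["Faint", "-", "Faint", "-", "+", "NA"]),
    ("4AL", "A2", 1, ["-", "-", "-", "-", "-", "NA"]),
    ("4AL", "A2", 2, ["Faint", "-", "-", "-", "-", "NA"]),
    ("4AL", "A2", 3, ["-", "-", "Faint", "-", "-", "NA"]),
    ("4AL", "A2", 4, ["-", "-", "-", "-", "-", "NA"]),
    ("4AL", "A3", 1, ["-", "-", "-", "-", "-", "NA"]),
    ("4AL", "A3", 2, ["-", "-", "-", "-", "-", "NA"]),
    ("4DS", "D1", 1, ["-", "-", "Faint", "-", "+", "ND"]),
    ("4DS", "D1", 2, ["-", "-", "Faint", "-", "+", "ND"]),
    ("4DS", "D2", 1, ["-", "-", "-", "-", "+", "ND"]),
    ("4DS", "D3", 1, ["-", "-", "-", "-", "-", "-"]),
    ("4DS", "D4", 1, ["-", "-", "-", "-", "-", "-"]),
    ("4DS", "D4", 2, ["-", "-", "-", "-", "-", "-"]),
    ("4DS", "D4", 3, ["-", "-", "-", "-", "-", "-"]),
    ("4DS", "D4", 4, ["FAINT", "-", "-", "-", "-", "-"]),
    ("4DS", "D5", 1, ["+", "+", "+", "+", "-", "+"]),
    ("4DS", "D5", 2, ["+", "+", "+", "+", "-", "+"]),
    ("4DS", "D5", 3, ["+", "+", "+", "+", "-", "+"]),
]

# Deletion-extent class of each line as reported in the study's narrative.
EXPECTED_CLASS_BY_LINE = {
    "A1": "distal_not_including_anchor",
    "A2": "spans_all_markers",
    "A3": "spans_all_markers",
    "D1": "distal_not_including_anchor",
    "D2": "distal_not_including_anchor",
    "D3": "spans_all_markers",
    "D4": "spans_all_markers",
    "D5": "anchor_only",
}

_GEL = {"+": "present", "-": "absent", "faint": "faint"}


def screen_row_observations(row) -> tuple[list[Marker], list[MarkerObservation]]:
    """Panel and observations for one screening-table row.

    Markers scored NA (no homoeologue) or ND (not determined) are dropped
    from that row's panel.  'Faint' and 'FAINT' are the same call.
    """
    arm, line, plant, calls = row
    base = PANEL_4AL if arm == "4AL" else PANEL_4DS
    by_id = {m.marker_id: m for m in base}
    panel, observations = [], []
    plant_id = f"{line}-{plant}"
    for marker_id, call in zip(MARKER_ORDER, calls):
        if call in ("NA", "ND") or marker_id not in by_id:
            continue
        panel.append(by_id[marker_id])
        observations.append(
            MarkerObservation(plant_id=plant_id, marker_id=marker_id, call=_GEL[call.lower()])
        )
    return panel, observations
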