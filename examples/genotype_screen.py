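"""Classify deletion mutants from a dominant PCR-marker screen.

Runs the published 19-plant screening table through the marker
interpretation rules (absent or faint product = putative deletion) and the
ordered-panel extent classifier, then interprets one multiplex
capillary-electrophoresis observation to identify a double mutant.
"""

from delscan import MarkerObservation, genotype_multiplex, infer_deletion_extent
from delscan.layouts import ANCHOR_MARKER, SCREEN_TABLE, screen_row_observations

print("plant        class                         deleted markers")
for row in SCREEN_TABLE:
    panel, obs = screen_row_observations(row)
    hyp = infer_deletion_extent(panel, obs, ANCHOR_MARKER)
    print(f"{row[0]} {hyp.plant_id:7s}  {hyp.classification:28s}  "
          f"{','.join(hyp.deleted_marker_ids) or '-'}")

# The multiplex marker amplifies four products (two A-genome copies, one B,
# one D); a genome is called deleted only when all its products are gone.
obs = MarkerObservation(
    "F2-117", "KT71",
    product_calls={"A1": "absent", "A2": "absent", "B": "present", "D": "absent"},
)
g = genotype_multiplex(obs)
print(f"\nmultiplex {obs.plant_id}: per-genome deleted = {g.genome_deleted}, "
      f"double mutant = {g.double_mutant}")
print("(dominant markers: only homozygous deletions are identifiable)")
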