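"""Discover large deletions in a simulated exome-capture mutant line.

Simulates paired mutant / wild-type binned coverage for the two published
mutant-line layouts (A1 and D4), normalizes the mutant to the wild type, and
applies the run-length deletion caller.  The printed intervals are the
called deletion extents at 1 Mb bin resolution; under the simulation's
default depth they match the planted (published) intervals exactly.
"""

from delscan import CallerParams, call_deletions, calls_to_frame, normalize_coverage
from delscan.layouts import line_a1_spec, line_d4_spec
from delscan.simulate import CoverageSimParams, simulate_coverage_pair

for spec in (line_a1_spec(), line_d4_spec()):
    mutant, wildtype, truth = simulate_coverage_pair(
        spec, CoverageSimParams(mean_reads_per_bin=100, seed=1)
    )
    normalized = normalize_coverage(mutant, wildtype)
    calls = call_deletions(normalized, CallerParams())
    print(f"\nLine {spec.line_id}: {len(calls)} large deletions "
          f"(planted: {len(spec.deletions)})")
    print(calls_to_frame(calls).to_string(index=False))

print(
    "\nEach row is one contiguous block of >=4 adjacent 1 Mb bins at <=10% of"
    "\nwild-type depth; size_bp = end - start at bin resolution."
)
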