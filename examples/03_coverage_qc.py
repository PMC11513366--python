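"""Coverage QC of simulated enrichment reads over the target region.

Recreates the run-statistics block of an enrichment experiment — on-target
read count, read N50, min/mean/max depth and the cumulative coverage curve —
from the simulator's truth intervals. A modest molecule count is used so the
depths resemble a real targeted run rather than a saturated one.
"""

from cas9tiling import (
    DesignConfig,
    FixtureSpec,
    GenomicRegion,
    SimConfig,
    apply_qscore_filter,
    design_tiling,
    make_reference,
    qc_summary,
    simulate_reads,
    truth_intervals,
)
from cas9tiling.coverage_qc import qc_table

ref = make_reference(FixtureSpec(seed=42, length=31133, gc_fraction=0.4))
region = GenomicRegion(ref.name, 0, 31133)
design = design_tiling(ref, region, DesignConfig(flank=0))

reads = simulate_reads(ref, design, SimConfig(n_molecules=60, seed=7))
passed = apply_qscore_filter(reads, 9)

summary = qc_summary(truth_intervals(passed, ref.name), region, thresholds=(1, 20, 60))
print(qc_table(summary).to_string(index=False))
# "% bases >= x20" is the cumulative coverage curve read at depth 20: the
# fraction of the locus sequenced at least 20-fold after Qscore filtering.
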