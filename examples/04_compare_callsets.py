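"""Compare two variant callsets over a locus and classify the variants.

Builds paired synthetic callsets — callset A with 71 variants (9 coding,
59 intronic, 3 in the 3'UTR) playing the enrichment role, callset B with 69
variants playing the orthogonal short-read role, 68 shared — then reports
concordance, the genic category breakdown and the rare/low-quality tallies.
"""

from cas9tiling import (
    CallsetSpec,
    FixtureSpec,
    GenomicRegion,
    TranscriptLayout,
    classify_variant,
    frequency_filter,
    make_callsets,
    make_reference,
    make_transcript,
    match_variants,
    summarize,
)
from cas9tiling.variant_compare import summary_table

ref = make_reference(FixtureSpec(seed=42, length=31133, gc_fraction=0.4))
region = GenomicRegion(ref.name, 0, 31133)
transcript = make_transcript(TranscriptLayout(), region)

spec = CallsetSpec(
    n_total_b=69, n_shared=68, n_only_a=3,
    category_mix={"coding": 9, "intronic": 59, "utr3": 3}, seed=11,
)
a, b = make_callsets(spec, region, transcript)

comparison = match_variants(a, b)
classes = [classify_variant(v, transcript) for v in a]
summary = summarize(classes, a)

print(summary_table(summary, comparison).to_string(index=False))
print(f"\nrare after AF<0.001 filter: {len(frequency_filter(a))}")
# Concordance is the share of the reference callset B recovered by A
# (68/69 = 98.55%); the three A-only calls carry QUAL 4-10, the signature of
# marginal false positives at low coverage.
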