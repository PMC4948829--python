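"""Event-rate arithmetic: from divergence fractions to per-generation rates.

A clone diverges if at least one event hit its lineage in g generations, so
an observed fraction f and a per-generation rate r are linked by
f = 1 - (1-r)**g.  The technical background (PCR/cloning/sequencing) acts as
an independent second layer and can be divided out.
"""

from telodiverge import (
    background_adjusted_fraction,
    compare_fractions,
    divergence_fraction,
    estimate_rate,
    expected_fraction,
)

# forward: the literature rate over ~30 doublings
f = expected_fraction(r=0.003, g=30)
print(f"r=0.3%/telomere/generation, g=30  ->  expected diverged fraction {100*f:.1f}%")

# inverse: an observed fraction back to a rate
r = estimate_rate(f=0.086, g=30)
print(f"observed fraction 8.6%, g=30      ->  rate {100*r:.2f}%/telomere/generation")

# observed counts with an exact binomial CI (3 diverged of 35 clones)
est = divergence_fraction([True] * 3 + [False] * 32, generations=30)
print(
    f"3/35 diverged: f={100*est.fraction:.1f}% "
    f"[95% CI {100*est.ci_low:.1f}-{100*est.ci_high:.1f}], "
    f"r={100*est.per_generation_rate:.2f}%/generation"
)

# correcting for the technical background measured in re-cloning controls
adj = background_adjusted_fraction(f_obs=0.086, f_bg=0.042)
print(f"8.6% observed with a 4.2% technical background -> {100*adj:.2f}% in vivo")

# comparing two divergence (or focus) counts: Fisher's exact test
p = compare_fractions(3, 35, 9, 34)
print(f"3/35 vs 9/34 diverged: two-sided Fisher p = {p:.3f}")
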