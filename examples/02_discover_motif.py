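"""Rediscover a planted palindromic motif by symmetry-constrained EM.

Plants one 18-bp, ~16-bit palindromic site in each of 20 background
regions and runs ZOOPS EM over a width search, then compares the
recovered PWM with the planted one.
"""

import numpy as np

from regulonkit import discover_motif
from regulonkit.comparative import pwm_similarity
from regulonkit.synthetic import _random_dna, make_planted_pwm, sample_site

rng = np.random.default_rng(7)
planted = make_planted_pwm(18, 16.0, "palindrome", rng)
regions = []
for _ in range(20):
    seq = _random_dna(rng, 200, gc=0.40)
    off = int(rng.integers(0, 200 - 18))
    site = sample_site(planted, rng, min_score=0.5 * planted.information_content)
    regions.append(seq[:off] + site + seq[off + 18:])

result = discover_motif(
    regions, width_range=(14, 24), width_step=2,
    symmetry="palindrome", n_restarts=20, seed=7,
)
print(f"planted consensus:   {planted.consensus}  ({planted.information_content:.1f} bits)")
print(f"recovered consensus: {result.pwm.consensus}  ({result.information_content:.1f} bits)")
print(f"selected width: {result.width}   sites found: {len(result.sites)}/20")
print(f"per-column correlation with planted PWM: {pwm_similarity(result.pwm, planted):.3f}")
# A correlation near 1.0 means the EM rebuilt the planted frequency
# matrix almost exactly; the width search settled on the planted 18 bp.
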