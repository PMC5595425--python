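"""False-discovery-rate adjustment and QQ-plot quantities.

Builds a p-value vector with 950 nulls and 50 strong signals, converts
it to q-values, and shows how many true signals the q <= 0.1 rule
recovers and at what realized false-discovery cost.  Also prints the
first rows of the QQ table (expected vs observed -log10 p with 95%
bands) that a genome scan would plot.
"""

import numpy as np

from triopoo import qq_table, qvalues, significant_at

rng = np.random.default_rng(20170912)
p = np.concatenate([rng.uniform(size=950), rng.beta(0.02, 1.0, size=50)])
is_signal = np.arange(p.size) >= 950

q = qvalues(p)
sel = significant_at(q, 0.1)
tp = int((sel & is_signal).sum())
fp = int((sel & ~is_signal).sum())
print(f"selected at q<=0.1: {int(sel.sum())}  (true: {tp}, false: {fp})")
print(f"realized true-positive proportion: {tp / max(sel.sum(), 1):.2%}")

t = qq_table(p)
print("\nQQ table, five smallest p-values (ranks at the top of the plot):")
print(t.head(5).to_string(index=False))
print(
    "\nPoints above band_hi at the high -log10 end are stronger than the\n"
    "null distribution of uniform order statistics allows."
)
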