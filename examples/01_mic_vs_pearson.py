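"""Score the relationship archetypes with MIC and Pearson correlation.

Builds one noiseless-ish example of each pairwise relationship shape
seen in strain-panel expression data and prints both association
scores. Pearson only rewards the linear pair; MIC scores every strong
functional relationship near 1, including the two-condition (GxE) pair
whose pooled correlation is near zero.
"""

import numpy as np

from mica import mic_score

rng = np.random.default_rng(0)
n = 100
f = rng.standard_normal(n)
f = (f - f.mean()) / f.std()
noise = lambda: rng.normal(0, 0.05, n)

conditions = np.zeros(n)
conditions[rng.choice(n, n // 2, replace=False)] = 1

pairs = {
    "linear": (f + noise(), 0.8 * f + noise()),
    "high threshold": (f + noise(), 1 / (1 + np.exp(-(f) / 0.15)) + noise()),
    "logarithmic": (f + noise(), np.log(f - f.min() + 1) + noise()),
    "quadratic": (f + noise(), f**2 + noise()),
    "gxe (two-condition)": (
        f + 6 * conditions + noise(),          # shifted under treatment
        f * (1 - 2 * conditions) + noise(),    # slope flips under treatment
    ),
}

print(f"{'relationship':22s} {'MIC':>6s} {'|r|':>6s}")
for name, (x, y) in pairs.items():
    mic = mic_score(x, y).mic
    r = abs(np.corrcoef(x, y)[0, 1])
    print(f"{name:22s} {mic:6.3f} {r:6.3f}")

print(
    "\nMIC stays near 1 for every functional shape; |r| collapses for the"
    "\nnon-monotone shapes and almost vanishes for the GxE pair."
)
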