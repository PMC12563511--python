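"""Choosing the embedding dimension (false nearest neighbors) and delay
(C-C method) from data, and pooling per-channel choices by their mode.

Run:  python examples/embedding_selection.py
"""

import numpy as np

import msptirr as mp

t = np.arange(3000)

# dimension: a clean sinusoid lives on a closed curve (m=2 suffices);
# measurement noise thickens the attractor and pushes the estimate up
clean = np.sin(2 * np.pi * t / 40)
noisy = clean + 0.1 * np.random.default_rng(0).standard_normal(t.size)
for name, x in (("clean sinusoid", clean), ("with 10% noise", noisy)):
    fnn = mp.fnn_dimension(x, tau=10, max_m=6)
    print(f"{name:<16} FNN fractions "
          f"{ {k: round(v, 3) for k, v in fnn.fractions.items()} } -> m={fnn.chosen_m}")

# delay: the C-C statistic tracks the oscillation's decorrelation, so the
# chosen delay grows with the period
print()
chosen_tau = []
for period in (20, 30, 40):
    x = np.sin(2 * np.pi * t / period)
    x = x + 0.1 * np.random.default_rng(1).standard_normal(t.size)
    cc = mp.cc_delay(x, max_tau=20)
    chosen_tau.append(cc.chosen_tau)
    print(f"period {period:>3} samples -> C-C delay tau={cc.chosen_tau}")

print(f"\nmode over the three channels: tau={mp.aggregate_by_mode(chosen_tau)}")
print(
    "\nThese selectors are advisory: on real multichannel data each channel\n"
    "votes and the per-channel modes decide. The analysis pipeline defaults\n"
    "to m=3, tau=2 without running them."
)
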