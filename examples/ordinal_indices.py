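"""Permutation entropy and permutation time irreversibility of reference
signals with known behavior.

Run:  python examples/ordinal_indices.py
"""

import math

import numpy as np

import msptirr as mp

signals = {
    "iid Gaussian noise": mp.gen_gaussian_ar(100_000, seed=0),
    "AR(1), a=0.9 (reversible)": mp.gen_gaussian_ar(100_000, coeffs=[0.9], seed=1),
    "logistic map r=4 (irreversible)": mp.gen_logistic_map(100_000, x0=0.2),
    "strict ramp": np.arange(10_000.0),
}

print(f"{'signal':<32} {'PE':>8} {'PE/log6':>8} {'PTIRR':>8}")
for name, x in signals.items():
    dist = mp.pattern_distribution(x, m=3, tau=2)
    pe = mp.permutation_entropy(dist)
    ptirr = mp.permutation_time_irreversibility(dist)
    print(f"{name:<32} {pe:8.4f} {pe / math.log(6):8.4f} {ptirr:8.4f}")

print(
    "\nPE near log(6) = 1.7918 means all 6 order patterns are equally likely\n"
    "(maximal ordinal complexity); PTIRR near 0 marks a time-reversible\n"
    "signal, while the chaotic map and the ramp are strongly asymmetric."
)
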