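"""MsPE / MsPTIRR curves: how ordinal complexity and temporal asymmetry
change with the coarse-graining scale factor.

Run:  python examples/multiscale_profiles.py
"""

import numpy as np

import msptirr as mp

n = 48_000
noise = mp.gen_gaussian_ar(n, coeffs=[0.7], seed=3)
irrev = noise + 1.5 * mp.irreversible_component(n, seed=4)

scales = (1, 2, 5, 10, 20, 50)
print(f"{'scale':>5} {'PTIRR (AR noise)':>18} {'PTIRR (+irrev.)':>16} {'PE (+irrev.)':>13}")
for s in scales:
    a = mp.index_at_scale(noise, s, kind="ptirr")
    b = mp.index_at_scale(irrev, s, kind="ptirr")
    pe = mp.index_at_scale(irrev, s, kind="pe")
    print(f"{s:>5} {a:>18.4f} {b:>16.4f} {pe:>13.4f}")

print(
    "\nThe reversible AR signal stays near the finite-sample noise floor\n"
    "(which itself rises as coarse series shorten).  In the mixed signal\n"
    "the asymmetry emerges at intermediate scales, once coarse-graining\n"
    "has averaged away the fast reversible fluctuations; its PE barely\n"
    "moves, which is why the irreversibility index is the more sensitive\n"
    "of the two."
)
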