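"""Surrogate test for nonlinearity: phase randomization preserves the
spectrum but destroys nonlinear temporal asymmetry.

Run:  python examples/surrogate_test.py
"""

import msptirr as mp

x = mp.gen_logistic_map(100_000, r=4.0, x0=0.2)
surrogates = [mp.phase_randomized_surrogate(x, seed=k) for k in range(5)]

pt = lambda s: mp.permutation_time_irreversibility(
    mp.pattern_distribution(s, m=3, tau=1)
)

pt_x = pt(x)
pt_s = [pt(s) for s in surrogates]
print(f"PTIRR of the logistic map:        {pt_x:.4f}")
print(f"PTIRR of 5 surrogates:            {[round(v, 4) for v in pt_s]}")
print(f"ratio original / max(surrogate):  {pt_x / max(pt_s):.1f}x")
print(
    "\nThe surrogates share the map's amplitude spectrum yet sit at the\n"
    "reversible noise floor: the irreversibility is a genuinely nonlinear\n"
    "property, not a spectral one."
)
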