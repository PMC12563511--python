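"""Preprocessing a whole-head recording: zero-phase filters, the five-band
decomposition, and CTF sensor-to-region grouping.

Run:  python examples/band_region_pipeline.py
"""

import numpy as np

import msptirr as mp

spec = mp.CohortSpec(
    n_per_group=(1, 1), group_labels=("A", "B"), n_channels=20,
    n_samples=12_000, sample_rate_hz=1200.0, seed=8,
)
rec = mp.gen_cohort(spec).subjects[0].recording

clean = mp.lowpass(rec.data, rec.sample_rate_hz, cutoff_hz=65.0)
clean = mp.notch(clean, rec.sample_rate_hz, line_hz=50.0)
bands = mp.band_decompose(clean, rec.sample_rate_hz)
print("variance share per frequency band (channel mean):")
total = clean.var(axis=1).mean()
for name, data in bands.items():
    print(f"  {name:<6} {data.var(axis=1).mean() / total:6.1%}")

rmap = mp.map_regions(rec.channel_labels)
print("\nchannels per (hemisphere, region) cell:")
for (hemi, region), chans in sorted(rmap.hemispheric_cells().items()):
    print(f"  {hemi}{region}: {len(chans)} channels ({', '.join(chans[:3])}...)")
print(
    "\nAll filters are forward-backward (zero-phase) so the preprocessing\n"
    "itself injects no temporal asymmetry into the irreversibility index."
)
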