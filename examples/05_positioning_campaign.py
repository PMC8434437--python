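"""Simulated probe-positioning robustness campaign.

Sweeps probe tilt over part of the evaluation grid with steady 34 cm/s flow,
repeating each position with independent seeds, and summarizes segmentation
accuracy (centre-error statistics with the 1 mm discard rule) and velocity
accuracy/repeatability per grid point.  Tilt rotates the flow within the
imaging plane; the dual-beam angle correction should keep the velocity error
small across the grid.
"""

import carodop as cd

spec = cd.CampaignSpec(series="tilt", grid=[-10.0, 0.0, 10.0], n_repeats=2,
                       base_seed=5, reference_velocity=0.34)
df = cd.run_campaign(spec)

print(df.to_string(index=False,
                   float_format=lambda v: f"{v:.3f}"))
print("\ncolumns: centre-error min/max/mean/r.m.s. in mm over both arrays' "
      "detections; mean peak velocity in m/s; Err% vs the 0.34 m/s reference; "
      "CV% across repeats; discard counts.")
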