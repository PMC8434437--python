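"""Closed-form acoustic and geometric limits of the dual-array probe.

The probe is two 128-element linear arrays whose axes form a 30 deg
inter-angle; each beam therefore sees a skin-parallel vessel at 75 deg and
105 deg.  The numbers below are the configuration's hard limits: how deep a
pulsed acquisition at 8 kHz per beam can see, the largest velocity the
full sampled Doppler band can represent, and the axial size of one gate's
sample volume.
"""

import carodop as cd

geom = cd.ProbeGeometry()
cfg = cd.AcquisitionConfig()

print(f"active aperture (96 el):   {cd.active_aperture(96, geom.pitch) * 1e3:.1f} mm")
print(f"full array aperture:       {cd.active_aperture(128, geom.pitch) * 1e3:.1f} mm")
a, b = cd.doppler_angles(geom)
print(f"Doppler angles:            {a:.0f} deg / {b:.0f} deg")
print(f"max unambiguous depth:     {cd.max_unambiguous_depth(cfg) * 1e2:.2f} cm")
print(f"max velocity (full PRF):   {cd.max_detectable_velocity(cfg, geom, a):.2f} m/s")
print(f"max velocity (Nyquist):    {cd.max_detectable_velocity(cfg, geom, a) / 2:.2f} m/s")
print(f"sample volume (axial):     {cd.sample_volume_axial_extent(geom, cfg) * 1e3:.3f} mm")
print(f"beam-origin separation:    {cd.beam_origin_separation(geom) * 1e3:.2f} mm "
      f"(axes cross at {geom.cross_depth * 1e3:.0f} mm depth)")
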