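"""Automatic lumen localization on a synthetic speckle phantom.

Generates a 15-frame B-mode sequence with a 3 mm-radius hypoechoic lumen at
a known position, runs the circular-Hough detector with multi-frame
consensus, and reports the localization error.  The error should be well
below the 1 mm discard threshold used in evaluation.
"""

import carodop as cd

truth = cd.PhantomTruth(center_x=2.0, center_y=23.0, radius=3.0, seed=42)
seq = cd.make_phantom_sequence(truth, n_frames=15, contrast_db=-25.0)

det = cd.segment_sequence(seq)
err = cd.distance_error((det.xc, det.yc), (truth.center_x, truth.center_y))

print(f"truth:     centre ({truth.center_x:.2f}, {truth.center_y:.2f}) mm, "
      f"radius {truth.radius:.2f} mm")
print(f"detected:  centre ({det.xc:.2f}, {det.yc:.2f}) mm, radius {det.rc:.2f} mm")
print(f"status:    {det.status}, modal triad supported by "
      f"{det.n_supporting_frames}/15 frames")
print(f"centre localization error: {err:.3f} mm "
      f"({'kept' if err <= 1.0 else 'discarded'} under the 1 mm rule)")
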