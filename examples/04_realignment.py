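"""Recover injected head motion by rigid-body realignment.

Applies known translations/rotations to a noiseless smooth phantom and
checks that the Gauss-Newton realigner recovers them.
"""

import numpy as np

import tmsfmri as tf
from tmsfmri import preproc

spec = tf.PhantomSpec(grid_shape=(16, 16, 16), n_dynamics=4, noise_sd=0,
                      drift_amplitude=0, effect_pct=0, seed=31)
series, _, _ = tf.generate_phantom(spec)
series = preproc.smooth(series, 6.0)

injected = np.zeros((4, 6))
injected[1] = [2.0, 0, 0, 1.0, 0, 0]
injected[2] = [0, -1.5, 1.0, 0, 1.0, 0]
injected[3] = [0.5, 0.5, -2.0, 0, 0, -1.0]
moved = tf.apply_motion(series, injected)

rr = preproc.realign(moved, reference="first")
err = rr.motion - injected
print("injected (tx ty tz mm, rx ry rz deg):")
print(np.round(injected, 3))
print("recovered:")
print(np.round(rr.motion, 3))
print(f"max error: {np.abs(err[:, :3]).max():.3f} mm, "
      f"{np.abs(err[:, 3:]).max():.3f} deg")
# Sub-0.1 mm / 0.1 degree errors leave the motion-corrected coil track
# accurate to a fraction of a voxel.
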