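"""Generate a synthetic concurrent TMS-fMRI acquisition.

Builds a 30-slice, 4 mm isotropic, 500-dynamic phantom at TR 2 s with an
interleaved 115%/60% RMT pulse schedule (random 5-8 dynamic gaps), a 1%
signal-change target region in grey matter, AR(1) noise and slow drift.
"""

import numpy as np

import tmsfmri as tf

spec = tf.PhantomSpec(seed=0)
series, masks, truth = tf.generate_phantom(spec)

gaps = np.diff(np.concatenate([[0.0], truth.pulse_train.onsets]))
print(f"grid {series.grid_shape}, {series.n_volumes} dynamics, TR {series.tr} s "
      f"({tf.acquisition_minutes(series.n_volumes, series.tr):.1f} min)")
print(f"{len(truth.pulse_train)} pulses, gaps {sorted(set(gaps.tolist()))} s, "
      f"levels start {list(truth.pulse_train.levels[:4])}")
print(f"GM/WM/CSF voxels: {masks['gm'].sum()}/{masks['wm'].sum()}/{masks['csf'].sum()}")
print(f"target region: {(truth.beta_map > 0).sum()} voxels, "
      f"true effect {truth.beta_map.max():.1f} signal units (1% of baseline)")
# The pulse gaps are whole dynamics of 10-16 s, matching the acquisition
# protocol; the target effect is what the GLM stage must recover.
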