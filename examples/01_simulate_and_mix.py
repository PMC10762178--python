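"""Generate EEG-like sources and mix them into observed channels.

Builds 5 standardized source signals from the waveform catalog, mixes them
through a random standard-normal matrix into 20 channels, and verifies the
two structural facts everything downstream relies on: the sources are
nearly uncorrelated with each other, and the noiseless mixture has rank
equal to the number of sources.
"""

import numpy as np

from icdim import mix_signals, simulate_sources

src = simulate_sources(q_true=5, n=500, seed=11)
print("waveforms:", ", ".join(src.kinds))

C = np.abs(np.corrcoef(src.signals))
off_diag_max = C[~np.eye(5, dtype=bool)].max()
print(f"max |corr| between distinct sources: {off_diag_max:.3f}")
# well below 0.3: the sources are close enough to independent for ICA

X, spec = mix_signals(src, p=20, snr_db=None, seed=2)
s = np.linalg.svd(X.data, compute_uv=False)
print(f"mixture: {X.p} channels x {X.n} samples")
print(f"singular values 5 and 6: {s[4]:.2f}, {s[5]:.2e}")
# the 6th singular value is numerically zero: 20 channels, but only a
# 5-dimensional signal — exactly the situation the estimator must detect
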