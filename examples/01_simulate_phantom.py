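"""Simulate a multi-coil cine phantom acquisition.

Builds the default 64x64, 8-coil, 8-frame beating phantom, undersampled at
R=2 with a 32-line ACS block, adds coil-correlated receiver noise and a
noise-only pre-scan, and prints what was produced.
"""

import numpy as np

from snraware import PhantomConfig, simulate_acquisition

cfg = PhantomConfig(seed=2024)
ksp, prescan, labels, coil_maps = simulate_acquisition(cfg)

print(f"k-space           : {ksp.data.shape}  (coil, ky, kx, frame)")
print(f"acquired lines    : {int(ksp.mask[:, 0].sum())} of {ksp.data.shape[1]} "
      f"(R={ksp.accel} grid + {ksp.n_acs} ACS)")
print(f"ACS block         : {ksp.acs.shape}")
print(f"noise pre-scan    : {prescan.samples.shape[1]} samples x "
      f"{prescan.samples.shape[0]} coils")
emp = prescan.samples @ prescan.samples.conj().T / prescan.samples.shape[1]
print(f"coil noise corr   : nearest-neighbour {emp[0, 1].real:.3f} "
      f"(requested 0.30)")
print(f"labels            : {sorted(labels)} "
      f"(blood {int(labels['blood'][..., 0].sum())} px in frame 0)")
print()
print("The mask marks which phase-encode lines were acquired; masked-out")
print("lines are exactly zero, and the pre-scan shares the receiver")
print("covariance, so the pre-whitening stage can be calibrated from it.")
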