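"""Evaluation: PSNR, SSIM, pseudo-replica SNR maps, ROI SNR and CNR.

Measures a noisy sample against its clean partner and runs the Monte-Carlo
pseudo-replica method on the clean SNR-unit series with the phantom's
blood/myocardium labels as ROIs.
"""

import numpy as np

from snraware import PhantomConfig, simulate_acquisition
from snraware.gfactor import G_CLAMP, compute_gfactor_set
from snraware.metrics import ROISpec, cnr, pseudo_replica_snr, psnr, ssim
from snraware.noise import NoiseAugConfig, make_training_pair
from snraware.recon import (apply_prewhitening, calibrate_grappa,
                            compute_prewhitener, estimate_coil_maps,
                            estimate_noise_covariance, kernel_to_unmixing,
                            reconstruct_snr_unit)

cfg = PhantomConfig(seed=2024)
ksp, prescan, labels, _ = simulate_acquisition(cfg)
white = apply_prewhitening(ksp, compute_prewhitener(
    estimate_noise_covariance(prescan)))
maps = estimate_coil_maps(white.acs, cfg.matrix_size)
unmix = kernel_to_unmixing(calibrate_grappa(white.acs, 2), maps,
                           cfg.matrix_size)
recon = reconstruct_snr_unit(white, unmix)
gset = compute_gfactor_set(white)

pair = make_training_pair(recon, gset, NoiseAugConfig(),
                          np.random.default_rng(3))
print(f"noisy sample: sigma={pair.sigma_used:.2f}, g-map R={pair.gmap_used.accel}")
print(f"PSNR noisy vs clean : {psnr(pair.noisy.data, pair.clean.data):6.2f} dB")
print(f"SSIM noisy vs clean : {ssim(pair.noisy.data, pair.clean.data):6.3f}")

rois = ROISpec(masks={"blood": labels["blood"][:, :, 0],
                      "myocardium": labels["myocardium"][:, :, 0]},
               source="phantom-labels")
S = recon.data / np.maximum(recon.native_g, G_CLAMP)[:, :, None]
res = pseudo_replica_snr(S, lambda x: x, n_replicas=64,
                         rng=np.random.default_rng(0), rois=rois)
for name in ("blood", "myocardium"):
    print(f"{name:11s}: SNR {res.roi_snr[name]:6.2f}  "
          f"(signal {res.roi_signal[name]:6.2f}, "
          f"noise SD {res.roi_noise_sd[name]:5.3f})")
print(f"CNR blood-myocardium: {cnr(res):.2f}")
print()
print("The pseudo-replica method injects fresh unit noise 64 times and takes")
print("the pixel-wise SD across repetitions — noise SD near 1 confirms the")
print("series really is in SNR units.")
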