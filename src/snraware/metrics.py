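"""Image-quality and SNR evaluation.

PSNR and SSIM on magnitude images, Monte-Carlo pseudo-replica noise/SNR maps
(add a fixed amount of fresh noise N times, process, take the pixel-wise SD
across repetitions), ROI SNR, the two-ROI contrast-to-noise ratio
``CNR = 2 (S_A - S_B) / (sd_A + sd_B)``, and SNR-gain ratios between two
processing chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["ROISpec", "SNRResult", "psnr", "ssim",
           "pseudo_replica_snr", "cnr", "snr_gain"]

_NOISE_FLOOR = 1e-6


@dataclass
class ROISpec:
    """Named binary ROI masks [H, W]; masks must be non-empty and disjoint."""

    masks: dict[str, np.ndarray]
    source: str = "user-supplied"

    def __post_init__(self) -> None:
        total = None
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if not m.any():
                raise ValueError(f"ROI '{name}' is empty")
            if total is not None and (total & m).any():
                raise ValueError(f"ROI '{name}' overlaps another ROI")
            total = m if total is None else (total | m)
            self.masks[name] = m


@dataclass
class SNRResult:
    """Pseudo-replica outcome: noise-SD map, SNR map and ROI summaries."""

    noise_sd_map: np.ndarray
    signal_map: np.ndarray
    snr_map: np.ndarray
    roi_snr: dict[str, float] = field(default_factory=dict)
    roi_noise_sd: dict[str, float] = field(default_factory=dict)
    roi_signal: dict[str, float] = field(default_factory=dict)
    n_replicas: int = 0


def psnr(pred: np.ndarray, reference: np.ndarray,
         max_value: float = 2048.0) -> float:
    """Peak SNR in dB: ``10 log10(MAX^2 / MSE)`` with MSE on magnitudes.

    The default MAX of 2048 suits images scaled to unit noise SD, where pixel
    SNR beyond that bound is implausible.
    """
    if pred.shape != reference.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((np.abs(pred) - np.abs(reference)) ** 2))
    if mse == 0:
        warnings.warn("identical images: PSNR is infinite")
        return float("inf")
    return float(10 * np.log10(max_value**2 / mse))


def ssim(pred: np.ndarray, reference: np.ndarray,
         data_range: float | None = None, win_size: int = 7) -> float:
    """Mean structural similarity.

    Complex inputs are compared on their magnitudes; real inputs as-is (so
    sign inversions register as negative similarity).  Gaussian-weighted 7x7
    window, K1=0.01, K2=0.03; ``data_range`` defaults to the reference
    magnitude maximum.  Series [H, W, T] are averaged over frames.
    """
    if pred.shape != reference.shape:
        raise ValueError("shape mismatch")
    if np.iscomplexobj(pred) or np.iscomplexobj(reference):
        p, r = np.abs(pred), np.abs(reference)
    else:
        p, r = np.asarray(pred, dtype=float), np.asarray(reference, dtype=float)
    if data_range is None:
        data_range = float(np.abs(r).max()) or 1.0
    if p.ndim == 2:
        p, r = p[:, :, None], r[:, :, None]
    vals = [
        structural_similarity(
            p[:, :, t], r[:, :, t], win_size=win_size, gaussian_weights=True,
            sigma=1.5, use_sample_covariance=False, K1=0.01, K2=0.03,
            data_range=data_range,
        )
        for t in range(p.shape[2])
    ]
    return float(np.mean(vals))


def pseudo_replica_snr(
    input_series: np.ndarray,
    processor: Callable[[np.ndarray], np.ndarray],
    n_replicas: int = 64,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    rois: ROISpec | None = None,
    noise_structure: np.ndarray | None = None,
) -> SNRResult:
    """Monte-Carlo SNR estimation by repeated noise injection.

    Each replica adds fresh complex noise of SD ``noise_sd`` — optionally
    shaped pixel-wise by ``noise_structure`` (e.g. the g-map, to mimic the
    spatially varying noise of an accelerated reconstruction) — to the input,
    applies ``processor`` (any image-to-image map; identity allowed), and the
    pixel-wise SD across replicas becomes the noise map; the replica mean
    magnitude is the signal map.  ROI SNR is the ratio of ROI-mean signal to
    ROI-mean noise SD.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = rng or np.random.default_rng()
    x = np.asarray(input_series)
    struct = 1.0
    if noise_structure is not None:
        struct = np.asarray(noise_structure)
        if struct.shape != x.shape[:struct.ndim]:
            raise ValueError("noise_structure shape incompatible with input")
        struct = struct.reshape(struct.shape + (1,) * (x.ndim - struct.ndim))
    outs = []
    for _ in range(n_replicas):
        noise = noise_sd * struct * (
            rng.standard_normal(x.shape)
            + 1j * rng.standard_normal(x.shape)) / np.sqrt(2)
        outs.append(np.asarray(processor(x + noise)))
    stack = np.stack(outs)
    if np.iscomplexobj(stack):
        sd = np.sqrt(np.var(stack.real, axis=0) + np.var(stack.imag, axis=0))
    else:
        sd = np.std(stack, axis=0)
    signal = np.abs(stack.mean(axis=0))
    if sd.ndim == 3:       # series [H, W, T]: summarize over frames
        sd2d, sig2d = sd.mean(axis=2), signal.mean(axis=2)
    else:
        sd2d, sig2d = sd, signal
    snr_map = sig2d / np.maximum(sd2d, _NOISE_FLOOR)

    result = SNRResult(noise_sd_map=sd2d, signal_map=sig2d, snr_map=snr_map,
                       n_replicas=n_replicas)
    if rois is not None:
        for name, m in rois.masks.items():
            result.roi_signal[name] = float(sig2d[m].mean())
            result.roi_noise_sd[name] = float(sd2d[m].mean())
            result.roi_snr[name] = result.roi_signal[name] / max(
                result.roi_noise_sd[name], _NOISE_FLOOR)
    return result


def cnr(result: SNRResult, roi_a: str = "blood", roi_b: str = "myocardium") -> float:
    """Contrast-to-noise ratio ``2 (S_a - S_b) / (sd_a + sd_b)`` between ROIs."""
    for roi in (roi_a, roi_b):
        if roi not in result.roi_signal:
            raise ValueError(f"ROI '{roi}' missing from SNRResult")
    return float(
        2 * (result.roi_signal[roi_a] - result.roi_signal[roi_b])
        / (result.roi_noise_sd[roi_a] + result.roi_noise_sd[roi_b])
    )


def snr_gain(before: SNRResult, after: SNRResult,
             roi: str | None = None) -> float | dict[str, float]:
    """Ratio of ROI SNR after/before a processing step.

    With ``roi=None`` returns the ratio per shared ROI name.
    """
    if before.noise_sd_map.shape != after.noise_sd_map.shape:
        raise ValueError("geometry mismatch between SNR results")
    shared = sorted(set(before.roi_snr) & set(after.roi_snr))
    if roi is not None:
        if roi not in shared:
            raise ValueError(f"ROI '{roi}' not present in both results")
        return after.roi_snr[roi] / before.roi_snr[roi]
    if not shared:
        raise ValueError("no shared ROIs between results")
    return {name: after.roi_snr[name] / before.roi_snr[name] for name in shared}
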