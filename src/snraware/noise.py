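"""MR-realistic noise synthesis and training-pair assembly.

Starting from a clean SNR-unit series S (unit noise SD), a noisy partner is
built the way a scanner would have produced it at lower SNR:

1. draw a noise level ``sigma ~ U[0, sigma_max]``;
2. draw one g-map ``g_aug`` from the augmentation set and amplify complex
   white noise pointwise — the spatial signature of parallel imaging;
3. push the noise through a separable k-space filter (Gaussian apodization x
   partial-Fourier Hann taper x resolution cutoff, drawn independently per
   axis) to introduce the spatial correlation that raw filters, partial
   Fourier and resolution reduction imprint on real reconstructions;
4. compose ``Sn = (S + n) / sqrt(sigma^2 + 1)``.

The ``sqrt(sigma^2 + 1)`` accounts for the unit noise already present in S
plus the added noise, so the noisy sample again has unit total noise SD up to
the ``g_aug`` amplification.  Every filter is power-normalized (mean squared
response 1), which preserves the spatially averaged noise power, so sigma
keeps its meaning regardless of the filter drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .fourier import fft2c, ifft2c
from .gfactor import GFactorMap, GFactorSet, draw_augmentation_gmap, G_CLAMP
from .recon import ReconImage

__all__ = [
    "NoiseAugConfig",
    "AugmentationDraw",
    "KSpaceFilter",
    "TrainingPair",
    "sample_augmentation",
    "build_filter",
    "generate_noise",
    "compose_noisy_sample",
    "make_training_pair",
    "replay_training_pair",
]


@dataclass
class NoiseAugConfig:
    """Noise-augmentation settings.

    Defaults follow the training recipe this package implements: noise sigma
    uniform on [0, 32] (in units of the unit noise SD), Gaussian k-space
    filter sigma from [0.8, 1.0, 1.5, 2.0, 2.25] on the normalized frequency
    axis, partial-Fourier and resolution ratios from
    [1.0, 0.85, 0.7, 0.65, 0.55], partial Fourier applied with probability
    0.5 — each drawn independently for the phase-encode and readout axes.
    """

    sigma_max: float = 32.0
    gaussian_sigmas: tuple[float, ...] = (0.8, 1.0, 1.5, 2.0, 2.25)
    pf_ratios: tuple[float, ...] = (1.0, 0.85, 0.7, 0.65, 0.55)
    pf_probability: float = 0.5
    resolution_ratios: tuple[float, ...] = (1.0, 0.85, 0.7, 0.65, 0.55)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be positive")
        for name in ("gaussian_sigmas", "pf_ratios", "resolution_ratios"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
        if any(not 0 < r <= 1 for r in self.pf_ratios + self.resolution_ratios):
            raise ValueError("ratios must lie in (0, 1]")
        if not 0 <= self.pf_probability <= 1:
            raise ValueError("pf_probability must be in [0, 1]")


@dataclass
class AugmentationDraw:
    """One realization of the stochastic augmentation parameters."""

    sigma: float
    gaussian_sigma_ky: float
    gaussian_sigma_kx: float
    pf_ratio_ky: float
    pf_ratio_kx: float
    pf_side_ky: int        # +1: truncate high frequencies side, -1: low side
    pf_side_kx: int
    res_ratio_ky: float
    res_ratio_kx: float


@dataclass
class KSpaceFilter:
    """Separable k-space filter with unit mean-square response per axis."""

    response_ky: np.ndarray
    response_kx: np.ndarray
    params: dict = field(default_factory=dict)

    def apply(self, kspace: np.ndarray) -> np.ndarray:
        """Pointwise multiply (..., H, W) k-space by the separable response."""
        return kspace * self.response_ky[:, None] * self.response_kx[None, :]


@dataclass
class TrainingPair:
    """Paired clean/noisy SNR-unit series plus the g-map channel.

    ``tensor`` is [C=3, T, H, W]: real(Sn), imag(Sn), g_aug broadcast along
    T — the channel-stacked layout a denoising network consumes (the batch
    axis is the consumer's).
    """

    clean: ReconImage
    noisy: ReconImage
    gmap_used: GFactorMap
    sigma_used: float
    filter_used: KSpaceFilter
    tensor: np.ndarray
    provenance: dict = field(default_factory=dict)


def sample_augmentation(cfg: NoiseAugConfig, rng: np.random.Generator) -> AugmentationDraw:
    """Draw one set of augmentation parameters.

    The draw order is fixed (sigma, then ky/kx Gaussian sigmas, partial
    Fourier gates/ratios/sides, resolution ratios) so a recorded draw replays
    bit-exactly from the same generator state.
    """
    sigma = float(rng.uniform(0, cfg.sigma_max))
    gky, gkx = (float(rng.choice(cfg.gaussian_sigmas)) for _ in range(2))
    pf = []
    for _ in range(2):
        if rng.uniform() < cfg.pf_probability:
            pf.append((float(rng.choice(cfg.pf_ratios)),
                       1 if rng.uniform() < 0.5 else -1))
        else:
            pf.append((1.0, 1))
    rky, rkx = (float(rng.choice(cfg.resolution_ratios)) for _ in range(2))
    return AugmentationDraw(
        sigma=sigma, gaussian_sigma_ky=gky, gaussian_sigma_kx=gkx,
        pf_ratio_ky=pf[0][0], pf_side_ky=pf[0][1],
        pf_ratio_kx=pf[1][0], pf_side_kx=pf[1][1],
        res_ratio_ky=rky, res_ratio_kx=rkx,
    )


def _axis_response(n: int, gaussian_sigma: float, pf_ratio: float,
                   pf_side: int, res_ratio: float) -> np.ndarray:
    """Separable filter response for one k-space axis (before normalization)."""
    if not 0 < pf_ratio <= 1 or not 0 < res_ratio <= 1:
        raise ValueError("filter ratios must lie in (0, 1]")
    khat = (np.arange(n) - n // 2) / (n / 2)   # normalized frequency in [-1, 1)
    f = np.exp(-(khat**2) / (2 * gaussian_sigma**2))

    if pf_ratio < 1.0:
        keep = int(np.ceil(pf_ratio * n))
        taper = np.zeros(n)
        width = max(1, int(round(0.1 * n)))
        ramp = 0.5 * (1 + np.cos(np.pi * np.arange(1, width + 1) / (width + 1)))
        if pf_side > 0:       # truncate the high-index side
            taper[:keep] = 1.0
            taper[keep - width:keep] = ramp
        else:
            taper[n - keep:] = 1.0
            taper[n - keep:n - keep + width] = ramp[::-1]
        f = f * taper

    if res_ratio < 1.0:
        keep = int(np.ceil(res_ratio * n))
        start = (n - keep) // 2
        mask = np.zeros(n)
        mask[start:start + keep] = 1.0
        f = f * mask
    return f


def build_filter(draw: AugmentationDraw, matrix_size: tuple[int, int]) -> KSpaceFilter:
    """Assemble and power-normalize the separable k-space filter.

    Each axis response is Gaussian window x partial-Fourier Hann taper x
    symmetric resolution mask, scaled so its mean squared value is 1; the
    separable product therefore preserves total noise power exactly.
    """
    H, W = matrix_size
    fky = _axis_response(H, draw.gaussian_sigma_ky, draw.pf_ratio_ky,
                         draw.pf_side_ky, draw.res_ratio_ky)
    fkx = _axis_response(W, draw.gaussian_sigma_kx, draw.pf_ratio_kx,
                         draw.pf_side_kx, draw.res_ratio_kx)
    fky = fky / np.sqrt(np.mean(fky**2))
    fkx = fkx / np.sqrt(np.mean(fkx**2))
    return KSpaceFilter(response_ky=fky, response_kx=fkx, params=asdict(draw))


def generate_noise(
    sigma: float,
    gmap: GFactorMap | np.ndarray,
    filt: KSpaceFilter,
    shape: tuple[int, int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially varying, correlated complex noise [T, H, W].

    White complex Gaussian noise with per-pixel SD ``sigma`` is amplified
    pointwise by the g-map, moved to k-space, shaped by the normalized filter
    and moved back.  Frames are independent (acquisition noise is temporally
    white).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    T, H, W = shape
    g = gmap.g if isinstance(gmap, GFactorMap) else np.asarray(gmap)
    if g.shape != (H, W):
        raise ValueError(f"g-map shape {g.shape} does not match image {H, W}")
    if sigma == 0:
        return np.zeros(shape, dtype=complex)
    white = sigma * (rng.standard_normal(shape)
                     + 1j * rng.standard_normal(shape)) / np.sqrt(2)
    k = fft2c(white * g[None, :, :], axes=(1, 2))
    return ifft2c(filt.apply(k), axes=(1, 2))


def compose_noisy_sample(clean: ReconImage, noise: np.ndarray,
                         sigma: float) -> ReconImage:
    """``Sn = (S + n) / sqrt(sigma^2 + 1)``.

    ``clean`` must already be in SNR units (unit noise SD); the rescale
    accounts for its intrinsic unit noise plus the added noise so the result
    is back at unit noise SD, times the g-map used to shape ``n``.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        data = clean.data.copy()
    else:
        data = (clean.data + np.transpose(noise, (1, 2, 0))) / np.sqrt(sigma**2 + 1)
    meta = {**clean.meta, "sigma": sigma,
            "noise_rescale": 1.0 / np.sqrt(sigma**2 + 1)}
    return ReconImage(data=data, native_g=clean.native_g.copy(), meta=meta)


def make_training_pair(
    recon: ReconImage,
    gset: GFactorSet,
    cfg: NoiseAugConfig,
    rng: np.random.Generator,
) -> TrainingPair:
    """Assemble one paired clean/noisy training sample.

    The clean sample is the SNR-unit image ``S = I / g_native`` (g clamped at
    ``1e-3``); the noisy partner adds g-augmented, filter-correlated noise as
    described in the module docstring.  All stochastic choices plus a derived
    noise seed are recorded in ``provenance``, from which
    :func:`replay_training_pair` rebuilds the pair bit-exactly.
    """
    H, W = recon.matrix_size
    S = recon.data / np.maximum(recon.native_g, G_CLAMP)[:, :, None]
    clean = ReconImage(data=S, native_g=recon.native_g.copy(),
                       meta={**recon.meta, "snr_unit_series": True})

    draw = sample_augmentation(cfg, rng)
    gmap = draw_augmentation_gmap(gset, rng)
    noise_seed = int(rng.integers(2**31))
    filt = build_filter(draw, (H, W))
    T = recon.n_frames
    noise = generate_noise(draw.sigma, gmap, filt, (T, H, W),
                           np.random.default_rng(noise_seed))
    noisy = compose_noisy_sample(clean, noise, draw.sigma)

    sn_t = np.transpose(noisy.data, (2, 0, 1))
    tensor = np.stack([
        sn_t.real,
        sn_t.imag,
        np.broadcast_to(gmap.g, (T, H, W)),
    ])
    provenance = {
        "draw": asdict(draw),
        "gmap_accel": gmap.accel,
        "noise_seed": noise_seed,
    }
    return TrainingPair(clean=clean, noisy=noisy, gmap_used=gmap,
                        sigma_used=draw.sigma, filter_used=filt,
                        tensor=tensor, provenance=provenance)


def replay_training_pair(recon: ReconImage, gset: GFactorSet,
                         provenance: dict) -> TrainingPair:
    """Rebuild a training pair bit-exactly from its recorded provenance."""
    H, W = recon.matrix_size
    S = recon.data / np.maximum(recon.native_g, G_CLAMP)[:, :, None]
    clean = ReconImage(data=S, native_g=recon.native_g.copy(),
                       meta={**recon.meta, "snr_unit_series": True})
    draw = AugmentationDraw(**provenance["draw"])
    accel = provenance["gmap_accel"]
    try:
        gmap = next(m for m in gset.maps if m.accel == accel)
    except StopIteration:
        raise ValueError(f"g-factor set has no map for R={accel}") from None
    filt = build_filter(draw, (H, W))
    T = recon.n_frames
    noise = generate_noise(draw.sigma, gmap, filt, (T, H, W),
                           np.random.default_rng(provenance["noise_seed"]))
    noisy = compose_noisy_sample(clean, noise, draw.sigma)
    sn_t = np.transpose(noisy.data, (2, 0, 1))
    tensor = np.stack([sn_t.real, sn_t.imag,
                       np.broadcast_to(gmap.g, (T, H, W))])
    return TrainingPair(clean=clean, noisy=noisy, gmap_used=gmap,
                        sigma_used=draw.sigma, filter_used=filt,
                        tensor=tensor, provenance=dict(provenance))
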