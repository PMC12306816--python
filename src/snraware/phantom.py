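"""Synthetic multi-coil cardiac cine phantom.

Generates a small dynamic phantom that mimics, geometrically, a balanced-SSFP
short-axis cine acquisition: a torso-like body ellipse, a "myocardium" annulus
and a bright "blood pool" that translate periodically through the cardiac
cycle, seen through smooth complex coil sensitivities and sampled on a
Cartesian k-space grid with a regular undersampling pattern plus a fully
sampled auto-calibration (ACS) block.  Receiver noise is complex Gaussian with
a user-chosen coil-to-coil covariance, and a matching noise-only pre-scan is
produced so that the downstream pre-whitening step has real calibration data
to work with.

The phantom is analytic (ellipses rasterized per frame, no anti-aliasing) so
the ground-truth labels are exact; it makes no attempt at relaxation, banding
or respiratory motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import fft2c

__all__ = [
    "PhantomConfig",
    "MultiCoilKSpace",
    "NoisePreScan",
    "exponential_coil_cov",
    "make_phantom_series",
    "make_coil_maps",
    "synthesize_kspace",
    "add_receiver_noise",
    "simulate_acquisition",
    "grid_lines",
]


def exponential_coil_cov(n_coils: int, rho: float = 0.3, sigma: float = 1.0) -> np.ndarray:
    """Coil noise covariance with exponentially decaying correlation.

    ``psi[i, j] = sigma**2 * rho**|i - j|`` — a standard stand-in for the
    coupling between neighbouring receive channels.  Positive definite for
    ``|rho| < 1``.
    """
    idx = np.arange(n_coils)
    return (sigma**2) * rho ** np.abs(idx[:, None] - idx[None, :]) + 0j


def _validate_cov(noise_cov: np.ndarray) -> np.ndarray:
    psi = np.asarray(noise_cov, dtype=complex)
    if psi.ndim != 2 or psi.shape[0] != psi.shape[1]:
        raise ValueError("noise_cov must be a square matrix")
    if not np.allclose(psi, psi.conj().T, atol=1e-10):
        raise ValueError("noise_cov must be Hermitian")
    eigvals = np.linalg.eigvalsh(psi)
    if eigvals.min() <= 0:
        raise ValueError(
            f"noise_cov must be positive definite (min eigenvalue {eigvals.min():.3g})"
        )
    return psi


@dataclass
class PhantomConfig:
    """Settings for one synthetic acquisition.

    ``motion_amplitude`` is the peak in-plane displacement of the heart as a
    fraction of the matrix height; ``signal_scale`` sets the blood-pool
    magnitude relative to the unit noise level after SNR-unit scaling (i.e.
    roughly the blood SNR of the fully sampled reconstruction).
    """

    matrix_size: tuple[int, int] = (64, 64)
    n_frames: int = 8
    n_coils: int = 8
    noise_cov: np.ndarray | None = None
    accel: int = 2
    n_acs: int = 32
    seed: int = 12345
    motion_amplitude: float = 0.05
    signal_scale: float = 100.0
    dwell_scale: float = 1.0

    def __post_init__(self) -> None:
        H, W = self.matrix_size
        if H < 32 or W < 32:
            raise ValueError("matrix_size must be at least 32 x 32")
        if self.n_coils < 2:
            raise ValueError("n_coils must be >= 2 (parallel imaging undefined otherwise)")
        if not 1 <= self.accel <= 8:
            raise ValueError("accel must be in 1..8")
        if not 16 <= self.n_acs <= H:
            raise ValueError("n_acs must be in [16, H]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_cov is None:
            self.noise_cov = exponential_coil_cov(self.n_coils)
        self.noise_cov = _validate_cov(self.noise_cov)
        if self.noise_cov.shape[0] != self.n_coils:
            raise ValueError("noise_cov size must match n_coils")


@dataclass
class MultiCoilKSpace:
    """Undersampled multi-coil k-space with its sampling mask and ACS block.

    ``data`` is [coil, ky, kx, frame] with masked-out phase-encode lines
    exactly zero; ``mask`` is [ky, frame] (1 = acquired); ``acs`` is a fully
    sampled central block [coil, ky_acs, kx].  Phase encode is the first
    spatial k-axis, DC sits at index ``H // 2`` (centered layout).
    """

    data: np.ndarray
    mask: np.ndarray
    acs: np.ndarray
    accel: int
    n_acs: int
    dwell_scale: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def matrix_size(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class NoisePreScan:
    """Noise-only calibration readouts: complex samples [coil, n_samples]."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        n_coils, n = self.samples.shape
        if n < 256 * n_coils:
            raise ValueError(
                f"pre-scan needs at least {256 * n_coils} samples for a stable "
                f"covariance estimate, got {n}"
            )


def grid_lines(n_ky: int, accel: int) -> np.ndarray:
    """Phase-encode indices of the regular R-grid anchored at the center line."""
    ky = np.arange(n_ky)
    return ky[(ky - n_ky // 2) % accel == 0]


def _ellipse_mask(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
                  ry: float, rx: float) -> np.ndarray:
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_phantom_series(cfg: PhantomConfig) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Rasterize the dynamic phantom.

    Returns the complex object-space series [H, W, frame] (before coil
    weighting) and boolean label masks {"blood", "myocardium", "body"} of the
    same shape.  The heart translates sinusoidally with peak displacement
    ``motion_amplitude * H``; frame-to-frame change is purely this rigid
    motion, so ``motion_amplitude = 0`` yields a static series.
    """
    H, W = cfg.matrix_size
    T = cfg.n_frames
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    images = np.zeros((H, W, T), dtype=complex)
    labels = {
        name: np.zeros((H, W, T), dtype=bool) for name in ("blood", "myocardium", "body")
    }

    # smooth global phase roll, as off-resonance would produce
    phase = np.exp(1j * 2 * np.pi * (0.06 * xx / W + 0.04 * yy / H))

    s = cfg.signal_scale
    for t in range(T):
        shift = cfg.motion_amplitude * H * np.sin(2 * np.pi * t / max(T, 1))
        body = _ellipse_mask(yy, xx, 0.50 * H, 0.50 * W, 0.40 * H, 0.44 * W)
        heart_cy, heart_cx = 0.52 * H + shift, 0.44 * W
        outer = _ellipse_mask(yy, xx, heart_cy, heart_cx, 0.18 * H, 0.18 * W)
        inner = _ellipse_mask(yy, xx, heart_cy, heart_cx, 0.115 * H, 0.115 * W)

        frame = np.zeros((H, W), dtype=float)
        frame[body] = 0.30 * s
        frame[outer & ~inner] = 0.55 * s   # myocardium
        frame[inner] = 1.00 * s            # blood pool

        images[:, :, t] = frame * phase
        labels["blood"][:, :, t] = inner
        labels["myocardium"][:, :, t] = outer & ~inner
        labels["body"][:, :, t] = body & ~outer

    return images, labels


def make_coil_maps(cfg: PhantomConfig) -> np.ndarray:
    """Smooth complex coil sensitivities [coil, H, W].

    Gaussian magnitude lobes centered on a ring around the field of view with
    a gentle per-coil linear phase.  The across-coil root-sum-of-squares is
    strictly positive at every pixel, and neighbouring coils on the ring
    overlap more than opposing ones.
    """
    if cfg.n_coils < 2:
        raise ValueError("n_coils must be >= 2")
    H, W = cfg.matrix_size
    C = cfg.n_coils
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    maps = np.zeros((C, H, W), dtype=complex)
    width = 0.25 * max(H, W)
    for c in range(C):
        theta = 2 * np.pi * c / C
        cy = 0.5 * H + (H / 2) * np.sin(theta)
        cx = 0.5 * W + (W / 2) * np.cos(theta)
        mag = 0.02 + np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width**2))
        ph = 2 * np.pi * (0.25 * np.cos(theta) * (xx - cx) / W
                          + 0.25 * np.sin(theta) * (yy - cy) / H) + theta / 3
        maps[c] = mag * np.exp(1j * ph)
    return maps


def synthesize_kspace(images: np.ndarray, coil_maps: np.ndarray,
                      cfg: PhantomConfig) -> MultiCoilKSpace:
    """Noiseless undersampled multi-coil k-space from an object series.

    Per-coil k-space is the centered unitary 2D FFT of ``coil_map * image``.
    The sampling pattern keeps every R-th phase-encode line anchored at the
    center line plus a contiguous centered ACS block.  The separate fully
    sampled ACS block is the temporal average over frames, as a
    time-interleaved cine calibration would deliver; its noise level (added
    later) is reduced by ``sqrt(n_frames)`` accordingly.
    """
    H, W = cfg.matrix_size
    if images.shape[:2] != (H, W) or coil_maps.shape[1:] != (H, W):
        raise ValueError("image / coil-map shapes inconsistent with config")
    if coil_maps.shape[0] != cfg.n_coils:
        raise ValueError("coil_maps coil count inconsistent with config")
    T = images.shape[2]

    coil_imgs = coil_maps[:, :, :, None] * images[None, :, :, :]
    kfull = fft2c(coil_imgs, axes=(1, 2))

    acs_start = (H - cfg.n_acs) // 2
    acs = kfull[:, acs_start:acs_start + cfg.n_acs, :, :].mean(axis=3)

    line_mask = np.zeros(H, dtype=np.uint8)
    line_mask[grid_lines(H, cfg.accel)] = 1
    line_mask[acs_start:acs_start + cfg.n_acs] = 1
    mask = np.repeat(line_mask[:, None], T, axis=1)

    data = kfull * line_mask[None, :, None, None]
    return MultiCoilKSpace(
        data=data,
        mask=mask,
        acs=acs,
        accel=cfg.accel,
        n_acs=cfg.n_acs,
        dwell_scale=cfg.dwell_scale,
        meta={"seed": cfg.seed, "fft_convention": "unitary-centered"},
    )


def add_receiver_noise(
    ksp: MultiCoilKSpace,
    noise_cov: np.ndarray,
    seed: int,
    n_prescan: int | None = None,
) -> tuple[MultiCoilKSpace, NoisePreScan]:
    """Add coil-correlated complex Gaussian receiver noise.

    Noise with across-coil covariance ``noise_cov`` (in the ``E[eta eta^H]``
    sense: a unit-variance complex channel has real and imaginary parts of
    variance 1/2 each) is added to acquired samples only — the masked lines of
    ``data`` and the ACS block.  The ACS receives noise at ``1/sqrt(T)`` of
    the per-sample level because it is the average of T interleaved
    calibration acquisitions.  A noise-only pre-scan drawn from the same
    covariance is returned alongside.
    """
    psi = _validate_cov(noise_cov)
    C = ksp.n_coils
    if psi.shape[0] != C:
        raise ValueError("noise_cov size must match coil count")
    L = np.linalg.cholesky(psi)
    rng = np.random.default_rng(seed)

    def corr_noise(shape: tuple[int, ...]) -> np.ndarray:
        # shape leads with the coil axis
        z = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
        return np.einsum("ij,j...->i...", L, z)

    data = ksp.data.copy()
    noise = corr_noise(data.shape)
    data += noise * ksp.mask[None, :, None, :]

    acs = ksp.acs + corr_noise(ksp.acs.shape) / np.sqrt(ksp.n_frames)

    if n_prescan is None:
        n_prescan = max(256 * C, 65536)
    prescan = NoisePreScan(samples=corr_noise((C, n_prescan)))

    noisy = MultiCoilKSpace(
        data=data, mask=ksp.mask.copy(), acs=acs, accel=ksp.accel,
        n_acs=ksp.n_acs, dwell_scale=ksp.dwell_scale,
        meta={**ksp.meta, "noise_seed": seed},
    )
    return noisy, prescan


def simulate_acquisition(
    cfg: PhantomConfig,
) -> tuple[MultiCoilKSpace, NoisePreScan, dict[str, np.ndarray], np.ndarray]:
    """Full phantom acquisition: noisy k-space, pre-scan, labels, true coil maps."""
    images, labels = make_phantom_series(cfg)
    coil_maps = make_coil_maps(cfg)
    ksp = synthesize_kspace(images, coil_maps, cfg)
    noisy, prescan = add_receiver_noise(ksp, cfg.noise_cov, seed=cfg.seed)
    return noisy, prescan, labels, coil_maps
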