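"""g-factor maps and g-factor augmentation.

The geometry (g-) factor quantifies the spatially varying noise amplification
a parallel-imaging reconstruction adds on top of the sqrt(R) penalty for
acquiring fewer samples.  Here it is computed analytically from the
image-domain unmixing coefficients — ``g(p) = (n_grid/H) * rss_c(u_c(p))``,
the quantity with noise-SD units under the SNR-unit scaling of
:mod:`snraware.recon` — and validated against the pseudo-replica Monte-Carlo
estimate.

The augmentation trick: although an acquisition is collected at a single
acceleration (typically R=2), its ACS block supports GRAPPA calibrations at
*any* acceleration, so realistic g-maps for R=2..8 can all be derived from
one scan and drawn at random when synthesizing training noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import MultiCoilKSpace, grid_lines
from .recon import (
    CalibrationError,
    UnmixingMap,
    calibrate_grappa,
    estimate_coil_maps,
    kernel_to_unmixing,
)

__all__ = ["GFactorMap", "GFactorSet", "compute_gfactor",
           "compute_gfactor_set", "draw_augmentation_gmap"]

#: floor applied before any division by g, to avoid blow-up outside the
#: coil-sensitivity support
G_CLAMP = 1e-3


@dataclass
class GFactorMap:
    """Pixel-wise noise-amplification map for one acceleration factor."""

    g: np.ndarray
    accel: int
    provenance: dict = field(default_factory=dict)

    def clamped(self) -> np.ndarray:
        """The map with the division-safe lower clamp applied."""
        return np.maximum(self.g, G_CLAMP)


@dataclass
class GFactorSet:
    """Ordered g-maps for several accelerations from one calibration."""

    maps: list[GFactorMap]
    source: str = ""

    def __post_init__(self) -> None:
        if len({m.accel for m in self.maps}) != len(self.maps):
            raise ValueError("duplicate acceleration values in GFactorSet")
        shapes = {m.g.shape for m in self.maps}
        if len(shapes) > 1:
            raise ValueError("all g-maps in a set must share one matrix size")
        self.maps = sorted(self.maps, key=lambda m: m.accel)

    @property
    def accels(self) -> list[int]:
        return [m.accel for m in self.maps]


def compute_gfactor(unmix: UnmixingMap) -> GFactorMap:
    """Analytic g-map from unmixing coefficients.

    ``g(p) = (n_grid/H) * sqrt(sum_c |u_c(p)|^2)`` — the root-sum-of-squares
    of the coefficients carries noise-SD units; the ``n_grid/H`` scalar (1/R
    for R dividing H) matches the SNR-unit reconstruction scaling so that g
    equals the pseudo-replica noise SD of the reconstruction at that R, and
    ``g == 1`` identically for R = 1.
    """
    H = unmix.matrix_size[0]
    n_grid = len(grid_lines(H, unmix.accel))
    g = (n_grid / H) * np.sqrt(np.sum(np.abs(unmix.u) ** 2, axis=0))
    return GFactorMap(g=g, accel=unmix.accel,
                      provenance=dict(unmix.provenance))


def _kernel_size_for(acs_shape: tuple[int, int, int], accel: int,
                     preferred: tuple[int, int] = (4, 5)) -> tuple[int, int]:
    """Largest supported kernel (by source blocks) the ACS can calibrate."""
    C, Ny, Nx = acs_shape
    nb0, nx = preferred
    for nb in range(nb0, 1, -1):
        blocks = np.arange(-((nb - 1) // 2), nb // 2 + 1)
        span = 0
        for o in range(1, accel):
            sd = blocks * accel - o
            span = max(span, sd.max() - sd.min())
        n_eq = max(0, Ny - span) * max(0, Nx - (nx - 1))
        if n_eq >= 4 * C * nb * nx:
            return (nb, nx)
    return (2, nx)


def compute_gfactor_set(
    ksp: MultiCoilKSpace,
    r_values: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    regularization: float = 1e-4,
) -> GFactorSet:
    """g-maps for several accelerations from one acquisition's ACS.

    For each requested R a GRAPPA calibration is run on the (pre-whitened)
    ACS at that synthetic acceleration, converted to unmixing coefficients,
    and reduced to a g-map.  The number of source blocks shrinks from the
    4-block default when the ACS cannot furnish 4x more calibration equations
    than unknowns; the choice is recorded per map.
    """
    if not np.any(ksp.acs):
        raise CalibrationError("acquisition has no ACS block; cannot calibrate")
    H, W = ksp.matrix_size
    coil_maps = estimate_coil_maps(ksp.acs, (H, W))
    maps: list[GFactorMap] = []
    for R in r_values:
        try:
            ks = _kernel_size_for(ksp.acs.shape, R)
            kern = calibrate_grappa(ksp.acs, R, kernel_size=ks,
                                    regularization=regularization)
        except (CalibrationError, np.linalg.LinAlgError) as exc:
            raise CalibrationError(f"g-factor calibration failed at R={R}: {exc}") from exc
        unmix = kernel_to_unmixing(kern, coil_maps, (H, W))
        gmap = compute_gfactor(unmix)
        gmap.provenance["kernel_size"] = ks
        if R > ksp.n_coils:
            gmap.provenance["warning"] = (
                f"acceleration R={R} exceeds the {ksp.n_coils}-coil count; "
                "the calibration is ill-conditioned (condition numbers: "
                f"{kern.provenance['condition_numbers']})"
            )
        maps.append(gmap)
    return GFactorSet(maps=maps, source=str(ksp.meta.get("seed", "unknown")))


def draw_augmentation_gmap(gset: GFactorSet, rng: np.random.Generator) -> GFactorMap:
    """Uniform random draw of one g-map from the set."""
    if not gset.maps:
        raise ValueError("cannot draw from an empty GFactorSet")
    return gset.maps[int(rng.integers(len(gset.maps)))]
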