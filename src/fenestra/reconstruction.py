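"""Quantitative-imaging topography reconstruction.

A force-volume scan stores a full approach curve per pixel, so the sample
topography can be rebuilt at any chosen load force after the fact: the
height at a pixel is the deflection-corrected tip position at the first
persistent crossing of the target force.  Reconstructing the same scan at
two forces (e.g. 170 and 300 pN) is what makes the fenestration
deformability statistic possible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mechanics import N_PER_M_TO_PN_PER_NM

__all__ = ["HeightMap", "reconstruct_height_at_force", "reconstruct_stack"]

log = logging.getLogger(__name__)

#: a force crossing must hold for this many consecutive samples to count
PERSISTENCE = 2


@dataclass
class HeightMap:
    """Topography (nm) reconstructed at one load force.

    Heights are relative (arbitrary global offset); invalid pixels (peak
    force below the target) are masked out and carry NaN.
    """

    heights: np.ndarray
    valid_mask: np.ndarray
    pixel_size: float
    load_force: float
    fast_axis: str = "x"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.heights.shape != self.valid_mask.shape:
            raise ValueError("heights and valid_mask shapes differ")
        if self.load_force <= 0:
            raise ValueError("load_force must be positive")

    @property
    def n_invalid(self) -> int:
        return int((~self.valid_mask).sum())


def _first_persistent_crossing(force: np.ndarray, z: np.ndarray, target: float):
    """Vectorised first crossing of ``target`` that persists PERSISTENCE
    samples, linearly interpolated between the bracketing samples.

    force : (npix, n).  Returns (z_cross, valid)."""
    npix, n = force.shape
    above = force >= target
    if PERSISTENCE > 1:
        ok = above.copy()
        for j in range(1, PERSISTENCE):
            ok[:, : n - j] &= above[:, j:]
        ok[:, n - PERSISTENCE + 1 :] = above[:, n - PERSISTENCE + 1 :]
    else:
        ok = above
    has = ok.any(axis=1)
    idx = np.where(has, ok.argmax(axis=1), n - 1)
    rows = np.arange(npix)
    f1 = force[rows, idx]
    z1 = z[idx]
    prev = np.maximum(idx - 1, 0)
    f0 = force[rows, prev]
    z0 = z[prev]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(f1 > f0, (target - f0) / (f1 - f0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    z_cross = np.where(idx > 0, z0 + frac * (z1 - z0), z1)
    return z_cross, has


def reconstruct_height_at_force(fvmap, F_target: float) -> HeightMap:
    """Rebuild the topography of a force-volume map at a chosen load force.

    Height = (z_max - z_cross) + F_target/k: the tip-sample surface
    position, deflection-corrected so that rigid and compliant pixels are
    comparable and height decreases monotonically with load.
    """
    if F_target <= 0:
        raise ValueError("F_target must be positive")
    force = np.asarray(fvmap.force, dtype=float)
    z = np.asarray(fvmap.z, dtype=float)
    ny, nx, n = force.shape
    z_cross, valid = _first_persistent_crossing(force.reshape(-1, n), z, F_target)
    k = fvmap.spring_constant * N_PER_M_TO_PN_PER_NM
    heights = (z[-1] - z_cross) + F_target / k
    heights = np.where(valid, heights, np.nan).reshape(ny, nx)
    valid = valid.reshape(ny, nx)
    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > 0.5:
        log.warning(
            "reconstruction at %.0f pN: %.0f%% of pixels never reach the target force",
            F_target,
            100 * frac_invalid,
        )
        warnings.warn(
            f"more than half of the pixels are invalid at {F_target:.0f} pN"
        )
    return HeightMap(
        heights=heights,
        valid_mask=valid,
        pixel_size=fvmap.pixel_size,
        load_force=float(F_target),
        fast_axis=getattr(fvmap, "fast_axis", "x"),
        metadata={"spring_constant_N_per_m": fvmap.spring_constant},
    )


def reconstruct_stack(fvmap, targets: Sequence[float]) -> list[HeightMap]:
    """One height map per target force, from the same scan (deterministic)."""
    targets = list(targets)
    if not targets:
        raise ValueError("targets must not be empty")
    if any(t <= 0 for t in targets):
        raise ValueError("targets must be positive")
    if sorted(targets) != targets:
        raise ValueError("targets must be sorted ascending")
    return [reconstruct_height_at_force(fvmap, t) for t in targets]
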