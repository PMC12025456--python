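"""Hertz–Sneddon contact mechanics for AFM force–distance curves.

Turns raw approach curves into contact points, indentation profiles and
apparent Young's moduli.  Everything internal runs in nm / pN / Pa: the
Hertz prefactor for a Pa modulus and nm lengths carries a factor 1e-6
(1 Pa = 1e-6 pN/nm^2), which keeps the delta^(3/2) terms well scaled.

Models
------
sphere (radius R):     F = (4/3) * E/(1-nu^2) * sqrt(R) * delta^(3/2)
pyramid (half-angle):  F = 0.7453 * tan(theta) * E/(1-nu^2) * delta^2

The pyramidal prefactor is the four-sided-pyramid constant; it is stored
on the result so downstream consumers can audit it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ForceCurve",
    "IndenterModel",
    "HertzFitResult",
    "NoContactError",
    "correct_baseline",
    "estimate_contact_point",
    "compute_indentation",
    "hertz_force_sphere",
    "sneddon_force_pyramid",
    "invert_indentation",
    "fit_apparent_modulus",
    "fit_force_volume",
]

#: 1 Pa expressed in pN/nm^2.
PA_TO_PN_PER_NM2 = 1e-6
#: 1 N/m expressed in pN/nm.
N_PER_M_TO_PN_PER_NM = 1e3
#: Four-sided pyramid (Bilodeau-type) prefactor.
PYRAMID_PREFACTOR = 0.7453

MIN_CURVE_SAMPLES = 16


class NoContactError(ValueError):
    """Raised when no tip-sample contact can be located in a curve."""


@dataclass
class ForceCurve:
    """A single approach force-distance record.

    z : piezo extension in nm, strictly monotonic, increasing toward the
        sample.  force : cantilever load in pN.  spring_constant in N/m is
    consumed as metadata (thermal-tune calibration happens upstream).
    """

    z: np.ndarray
    force: np.ndarray
    spring_constant: float
    direction: Literal["approach", "retract"] = "approach"
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape:
            raise ValueError("z and force must have the same length")
        if self.z.size < MIN_CURVE_SAMPLES:
            raise ValueError(
                f"curve needs at least {MIN_CURVE_SAMPLES} samples, got {self.z.size}"
            )
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotonic")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")

    @property
    def k_pn_per_nm(self) -> float:
        return self.spring_constant * N_PER_M_TO_PN_PER_NM

    @property
    def sample_spacing(self) -> float:
        return float(np.median(np.abs(np.diff(self.z))))


@dataclass
class IndenterModel:
    """Tip geometry plus the Poisson ratio of the sample.

    ``kind`` selects the contact law; only the fields of that kind are
    meaningful.  nu defaults to 0.5 (incompressible), the standard soft
    matter assumption.
    """

    kind: Literal["sphere", "pyramid"]
    tip_radius: float | None = None
    half_angle: float | None = None
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.kind == "sphere":
            if self.tip_radius is None or self.tip_radius <= 0:
                raise ValueError("sphere model requires tip_radius > 0")
            if self.half_angle is not None:
                raise ValueError("sphere model must not set half_angle")
        elif self.kind == "pyramid":
            if self.half_angle is None or not 0 < self.half_angle < 90:
                raise ValueError("pyramid model requires 0 < half_angle < 90 deg")
            if self.tip_radius is not None:
                raise ValueError("pyramid model must not set tip_radius")
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown indenter kind {self.kind!r}")

    def prefactor(self, modulus_pa: float | np.ndarray) -> float | np.ndarray:
        """Contact-law prefactor A with F = A * delta^exponent (pN, nm)."""
        red = modulus_pa * PA_TO_PN_PER_NM2 / (1.0 - self.poisson_ratio**2)
        if self.kind == "sphere":
            return (4.0 / 3.0) * red * np.sqrt(self.tip_radius)
        return PYRAMID_PREFACTOR * np.tan(np.deg2rad(self.half_angle)) * red

    @property
    def exponent(self) -> float:
        return 1.5 if self.kind == "sphere" else 2.0


@dataclass
class HertzFitResult:
    """Apparent modulus fit of one approach curve."""

    E_app: float
    contact_point: float
    indentation_max: float
    residual_rms: float
    model: IndenterModel
    fit_window: tuple[float, float]
    n_samples: int = 0
    prefactor_constant: float = field(default=PYRAMID_PREFACTOR)


# ---------------------------------------------------------------------------
# closed-form sphere model


def hertz_force_sphere(delta, E: float, nu: float = 0.5, R: float = 25.0):
    """Hertz sphere force (pN) at indentation delta (nm)."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    if E <= 0 or R <= 0:
        raise ValueError("E and R must be positive")
    A = (4.0 / 3.0) * E * PA_TO_PN_PER_NM2 / (1.0 - nu**2) * np.sqrt(R)
    out = A * delta**1.5
    return float(out) if out.ndim == 0 else out


def sneddon_force_pyramid(delta, E: float, nu: float = 0.5, half_angle: float = 17.5):
    """Four-sided pyramid force (pN) at indentation delta (nm)."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    if E <= 0:
        raise ValueError("E must be positive")
    if not 0 < half_angle < 90:
        raise ValueError("half_angle must lie in (0, 90) degrees")
    A = PYRAMID_PREFACTOR * np.tan(np.deg2rad(half_angle)) * E * PA_TO_PN_PER_NM2 / (1.0 - nu**2)
    out = A * delta**2
    return float(out) if out.ndim == 0 else out


def invert_indentation(F, E: float, nu: float = 0.5, R: float = 25.0):
    """Indentation (nm) of a Hertz sphere at force F (pN); exact inverse of
    :func:`hertz_force_sphere`: delta = [3 F (1-nu^2) / (4 E sqrt(R))]^(2/3)."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    if E <= 0 or R <= 0:
        raise ValueError("E and R must be positive")
    A = (4.0 / 3.0) * E * PA_TO_PN_PER_NM2 / (1.0 - nu**2) * np.sqrt(R)
    out = (F / A) ** (2.0 / 3.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# curve processing


def correct_baseline(curve: ForceCurve, baseline_fraction: float = 0.3) -> ForceCurve:
    """Subtract a straight line fitted to the leading (non-contact) part.

    The line is fitted to the first ``baseline_fraction`` of the approach;
    the corrected baseline has (near) zero mean and slope, which removes
    instrument drift before any contact analysis.
    """
    if not 0.0 < baseline_fraction < 0.9:
        raise ValueError("baseline_fraction must lie in (0, 0.9)")
    n = curve.z.size
    m = max(int(round(n * baseline_fraction)), 4)
    coef = np.polyfit(curve.z[:m], curve.force[:m], 1)
    corrected = curve.force - np.polyval(coef, curve.z)
    return ForceCurve(
        z=curve.z.copy(),
        force=corrected,
        spring_constant=curve.spring_constant,
        direction=curve.direction,
        temperature=curve.temperature,
    )


def _baseline_noise_sd(force: np.ndarray, fraction: float = 0.3) -> float:
    m = max(int(round(force.size * fraction)), 4)
    return float(np.std(force[:m]))


def _threshold_crossing_index(
    force: np.ndarray, threshold: float, persist: int
) -> int | None:
    """First index where force exceeds threshold for ``persist`` samples."""
    above = force > threshold
    if persist <= 1:
        idx = np.flatnonzero(above)
        return int(idx[0]) if idx.size else None
    run = np.convolve(above.astype(int), np.ones(persist, dtype=int), mode="valid")
    idx = np.flatnonzero(run == persist)
    return int(idx[0]) if idx.size else None


def _threshold_contact(
    curve: ForceCurve,
    n_sigma: float = 3.0,
    persist: int = 5,
    extrapolate: bool = True,
) -> float:
    sd = _baseline_noise_sd(curve.force)
    threshold = max(n_sigma * sd, 1e-12)
    i0 = _threshold_crossing_index(curve.force, threshold, persist)
    if i0 is None:
        raise NoContactError("no contact: force never exceeds the noise threshold")
    if not extrapolate:
        return float(curve.z[i0])
    # Back-extrapolate F^(2/3) (linear in z for a Hertz sphere at small
    # deflection) to zero force; undoes the systematic lateness of the raw
    # crossing on compliant samples.
    hi = min(i0 + 25, curve.z.size)
    seg = slice(i0, hi)
    f = curve.force[seg]
    z = curve.z[seg]
    good = f > 0
    if good.sum() < 3:
        return float(curve.z[i0])
    y = f[good] ** (2.0 / 3.0)
    b, a = np.polyfit(z[good], y, 1)
    if b <= 0:
        return float(curve.z[i0])
    zc = -a / b
    # keep the estimate inside a sane bracket around the raw crossing
    lo = curve.z[0]
    return float(np.clip(zc, lo, curve.z[i0]))


def _residual_search_contact(
    curve: ForceCurve,
    model: IndenterModel,
    fit_window: tuple[float, float] | None,
    candidates: np.ndarray | None = None,
) -> float:
    """Brute-force contact point: the candidate z_c minimising the
    least-squares contact-model residual.  Serves as the auditable oracle.

    Candidates are scored on a fixed curve segment running from the start
    of the ramp to one fit-window depth past the noise-threshold crossing,
    with the baseline modelled as zero force — anchoring the segment to
    the curve (not the candidate) is what makes misplaced contact points
    pay for the unexplained force rise."""
    z, force = curve.z, curve.force
    sd = _baseline_noise_sd(force)
    i0 = _threshold_crossing_index(force, max(3.0 * sd, 1e-12), 2)
    if i0 is None:
        raise NoContactError("no contact: force never exceeds the noise threshold")
    if candidates is None:
        candidates = z[: i0 + 2]
    hi = fit_window[1] if fit_window is not None else float(z[-1] - z[i0])
    i_end = int(np.searchsorted(z, z[i0] + 1.1 * hi))
    seg = slice(0, min(i_end + 1, z.size))
    unit = model.prefactor(1.0)
    best_zc, best_res = None, np.inf
    for zc in np.atleast_1d(candidates):
        res = _fit_at_contact(curve, model, float(zc), fit_window)
        if res is None:
            continue
        E = res[0]
        delta = np.clip((z - zc) - force / curve.k_pn_per_nm, 0.0, None)
        pred = np.where(z >= zc, E * unit * delta**model.exponent, 0.0)
        score = float(np.mean((force[seg] - pred[seg]) ** 2))
        if score < best_res:
            best_zc, best_res = float(zc), score
    if best_zc is None:
        raise NoContactError("no candidate contact point admits a valid fit")
    return best_zc


def estimate_contact_point(
    curve: ForceCurve,
    method: Literal["threshold", "residual_search"] = "threshold",
    n_sigma: float = 3.0,
    persist: int = 5,
    extrapolate: bool = True,
    model: IndenterModel | None = None,
    fit_window: tuple[float, float] | None = None,
) -> float:
    """Locate the tip-sample contact point of a baseline-corrected approach.

    threshold : first persistent crossing of n_sigma x baseline noise,
    refined by Hertz-consistent back-extrapolation (``extrapolate``).
    residual_search : exhaustive scan of candidate contact points
    minimising the contact-model fit residual (needs ``model``).
    """
    if method == "threshold":
        return _threshold_contact(curve, n_sigma, persist, extrapolate)
    if method == "residual_search":
        if model is None:
            model = IndenterModel(kind="sphere", tip_radius=25.0)
        return _residual_search_contact(curve, model, fit_window)
    raise ValueError(f"unknown contact method {method!r}")


def compute_indentation(curve: ForceCurve, z_c: float) -> np.ndarray:
    """Indentation delta = (z - z_c) - F/k beyond contact, clipped at 0."""
    if curve.spring_constant <= 0:
        raise ValueError("spring constant must be positive")
    if not curve.z.min() <= z_c <= curve.z.max():
        raise ValueError("contact point lies outside the curve range")
    delta = (curve.z - z_c) - curve.force / curve.k_pn_per_nm
    delta[curve.z < z_c] = 0.0
    return np.clip(delta, 0.0, None)


def _fit_at_contact(
    curve: ForceCurve,
    model: IndenterModel,
    z_c: float,
    fit_window: tuple[float, float] | None,
    min_samples: int = 8,
) -> tuple[float, float, np.ndarray, np.ndarray] | None:
    """Closed-form least-squares modulus at a fixed contact point.

    E enters the contact law linearly, so for given z_c the LSQ modulus is
    sum(F*x)/sum(x^2) with x = A(E=1) * delta^exp.  Returns
    (E, rss_per_sample, delta, force) or None if the window is too thin.
    """
    delta = (curve.z - z_c) - curve.force / curve.k_pn_per_nm
    mask = curve.z >= z_c
    if fit_window is not None:
        lo, hi = fit_window
        mask &= (delta >= lo) & (delta <= hi)
    else:
        lo, hi = 0.0, np.inf
        mask &= delta > 0
    if mask.sum() < min_samples:
        return None
    d = np.clip(delta[mask], 0.0, None)
    f = curve.force[mask]
    x = model.prefactor(1.0) * d**model.exponent
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        return None
    E = float(np.dot(f, x) / sxx)
    if E <= 0:
        return None
    rss = float(np.mean((f - E * x) ** 2))
    return E, rss, d, f


def fit_apparent_modulus(
    curve: ForceCurve,
    model: IndenterModel,
    fit_window: tuple[float, float],
    z_c: float | None = None,
    refine: bool = True,
    refine_halfwidth: int = 30,
) -> HertzFitResult:
    """Least-squares apparent Young's modulus over an indentation window.

    If no contact point is supplied, a threshold estimate is refined by a
    local residual-search grid (joint z_c/E fit), which removes the
    contact-point bias that otherwise dominates on soft samples.
    """
    lo, hi = fit_window
    if not 0 <= lo < hi:
        raise ValueError("fit_window must satisfy 0 <= lo < hi")
    if z_c is None:
        z_c = _threshold_contact(curve)
        if refine:
            dz = curve.sample_spacing
            grid = z_c + dz * np.arange(-refine_halfwidth, refine_halfwidth + 1)
            grid = grid[(grid >= curve.z[0]) & (grid <= curve.z[-1])]
            z_c = _residual_search_contact(curve, model, fit_window, candidates=grid)
    res = _fit_at_contact(curve, model, z_c, fit_window)
    if res is None:
        raise ValueError(
            "fewer than 8 samples fall inside the fit window; widen the window "
            "or check the contact point"
        )
    E, rss, d, f = res
    return HertzFitResult(
        E_app=E,
        contact_point=float(z_c),
        indentation_max=float(d.max()),
        residual_rms=float(np.sqrt(rss)),
        model=model,
        fit_window=(float(lo), float(hi)),
        n_samples=int(d.size),
    )


# ---------------------------------------------------------------------------
# vectorised force-volume fitting


def fit_force_volume(
    fvmap,
    model: IndenterModel,
    fit_window: tuple[float, float],
    n_sigma: float = 3.0,
    persist: int = 5,
    refine_halfwidth: int = 32,
):
    """Fit every pixel of a force-volume map (vectorised over the grid).

    Per pixel: threshold contact estimate, then a residual-search grid of
    ``2*refine_halfwidth+1`` sample-spaced candidate contact points with the
    closed-form modulus at each; the candidate with the smallest residual
    wins.  Returns (E_map Pa, zc_map nm, residual_rms_map pN); pixels where
    no contact or no valid window exists carry NaN.

    ``fvmap`` is a ``fenestra.synthetic.ForceVolumeMap`` or anything with
    .force (ny, nx, n) pN, .z (n) nm and .spring_constant N/m.
    """
    force = np.asarray(fvmap.force, dtype=float)
    z = np.asarray(fvmap.z, dtype=float)
    ny, nx, n = force.shape
    k = fvmap.spring_constant * N_PER_M_TO_PN_PER_NM
    flat = force.reshape(-1, n)
    npix = flat.shape[0]
    dz = float(np.median(np.diff(z)))

    # baseline noise and raw threshold crossing, vectorised
    nb = max(int(round(n * 0.3)), 4)
    sd = flat[:, :nb].std(axis=1)
    thr = np.maximum(n_sigma * sd, 1e-12)
    above = flat > thr[:, None]
    if persist > 1:
        kern = np.ones(persist, dtype=int)
        runs = np.apply_along_axis(
            lambda a: np.convolve(a, kern, mode="valid"), 1, above.astype(int)
        )
        hit = runs == persist
    else:
        hit = above
    has = hit.any(axis=1)
    first = np.where(has, hit.argmax(axis=1), 0)
    zc0 = z[first]

    lo, hi = fit_window
    x_unit = model.prefactor(1.0)
    expo = model.exponent

    best_E = np.full(npix, np.nan)
    best_zc = np.full(npix, np.nan)
    best_rss = np.full(npix, np.inf)
    best_n = np.zeros(npix, dtype=int)
    defl = flat / k

    def _sweep(centers: np.ndarray, offsets: np.ndarray) -> None:
        for off in offsets:
            zc = centers + off
            _score(zc)

    def _score(zc: np.ndarray) -> None:
        delta = (z[None, :] - zc[:, None]) - defl
        mask = (z[None, :] >= zc[:, None]) & (delta >= lo) & (delta <= hi)
        d = np.where(mask, np.clip(delta, 0.0, None), 0.0)
        x = x_unit * d**expo
        sxx = np.einsum("ij,ij->i", x, x)
        sxf = np.einsum("ij,ij->i", x, np.where(mask, flat, 0.0))
        nsamp = mask.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            E = sxf / sxx
        resid = np.where(mask, flat - E[:, None] * x, 0.0)
        with np.errstate(invalid="ignore"):
            rss = np.einsum("ij,ij->i", resid, resid) / np.maximum(nsamp, 1)
        ok = has & (nsamp >= 8) & (E > 0) & np.isfinite(rss)
        better = ok & (rss < best_rss)
        best_E[better] = E[better]
        best_zc[better] = zc[better]
        best_rss[better] = rss[better]
        best_n[better] = nsamp[better]

    # coarse pass at sample spacing, then a sub-sample pass around the best
    _sweep(zc0, dz * np.arange(-refine_halfwidth, refine_halfwidth + 1))
    coarse = np.where(np.isfinite(best_zc), best_zc, zc0)
    _sweep(coarse, dz * np.arange(-4, 5) * 0.2)

    valid = np.isfinite(best_E)
    if valid.sum() < 0.5 * npix:
        warnings.warn("more than half of the pixels failed the modulus fit")
    shape = (ny, nx)
    return (
        best_E.reshape(shape),
        best_zc.reshape(shape),
        np.sqrt(np.where(np.isfinite(best_rss), best_rss, np.nan)).reshape(shape),
    )
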