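"""Synthetic ground-truth data for every stage of the pipeline.

The force-volume phantom emulates a fenestrated endothelial cell resting on
a hydrogel-like substrate, scanned in a quantitative-imaging mode: one
approach force-distance curve per pixel.  The phantom carries a hidden
:class:`GroundTruth` (height map, modulus map, pore table, porosity,
per-load pore diameters) so that parameter-recovery tests need no
instrument data.

Membrane / pore model
---------------------
The cell body is a membrane of height ``cell_height`` with Young's modulus
``cell_modulus`` over a substrate of ``substrate_modulus``; the nucleus is
a flat-topped dome.  A fenestration is an open hole of radius r0 (tip
reaches the substrate) surrounded by an annular rim of width
``w = rim_compliance * r0``.  The rim membrane supports Hertzian load up to
a critical collapse force that rises linearly across the annulus,

    F_crit(r) = rim_collapse_force * (r - r0) / w,

after which the curve plateaus while the tip passes through to the
substrate.  At imaging force F the apparent pore radius is therefore

    r_app(F) = r0 + w * clip(F / rim_collapse_force, 0, 1),

non-decreasing in load, strictly increasing in ``rim_compliance``, and
invertible in closed form (:func:`calibrate_rim_compliance`).  This is a
stand-in for the unknown mechanics of fenestration deformability, not a
mechanistic claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .mechanics import N_PER_M_TO_PN_PER_NM, PA_TO_PN_PER_NM2

__all__ = [
    "PhantomSpec",
    "PorePlacement",
    "GroundTruth",
    "ForceVolumeMap",
    "AmplitudeSweep",
    "generate_phantom",
    "generate_amplitude_sweep",
    "generate_nuclei_image",
    "generate_endocytosis_table",
    "calibrate_rim_compliance",
    "control_like_spec",
    "ko_like_spec",
    "deformability_spec",
]

#: fraction of the headroom above the tallest feature reserved as
#: pre-contact baseline (the rest is post-contact travel)
_BASELINE_HEADROOM = 0.3


class PhantomSpec(BaseModel):
    """Parameters of a force-volume phantom.  Lengths nm, moduli Pa,
    forces pN, spring constant N/m."""

    grid_nx: int = 64
    grid_ny: int = 64
    pixel_size: float = 25.0
    curve_n_samples: int = 256
    z_range: float = 1000.0
    substrate_modulus: float = 52_000.0
    cell_modulus: float = 8_000.0
    cell_height: float = 400.0
    nucleus_height: float = 300.0
    nucleus_radius: float = 300.0
    n_sieve_plates: int = 2
    pores_per_plate: int = 3
    pore_diameter_mean: float = 200.0
    pore_diameter_sd: float = 50.0
    pore_diameter_min: float = 50.0
    pore_diameter_max: float = 350.0
    rim_compliance: float = Field(default=0.5, ge=0.0)
    rim_collapse_force: float = 400.0
    labyrinth_pores: int = 0
    tip_radius: float = 25.0
    poisson_ratio: float = 0.5
    spring_constant: float = 0.1
    force_noise_sd: float = 15.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if self.grid_nx < 4 or self.grid_ny < 4:
            raise ValueError("grid_nx/grid_ny must be at least 4")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.curve_n_samples < 32:
            raise ValueError("curve_n_samples must be at least 32")
        if self.pore_diameter_min < 0:
            raise ValueError("pore_diameter_min must be non-negative")
        if self.pore_diameter_max < self.pore_diameter_min:
            raise ValueError("pore_diameter_max must be >= pore_diameter_min")
        for name in ("substrate_modulus", "cell_modulus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.tip_radius <= 0:
            raise ValueError("tip_radius must be positive")
        if self.force_noise_sd < 0:
            raise ValueError("force_noise_sd must be non-negative")
        if self.rim_collapse_force <= 0:
            raise ValueError("rim_collapse_force must be positive")
        if self.cell_height < 0 or self.nucleus_height < 0:
            raise ValueError("cell_height/nucleus_height must be non-negative")
        h_max = self.cell_height + self.nucleus_height
        dz = self.z_range / (self.curve_n_samples - 1)
        if self.z_range <= h_max + max(200.0, 16 * dz) / _BASELINE_HEADROOM * 0.3:
            # headroom must leave both a baseline and post-contact travel
            raise ValueError(
                "z_range too small: must exceed cell_height + nucleus_height "
                "plus room for baseline and indentation"
            )
        n_pores = self.n_sieve_plates * self.pores_per_plate + self.labyrinth_pores
        if n_pores > 0 and self.cell_height <= 0:
            raise ValueError("cell_height must be positive when pores are requested")
        return self

    @property
    def hertz_prefactor_cell(self) -> float:
        return _hertz_A(self.cell_modulus, self.poisson_ratio, self.tip_radius)

    @property
    def hertz_prefactor_substrate(self) -> float:
        return _hertz_A(self.substrate_modulus, self.poisson_ratio, self.tip_radius)


def _hertz_A(E: float, nu: float, R: float) -> float:
    """Sphere contact prefactor in pN/nm^1.5."""
    return (4.0 / 3.0) * E * PA_TO_PN_PER_NM2 / (1.0 - nu**2) * np.sqrt(R)


@dataclass
class PorePlacement:
    """One placed pore: rest geometry plus its load-dependent appearance."""

    x_nm: float
    y_nm: float
    radius_nm: float
    rim_width_nm: float
    collapse_force_pn: float
    sieve_plate_id: int | None
    in_nucleus: bool = False

    @property
    def diameter_nm(self) -> float:
        return 2.0 * self.radius_nm

    def apparent_radius(self, force_pn: float) -> float:
        t = np.clip(force_pn / self.collapse_force_pn, 0.0, 1.0)
        return self.radius_nm + self.rim_width_nm * t

    def apparent_diameter(self, force_pn: float) -> float:
        return 2.0 * self.apparent_radius(force_pn)


@dataclass
class GroundTruth:
    """Hidden truth of a phantom, for parameter-recovery testing."""

    true_height_map: np.ndarray
    true_modulus_map: np.ndarray
    pore_table: list[PorePlacement]
    cell_mask: np.ndarray
    nuclear_mask: np.ndarray
    pore_mask: np.ndarray
    rim_mask: np.ndarray
    pixel_size: float
    true_porosity: float
    true_enlargement: float
    n_rejected: int = 0

    @property
    def cell_area_um2(self) -> float:
        return float(self.cell_mask.sum()) * self.pixel_size**2 / 1e6

    @property
    def pure_phase_mask(self) -> np.ndarray:
        """Pixels whose curve follows a single Hertz law (no rim plateau)."""
        return ~self.rim_mask

    def enlargement_between(self, f_low: float, f_high: float) -> float:
        pores = [p for p in self.pore_table if not p.in_nucleus]
        if not pores:
            return 1.0
        folds = [p.apparent_diameter(f_high) / p.apparent_diameter(f_low) for p in pores]
        return float(np.mean(folds))


@dataclass
class ForceVolumeMap:
    """Dense grid of approach force-distance curves (the raw substrate of
    all downstream AFM analyses)."""

    force: np.ndarray  # (ny, nx, n) pN
    z: np.ndarray  # (n,) nm, shared piezo ramp
    pixel_size: float  # nm
    spring_constant: float  # N/m
    fast_axis: str = "x"
    direction: str = "approach"
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.force.shape[:2]

    def curve(self, iy: int, ix: int):
        from .mechanics import ForceCurve

        return ForceCurve(
            z=self.z.copy(),
            force=self.force[iy, ix].astype(float),
            spring_constant=self.spring_constant,
        )


def calibrate_rim_compliance(
    target_fold: float,
    f_low: float = 170.0,
    f_high: float = 300.0,
    collapse_force: float = 400.0,
) -> float:
    """Rim compliance whose true enlargement (f_high/f_low fold change)
    equals ``target_fold``; closed-form inverse of the rim model."""
    if target_fold < 1.0:
        raise ValueError("target_fold must be >= 1")
    t_lo = min(f_low / collapse_force, 1.0)
    t_hi = min(f_high / collapse_force, 1.0)
    denom = t_hi - target_fold * t_lo
    if denom <= 0:
        raise ValueError(
            f"target fold {target_fold} unreachable: maximum is {t_hi / t_lo:.3f} "
            "for these forces and collapse force"
        )
    return (target_fold - 1.0) / denom


# ---------------------------------------------------------------------------
# phantom construction


def _place_pores(spec: PhantomSpec, rng: np.random.Generator):
    """Sieve-plate pore placement with overlap rejection.

    Returns (pores, n_rejected).  Pore diameters are drawn from a normal
    truncated to [pore_diameter_min, pore_diameter_max]; positions by
    rejection sampling inside elliptical plates, keeping full rim
    footprints inside the cell, outside the nucleus and non-overlapping.
    """
    pores: list[PorePlacement] = []
    rejected = 0
    ext_x = spec.grid_nx * spec.pixel_size
    ext_y = spec.grid_ny * spec.pixel_size
    cx, cy = ext_x / 2.0, ext_y / 2.0
    ax, ay = 0.45 * ext_x, 0.45 * ext_y  # cell ellipse semi-axes

    def draw_diameter() -> float:
        for _ in range(1000):
            d = rng.normal(spec.pore_diameter_mean, spec.pore_diameter_sd)
            if spec.pore_diameter_min <= d <= spec.pore_diameter_max:
                return d
        return float(
            np.clip(spec.pore_diameter_mean, spec.pore_diameter_min, spec.pore_diameter_max)
        )

    def footprint(r0: float) -> float:
        return r0 * (1.0 + spec.rim_compliance) + spec.pixel_size

    def ok(x: float, y: float, fp: float, nuclear: bool) -> bool:
        # inside the cell ellipse with full footprint margin
        if ((x - cx) / (ax - fp)) ** 2 + ((y - cy) / (ay - fp)) ** 2 > 1.0:
            return False
        rn = np.hypot(x - cx, y - cy)
        if nuclear:
            if spec.nucleus_radius <= 0 or rn > spec.nucleus_radius - fp:
                return False
        elif spec.nucleus_radius > 0 and rn < spec.nucleus_radius + fp:
            return False
        for p in pores:
            lim = fp + p.radius_nm * (1.0 + spec.rim_compliance) + spec.pixel_size
            if np.hypot(x - p.x_nm, y - p.y_nm) < lim:
                return False
        return True

    fp_nominal = footprint(spec.pore_diameter_mean / 2.0)
    plate_r = fp_nominal * (np.sqrt(max(spec.pores_per_plate, 1)) + 0.9)
    for plate in range(spec.n_sieve_plates):
        placed_in_plate = 0
        for attempt in range(25):  # re-seat the plate if it cannot host its pores
            px = cx + rng.uniform(-0.8, 0.8) * ax
            py = cy + rng.uniform(-0.8, 0.8) * ay
            theta = rng.uniform(0, np.pi)
            ar_a, ar_b = plate_r * rng.uniform(0.9, 1.3), plate_r * rng.uniform(0.7, 1.0)
            trial: list[PorePlacement] = []
            for _ in range(spec.pores_per_plate):
                d = draw_diameter()
                fp = footprint(d / 2.0)
                for _ in range(400):
                    u, v = rng.uniform(-1, 1, 2)
                    if u * u + v * v > 1:
                        continue
                    x = px + u * ar_a * np.cos(theta) - v * ar_b * np.sin(theta)
                    y = py + u * ar_a * np.sin(theta) + v * ar_b * np.cos(theta)
                    if ok(x, y, fp, nuclear=False):
                        p = PorePlacement(
                            x_nm=x,
                            y_nm=y,
                            radius_nm=d / 2.0,
                            rim_width_nm=spec.rim_compliance * d / 2.0,
                            collapse_force_pn=spec.rim_collapse_force,
                            sieve_plate_id=plate,
                        )
                        pores.append(p)
                        trial.append(p)
                        break
            if len(trial) == spec.pores_per_plate:
                placed_in_plate = len(trial)
                break
            for p in trial:  # plate failed: release and re-seat
                pores.remove(p)
        if placed_in_plate < spec.pores_per_plate:
            # final pass: place whatever fits at this plate's last position
            for _ in range(spec.pores_per_plate - placed_in_plate):
                d = draw_diameter()
                fp = footprint(d / 2.0)
                done = False
                for _ in range(400):
                    u, v = rng.uniform(-1, 1, 2)
                    if u * u + v * v > 1:
                        continue
                    x = cx + u * ax
                    y = cy + v * ay
                    if ok(x, y, fp, nuclear=False):
                        pores.append(
                            PorePlacement(
                                x_nm=x,
                                y_nm=y,
                                radius_nm=d / 2.0,
                                rim_width_nm=spec.rim_compliance * d / 2.0,
                                collapse_force_pn=spec.rim_collapse_force,
                                sieve_plate_id=plate,
                            )
                        )
                        done = True
                        break
                if not done:
                    rejected += 1
    for _ in range(spec.labyrinth_pores):
        d = draw_diameter()
        fp = footprint(d / 2.0)
        done = False
        for _ in range(400):
            rr = spec.nucleus_radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            x, y = cx + rr * np.cos(th), cy + rr * np.sin(th)
            if ok(x, y, fp, nuclear=True):
                pores.append(
                    PorePlacement(
                        x_nm=x,
                        y_nm=y,
                        radius_nm=d / 2.0,
                        rim_width_nm=spec.rim_compliance * d / 2.0,
                        collapse_force_pn=spec.rim_collapse_force,
                        sieve_plate_id=None,
                        in_nucleus=True,
                    )
                )
                done = True
                break
        if not done:
            rejected += 1
    if rejected:
        warnings.warn(
            f"{rejected} pore(s) could not be placed without overlap; "
            "ground truth records the pores actually placed"
        )
    return pores, rejected


def _piecewise_force(delta, AM, FCAP, H, A_sub):
    """Membrane-over-substrate contact law, vectorised.

    Hertz (AM) capped at FCAP while delta <= H; beyond H the tip has passed
    the membrane and loads the substrate in series."""
    f = np.minimum(AM * np.clip(delta, 0.0, None) ** 1.5, FCAP)
    over = delta > H
    if np.any(over):
        f = np.where(over, FCAP + A_sub * np.clip(delta - H, 0.0, None) ** 1.5, f)
    return f


def _solve_force(s, AM, FCAP, H, A_sub, k_pn_nm, iters: int = 48):
    """Force at piezo-past-contact distance s: solves F(delta) = k (s - delta)
    by vectorised bisection (F non-decreasing, RHS strictly decreasing)."""
    s = np.clip(s, 0.0, None)
    lo = np.zeros_like(s)
    hi = s.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g = _piecewise_force(mid, AM, FCAP, H, A_sub) + k_pn_nm * mid - k_pn_nm * s
        high = g > 0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    delta = 0.5 * (lo + hi)
    return k_pn_nm * (s - delta)


def generate_phantom(spec: PhantomSpec) -> tuple[GroundTruth, ForceVolumeMap]:
    """Generate a fenestrated-cell force-volume phantom with ground truth.

    Deterministic in ``spec`` (including its seed): identical specs yield
    bit-identical maps.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.grid_ny, spec.grid_nx
    px = spec.pixel_size
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    X, Y = np.meshgrid(xs, ys)
    ext_x, ext_y = nx * px, ny * px
    cx, cy = ext_x / 2.0, ext_y / 2.0
    ax, ay = 0.45 * ext_x, 0.45 * ext_y

    if spec.cell_height > 0:
        cell_mask = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0
    else:
        cell_mask = np.zeros((ny, nx), dtype=bool)

    rnuc = np.hypot(X - cx, Y - cy)
    if spec.nucleus_radius > 0 and spec.nucleus_height > 0 and spec.cell_height > 0:
        nuclear_mask = cell_mask & (rnuc <= spec.nucleus_radius)
        # flat-topped (quartic) dome: steep flanks, wide plateau
        dome = np.zeros((ny, nx))
        inside = rnuc <= spec.nucleus_radius
        dome[inside] = spec.nucleus_height * np.sqrt(
            np.clip(1.0 - (rnuc[inside] / spec.nucleus_radius) ** 4, 0.0, 1.0)
        )
        dome[~cell_mask] = 0.0
    else:
        nuclear_mask = np.zeros((ny, nx), dtype=bool)
        dome = np.zeros((ny, nx))

    h_membrane = np.where(cell_mask, spec.cell_height + dome, 0.0)

    pores, rejected = (
        _place_pores(spec, rng)
        if (spec.n_sieve_plates * spec.pores_per_plate + spec.labyrinth_pores) > 0
        and spec.cell_height > 0
        else ([], 0)
    )

    A_cell = spec.hertz_prefactor_cell
    A_sub = spec.hertz_prefactor_substrate

    # per-pixel contact parameters
    H = h_membrane.copy()  # membrane thickness above substrate
    AM = np.where(cell_mask, A_cell, A_sub)
    FCAP = AM * H**1.5  # cell pixels bottom out, no plateau
    pore_mask = np.zeros((ny, nx), dtype=bool)
    rim_mask = np.zeros((ny, nx), dtype=bool)
    true_height = h_membrane.copy()
    for p in pores:
        r = np.hypot(X - p.x_nm, Y - p.y_nm)
        interior = r <= p.radius_nm
        rim = (r > p.radius_nm) & (r <= p.radius_nm + p.rim_width_nm)
        pore_mask |= interior
        rim_mask |= rim
        # open hole: tip reaches the substrate unhindered
        H[interior] = 0.0
        FCAP[interior] = 0.0
        true_height[interior] = 0.0
        if p.rim_width_nm > 0:
            t = (r[rim] - p.radius_nm) / p.rim_width_nm
            FCAP[rim] = np.minimum(p.collapse_force_pn * t, FCAP[rim])

    true_modulus = np.where(H > 0, spec.cell_modulus, spec.substrate_modulus)

    z = np.linspace(0.0, spec.z_range, spec.curve_n_samples)
    h_max = float(true_height.max(initial=0.0))
    z_offset = h_max + _BASELINE_HEADROOM * (spec.z_range - h_max)
    z_contact = z_offset - np.where(H > 0, H, true_height)  # top of local structure

    k_pn_nm = spec.spring_constant * N_PER_M_TO_PN_PER_NM
    force = np.zeros((ny, nx, z.size))
    flatH = H.reshape(-1)
    flatAM = AM.reshape(-1)
    flatFC = FCAP.reshape(-1)
    flatZC = z_contact.reshape(-1)
    out = force.reshape(-1, z.size)
    block = 4096
    for start in range(0, out.shape[0], block):
        sl = slice(start, min(start + block, out.shape[0]))
        s = z[None, :] - flatZC[sl, None]
        f = _solve_force(
            s,
            flatAM[sl, None],
            flatFC[sl, None],
            flatH[sl, None],
            A_sub,
            k_pn_nm,
        )
        out[sl] = np.where(s > 0, f, 0.0)
    if spec.force_noise_sd > 0:
        force += rng.normal(0.0, spec.force_noise_sd, size=force.shape)

    n_countable = sum(1 for p in pores if not p.in_nucleus)
    cell_area = float(cell_mask.sum()) * px**2 / 1e6
    porosity = n_countable / cell_area if cell_area > 0 else 0.0

    truth = GroundTruth(
        true_height_map=true_height,
        true_modulus_map=true_modulus,
        pore_table=pores,
        cell_mask=cell_mask,
        nuclear_mask=nuclear_mask,
        pore_mask=pore_mask,
        rim_mask=rim_mask,
        pixel_size=px,
        true_porosity=porosity,
        true_enlargement=1.0,
        n_rejected=rejected,
    )
    truth.true_enlargement = truth.enlargement_between(170.0, 300.0)

    fvmap = ForceVolumeMap(
        force=force,
        z=z,
        pixel_size=px,
        spring_constant=spec.spring_constant,
        metadata={
            "z_offset_nm": z_offset,
            "tip_radius_nm": spec.tip_radius,
            "poisson_ratio": spec.poisson_ratio,
            "seed": spec.seed,
        },
    )
    return truth, fvmap


# ---------------------------------------------------------------------------
# preset phantoms for the regimes studied


def control_like_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Phantom in the healthy-porosity regime (~1.5 fen./um^2)."""
    kw = dict(
        grid_nx=128,
        grid_ny=128,
        n_sieve_plates=2,
        pores_per_plate=5,
        nucleus_radius=280.0,
        pore_diameter_mean=200.0,
        pore_diameter_sd=40.0,
        pore_diameter_min=80.0,
        pore_diameter_max=300.0,
        rim_compliance=0.3,
        seed=seed,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def ko_like_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Phantom in the defenestrated regime (~0.4 fen./um^2)."""
    kw = dict(
        grid_nx=128,
        grid_ny=128,
        n_sieve_plates=1,
        pores_per_plate=3,
        nucleus_radius=280.0,
        pore_diameter_mean=200.0,
        pore_diameter_sd=40.0,
        pore_diameter_min=80.0,
        pore_diameter_max=300.0,
        rim_compliance=0.3,
        seed=seed,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def deformability_spec(
    seed: int = 0, target_enlargement_pct: float = 40.0, **overrides
) -> PhantomSpec:
    """Phantom whose true 300/170 pN enlargement equals the target."""
    fold = 1.0 + target_enlargement_pct / 100.0
    kw = dict(
        grid_nx=192,
        grid_ny=192,
        n_sieve_plates=4,
        pores_per_plate=2,
        nucleus_radius=250.0,
        nucleus_height=250.0,
        pore_diameter_mean=220.0,
        pore_diameter_sd=30.0,
        pore_diameter_min=160.0,
        pore_diameter_max=280.0,
        rim_compliance=calibrate_rim_compliance(fold),
        seed=seed,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


# ---------------------------------------------------------------------------
# amplitude sweeps


@dataclass
class AmplitudeSweep:
    """Oscillatory amplitude sweep: strain (%) vs storage/loss moduli (Pa)."""

    strain: np.ndarray
    g_prime: np.ndarray
    g_doubleprime: np.ndarray
    angular_frequency: float = 1.0
    temperature: float = 37.0

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.g_prime = np.asarray(self.g_prime, dtype=float)
        self.g_doubleprime = np.asarray(self.g_doubleprime, dtype=float)
        if not (self.strain.size == self.g_prime.size == self.g_doubleprime.size):
            raise ValueError("strain, g_prime and g_doubleprime must align")
        if self.strain.size < 8:
            raise ValueError("sweep needs at least 8 points")
        if np.any(self.strain <= 0) or np.any(np.diff(self.strain) <= 0):
            raise ValueError("strains must be positive and strictly increasing")
        if np.any(self.g_prime <= 0) or np.any(self.g_doubleprime <= 0):
            raise ValueError("moduli must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain_percent": self.strain,
                "G_prime_Pa": self.g_prime,
                "G_doubleprime_Pa": self.g_doubleprime,
            }
        )


def default_strain_grid(n: int = 31) -> np.ndarray:
    """Log-spaced strains over 0.01-100 %, the usual amplitude-sweep span."""
    return np.logspace(-2, 2, n)


def generate_amplitude_sweep(
    plateau_G_prime: float,
    loss_factor: float = 0.1,
    yield_strain: float = 1.0,
    decay_exponent: float = 1.0,
    strain_grid: Sequence[float] | None = None,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> AmplitudeSweep:
    """Synthetic amplitude sweep: plateau up to the yield strain, then
    power-law decay; G'' tracks G' scaled by the loss factor."""
    if plateau_G_prime <= 0:
        raise ValueError("plateau_G_prime must be positive")
    if loss_factor <= 0:
        raise ValueError("loss_factor must be positive")
    if strain_grid is None:
        strain_grid = default_strain_grid()
    gamma = np.asarray(strain_grid, dtype=float)
    if gamma.size == 0:
        raise ValueError("strain_grid must not be empty")
    if np.any(gamma <= 0) or np.any(np.diff(gamma) <= 0):
        raise ValueError("strain_grid must be positive and increasing")
    rng = np.random.default_rng(seed)
    shape = np.where(gamma <= yield_strain, 1.0, (gamma / yield_strain) ** (-decay_exponent))
    gp = plateau_G_prime * shape
    gpp = loss_factor * gp
    if noise_rel > 0:
        gp = gp * (1.0 + rng.normal(0.0, noise_rel, gamma.size))
        gpp = gpp * (1.0 + rng.normal(0.0, noise_rel, gamma.size))
    gp = np.clip(gp, 1e-9, None)
    gpp = np.clip(gpp, 1e-9, None)
    return AmplitudeSweep(strain=gamma, g_prime=gp, g_doubleprime=gpp)


# ---------------------------------------------------------------------------
# fluorescence nuclei images and endocytosis tables


def generate_nuclei_image(
    n_nuclei: int,
    image_size: int = 512,
    nucleus_radius_px: float = 12.0,
    intensity: float = 180.0,
    background: float = 20.0,
    noise_sd: float = 4.0,
    seed: int = 0,
    max_attempts_per_nucleus: int = 500,
) -> tuple[np.ndarray, int]:
    """Stained-nuclei intensity image with non-overlapping disks.

    Rejection sampling keeps nuclei disjoint; an error is raised when the
    requested density is infeasible within the attempt budget.
    Returns (image, true_count).
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be non-negative")
    rng = np.random.default_rng(seed)
    img = np.full((image_size, image_size), float(background))
    r = nucleus_radius_px
    centers: list[tuple[float, float]] = []
    for i in range(n_nuclei):
        for _ in range(max_attempts_per_nucleus):
            x = rng.uniform(r + 1, image_size - r - 1)
            y = rng.uniform(r + 1, image_size - r - 1)
            if all(np.hypot(x - cx, y - cy) >= 2 * r + 2 for cx, cy in centers):
                centers.append((x, y))
                break
        else:
            raise ValueError(
                f"could not place nucleus {i + 1}/{n_nuclei} without overlap; "
                "reduce n_nuclei or the nucleus radius"
            )
    if centers:
        yy, xx = np.mgrid[0:image_size, 0:image_size]
        for cx_, cy_ in centers:
            img[(xx - cx_) ** 2 + (yy - cy_) ** 2 <= r**2] = float(intensity)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return img, len(centers)


def generate_endocytosis_table(
    n_wells: int = 6,
    cells_per_well: int = 400_000,
    cell_associated_mean: float = 1000.0,
    degraded_mean: float = 600.0,
    noise: float = 0.0,
    seed: int = 0,
    substrate_label: str = "plastic",
) -> pd.DataFrame:
    """Per-well endocytosis activity table (arbitrary activity units).

    The default six wells mirror a 3-bioreplicate x 2-technical-replicate
    layout.  Columns: cell_associated, degraded, n_cells, substrate_label.
    """
    if n_wells <= 0:
        raise ValueError("n_wells must be positive")
    if cells_per_well <= 0:
        raise ValueError("cells_per_well must be positive")
    rng = np.random.default_rng(seed)
    ca = np.full(n_wells, float(cell_associated_mean))
    dg = np.full(n_wells, float(degraded_mean))
    cells = np.full(n_wells, int(cells_per_well))
    if noise > 0:
        ca = np.clip(ca * (1.0 + rng.normal(0.0, noise, n_wells)), 0.0, None)
        dg = np.clip(dg * (1.0 + rng.normal(0.0, noise, n_wells)), 0.0, None)
    return pd.DataFrame(
        {
            "cell_associated": ca,
            "degraded": dg,
            "n_cells": cells,
            "substrate_label": substrate_label,
        }
    )
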