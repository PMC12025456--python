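"""Amplitude-sweep rheology: LVER detection and shear→Young conversion.

The linear viscoelastic range (LVER) is the low-strain region where the
storage modulus G′ sits on its plateau; it ends at the last strain whose
G′ is still within a stated deviation (default 10%) of the plateau.  The
mean G′ over the LVER estimates the shear modulus, converted to a Young's
modulus via E = 2·G′·(1+ν); for an incompressible gel (ν = 0.5) this is
exactly E = 3·G′.  The loss factor G″/G′ (< 1 for a solid-like gel) is
averaged over the same range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import AmplitudeSweep

__all__ = [
    "LverResult",
    "NoLverError",
    "find_lver",
    "mean_storage_modulus",
    "youngs_from_shear",
    "loss_factor",
    "analyze_sweep",
    "read_sweep_csv",
    "combine_replicates",
]


class NoLverError(ValueError):
    """The sweep has no strain-independent plateau."""


@dataclass
class LverResult:
    """Plateau-derived moduli of one amplitude sweep."""

    lver_strain_min: float
    lver_strain_max: float
    mean_G_prime: float
    sd_G_prime: float
    youngs_modulus: float
    loss_factor: float
    n_points_in_lver: int
    poisson_ratio: float = 0.5
    deviation: float = 0.10


def _plateau_estimate(sweep: AmplitudeSweep, deviation: float) -> float:
    """Two-pass plateau: median of the leading quarter, refined by a
    constant least-squares fit over points within the deviation band."""
    gp = sweep.g_prime
    lead = gp[: max(2, gp.size // 4)]
    p0 = float(np.median(lead))
    near = gp[np.abs(gp - p0) <= deviation * p0]
    if near.size >= 2:
        return float(near.mean())
    return p0


def find_lver(sweep: AmplitudeSweep, deviation: float = 0.10) -> tuple[float, float]:
    """Closed strain interval (%) of the linear viscoelastic range.

    Ends at the last strain where G′ ≥ (1 − deviation) × plateau; raises
    :class:`NoLverError` when no plateau exists (G′ decays from the first
    point by more than the deviation).
    """
    if not 0.0 < deviation < 0.5:
        raise ValueError("deviation must lie in (0, 0.5)")
    lead = sweep.g_prime[: max(4, sweep.g_prime.size // 2)]
    if np.all(np.diff(lead) < 0) and lead[-1] < (1.0 - deviation) * lead[0]:
        raise NoLverError(
            "no LVER: storage modulus decays monotonically from the first point"
        )
    plateau = _plateau_estimate(sweep, deviation)
    qualify = sweep.g_prime >= (1.0 - deviation) * plateau
    if qualify.sum() < 2:
        raise NoLverError("no LVER: storage modulus has no plateau region")
    last = int(np.flatnonzero(qualify)[-1])
    return float(sweep.strain[0]), float(sweep.strain[last])


def _lver_slice(sweep: AmplitudeSweep, lver: tuple[float, float]) -> np.ndarray:
    lo, hi = lver
    mask = (sweep.strain >= lo) & (sweep.strain <= hi)
    if not mask.any():
        raise ValueError("empty LVER interval")
    return mask


def mean_storage_modulus(
    sweep: AmplitudeSweep, lver: tuple[float, float]
) -> tuple[float, float]:
    """Arithmetic mean ± sd of G′ over the LVER points (Pa)."""
    mask = _lver_slice(sweep, lver)
    g = sweep.g_prime[mask]
    sd = float(g.std(ddof=1)) if g.size > 1 else 0.0
    return float(g.mean()), sd


def youngs_from_shear(G_prime: float, nu: float = 0.5) -> float:
    """E = 2·G′·(1+ν); exactly 3·G′ for an incompressible material."""
    if G_prime <= 0:
        raise ValueError("G_prime must be positive")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("nu must lie in [0, 0.5]")
    return 2.0 * G_prime * (1.0 + nu)


def loss_factor(sweep: AmplitudeSweep, lver: tuple[float, float]) -> float:
    """Mean pointwise G″/G′ over the LVER."""
    mask = _lver_slice(sweep, lver)
    return float(np.mean(sweep.g_doubleprime[mask] / sweep.g_prime[mask]))


def analyze_sweep(
    sweep: AmplitudeSweep, deviation: float = 0.10, nu: float = 0.5
) -> LverResult:
    """Full LVER analysis of one sweep."""
    lver = find_lver(sweep, deviation)
    mean_g, sd_g = mean_storage_modulus(sweep, lver)
    mask = _lver_slice(sweep, lver)
    return LverResult(
        lver_strain_min=lver[0],
        lver_strain_max=lver[1],
        mean_G_prime=mean_g,
        sd_G_prime=sd_g,
        youngs_modulus=youngs_from_shear(mean_g, nu),
        loss_factor=loss_factor(sweep, lver),
        n_points_in_lver=int(mask.sum()),
        poisson_ratio=nu,
        deviation=deviation,
    )


def combine_replicates(results: list[LverResult]) -> dict:
    """Mean ± sd across sweep-level results (replicates are averaged at
    the result level, not pooled point-wise)."""
    if not results:
        raise ValueError("no replicate results")
    gp = np.array([r.mean_G_prime for r in results])
    e = np.array([r.youngs_modulus for r in results])
    lf = np.array([r.loss_factor for r in results])
    sd = lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0  # noqa: E731
    return {
        "n_replicates": len(results),
        "G_prime_Pa_mean": float(gp.mean()),
        "G_prime_Pa_sd": sd(gp),
        "youngs_modulus_Pa_mean": float(e.mean()),
        "youngs_modulus_Pa_sd": sd(e),
        "loss_factor_mean": float(lf.mean()),
        "loss_factor_sd": sd(lf),
    }


def read_sweep_csv(path) -> AmplitudeSweep:
    """Read an amplitude sweep from CSV with columns strain_percent,
    G_prime_Pa, G_doubleprime_Pa (header required)."""
    df = pd.read_csv(path)
    required = {"strain_percent", "G_prime_Pa", "G_doubleprime_Pa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sweep CSV missing columns: {sorted(missing)}")
    return AmplitudeSweep(
        strain=df["strain_percent"].to_numpy(),
        g_prime=df["G_prime_Pa"].to_numpy(),
        g_doubleprime=df["G_doubleprime_Pa"].to_numpy(),
    )
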