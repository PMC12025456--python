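"""End-to-end orchestration: phantom → curve fits → QI reconstruction →
morphometry → statistics, driven by a single declarative configuration.

Every configurable number and derived threshold lands in the provenance
block of the report, and a rerun with the same configuration reproduces
the numeric outputs byte-identically (no timestamps, fixed seeds).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import io as fio
from . import morphometry as morph
from .mechanics import IndenterModel, fit_force_volume
from .reconstruction import reconstruct_stack
from .stats import summarize_group
from .synthetic import PhantomSpec, generate_phantom

__all__ = ["RunConfig", "FitConfig", "MorphometryConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and config echo."""

    def __init__(self, stage: str, config: "RunConfig", cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}\nconfig: {config.model_dump()}")
        self.stage = stage
        self.cause = cause


class FitConfig(BaseModel):
    model_kind: str = "sphere"
    tip_radius: float | None = 25.0
    half_angle: float | None = None
    poisson_ratio: float = 0.5
    window_nm: tuple[float, float] = (20.0, 250.0)

    def indenter(self) -> IndenterModel:
        if self.model_kind == "sphere":
            return IndenterModel(
                kind="sphere", tip_radius=self.tip_radius, poisson_ratio=self.poisson_ratio
            )
        return IndenterModel(
            kind="pyramid", half_angle=self.half_angle, poisson_ratio=self.poisson_ratio
        )


class MorphometryConfig(BaseModel):
    cell_height_threshold_nm: float | None = None  # None: half the p97 height
    bulge_threshold_nm: float | None = None  # None: auto from bulge amplitude
    depth_threshold_nm: float | None = None  # None: half local membrane height
    d_range_nm: tuple[float, float] = (50.0, 350.0)
    min_circularity: float = 0.3
    match_dist_pixels: float = 3.0
    criterion: str = "half-depth"
    flatten_order: int = 1


class RunConfig(BaseModel):
    phantom: PhantomSpec | None = None
    input_force_volume: str | None = None
    reconstruction_targets: list[float] = Field(default_factory=lambda: [170.0, 300.0])
    fit: FitConfig = Field(default_factory=FitConfig)
    morphometry: MorphometryConfig = Field(default_factory=MorphometryConfig)
    alpha_levels: list[float] = Field(default_factory=lambda: [0.05, 0.01, 0.001])
    output_dir: str = "fenestra_run"
    seed: int = 0
    save_force_volume: bool = False
    make_figures: bool = False

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.phantom is None and self.input_force_volume is None:
            raise ValueError("either a phantom spec or an input force-volume path is required")
        if self.input_force_volume is not None and not Path(self.input_force_volume).exists():
            raise ValueError(f"input force volume not found: {self.input_force_volume}")
        t = self.reconstruction_targets
        if not t or any(x <= 0 for x in t) or sorted(t) != t:
            raise ValueError("reconstruction_targets must be positive and sorted ascending")
        return self


def _auto_thresholds(flat_map, mcfg: MorphometryConfig) -> dict:
    if mcfg.cell_height_threshold_nm is not None:
        cell_thr = mcfg.cell_height_threshold_nm
    else:
        from skimage.filters import threshold_otsu

        h = flat_map.heights[np.isfinite(flat_map.heights)]
        cell_thr = float(threshold_otsu(h))
    return {"cell_height_threshold_nm": cell_thr}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain and write the artifact set.

    Returns the report dictionary (also written as report.json)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}
    provenance: dict = {"config": json.loads(config.model_dump_json())}

    # --- acquire ----------------------------------------------------------
    try:
        if config.phantom is not None:
            truth, fvmap = generate_phantom(config.phantom)
            fio.save_ground_truth(outdir / "ground_truth", truth)
            report["phantom"] = {
                "true_porosity_per_um2": truth.true_porosity,
                "true_enlargement_fold": truth.true_enlargement,
                "n_pores": len(truth.pore_table),
            }
        else:
            truth = None
            fvmap = fio.load_force_volume(config.input_force_volume)
        if config.save_force_volume:
            fio.save_force_volume(outdir / "force_volume.h5", fvmap)
        report["stages"].append("acquire")
    except Exception as exc:  # noqa: BLE001
        raise StageError("acquire", config, exc) from exc

    # --- modulus fitting --------------------------------------------------
    try:
        model = config.fit.indenter()
        E_map, zc_map, rms_map = fit_force_volume(fvmap, model, config.fit.window_nm)
        fio.save_modulus_map(outdir / "modulus_map_Pa.tif", E_map, fvmap.pixel_size)
        ny, nx = E_map.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        import pandas as pd

        fits = pd.DataFrame(
            {
                "px_x": xx.ravel(),
                "px_y": yy.ravel(),
                "E_app_Pa": E_map.ravel(),
                "z_c_nm": zc_map.ravel(),
                "residual_rms_pN": rms_map.ravel(),
                "model": config.fit.model_kind,
                "window_nm": f"{config.fit.window_nm[0]}-{config.fit.window_nm[1]}",
            }
        )
        fits.to_csv(outdir / "modulus_fits.csv", index=False)
        report["modulus"] = {
            "median_E_Pa": float(np.nanmedian(E_map)),
            "n_failed_pixels": int(np.isnan(E_map).sum()),
        }
        report["stages"].append("fit")
    except Exception as exc:  # noqa: BLE001
        raise StageError("fit", config, exc) from exc

    # --- reconstruction ---------------------------------------------------
    try:
        stack = reconstruct_stack(fvmap, config.reconstruction_targets)
        flat_stack = [morph.flatten(hm, config.morphometry.flatten_order) for hm in stack]
        invalid = {}
        for hm, fl in zip(stack, flat_stack):
            fio.save_height_map(outdir / f"height_{hm.load_force:.0f}pN.tif", fl)
            invalid[f"{hm.load_force:.0f}"] = hm.n_invalid
        report["reconstruction"] = {"invalid_pixels": invalid}
        report["stages"].append("reconstruct")
    except Exception as exc:  # noqa: BLE001
        raise StageError("reconstruct", config, exc) from exc

    # --- morphometry ------------------------------------------------------
    try:
        mcfg = config.morphometry
        base = flat_stack[0]  # lowest-force (least distorted) map
        thresholds = _auto_thresholds(base, mcfg)
        cell_mask, cell_area = morph.segment_cell(base, thresholds["cell_height_threshold_nm"])
        cell_level = float(np.nanmedian(base.heights[cell_mask]))
        peak = float(np.nanpercentile(base.heights, 99.5))
        if mcfg.bulge_threshold_nm is not None:
            bulge_thr = mcfg.bulge_threshold_nm
        elif peak - cell_level > 100.0:
            bulge_thr = cell_level + 0.3 * (peak - cell_level)
        else:
            bulge_thr = peak + 1.0  # no discernible bulge
        nuclear_mask = morph.detect_nuclear_region(base, bulge_thr)
        thresholds.update(
            {"bulge_threshold_nm": bulge_thr, "depth_threshold_nm": mcfg.depth_threshold_nm}
        )
        pores_by_force = {}
        for fl in flat_stack:
            pores = morph.detect_pores(
                fl,
                cell_mask,
                depth_threshold=mcfg.depth_threshold_nm,
                d_range=mcfg.d_range_nm,
                min_circularity=mcfg.min_circularity,
                criterion=mcfg.criterion,
                nuclear_mask=nuclear_mask,
            )
            morph.assign_sieve_plates(pores)
            pores_by_force[fl.load_force] = pores
            fio.pores_to_frame(pores).to_csv(
                outdir / f"pores_{fl.load_force:.0f}pN.csv", index=False
            )
        base_pores = pores_by_force[flat_stack[0].load_force]
        porosity = morph.compute_porosity(base_pores, cell_mask, nuclear_mask, base.pixel_size)
        report["porosity"] = {
            "n_fenestrations": porosity.n_fenestrations,
            "cell_area_um2": porosity.cell_area_um2,
            "porosity_per_um2": porosity.porosity_per_um2,
            "n_excluded_nuclear": porosity.n_excluded_nuclear,
        }
        provenance["thresholds"] = thresholds
        report["stages"].append("morphometry")
    except Exception as exc:  # noqa: BLE001
        raise StageError("morphometry", config, exc) from exc

    # --- deformability ----------------------------------------------------
    if len(flat_stack) >= 2:
        try:
            low = flat_stack[0]
            high = flat_stack[-1]
            pairs, un_lo, un_hi = morph.match_pores(
                pores_by_force[low.load_force],
                pores_by_force[high.load_force],
                max_centroid_dist=mcfg.match_dist_pixels * base.pixel_size,
            )
            if pairs:
                summary = morph.deformability_summary(pairs)
                report["deformability"] = {
                    "force_low_pN": low.load_force,
                    "force_high_pN": high.load_force,
                    "mean_fold_change": summary.mean_fold_change,
                    "sd_fold_change": summary.sd_fold_change,
                    "percent_enlargement": summary.percent_enlargement,
                    "n_pairs": summary.n_pairs,
                    "n_unmatched_low": len(un_lo),
                    "n_unmatched_high": len(un_hi),
                }
            else:
                report["deformability"] = {"n_pairs": 0}
            report["stages"].append("deformability")
        except Exception as exc:  # noqa: BLE001
            raise StageError("deformability", config, exc) from exc

    # --- summaries --------------------------------------------------------
    try:
        diam = [p.diameter_fast_axis_nm for p in base_pores if not p.in_nuclear_region]
        if diam:
            s = summarize_group(diam, label="fenestration_diameter_nm")
            report["diameter_summary"] = {
                "label": s.label,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "percentile_5": s.percentile_5,
                "percentile_95": s.percentile_95,
                "percentile_convention": s.percentile_convention,
            }
        report["stages"].append("summaries")
    except Exception as exc:  # noqa: BLE001
        raise StageError("summaries", config, exc) from exc

    if config.make_figures:
        try:
            _write_figures(outdir, E_map, flat_stack)
            report["stages"].append("figures")
        except Exception as exc:  # noqa: BLE001
            raise StageError("figures", config, exc) from exc

    report["provenance"] = provenance
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _write_figures(outdir: Path, E_map: np.ndarray, flat_stack) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 1 + len(flat_stack), figsize=(4 * (1 + len(flat_stack)), 4))
    axes = np.atleast_1d(axes)
    im = axes[0].imshow(E_map / 1e3, cmap="viridis")
    axes[0].set_title("apparent E (kPa)")
    fig.colorbar(im, ax=axes[0], shrink=0.8)
    for ax, fl in zip(axes[1:], flat_stack):
        im = ax.imshow(fl.heights, cmap="afmhot")
        ax.set_title(f"height at {fl.load_force:.0f} pN (nm)")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(outdir / "maps.png", dpi=120)
    plt.close(fig)
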