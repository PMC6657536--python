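"""End-to-end pipeline: per-condition fits, dose model, nano effect, phase laws.

``run_pipeline`` orchestrates the full analysis on one long-format dataset
and writes every result as CSV (plus optional plots) together with a
machine-readable manifest.  Given the same config and seed, reruns produce
byte-identical CSVs: every stage is deterministic and no timestamps enter
the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import default_knots
from .datasets import read_dataset
from .dose import default_pairing, estimate_nano_effect, fit_dose_model, nano_effect_plot
from .phase import (
    DEFAULT_TRIM,
    find_steady_states,
    fit_linear_phase,
    fit_smooth_phase,
    phase_points,
    trimmed_grid,
)
from .simulate import AGONIST_ONLY, AGONIST_PLUS_NP
from .splines import fit_penalized_spline, predict_curve

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

STAGES = ("condition_fits", "derivatives", "dose_model", "nano_effect", "phase")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Settings for a full pipeline run.

    ``degree``/``knots`` configure the shared spline basis; ``phase_law``
    is ``"linear"``, ``"smooth"`` or ``"both"``; ``trim`` is the fraction
    of the time range dropped at each end before phase fitting;
    ``pairing`` optionally lists nanoparticle contrast pairs as
    ``{label: [[dose, group], [dose, group]], ...}`` (by default equal
    doses across the two groups are paired).
    """

    input_path: str
    output_dir: str
    degree: int = 5
    knots: int | str = "auto"
    level: float = 0.95
    phase_law: str = "both"
    trim: float = DEFAULT_TRIM
    tolerance: float = 1e-6
    grid_size: int = 200
    seed: int = 0
    pairing: dict | None = None
    baseline_label: str = "overall"
    make_plots: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.phase_law not in ("linear", "smooth", "both"):
            raise ValueError(f"phase_law must be linear/smooth/both, got {self.phase_law!r}")
        if not 0 <= self.trim < 0.5:
            raise ValueError(f"trim must be in [0, 0.5), got {self.trim}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _cond_tag(dose: float, group: str) -> str:
    g = "NP" if group == AGONIST_PLUS_NP else "ADP"
    return f"{g}_{dose:g}"


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary.

    Outputs under ``config.output_dir``:

    * ``curves/<cond>_d{0,1,2}.csv`` — mean curve, velocity, acceleration
      with columns ``time, estimate, se, lo, hi``;
    * ``dose_model.csv`` — fitted condition curves on a common grid;
    * ``nano_effect.csv`` — per-dose contrasts + overall mean (two groups
      present only);
    * ``phase_<cond>_{linear,smooth}.csv`` — phase-law coefficients or
      evaluations, and ``fixed_points.csv``;
    * ``manifest.json`` — inputs, settings, seed, package version and the
      completed stages.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "input": str(config.input_path),
        "settings": {k: v for k, v in asdict(config).items() if k != "input_path"},
        "seed": config.seed,
        "version": __version__,
        "stages_completed": [],
        "failed_stage": None,
        "outputs": [],
    }

    def _write_manifest():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    def _fail(stage: str, exc: BaseException):
        manifest["failed_stage"] = stage
        _write_manifest()
        raise PipelineError(stage, exc) from exc

    def _save_csv(frame: pd.DataFrame, rel: str):
        p = outdir / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(p, index=False)
        manifest["outputs"].append(rel)

    dataset = read_dataset(config.input_path)
    if config.pairing is not None:
        known = set(map(tuple, (tuple(c) for c in dataset.conditions())))
        for key, (a, b) in config.pairing.items():
            for cond in (tuple(a), tuple(b)):
                cond = (float(cond[0]), str(cond[1]))
                if cond not in {(float(d), g) for d, g in known}:
                    raise ValueError(
                        f"pairing entry {key!r} references condition {cond!r} "
                        "absent from the input"
                    )

    conditions = dataset.conditions()
    t_all = dataset.df["time_min"].to_numpy(float)
    spec = default_knots(t_all, K=config.knots, degree=config.degree)
    grid = np.linspace(float(t_all.min()), float(t_all.max()), config.grid_size)

    # --- stage 1 & 2: per-condition fits and derivative curves ------------
    cond_fits = {}
    stage = "condition_fits"
    try:
        for dose, group in conditions:
            sub = dataset.condition(dose, group)
            cond_fits[(dose, group)] = fit_penalized_spline(
                (sub["time_min"].to_numpy(), sub["aggregation_pct"].to_numpy()), spec
            )
        manifest["stages_completed"].append(stage)
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    stage = "derivatives"
    try:
        for (dose, group), fit in cond_fits.items():
            tag = _cond_tag(dose, group)
            for m in (0, 1, 2):
                est = predict_curve(fit, grid, m, level=config.level)
                _save_csv(est.to_frame(), f"curves/{tag}_d{m}.csv")
            if config.make_plots:
                from .plots import plot_curve_panels

                plot_curve_panels(
                    fit, grid, config.level, outdir / f"curves/{tag}.png", title=tag
                )
        manifest["stages_completed"].append(stage)
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # --- stage 3: joint dose model ---------------------------------------
    stage = "dose_model"
    try:
        dose_fit = fit_dose_model(dataset, spec) if len(conditions) > 1 else None
        if dose_fit is not None:
            cols = {"time": grid}
            for cond in dose_fit.conditions:
                cols[_cond_tag(*cond)] = dose_fit.predict_condition(cond, grid).estimate
            _save_csv(pd.DataFrame(cols), "dose_model.csv")
        manifest["stages_completed"].append(stage)
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # --- stage 4: nano effect (needs both groups) -------------------------
    stage = "nano_effect"
    try:
        has_pairs = dose_fit is not None and (
            config.pairing
            or (
                AGONIST_ONLY in dataset.groups
                and AGONIST_PLUS_NP in dataset.groups
                and set(d for d, g in conditions if g == AGONIST_ONLY)
                & set(d for d, g in conditions if g == AGONIST_PLUS_NP)
            )
        )
        if has_pairs:
            pairing = (
                {
                    k: ((float(a[0]), str(a[1])), (float(b[0]), str(b[1])))
                    for k, (a, b) in config.pairing.items()
                }
                if config.pairing
                else default_pairing(dose_fit)
            )
            effect = estimate_nano_effect(dose_fit, pairing, grid, level=config.level)
            _save_csv(effect.to_frame(), "nano_effect.csv")
            if config.make_plots:
                nano_effect_plot(
                    effect,
                    config.baseline_label,
                    png_path=outdir / "nano_effect.png",
                )
        manifest["stages_completed"].append(stage)
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # --- stage 5: phase-plane laws ----------------------------------------
    stage = "phase"
    try:
        lin_rows, fp_rows = [], []
        for (dose, group), fit in cond_fits.items():
            tag = _cond_tag(dose, group)
            pts = phase_points(fit, trimmed_grid(fit, config.grid_size, config.trim))
            _save_csv(pts, f"phase/{tag}_points.csv")
            if config.phase_law in ("linear", "both"):
                lin = fit_linear_phase(pts)
                lin_rows.append(
                    {
                        "condition": tag,
                        "gamma0": lin.gamma0,
                        "se_gamma0": lin.se_gamma0,
                        "gamma1": lin.gamma1,
                        "se_gamma1": lin.se_gamma1,
                        "tau2": lin.tau2,
                        "adj_r2": lin.adj_r2,
                        "adj_r2_raw": lin.adj_r2_raw,
                        "n": lin.n,
                    }
                )
                for ystar, flag in find_steady_states(lin, config.tolerance):
                    fp_rows.append(
                        {"condition": tag, "law": "linear", "y_star": ystar, "stability": flag}
                    )
            if config.phase_law in ("smooth", "both"):
                smf = fit_smooth_phase(pts, tolerance=config.tolerance)
                ygrid = np.linspace(*smf.y_range, config.grid_size)
                est = smf.law(ygrid, level=config.level)
                frame = est.to_frame().rename(columns={"time": "aggregation"})
                _save_csv(frame, f"phase/{tag}_smooth_law.csv")
                for ystar, flag in smf.fixed_points:
                    fp_rows.append(
                        {"condition": tag, "law": "smooth", "y_star": ystar, "stability": flag}
                    )
                if config.make_plots:
                    from .plots import plot_phase

                    plot_phase(pts, smf, outdir / f"phase/{tag}.png", title=tag)
        if lin_rows:
            _save_csv(pd.DataFrame(lin_rows), "phase/linear_coefficients.csv")
        if fp_rows:
            _save_csv(pd.DataFrame(fp_rows), "phase/fixed_points.csv")
        manifest["stages_completed"].append(stage)
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    _write_manifest()
    log.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), outdir)
    return manifest
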