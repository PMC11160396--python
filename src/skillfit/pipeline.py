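"""End-to-end orchestration of the two-stage analysis.

Reads trial tables, optionally applies the online-experiment participant
exclusions, fits the learning-curve hierarchy on all trials and the DDM
hierarchy on the asymptotic window per participant, computes BIC-weight
comparisons and diagnostics, and writes all tables plus a machine-readable
run manifest.  Every stage is seeded, so a rerun with the same configuration
reproduces the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ddm import ContaminantSpec, DiffusionModel, QuadratureConfig
from .diagnostics import llr_ddm, llr_slope
from .learning_curve import ExponentialLearningModel
from .model_selection import ModelComparison
from .optim import OptimizerConfig
from .synthetic import TRIAL_COLUMNS

__all__ = [
    "RunConfig",
    "ExclusionReport",
    "read_trials",
    "write_trials",
    "apply_exp2_exclusions",
    "select_asymptotic_window",
    "run_analysis",
]

logger = logging.getLogger("skillfit.pipeline")

_MANDATORY = [c for c in TRIAL_COLUMNS if c != "is_contaminant"]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as comma-separated text with the standard header."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    missing = [c for c in _MANDATORY if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    trials[cols].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table, validating the schema.

    The ``is_contaminant`` column is optional and ``repetition`` is
    recomputed from trial order when absent.  RTs are expected in seconds;
    if every RT exceeds 10 the column is assumed to be in milliseconds and
    rescaled with a warning, while a mixture of scales is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    optional = {"repetition", "is_contaminant"}
    missing = [c for c in _MANDATORY if c not in df.columns and c not in optional]
    if missing:
        raise ValueError(f"trial file {path.name} is missing column(s): {missing}")
    bad = df.index[df["rt"].isna() | ~np.isfinite(df["rt"].to_numpy(dtype=float))]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # header + 1-based
        raise ValueError(f"malformed rt values at line(s) {lines}")
    rt = df["rt"].to_numpy(dtype=float)
    ms_like = rt > 10.0
    if ms_like.all() and len(df):
        warnings.warn(
            "all RTs exceed 10; assuming milliseconds and rescaling to seconds",
            UserWarning,
            stacklevel=2,
        )
        df["rt"] = rt / 1000.0
    elif ms_like.any():
        raise ValueError(
            f"{int(ms_like.sum())} of {len(df)} RTs exceed 10 s: mixed units?"
        )
    if "repetition" not in df.columns:
        df["repetition"] = df.groupby(["participant", "stimulus"]).cumcount()
    return df


@dataclass
class ExclusionReport:
    """Outcome of the sequential participant-exclusion filters."""

    filters: tuple = (
        "slower_last_200",
        "accuracy_at_most_60",
        "mean_rt_over_2s",
        "mean_rt_under_150ms",
    )
    flags: pd.DataFrame = None
    retained: list = field(default_factory=list)
    unevaluable: list = field(default_factory=list)

    def counts(self) -> dict:
        out = {f: int(self.flags[f].sum()) for f in self.filters}
        out["retained"] = len(self.retained)
        out["unevaluable"] = len(self.unevaluable)
        return out


def apply_exp2_exclusions(
    trials: pd.DataFrame, min_trials: int = 400
) -> tuple[ExclusionReport, pd.DataFrame]:
    """Sequential participant exclusions for the online experiment.

    In order: (1) mean RT of the last 200 trials above the first 200
    (no learning); (2) overall accuracy not above 60%; (3) mean RT above
    2 s; (4) mean RT below 150 ms.  A participant caught by an earlier
    filter is not re-counted by later ones.  Participants with fewer than
    ``min_trials`` trials are flagged unevaluable and retained.
    """
    rows = []
    retained, unevaluable = [], []
    for pid, sub in trials.groupby("participant", sort=True):
        rec = {"participant": pid, **{f: False for f in ExclusionReport().filters}}
        if len(sub) < min_trials:
            unevaluable.append(pid)
            retained.append(pid)
            rec["unevaluable"] = True
            rows.append(rec)
            continue
        rec["unevaluable"] = False
        rt = sub["rt"].to_numpy(dtype=float)
        acc = sub["accuracy"].to_numpy(dtype=float)
        excluded = False
        if rt[-200:].mean() > rt[:200].mean():
            rec["slower_last_200"] = True
            excluded = True
        elif acc.mean() <= 0.60:  # strict "over 60%" reading
            rec["accuracy_at_most_60"] = True
            excluded = True
        elif rt.mean() > 2.0:
            rec["mean_rt_over_2s"] = True
            excluded = True
        elif rt.mean() < 0.150:
            rec["mean_rt_under_150ms"] = True
            excluded = True
        if not excluded:
            retained.append(pid)
        rows.append(rec)
    flags = pd.DataFrame(rows).set_index("participant")
    report = ExclusionReport(flags=flags, retained=retained, unevaluable=unevaluable)
    kept = trials[trials["participant"].isin(retained)].reset_index(drop=True)
    return report, kept


def select_asymptotic_window(trials: pd.DataFrame, last_k: int) -> pd.DataFrame:
    """Keep exactly the final ``last_k`` presentations per (participant, stimulus).

    Trial order and all columns are preserved.  Series shorter than
    ``last_k`` raise an error naming the stimulus.
    """
    if last_k < 1:
        raise ValueError("last_k must be >= 1")
    counts = trials.groupby(["participant", "stimulus"])["repetition"].agg(["count", "max"])
    short = counts[counts["count"] < last_k]
    if len(short):
        pid, stim = short.index[0]
        raise ValueError(
            f"stimulus {stim!r} of participant {pid!r} has only "
            f"{int(short['count'].iloc[0])} repetitions (< {last_k})"
        )
    cutoff = counts["max"] - last_k
    key = pd.MultiIndex.from_frame(trials[["participant", "stimulus"]])
    keep = trials["repetition"].to_numpy() > cutoff.loc[key].to_numpy()
    return trials[keep]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (mirrors the YAML config file)."""

    input_path: str = ""
    experiment: int = 1
    last_k: int = 10
    contaminant_proportion: float = 0.05
    correct_only_curve: bool = False
    apply_exclusions: bool = False
    seed: int = 0
    output_dir: str = "skillfit_out"
    curve_optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(swarm_size=40, iterations=300, n_restarts=5)
    )
    ddm_optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(
            swarm_size=16,
            iterations=60,
            n_restarts=1,
            polish_maxfev_per_dim=30,
            stall_iterations=12,
        )
    )
    quad: QuadratureConfig = field(
        default_factory=lambda: QuadratureConfig(n_drift=7, n_start=3, n_t0=5)
    )

    def __post_init__(self):
        if self.last_k < 3:
            raise ValueError("last_k must be >= 3")
        if self.experiment == 2 and self.last_k != 15:
            warnings.warn(
                "experiment 2 analyses conventionally use last_k=15",
                UserWarning,
                stacklevel=2,
            )
        if self.experiment == 1 and self.last_k != 10:
            warnings.warn(
                "experiment 1 analyses conventionally use last_k=10",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("curve_optimizer", "ddm_optimizer"):
            if key in raw:
                raw[key] = OptimizerConfig(**raw[key])
        if "quad" in raw:
            raw["quad"] = QuadratureConfig(**raw["quad"])
        return cls(**raw)


def _comparison_rows(pid, comparison: ModelComparison, stage: str) -> list[dict]:
    rows = []
    for fit, w in zip(comparison.fits, comparison.weights):
        base = {
            "participant": pid,
            "stage": stage,
            "spec": fit.spec.name,
            "k": fit.k,
            "n": fit.n,
            "bic": fit.bic,
            "weight": float(w),
        }
        base["sse" if stage == "curve" else "sll"] = (
            fit.sse if stage == "curve" else fit.sll
        )
        for cond, params in fit.params_by_condition.items():
            for name, value in params.as_dict().items():
                base[f"{name}[{cond}]"] = value
        rows.append(base)
    return rows


def run_analysis(config: RunConfig, trials: pd.DataFrame | None = None) -> dict:
    """Run the full two-stage analysis and write the report bundle.

    Stages: read -> (optional exclusions) -> curve hierarchy fits on all
    trials -> asymptotic-window selection -> DDM hierarchy fits ->
    comparisons -> diagnostics.  Returns a dict with the in-memory results
    and writes delimited-text tables plus ``manifest.json`` to
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        if trials is None:
            trials = read_trials(config.input_path)
        write_trials(trials, out / "trials.csv")

        exclusion_report = None
        if config.apply_exclusions:
            stage = "exclusions"
            exclusion_report, trials = apply_exp2_exclusions(trials)

        participants = sorted(trials["participant"].unique().tolist())
        root = np.random.SeedSequence(config.seed)
        curve_rows, ddm_rows, diag_rows = [], [], []
        curve_comparisons, ddm_comparisons = {}, {}
        contaminant = ContaminantSpec(proportion=config.contaminant_proportion)
        for pid, child in zip(participants, root.spawn(len(participants))):
            s_curve, s_ddm = [int(x) for x in child.generate_state(2) % (2**31)]
            sub = trials[trials["participant"] == pid]
            multi = sub["instruction"].nunique() > 1

            stage = "curve_fits"
            logger.info("participant=%s stage=curve n=%d", pid, len(sub))
            curve_model = ExponentialLearningModel(
                sub, correct_only=config.correct_only_curve
            )
            if multi:
                ccomp = curve_model.fit_hierarchy(
                    optimizer=config.curve_optimizer, seed=s_curve, participant_id=pid
                )
                curve_comparisons[pid] = ccomp
                curve_rows.extend(_comparison_rows(pid, ccomp, "curve"))
            else:
                fit = curve_model.fit(optimizer=config.curve_optimizer, seed=s_curve)
                curve_rows.extend(
                    _comparison_rows(pid, ModelComparison(pid, [fit]), "curve")
                )

            stage = "window"
            asym = select_asymptotic_window(sub, config.last_k)

            stage = "ddm_fits"
            logger.info("participant=%s stage=ddm n=%d", pid, len(asym))
            ddm_model = DiffusionModel(asym, contaminant=contaminant, quad=config.quad)
            if multi:
                dcomp = ddm_model.fit_hierarchy(
                    optimizer=config.ddm_optimizer, seed=s_ddm, participant_id=pid
                )
                ddm_comparisons[pid] = dcomp
                ddm_rows.extend(_comparison_rows(pid, dcomp, "ddm"))
            else:
                fit = ddm_model.fit(optimizer=config.ddm_optimizer, seed=s_ddm)
                dcomp = ModelComparison(pid, [fit])
                ddm_rows.extend(_comparison_rows(pid, dcomp, "ddm"))

            stage = "diagnostics"
            for cond, cond_trials in asym.groupby("instruction"):
                row = {
                    "participant": pid,
                    "condition": cond,
                    "llr_slope": llr_slope(cond_trials),
                }
                if multi and pid in ddm_comparisons:
                    row["llr_ddm"] = llr_ddm(ddm_comparisons[pid])
                diag_rows.append(row)

        stage = "write"
        curve_fits = pd.DataFrame(curve_rows)
        ddm_fits = pd.DataFrame(ddm_rows)
        diagnostics = pd.DataFrame(diag_rows)
        weights = pd.concat([curve_fits, ddm_fits], ignore_index=True)[
            ["participant", "stage", "spec", "bic", "weight"]
        ]
        curve_fits.to_csv(out / "curve_fits.csv", index=False)
        ddm_fits.to_csv(out / "ddm_fits.csv", index=False)
        weights.to_csv(out / "weights.csv", index=False)
        diagnostics.to_csv(out / "diagnostics.csv", index=False)
        if exclusion_report is not None:
            exclusion_report.flags.to_csv(out / "exclusions.csv")

        manifest = {
            "skillfit_version": __version__,
            "seed": config.seed,
            "config": _config_echo(config),
            "n_participants": len(participants),
            "n_trials": int(len(trials)),
            "curve_fits_per_participant": 8 if curve_comparisons else 1,
            "ddm_fits_per_participant": 8 if ddm_comparisons else 1,
            "outputs": [
                "trials.csv",
                "curve_fits.csv",
                "ddm_fits.csv",
                "weights.csv",
                "diagnostics.csv",
            ],
        }
        if exclusion_report is not None:
            manifest["exclusions"] = exclusion_report.counts()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "curve_fits": curve_fits,
        "ddm_fits": ddm_fits,
        "diagnostics": diagnostics,
        "curve_comparisons": curve_comparisons,
        "ddm_comparisons": ddm_comparisons,
        "exclusion_report": exclusion_report,
        "manifest": manifest,
    }


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        return obj

    return enc(config)
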