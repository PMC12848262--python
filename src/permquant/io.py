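"""File formats, configuration and pipeline orchestration.

Times are hours at the I/O boundary (matching how spot samples are
recorded) and days internally.  All artifacts are plain text: CSV for
tabular data, JSON (sorted keys, fixed float formatting) for results, so
identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .excretion import AnimalExcretion, DEFAULT_CREATININE_RATE, DEFAULT_DOSE_CO_MG, cohort_excretion
from .group_stats import AncovaResult, LinearModelTable, ancova_stepwise, factorial_anova
from .population import FitSettings, NpdeReport, PopulationFitResult, UrineSeries, compute_npde, fit_population
from .simulate import MARKER_COLUMNS

__all__ = [
    "PipelineConfig",
    "read_urine_csv",
    "write_urine_csv",
    "read_serum_csv",
    "write_serum_csv",
    "fit_result_to_dict",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

URINE_COLUMNS = ("animal_id", "breed", "treatment", "bw_kg", "time_h", "co_creatinine_ratio")
URINE_RAW_COLUMNS = ("animal_id", "breed", "treatment", "bw_kg", "time_h", "co_mg_l", "creatinine_mg_l")


@dataclass
class PipelineConfig:
    urine_csv: str = ""
    serum_csv: str = ""
    out_dir: str = "results"
    creatinine_rate: float = DEFAULT_CREATININE_RATE
    dose_co_mg: float = DEFAULT_DOSE_CO_MG
    auc_t_end: float = 1.5  # days
    auc_n_grid: int = 10_001
    n_explore: int = 300
    n_smooth: int = 100
    n_chains: int = 1
    error_model: str = "proportional"
    seed: int = 0
    npde_n_sim: int = 1000
    alpha: float = 0.05
    include_t0: bool = False

    def __post_init__(self) -> None:
        for name in ("creatinine_rate", "dose_co_mg", "auc_t_end", "auc_n_grid",
                     "n_explore", "n_smooth", "n_chains", "npde_n_sim", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config value {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def fit_settings(self) -> FitSettings:
        return FitSettings(
            n_explore=self.n_explore, n_smooth=self.n_smooth, n_chains=self.n_chains,
            error_model=self.error_model, seed=self.seed, include_t0=self.include_t0,
        )

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (paths excluded)."""
        d = dataclasses.asdict(self)
        for key in ("urine_csv", "serum_csv", "out_dir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_urine_csv(path: str | Path) -> list[UrineSeries]:
    """Read a spot-urine table into per-animal series (hours -> days).

    Accepts either a ready-made ``co_creatinine_ratio`` column or separate
    ``co_mg_l`` + ``creatinine_mg_l`` columns, whose quotient is used.
    Duplicate (animal, time) rows and negative ratios are rejected with the
    offending row identified.
    """
    df = pd.read_csv(path)
    cols = tuple(df.columns)
    if cols == URINE_COLUMNS:
        ratio = df["co_creatinine_ratio"]
    elif cols == URINE_RAW_COLUMNS:
        if (df["creatinine_mg_l"] <= 0).any():
            bad = int(df.index[df["creatinine_mg_l"] <= 0][0]) + 2
            raise ValueError(f"non-positive creatinine concentration at row {bad}")
        ratio = df["co_mg_l"] / df["creatinine_mg_l"]
    else:
        raise ValueError(
            f"unexpected urine CSV header {list(cols)}; expected "
            f"{list(URINE_COLUMNS)} or {list(URINE_RAW_COLUMNS)}"
        )
    for col in ("bw_kg", "time_h"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = int(df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]) + 2
            raise ValueError(f"non-numeric value in column {col!r} at row {bad}")
    if not np.issubdtype(np.asarray(ratio).dtype, np.number) or ratio.isna().any():
        bad = int(df.index[pd.to_numeric(ratio, errors="coerce").isna()][0]) + 2
        raise ValueError(f"non-numeric Co:creatinine ratio at row {bad}")
    if (ratio < 0).any():
        bad = int(df.index[ratio < 0][0]) + 2
        raise ValueError(f"negative Co:creatinine ratio at row {bad}")
    df = df.assign(_ratio=ratio)

    dup = df.duplicated(subset=["animal_id", "time_h"], keep=False)
    if dup.any():
        a = df.loc[dup, "animal_id"].iloc[0]
        t = df.loc[dup, "time_h"].iloc[0]
        raise ValueError(f"duplicated sample time {t} h for animal {a!r}")

    series = []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("time_h")
        series.append(
            UrineSeries(
                animal_id=str(aid),
                breed=str(grp["breed"].iloc[0]),
                treatment=float(grp["treatment"].iloc[0]),
                bw_kg=float(grp["bw_kg"].iloc[0]),
                times_d=grp["time_h"].to_numpy(float) / 24.0,
                ratios=grp["_ratio"].to_numpy(float),
            )
        )
    return series


def write_urine_csv(series: list[UrineSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t_d, r in zip(s.times_d, s.ratios):
            rows.append({
                "animal_id": s.animal_id, "breed": s.breed, "treatment": s.treatment,
                "bw_kg": s.bw_kg, "time_h": t_d * 24.0, "co_creatinine_ratio": r,
            })
    pd.DataFrame(rows, columns=list(URINE_COLUMNS)).to_csv(path, index=False)


def read_serum_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "breed", "treatment", *MARKER_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"serum CSV missing column(s): {sorted(missing)}")
    return df


def write_serum_csv(serum: pd.DataFrame, path: str | Path) -> None:
    serum.to_csv(path, index=False)


# --- serialization ----------------------------------------------------------

def _round(x: float) -> float:
    return float(f"{x:.10g}")


def fit_result_to_dict(fit: PopulationFitResult) -> dict:
    return {
        "fixed_effects": {k: _round(v) for k, v in fit.model.fixed_effects_natural().items()},
        "log_mu": [_round(v) for v in fit.model.mu],
        "omega": [_round(v) for v in fit.model.omega],
        "sigma": [_round(v) for v in fit.model.sigma],
        "error_model": fit.model.error_model,
        "converged": bool(fit.converged),
        "rel_change": _round(fit.rel_change),
        "seed": int(fit.seed),
        "n_iterations": int(len(fit.loglik_trace)),
        "loglik_final": _round(float(fit.loglik_trace[-1])),
        "excluded_animals": list(fit.excluded_animals),
        "individual_params": {
            aid: {"A": _round(p.A), "B": _round(p.B), "k1": _round(p.k1), "k2": _round(p.k2)}
            for aid, p in sorted(fit.individual_params.items())
        },
    }


def _table_to_dict(tab: LinearModelTable) -> dict:
    return {
        "response": tab.response,
        "terms": [
            {"term": t, "df": d, "sum_sq": _round(ss), "F": _round(f), "p": _round(p)}
            for t, d, ss, f, p in tab.terms
        ],
        "df_error": tab.df_error,
        "mse": _round(tab.mse),
        "cell_means": {k: _round(v) for k, v in tab.cell_means.items()},
        "sem": None if tab.sem is None else _round(tab.sem),
    }


def _ancova_to_dict(res: AncovaResult) -> dict:
    return {
        "response": res.response,
        "elimination_path": [{"term": t, "p": _round(p)} for t, p in res.elimination_path],
        "final_terms": [{"term": t, "F": _round(f), "p": _round(p)} for t, f, p in res.final_terms],
        "slope": None if res.slope is None else _round(res.slope),
    }


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run fit -> npde -> excretion -> ANOVA/ANCOVA and write all artifacts.

    Writes fit.json, npde.csv, excretion.csv, stats.json and report.txt to
    ``config.out_dir``.  Any stage failure raises with a stage-tagged
    message and leaves no partial artifact set behind.
    """
    out = Path(config.out_dir)
    stage = "input"
    try:
        series = read_urine_csv(config.urine_csv)
        serum = read_serum_csv(config.serum_csv)

        stage = "fit"
        fit = fit_population(series, config.fit_settings())

        stage = "npde"
        npde = compute_npde(fit, series, n_sim=config.npde_n_sim, seed=config.seed)

        stage = "excretion"
        excretion = cohort_excretion(
            fit, series, t_end=config.auc_t_end, n_grid=config.auc_n_grid,
            creatinine_rate=config.creatinine_rate, dose_co_mg=config.dose_co_mg,
        )

        stage = "stats"
        exc_df = pd.DataFrame([dataclasses.asdict(e) for e in excretion])
        meta = serum[["animal_id", "breed", "treatment"]]
        exc_df = exc_df.merge(meta, on="animal_id")
        anova: dict[str, dict] = {}
        ancova: dict[str, dict] = {}
        anova["total_co_mg"] = _table_to_dict(
            factorial_anova(exc_df.rename(columns={"treatment": "aspirin"}),
                            "total_co_mg", factor_a="aspirin", factor_b="breed")
        )
        merged = serum.merge(exc_df[["animal_id", "total_co_mg"]], on="animal_id")
        merged = merged.rename(columns={"treatment": "aspirin", "total_co_mg": "co_excretion"})
        for marker in MARKER_COLUMNS:
            anova[marker] = _table_to_dict(
                factorial_anova(merged, marker, factor_a="aspirin", factor_b="breed")
            )
            ancova[marker] = _ancova_to_dict(
                ancova_stepwise(merged, marker, covariate="co_excretion",
                                factor_a="aspirin", factor_b="breed", alpha=config.alpha)
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "write"
    out.mkdir(parents=True, exist_ok=True)
    _write_json(fit_result_to_dict(fit), out / "fit.json")
    pd.DataFrame({
        "animal_id": npde.animal_ids, "time_h": npde.times_d * 24.0,
        "observed": npde.observed, "npde": npde.npde,
    }).to_csv(out / "npde.csv", index=False)
    exc_df.to_csv(out / "excretion.csv", index=False)
    _write_json({"anova": anova, "ancova": ancova}, out / "stats.json")

    mean_total = float(exc_df["total_co_mg"].mean())
    mean_frac = float(exc_df["dose_fraction_pct"].mean())
    lines = [
        "permquant pipeline report",
        f"config digest: {config.digest()}   seed: {config.seed}",
        f"animals fitted: {len(fit.individual_params)} "
        f"(excluded: {len(fit.excluded_animals)})   converged: {fit.converged}",
        "population fixed effects: "
        + ", ".join(f"{k}={v:.4g}" for k, v in fit.model.fixed_effects_natural().items()),
        f"npde adequacy p-values: shapiro={npde.shapiro_p:.3f} "
        f"wilcoxon={npde.wilcoxon_p:.3f} variance={npde.fisher_var_p:.3f}",
        f"mean total urinary Co: {mean_total:.1f} mg "
        f"({mean_frac:.2f}% of the {config.dose_co_mg:.0f} mg Co dose)",
    ]
    for marker in MARKER_COLUMNS:
        sl = ancova[marker]["slope"]
        lines.append(
            f"ANCOVA {marker}: covariate "
            + (f"retained, slope {sl:.4g} per mg Co" if sl is not None else "eliminated")
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")

    return {"fit": fit, "npde": npde, "excretion": excretion,
            "anova": anova, "ancova": ancova}
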