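"""Risk scoring and observed-vs-simulated validation summaries.

Risk scores condense a participant-phase record (age, sex, blood pressure,
lipids, glycaemia, smoking, family history) into a probability of a long-term
event.  Score definitions are pluggable JSON documents so the validation
machinery is score-agnostic; two link functions are supported:

- ``cox``: survival-based, ``risk = 1 − S0 ** exp(lp − lp_mean)`` at a fixed
  horizon (the form of the 2008 general cardiovascular Framingham equation);
- ``logistic``: ``risk = 1 / (1 + exp(−(intercept + lp)))``.

The validation summaries mirror a cohort-replication design: per-phase means,
SDs and correlation matrices of observed versus simulated measures, age-binned
mean curves, and per-phase risk-score comparisons where the simulated mean/SD
pools all participant-replicate scores while correlations are computed per
replicate and then averaged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CohortTable
from .model import MEASURES
from .simulate import TrajectorySet

__all__ = [
    "RiskScoreDef",
    "ValidationReport",
    "load_score",
    "packaged_score",
    "compute_risk_scores",
    "compare_moments",
    "risk_score_comparison",
]

_COLUMN_ALIASES = {"age": "age_at_phase"}


@dataclass(frozen=True)
class RiskScoreDef:
    """A risk-score definition loaded from JSON.

    ``terms`` entries carry: ``input`` (record column, ``age`` aliases
    ``age_at_phase``), ``transform`` (``identity`` | ``log`` | ``threshold``),
    optional ``scale`` (unit conversion applied before the transform),
    optional ``threshold`` (for the indicator transform), optional ``center``
    subtracted after the transform, and ``coef`` (a number, or a
    ``{"male": .., "female": ..}`` pair for sex-specific equations).
    """

    name: str
    link: str
    terms: tuple
    intercept: float = 0.0
    baseline_survival: Optional[dict] = None
    lp_mean: Optional[dict] = None
    horizon_years: Optional[float] = None
    description: str = ""

    def __post_init__(self):
        if self.link not in ("cox", "logistic"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "cox" and (self.baseline_survival is None or self.lp_mean is None):
            raise ValueError("cox link requires baseline_survival and lp_mean")
        for term in self.terms:
            if term.get("transform", "identity") not in ("identity", "log", "threshold"):
                raise ValueError(f"unknown transform in term {term}")
            if "input" not in term or "coef" not in term:
                raise ValueError(f"malformed term {term}")

    @property
    def required_inputs(self) -> set:
        cols = {_COLUMN_ALIASES.get(t["input"], t["input"]) for t in self.terms}
        if self.link == "cox" or any(isinstance(t["coef"], dict) for t in self.terms):
            cols.add("sex")
        return cols


def load_score(path) -> RiskScoreDef:
    with open(path) as fh:
        doc = json.load(fh)
    return RiskScoreDef(
        name=doc["name"],
        link=doc["link"],
        terms=tuple(doc["terms"]),
        intercept=float(doc.get("intercept", 0.0)),
        baseline_survival=doc.get("baseline_survival"),
        lp_mean=doc.get("lp_mean"),
        horizon_years=doc.get("horizon_years"),
        description=doc.get("description", ""),
    )


def packaged_score(name: str) -> RiskScoreDef:
    """Load a packaged score: ``framingham_cvd_2008``,
    ``diabetes_fpg_synthetic`` or ``diabetes_2h_synthetic``."""
    res = resources.files("metatraj.data").joinpath(f"{name}.json")
    with res.open() as fh:
        doc = json.load(fh)
    return RiskScoreDef(
        name=doc["name"], link=doc["link"], terms=tuple(doc["terms"]),
        intercept=float(doc.get("intercept", 0.0)),
        baseline_survival=doc.get("baseline_survival"),
        lp_mean=doc.get("lp_mean"), horizon_years=doc.get("horizon_years"),
        description=doc.get("description", ""),
    )


def _coef_vector(coef, sex: np.ndarray) -> np.ndarray:
    if isinstance(coef, dict):
        return np.where(sex == 1, float(coef["male"]), float(coef["female"]))
    return np.full(sex.shape, float(coef))


def compute_risk_scores(records: pd.DataFrame, sdef: RiskScoreDef) -> pd.Series:
    """Per-record event probability; records with any missing input get NaN.

    ``records`` has one row per participant-phase with measure columns and
    ``age_at_phase``/``sex``/covariate columns (a ``CohortTable.frame`` works
    directly).
    """
    n = len(records)
    missing_cols = sdef.required_inputs - set(records.columns)
    if missing_cols:
        raise KeyError(f"records lack required inputs {sorted(missing_cols)}")
    sex = records["sex"].to_numpy() if "sex" in records.columns else np.zeros(n)
    lp = np.full(n, float(sdef.intercept))
    valid = np.ones(n, dtype=bool)
    for term in sdef.terms:
        col = _COLUMN_ALIASES.get(term["input"], term["input"])
        x = records[col].to_numpy(dtype=float)
        x = x * float(term.get("scale", 1.0))
        tf = term.get("transform", "identity")
        if tf == "log":
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.log(x)
        elif tf == "threshold":
            v = (x >= float(term["threshold"])).astype(float)
        else:
            v = x
        # missing inputs, and inputs outside a transform's domain (e.g. a
        # non-positive concentration under a log link), make the record
        # unscoreable rather than silently contributing zero
        valid &= np.isfinite(v)
        v = v - float(term.get("center", 0.0))
        lp = lp + _coef_vector(term["coef"], sex) * np.nan_to_num(v)
    if sdef.link == "logistic":
        risk = 1.0 / (1.0 + np.exp(-lp))
    else:
        s0 = np.where(sex == 1, sdef.baseline_survival["male"], sdef.baseline_survival["female"])
        mean = np.where(sex == 1, sdef.lp_mean["male"], sdef.lp_mean["female"])
        risk = 1.0 - s0 ** np.exp(lp - mean)
    risk = np.where(valid, risk, np.nan)
    return pd.Series(risk, index=records.index, name=sdef.name)


# ---------------------------------------------------------------------------
# observed vs simulated comparisons
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Observed-versus-simulated summaries.

    ``moments``: per phase and measure, observed mean (with 95% CI) and SD
    against the replicate-averaged simulated mean and SD, plus the simulated
    minus observed difference.  ``correlations``: per-phase correlation
    matrices for both sources.  ``age_curves``: 5-year age-binned means.
    """

    moments: pd.DataFrame
    correlations: dict
    age_curves: pd.DataFrame
    n_replicates: int = 0
    risk: Optional[pd.DataFrame] = None

    def to_json(self, path) -> None:
        doc = {
            "n_replicates": self.n_replicates,
            "moments": self.moments.to_dict(orient="records"),
            "age_curves": self.age_curves.to_dict(orient="records"),
            "correlations": {
                str(phase): {src: mat.tolist() for src, mat in d.items()}
                for phase, d in self.correlations.items()
            },
        }
        if self.risk is not None:
            doc["risk"] = self.risk.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)
            fh.write("\n")


def _sim_records(traj: TrajectorySet, observed_frame: pd.DataFrame) -> pd.DataFrame:
    """Wide participant-phase records for one replicate, with ages and
    covariates merged from the observed cohort (the simulation conditions on
    the same baseline table)."""
    long = traj.to_frame()
    wide = long.pivot_table(index=["participant", "phase"], columns="measure",
                            values="value", observed=True).reset_index()
    for m in MEASURES:
        if m not in wide.columns:
            wide[m] = np.nan
    meta_cols = ["participant", "phase", "elapsed_years", "age_at_phase",
                 "sex", "ethnicity", "smoking", "fh_diabetes", "fh_cvd"]
    meta = observed_frame[meta_cols]
    return meta.merge(wide, on=["participant", "phase"], how="inner")


def compare_moments(observed: CohortTable, simulated: Sequence[TrajectorySet],
                    age_bin_years: float = 5.0) -> ValidationReport:
    """Per-phase moment and correlation comparison plus age-binned curves."""
    obs = observed.frame
    sim_ids = set(np.concatenate([t.participants for t in simulated]))
    common = set(obs["participant"]) & sim_ids
    if not common:
        raise ValueError("observed and simulated participants do not overlap")
    obs = obs[obs["participant"].isin(common)]

    sim_frames = [
        _sim_records(t, obs).assign(replicate=t.replicate) for t in simulated
    ]
    sim = pd.concat(sim_frames, ignore_index=True)

    rows = []
    correlations = {}
    phases = sorted(obs["phase"].unique())
    for t in phases:
        o = obs[obs["phase"] == t]
        s = sim[sim["phase"] == t]
        for m in MEASURES:
            ov = o[m].dropna()
            sv = s[m].dropna()
            if len(ov) == 0 and len(sv) == 0:
                continue
            om, osd = ov.mean(), ov.std()
            half = 1.959963984540054 * osd / np.sqrt(len(ov)) if len(ov) else np.nan
            rows.append({
                "phase": t, "measure": m,
                "observed_mean": om, "observed_sd": osd,
                "observed_ci_low": om - half, "observed_ci_high": om + half,
                "n_observed": len(ov),
                "simulated_mean": sv.mean(), "simulated_sd": sv.std(),
                "difference": sv.mean() - om,
            })
        correlations[t] = {
            "observed": o[list(MEASURES)].corr().to_numpy(),
            "simulated": s[list(MEASURES)].corr().to_numpy(),
        }
    moments = pd.DataFrame(rows)

    def _binned(df, source):
        d = df.copy()
        d["age_bin"] = (np.floor(d["age_at_phase"] / age_bin_years) * age_bin_years)
        g = d.groupby("age_bin")[list(MEASURES)].mean().reset_index()
        return g.melt(id_vars="age_bin", var_name="measure", value_name="mean").assign(source=source)

    age_curves = pd.concat([_binned(obs, "observed"), _binned(sim, "simulated")],
                           ignore_index=True).dropna(subset=["mean"])
    return ValidationReport(moments=moments, correlations=correlations,
                            age_curves=age_curves, n_replicates=len(simulated))


def risk_score_comparison(observed: CohortTable, simulated: Sequence[TrajectorySet],
                          defs: Sequence[RiskScoreDef]) -> pd.DataFrame:
    """Per-phase, per-score comparison in the layout of a replication table.

    Columns: observed mean (SD), simulated mean (SD) pooled over replicates,
    difference (simulated − observed means), and the across-replicate mean of
    the per-replicate correlation between each participant's observed and
    simulated score.
    """
    obs = observed.frame
    rows = []
    obs_scores = {d.name: compute_risk_scores(obs, d) for d in defs}
    sim_records = [_sim_records(t, obs) for t in simulated]
    for d in defs:
        o_sc = obs.assign(score=obs_scores[d.name])
        sims = []
        for rec, t in zip(sim_records, simulated):
            sims.append(rec.assign(score=compute_risk_scores(rec, d).to_numpy(),
                                   replicate=t.replicate))
        sim_all = pd.concat(sims, ignore_index=True)
        for phase in sorted(obs["phase"].unique()):
            ov = o_sc[o_sc["phase"] == phase][["participant", "score"]].dropna()
            sv = sim_all[sim_all["phase"] == phase]
            if len(ov) == 0 or sv["score"].notna().sum() == 0:
                continue
            corrs = []
            for _, grp in sv.groupby("replicate"):
                merged = ov.merge(grp[["participant", "score"]], on="participant",
                                  suffixes=("_obs", "_sim")).dropna()
                if len(merged) >= 3 and merged["score_obs"].std() > 0 and merged["score_sim"].std() > 0:
                    corrs.append(merged["score_obs"].corr(merged["score_sim"]))
            rows.append({
                "score": d.name, "phase": phase,
                "observed_mean": ov["score"].mean(),
                "observed_sd": ov["score"].std(),
                "simulated_mean": sv["score"].mean(),
                "simulated_sd": sv["score"].std(),
                "difference": sv["score"].mean() - ov["score"].mean(),
                "mean_correlation": float(np.mean(corrs)) if corrs else np.nan,
                "n_observed_scored": len(ov),
                "n_simulated_unscored": int(sv["score"].isna().sum()),
            })
    return pd.DataFrame(rows)
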