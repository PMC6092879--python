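"""Synthetic cohort generator emulating a Whitehall-II-like analytic sample.

The restricted source cohort cannot be redistributed, so this module
fabricates a structurally faithful stand-in: baseline demographics of a
middle-aged occupational cohort, model-generated metabolic trajectories over
four clinical phases at 0/6/11/16 years, clinical-alert censoring, monotone
visit dropout plus item-level missing-at-random deletion, and the exclusion
of participants contributing no clinical data.  Every step records counts so
the provenance of the final sample is explicit.

The demographic default proportions are plausible placeholders for a cohort
known to under-represent women and ethnic minorities; all are configurable,
and nothing downstream depends on their exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import CohortTable
from .model import MEASURES, ModelSpec, ParameterSet, build_index_map, default_spec
from .simulate import AlertThresholds, simulate_trajectories, apply_alert_censoring

__all__ = [
    "DemographicsConfig",
    "MissingnessConfig",
    "generate_baseline",
    "impose_missingness",
    "generate_cohort",
    "WHITEHALL_EXCLUSION_CASCADE",
    "exclusion_cascade_summary",
]

#: published exclusion cascade of the source cohort (counts of participants);
#: the percentages in the summary are recomputed from these counts.
WHITEHALL_EXCLUSION_CASCADE = {
    "recruited": 10308,
    "lost_before_phase3": 1075,
    "no_clinical_data": 408,
    "prevalent_diabetes": 136,
    "cvd_history": 439,
    "final_sample": 8150,
}


def exclusion_cascade_summary(cascade: Optional[dict] = None) -> pd.DataFrame:
    """Percentages of the recruited sample for each exclusion step.

    Note the steps overlap in the source cohort (the counts do not subtract
    to the final sample), so no consistency between rows is implied.
    """
    c = dict(cascade or WHITEHALL_EXCLUSION_CASCADE)
    total = c.pop("recruited")
    rows = [{"step": "recruited", "count": total, "pct_of_recruited": 100.0}]
    for step, count in c.items():
        rows.append({
            "step": step,
            "count": count,
            "pct_of_recruited": round(100.0 * count / total, 1),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DemographicsConfig:
    """Baseline demographics of the synthetic cohort.

    The default age range (41-61) is the recruitment span of 35-55 shifted by
    the ~6 years between recruitment and the first clinical baseline.
    """

    n: int = 8150
    age_range: tuple = (41.0, 61.0)
    p_male: float = 0.67
    p_nonwhite: float = 0.09
    p_smoker: float = 0.15
    p_fh_diabetes: float = 0.15
    p_fh_cvd: float = 0.25

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age range must have positive width")
        for nm in ("p_male", "p_nonwhite", "p_smoker", "p_fh_diabetes", "p_fh_cvd"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1]")


@dataclass(frozen=True)
class MissingnessConfig:
    """Missing-at-random data deletion.

    ``visit_dropout_hazard[t]`` is the probability of permanently leaving the
    study at phase t given attendance up to t-1 (monotone dropout; the first
    entry should be 0 so everyone has a baseline).  Item-level deletion is
    logistic: at phase 1 the probability is ``sigmoid(item_intercept)``; at
    later phases standardized previous-phase observed values enter with
    ``item_prev_coef`` each (missing previous values contribute 0), making
    missingness depend on observed responses only.
    """

    visit_dropout_hazard: tuple = (0.0, 0.05, 0.07, 0.08)
    item_intercept: float = -2.944  # sigmoid(-2.944) ~= 0.05
    item_prev_coef: float = 0.2

    def __post_init__(self):
        for h in self.visit_dropout_hazard:
            if not 0.0 <= h <= 1.0:
                raise ValueError("dropout hazards must be probabilities")

    @classmethod
    def none(cls) -> "MissingnessConfig":
        return cls(visit_dropout_hazard=(0.0, 0.0, 0.0, 0.0),
                   item_intercept=-np.inf, item_prev_coef=0.0)

    @classmethod
    def mar_rate(cls, rate: float, prev_coef: float = 0.0,
                 dropout: tuple = (0.0, 0.0, 0.0, 0.0)) -> "MissingnessConfig":
        """Intercept-only item-level MAR at the given marginal rate."""
        if not 0.0 < rate < 1.0:
            raise ValueError("rate must be in (0, 1)")
        return cls(visit_dropout_hazard=dropout,
                   item_intercept=float(np.log(rate / (1.0 - rate))),
                   item_prev_coef=prev_coef)


def generate_baseline(config: DemographicsConfig, rng) -> pd.DataFrame:
    """Independent covariate draws at the configured proportions."""
    n = config.n
    lo, hi = config.age_range
    return pd.DataFrame({
        "participant": np.arange(1, n + 1),
        "age_base": rng.uniform(lo, hi, size=n),
        "sex": (rng.random(n) < config.p_male).astype(int),
        "ethnicity": (rng.random(n) < config.p_nonwhite).astype(int),
        "smoking": (rng.random(n) < config.p_smoker).astype(int),
        "fh_diabetes": (rng.random(n) < config.p_fh_diabetes).astype(int),
        "fh_cvd": (rng.random(n) < config.p_fh_cvd).astype(int),
    })


def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def impose_missingness(cohort: CohortTable, config: MissingnessConfig, rng) -> CohortTable:
    """Apply monotone visit dropout then item-level MAR deletion.

    Returns a new table; realized missingness fractions are attached as
    ``.missingness_report`` on the result.
    """
    spec = cohort.spec
    df = cohort.frame.copy()
    pids = df["participant"].unique()
    n = len(pids)
    nT = spec.n_phases

    hazards = np.asarray(config.visit_dropout_hazard, float)
    if hazards.size != nT:
        raise ValueError(f"need one dropout hazard per phase ({nT})")
    u = rng.random((n, nT)) < hazards[None, :]
    dropped = np.cumsum(u, axis=1) > 0          # monotone: once out, always out
    drop_map = dict(zip(pids, dropped))

    measures = list(MEASURES)
    # standardize per measure for the MAR logit (observed values only)
    stats = {m: (df[m].mean(), df[m].std(ddof=0) or 1.0) for m in measures}

    pid_index = {pid: i for i, pid in enumerate(pids)}
    prev_values = {}
    n_cells = 0
    n_missing = 0
    for t in range(nT):
        sel = df["phase"] == t + 1
        idx = df.index[sel]
        rows_pid = df.loc[idx, "participant"].to_numpy()
        visit_out = np.array([drop_map[pid][t] for pid in rows_pid])
        for m in measures:
            vals = df.loc[idx, m].to_numpy(dtype=float)
            present = ~np.isnan(vals)
            n_cells += int(present.sum())
            # item-level MAR logit on previous phase's observed values
            if t == 0 or config.item_prev_coef == 0.0:
                lp = np.full(len(idx), config.item_intercept)
            else:
                zprev = np.zeros(len(idx))
                for mm in measures:
                    pv = prev_values.get(mm)
                    if pv is None:
                        continue
                    z = (pv[[pid_index[p] for p in rows_pid]] - stats[mm][0]) / stats[mm][1]
                    zprev += np.where(np.isnan(z), 0.0, z)
                lp = config.item_intercept + config.item_prev_coef * zprev
            item_out = rng.random(len(idx)) < _sigmoid(lp)
            out = visit_out | item_out
            n_missing += int((present & out).sum())
            vals[out] = np.nan
            df.loc[idx, m] = vals
        # record this phase's (post-deletion) values for the next phase's logit
        for m in measures:
            pv = np.full(n, np.nan)
            pv[[pid_index[p] for p in rows_pid]] = df.loc[idx, m].to_numpy(dtype=float)
            prev_values[m] = pv

    out_table = CohortTable(frame=df, spec=spec)
    out_table.missingness_report = {
        "n_value_cells": n_cells,
        "n_deleted": n_missing,
        "fraction_deleted": (n_missing / n_cells) if n_cells else 0.0,
    }
    return out_table


def generate_cohort(
    n: int,
    params: ParameterSet,
    spec: Optional[ModelSpec] = None,
    demographics: Optional[DemographicsConfig] = None,
    missingness: Optional[MissingnessConfig] = None,
    thresholds: Optional[AlertThresholds] = None,
    rng=None,
    seed: Optional[int] = None,
    exclude_prevalent: bool = False,
) -> tuple[CohortTable, dict]:
    """Full synthetic-cohort pipeline with provenance counts.

    Composes baseline generation, one trajectory replicate, alert censoring,
    optional prevalent-hyperglycaemia exclusion (baseline FPG >= 7.0 or 2-h
    glucose >= 11.1 mmol/L, echoing diagnostic cut-offs), MAR missingness,
    and removal of participants left with no clinical data.
    """
    spec = spec or default_spec()
    demographics = demographics or DemographicsConfig(n=n)
    if demographics.n != n:
        demographics = DemographicsConfig(**{**demographics.__dict__, "n": n})
    missingness = missingness if missingness is not None else MissingnessConfig()
    thresholds = thresholds if thresholds is not None else AlertThresholds()
    if seed is None:
        seed = int(rng.integers(2**31)) if rng is not None else 0
    rng_base = np.random.default_rng([seed, 10_001])
    rng_miss = np.random.default_rng([seed, 10_002])

    provenance = {"seed": seed, "n_requested": n}
    baseline = generate_baseline(demographics, rng_base)
    traj = simulate_trajectories(params, baseline, spec, n_replicates=1, seed=seed)[0]
    censored = apply_alert_censoring(traj, thresholds)
    provenance["n_censored_positions"] = int(censored.censored.sum())

    W_cov = np.column_stack([
        (baseline["age_base"].to_numpy() - spec.age_center)
        if c == "age_base_c" else baseline[c].to_numpy(dtype=float)
        for c in spec.covariates
    ])
    table = CohortTable.from_matrices(censored.values, W_cov, spec,
                                      participants=baseline["participant"].to_numpy())

    if exclude_prevalent:
        imap = build_index_map(spec)
        fpg0 = censored.values[:, imap.index("fpg", 0)]
        g2h0 = censored.values[:, imap.index("glu2h", 0)]
        prevalent = (np.nan_to_num(fpg0, nan=-np.inf) >= 7.0) | (
            np.nan_to_num(g2h0, nan=-np.inf) >= 11.1
        )
        keep_ids = set(baseline["participant"].to_numpy()[~prevalent])
        provenance["n_prevalent_excluded"] = int(prevalent.sum())
        table = CohortTable(
            frame=table.frame[table.frame["participant"].isin(keep_ids)],
            spec=spec,
        )
    else:
        provenance["n_prevalent_excluded"] = 0

    table = impose_missingness(table, missingness, rng_miss)
    provenance["missingness"] = table.missingness_report
    table, n_dropped = table.drop_empty_participants()
    provenance["n_dropped_no_data"] = n_dropped
    provenance["n_final"] = len(table)
    return table, provenance
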