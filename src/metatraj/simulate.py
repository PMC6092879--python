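"""Forward microsimulation of metabolic risk factor trajectories.

Given a parameter set and a table of baseline characteristics, draws
person-level growth factors, per-phase latent-glycaemia disturbances and
measurement residuals, and emits the full measure-by-phase observation matrix.
The default design generates 100 replicate trajectory sets conditional on the
same baseline table, mirroring a cohort-validation simulation.

Clinical-alert censoring reproduces the study-protocol artefact that a
participant whose test result crossed a general-practitioner alert threshold
may change behaviour or treatment afterwards: observations at phases after
the first alerting phase are removed (the alerting observation itself was
recorded before any intervention and is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    FACTORS,
    GLYCAEMIC_INDICATORS,
    MEASURES,
    ModelSpec,
    ParameterSet,
    build_index_map,
    default_spec,
    moment_maps,
)

__all__ = [
    "AlertThresholds",
    "TrajectorySet",
    "DEFAULT_N_REPLICATES",
    "draw_growth_factors",
    "simulate_trajectories",
    "apply_alert_censoring",
]

#: replicate trajectory sets generated by default in the validation design
DEFAULT_N_REPLICATES = 100

BASELINE_COLUMNS = ("participant", "age_base", "sex", "ethnicity", "smoking",
                    "fh_diabetes", "fh_cvd")


@dataclass(frozen=True)
class AlertThresholds:
    """Per-measure clinical alert cut-offs; ``None`` disables a measure.

    Defaults are conventional referral levels: FPG >= 7.0 mmol/L,
    2-h glucose >= 11.1 mmol/L, SBP >= 160 mmHg, TC >= 7.8 mmol/L.
    """

    fpg: Optional[float] = 7.0
    glu2h: Optional[float] = 11.1
    sbp: Optional[float] = 160.0
    tc: Optional[float] = 7.8

    def __post_init__(self):
        for m in ("fpg", "glu2h", "sbp", "tc"):
            v = getattr(self, m)
            if v is not None and v <= 0:
                raise ValueError(f"alert threshold for {m} must be positive")

    @classmethod
    def none(cls) -> "AlertThresholds":
        return cls(fpg=None, glu2h=None, sbp=None, tc=None)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in ("fpg", "glu2h", "sbp", "tc")}


@dataclass
class TrajectorySet:
    """One replicate of simulated trajectories for a baseline table.

    ``values`` is participants x positions (index-map order); censored
    positions hold NaN and are flagged in ``censored``.
    """

    replicate: int
    participants: np.ndarray
    factors: np.ndarray          # (n, 12), order per FACTORS
    values: np.ndarray           # (n, p)
    censored: np.ndarray         # (n, p) bool
    seed: int
    spec: ModelSpec = field(repr=False, default_factory=default_spec)

    def to_frame(self) -> pd.DataFrame:
        """Long format: participant, phase, measure, value, censored."""
        imap = build_index_map(self.spec)
        rows = []
        for pos, (m, t) in enumerate(imap.positions):
            rows.append(pd.DataFrame({
                "participant": self.participants,
                "phase": t + 1,
                "measure": m,
                "value": self.values[:, pos],
                "censored": self.censored[:, pos],
            }))
        out = pd.concat(rows, ignore_index=True)
        out.insert(0, "replicate", self.replicate)
        return out.sort_values(["participant", "phase", "measure"], kind="stable").reset_index(drop=True)


def _covariate_matrix(baseline: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    cols = []
    for c in spec.covariates:
        if c == "age_base_c":
            cols.append(np.asarray(baseline["age_base"], float) - spec.age_center)
        elif c in baseline.columns:
            cols.append(np.asarray(baseline[c], float))
        else:
            raise KeyError(f"baseline table lacks covariate column {c!r}")
    extra = set(baseline.columns) - set(BASELINE_COLUMNS)
    if extra:
        raise ValueError(f"unknown baseline columns: {sorted(extra)}")
    return np.column_stack(cols) if cols else np.zeros((len(baseline), 0))


def _factor_transform(params: ParameterSet):
    Bt = np.zeros((9, 3))
    Bt[:, :2] = params.B
    T = np.eye(12)
    T[3:, :3] = Bt
    A0 = np.concatenate([params.alpha_b, params.alpha_f + Bt @ params.alpha_b])
    Aw = np.concatenate([params.Gamma_b, Bt @ params.Gamma_b + params.Gamma_f])
    return T, A0, Aw


def draw_growth_factors(params: ParameterSet, covariate_profiles, rng) -> np.ndarray:
    """Draw the 12 growth factors for each covariate profile row.

    Random effects ``u ~ N(0, Psi_b)`` and disturbances
    ``zeta ~ N(0, Psi_zeta)`` propagate through the structural paths, so the
    joint draw is multivariate normal with exactly the path-implied
    covariance used by the moment computation.
    """
    W = np.atleast_2d(np.asarray(covariate_profiles, float))
    n = W.shape[0]
    T, A0, Aw = _factor_transform(params)
    mean = A0[None, :] + W @ Aw.T
    Lb = np.zeros((3, 3))
    if np.any(params.Psi_b):
        try:
            Lb = np.linalg.cholesky(params.Psi_b)
        except np.linalg.LinAlgError:   # semi-definite (e.g. fixed b2)
            w, V = np.linalg.eigh(params.Psi_b)
            Lb = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    Lz = np.linalg.cholesky(params.Psi_zeta) if np.any(params.Psi_zeta) else np.zeros((9, 9))
    u = rng.standard_normal((n, 3)) @ Lb.T
    z = rng.standard_normal((n, 9)) @ Lz.T
    return mean + np.column_stack([u, z]) @ T.T


def _deterministic_mean_parts(params: ParameterSet, spec: ModelSpec):
    """Split the mean maps into the factor part and the deterministic
    (intercept/covariate) part so simulated draws stay moment-consistent."""
    M0, Mw, _ = moment_maps(params, spec)
    # subtract the factor-driven component: Lam @ A0 and Lam @ Aw
    imap = build_index_map(spec)
    T, A0, Aw = _factor_transform(params)
    Lam, Ld = _loadings(params, spec, imap)
    d0 = M0 - Lam @ A0
    dW = Mw - Lam @ Aw
    return Lam, Ld, d0, dW


def _loadings(params: ParameterSet, spec: ModelSpec, imap):
    s = np.asarray(spec.phase_times, float)
    p = len(imap)
    Lam = np.zeros((p, 12))
    Ld = np.zeros((p, spec.n_phases))
    glyc = {m: i for i, m in enumerate(GLYCAEMIC_INDICATORS)}
    basis = {
        "bmi": (0, 1, 2), "glycaemia": (3, 4, 5),
        "sbp": (6, 7), "tc": (8, 9), "hdl": (10, 11),
    }
    for r, (m, t) in enumerate(imap.positions):
        if m in glyc:
            lam = params.lam[glyc[m]]
            for k, j in enumerate(basis["glycaemia"]):
                Lam[r, j] = lam * s[t] ** k
            Ld[r, t] = lam
        else:
            for k, j in enumerate(basis[m]):
                Lam[r, j] = s[t] ** k
    return Lam, Ld


def simulate_trajectories(
    params: ParameterSet,
    baseline_table: pd.DataFrame,
    spec: Optional[ModelSpec] = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
    rng=None,
    seed: Optional[int] = None,
) -> list[TrajectorySet]:
    """Generate replicate trajectory sets conditional on baseline covariates.

    Each replicate uses an independent random stream derived from
    ``(seed, replicate)`` so any replicate is reproducible in isolation.
    """
    spec = spec or default_spec()
    params.validate(spec, require_pd=False)
    if seed is None:
        seed = int(rng.integers(2**31)) if rng is not None else 0
    W = _covariate_matrix(baseline_table, spec)
    n = W.shape[0]
    imap = build_index_map(spec)
    p = len(imap)
    Lam, Ld, d0, dW = _deterministic_mean_parts(params, spec)
    measure_idx = {m: i for i, m in enumerate(MEASURES)}
    th = np.array([params.theta[measure_idx[m]] for m, _ in imap.positions])
    out = []
    for rep in range(n_replicates):
        r = np.random.default_rng([seed, rep])
        F = draw_growth_factors(params, W, r)
        delta = r.standard_normal((n, spec.n_phases)) * np.sqrt(params.omega)
        eps = r.standard_normal((n, p)) * np.sqrt(th)
        Y = F @ Lam.T + delta @ Ld.T + d0[None, :] + (W @ dW.T if W.size else 0.0) + eps
        out.append(TrajectorySet(
            replicate=rep,
            participants=np.asarray(baseline_table["participant"]),
            factors=F,
            values=Y,
            censored=np.zeros((n, p), dtype=bool),
            seed=seed,
            spec=spec,
        ))
    return out


def apply_alert_censoring(traj: TrajectorySet, thresholds: AlertThresholds) -> TrajectorySet:
    """Censor observations after the first clinical-alert phase.

    For each participant, the earliest phase at which any thresholded measure
    meets or exceeds its cut-off is found; every observation at a strictly
    later phase is removed.  The alerting observation itself is retained.
    Idempotent, and monotone in the thresholds (lower cut-offs censor a
    superset of positions).
    """
    spec = traj.spec
    imap = build_index_map(spec)
    n, p = traj.values.shape
    alert_phase = np.full(n, spec.n_phases, dtype=int)  # n_phases = never
    for pos, (m, t) in enumerate(imap.positions):
        cut = getattr(thresholds, m, None) if m in ("fpg", "glu2h", "sbp", "tc") else None
        if cut is None:
            continue
        vals = traj.values[:, pos]
        hit = np.isfinite(vals) & (vals >= cut)
        alert_phase = np.where(hit & (t < alert_phase), t, alert_phase)
    censored = traj.censored.copy()
    values = traj.values.copy()
    for pos, (m, t) in enumerate(imap.positions):
        drop = t > alert_phase
        censored[:, pos] |= drop
        values[drop, pos] = np.nan
    return TrajectorySet(
        replicate=traj.replicate,
        participants=traj.participants,
        factors=traj.factors,
        values=values,
        censored=censored,
        seed=traj.seed,
        spec=spec,
    )
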