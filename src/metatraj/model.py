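"""Joint second-order latent growth curve model for metabolic risk factors.

The model describes seven metabolic measures observed at four clinical phases:
body mass index (BMI, kg/m^2), fasting plasma glucose (FPG, mmol/L), 2-h
post-load glucose (mmol/L), HbA1c (%), systolic blood pressure (SBP, mmHg),
total cholesterol (TC, mmol/L) and HDL cholesterol (mmol/L).

Each measure follows a polynomial growth curve with person-level random growth
factors.  BMI and glycaemia are quadratic; SBP, TC and HDL are linear.
Glycaemia is a first-order latent construct measured by FPG (reference
indicator, loading 1, intercept 0), 2-h glucose and HbA1c; HbA1c is observed
only at the last two phases.  The BMI intercept and slope act as exogenous
growth factors with structural regressions onto the growth factors of the
other measures; disturbances of the endogenous growth factors are freely
correlated.  Baseline covariates (sex, ethnicity, smoking, family histories,
centred baseline age) shift the growth-factor means, and the three glycaemic
indicators carry additional observation-level covariate adjustments
(age at phase, sex, ethnicity, family history of diabetes).

Because every equation is linear-Gaussian, the implied distribution of the
26 observed variables is multivariate normal with a mean that is affine in the
covariate profile and a covariance shared by all individuals; this module
computes those implied moments in closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MEASURES",
    "GLYCAEMIC_INDICATORS",
    "FACTORS",
    "ModelSpec",
    "ParameterSet",
    "IndexMap",
    "MomentStructure",
    "ParameterError",
    "build_index_map",
    "implied_moments",
    "moment_maps",
    "pack_parameters",
    "unpack_parameters",
    "n_free_parameters",
    "free_parameter_names",
    "default_spec",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

MEASURES = ("bmi", "fpg", "glu2h", "hba1c", "sbp", "tc", "hdl")
GLYCAEMIC_INDICATORS = ("fpg", "glu2h", "hba1c")
#: growth factors: BMI (b0,b1,b2) exogenous; glycaemia (g0,g1,g2), SBP (p0,p1),
#: TC (c0,c1), HDL (h0,h1) endogenous.
FACTORS = ("b0", "b1", "b2", "g0", "g1", "g2", "p0", "p1", "c0", "c1", "h0", "h1")
ENDOGENOUS_FACTORS = FACTORS[3:]

DEFAULT_COVARIATES = ("sex", "ethnicity", "smoking", "fh_diabetes", "fh_cvd", "age_base_c")
DEFAULT_INDICATOR_COVARIATES = ("age_at_phase", "sex", "ethnicity", "fh_diabetes")

# Structural path matrix pattern: endogenous factor <- (b0, b1).  True = free.
# The BMI quadratic term and the glycaemia quadratic term carry no structural
# paths, and HDL-slope <- BMI-slope is a structural zero (not identifiable).
B_FREE = np.array(
    [
        [True, False],   # g0 <- b0
        [True, True],    # g1 <- b0, b1
        [False, False],  # g2
        [True, False],   # p0 <- b0
        [True, True],    # p1 <- b0, b1
        [True, False],   # c0 <- b0
        [True, True],    # c1 <- b0, b1
        [True, False],   # h0 <- b0
        [True, False],   # h1 <- b0 only; h1 <- b1 structurally zero
    ]
)


class ParameterError(ValueError):
    """Raised when a parameter set violates model constraints."""


def gamma_f_free_mask(spec: "ModelSpec") -> np.ndarray:
    """Free-entry mask for the covariate effects on endogenous factors.

    A covariate that already adjusts the glycaemic indicators (kappa) cannot
    also shift the glycaemia *intercept* factor: the two parameterizations
    produce identical means (the indicator loadings absorb the trade-off, and
    for age the slope intercept absorbs the drift), so those entries of the
    g0 row are structural zeros.  Slope/quadratic rows remain free — a
    time-constant indicator adjustment cannot mimic a growth-rate effect.
    """
    q = spec.n_covariates
    mask = np.ones((9, q), dtype=bool)
    blocked = set(spec.indicator_covariates)
    if "age_at_phase" in blocked:
        blocked.add("age_base_c")
    for j, c in enumerate(spec.covariates):
        if c in blocked:
            mask[0, j] = False   # g0 row
    return mask


def _default_availability() -> dict:
    avail = {m: (True, True, True, True) for m in MEASURES}
    avail["hba1c"] = (False, False, True, True)
    return avail


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of the joint growth model.

    Parameters
    ----------
    phase_times
        Time scores ``s_t`` for the clinical phases, in decades of follow-up
        by default (0, 0.6, 1.1, 1.6 for visits at 0/6/11/16 years).  Decades
        keep the quadratic terms numerically well scaled.
    time_scale_years
        Years per unit of ``phase_times`` (10 for decade coding); used to
        derive elapsed years and age at phase.
    availability
        Measure -> per-phase observation flags.  The default observes HbA1c
        only at the last two phases.
    covariates
        Baseline covariates shifting growth-factor means; 0/1 indicators plus
        centred baseline age in years.
    indicator_covariates
        Observation-level covariates on the glycaemic indicators.
        ``age_at_phase`` is time-varying: centred baseline age + elapsed years.
    age_center
        Baseline age (years) subtracted before use as a covariate.
    b2_random
        Whether the BMI quadratic factor has between-person variance.
    """

    phase_times: tuple = (0.0, 0.6, 1.1, 1.6)
    time_scale_years: float = 10.0
    availability: Mapping[str, Sequence[bool]] = field(default_factory=_default_availability)
    covariates: tuple = DEFAULT_COVARIATES
    indicator_covariates: tuple = DEFAULT_INDICATOR_COVARIATES
    age_center: float = 50.0
    b2_random: bool = True

    def __post_init__(self):
        t = np.asarray(self.phase_times, dtype=float)
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("phase_times must start at 0 and be strictly increasing")
        for m in MEASURES:
            if m not in self.availability:
                raise ValueError(f"availability missing measure {m!r}")
            if len(self.availability[m]) != len(t):
                raise ValueError(f"availability for {m!r} must have one flag per phase")

    @property
    def n_phases(self) -> int:
        return len(self.phase_times)

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    @property
    def elapsed_years(self) -> np.ndarray:
        return np.asarray(self.phase_times, float) * self.time_scale_years

    def growth_order(self, measure: str) -> int:
        if measure in ("bmi", "glycaemia"):
            return 2
        if measure in ("sbp", "tc", "hdl"):
            return 1
        raise KeyError(measure)


def default_spec() -> ModelSpec:
    return ModelSpec()


class IndexMap:
    """Bijection between available (measure, phase) pairs and vector positions.

    Ordering is measure-major (in ``MEASURES`` order), phase-minor, so the
    default layout is BMI at phases 1-4, FPG 1-4, 2-h glucose 1-4, HbA1c 3-4,
    SBP 1-4, TC 1-4, HDL 1-4 (phases are 1-based in labels, 0-based in code).
    """

    def __init__(self, spec: ModelSpec):
        self.positions: list[tuple[str, int]] = []
        self._lookup: dict[tuple[str, int], int] = {}
        for m in MEASURES:
            for t in range(spec.n_phases):
                if spec.availability[m][t]:
                    self._lookup[(m, t)] = len(self.positions)
                    self.positions.append((m, t))

    def __len__(self) -> int:
        return len(self.positions)

    def index(self, measure: str, phase: int) -> int:
        try:
            return self._lookup[(measure, phase)]
        except KeyError:
            raise KeyError(
                f"({measure!r}, phase {phase + 1}) is not an available observation"
            ) from None

    def __contains__(self, key) -> bool:
        return key in self._lookup

    def labels(self) -> list[str]:
        return [f"{m}_p{t + 1}" for m, t in self.positions]


def build_index_map(spec: ModelSpec) -> IndexMap:
    """Deterministic measure-major, phase-minor position map (26 by default)."""
    return IndexMap(spec)


@dataclass
class ParameterSet:
    """All parameters of the joint model (free and fixed).

    Shapes (q = number of baseline covariates):

    - ``alpha_b`` (3,): means of the BMI growth factors.
    - ``Gamma_b`` (3, q): covariate effects on BMI factors.
    - ``Psi_b`` (3, 3): BMI random-effect covariance.
    - ``B`` (9, 2): structural paths endogenous-factor <- (b0, b1); entries
      outside ``B_FREE`` are structurally zero.
    - ``alpha_f`` (9,): intercepts of the endogenous growth factors.
    - ``Gamma_f`` (9, q): covariate effects on endogenous factors.
    - ``Psi_zeta`` (9, 9): disturbance covariance of endogenous factors.
    - ``omega`` (): variance of the per-phase latent-glycaemia disturbance.
    - ``lam`` (3,): glycaemic indicator loadings (FPG fixed to 1).
    - ``nu`` (3,): glycaemic indicator intercepts (FPG fixed to 0).
    - ``kappa`` (3, 4): indicator-level covariate coefficients, rows FPG /
      2-h glucose / HbA1c, columns per ``spec.indicator_covariates``.
    - ``theta`` (7,): time-constant residual variances, one per measure.
    """

    alpha_b: np.ndarray
    Gamma_b: np.ndarray
    Psi_b: np.ndarray
    B: np.ndarray
    alpha_f: np.ndarray
    Gamma_f: np.ndarray
    Psi_zeta: np.ndarray
    omega: float
    lam: np.ndarray
    nu: np.ndarray
    kappa: np.ndarray
    theta: np.ndarray

    def copy(self) -> "ParameterSet":
        return ParameterSet(**{k: np.array(getattr(self, k), copy=True) if isinstance(getattr(self, k), np.ndarray) else getattr(self, k) for k in self.__dataclass_fields__})

    def validate(self, spec: ModelSpec, require_pd: bool = True) -> None:
        """Check shapes, fixed-value and positivity constraints.

        ``require_pd=False`` (used when only simulating, never inverting)
        relaxes strict positive definiteness to positive semi-definiteness
        and allows zero residual variances, so noiseless degenerate
        configurations are expressible.
        """
        q = spec.n_covariates
        if self.alpha_b.shape != (3,) or self.alpha_f.shape != (9,):
            raise ParameterError("growth-factor mean vectors have wrong shape")
        if self.Gamma_b.shape != (3, q) or self.Gamma_f.shape != (9, q):
            raise ParameterError("covariate coefficient matrices have wrong shape")
        if self.B.shape != (9, 2):
            raise ParameterError("B must be 9x2")
        if np.any(self.B[~B_FREE] != 0.0):
            raise ParameterError("structurally zero entries of B must be 0")
        gmask = gamma_f_free_mask(spec)
        if np.any(self.Gamma_f[~gmask] != 0.0):
            raise ParameterError(
                "covariates with indicator-level adjustments cannot also load "
                "on the glycaemia intercept factor (structural zeros in Gamma_f)"
            )
        if self.lam[0] != 1.0 or self.nu[0] != 0.0:
            raise ParameterError("FPG is the reference indicator: lambda=1, nu=0")
        if require_pd:
            if np.any(np.asarray(self.theta) <= 0) or self.omega <= 0:
                raise ParameterError("residual variances theta and omega must be positive")
        elif np.any(np.asarray(self.theta) < 0) or self.omega < 0:
            raise ParameterError("residual variances theta and omega must be non-negative")
        for name, P in (("Psi_b", self.Psi_b), ("Psi_zeta", self.Psi_zeta)):
            P = np.asarray(P, float)
            if not np.allclose(P, P.T):
                raise ParameterError(f"{name} must be symmetric")
            if name == "Psi_b" and not spec.b2_random:
                P = P[:2, :2]
            if require_pd:
                try:
                    np.linalg.cholesky(P)
                except np.linalg.LinAlgError:
                    raise ParameterError(f"{name} is not positive definite") from None
            elif np.linalg.eigvalsh(P).min() < -1e-10:
                raise ParameterError(f"{name} is not positive semi-definite")


@dataclass
class MomentStructure:
    """Model-implied moments of the observed vector for one covariate profile.

    ``Sigma`` is shared by all individuals; ``mu`` is affine in the profile.
    """

    index_map: IndexMap
    mu: np.ndarray
    Sigma: np.ndarray


def _btilde(B):
    """9x3 structural matrix: B padded with a zero column for b2."""
    Bt = np.zeros((9, 3), dtype=B.dtype)
    Bt[:, :2] = B
    return Bt


def _growth_design(spec: ModelSpec, dtype=float) -> dict:
    """Per-measure loading rows onto the factor vector, per phase."""
    s = np.asarray(spec.phase_times, dtype=dtype)
    cols = {"bmi": (0, 1, 2), "glycaemia": (3, 4, 5), "sbp": (6, 7), "tc": (8, 9), "hdl": (10, 11)}
    basis = {}
    for name, idx in cols.items():
        rows = np.zeros((spec.n_phases, 12), dtype=dtype)
        for k, j in enumerate(idx):
            rows[:, j] = s**k
        basis[name] = rows
    return basis


def moment_maps(params: ParameterSet, spec: ModelSpec):
    """Closed-form moment structure of the observed vector.

    Returns ``(M0, Mw, Sigma)`` with individual mean ``mu_i = M0 + Mw @ w_i``,
    where ``w_i`` is the baseline covariate vector in ``spec.covariates``
    order, and ``Sigma`` the (covariate-independent) covariance.

    Derivation: stacking the twelve growth factors as ``eta = (b, f)`` with
    ``b = alpha_b + Gamma_b w + u`` and
    ``f = alpha_f + B (b0, b1) + Gamma_f w + zeta`` gives
    ``eta = T (A0 + Aw w + e)`` in reduced form with
    ``T = [[I, 0], [Btilde, I]]``, so ``cov(eta) = T diag(Psi_b, Psi_zeta) T'``.
    Observations load on ``eta`` through the polynomial time basis and the
    indicator loadings; the latent glycaemia disturbance ``delta_t`` adds
    ``lam_j lam_k omega`` within each phase across glycaemic indicators.
    """
    dtype = np.result_type(params.alpha_b, params.B, params.lam, params.theta, float)
    imap = build_index_map(spec)
    p = len(imap)
    q = spec.n_covariates
    nT = spec.n_phases

    Bt = _btilde(np.asarray(params.B, dtype=dtype))
    A0 = np.concatenate([params.alpha_b, params.alpha_f + Bt @ params.alpha_b]).astype(dtype)
    Aw = np.concatenate([params.Gamma_b, Bt @ params.Gamma_b + params.Gamma_f]).astype(dtype)

    T = np.eye(12, dtype=dtype)
    T[3:, :3] = Bt
    Psi = np.zeros((12, 12), dtype=dtype)
    Psi[:3, :3] = params.Psi_b
    Psi[3:, 3:] = params.Psi_zeta
    Phi = T @ Psi @ T.T

    basis = _growth_design(spec, dtype)
    measure_idx = {m: i for i, m in enumerate(MEASURES)}
    glyc_idx = {m: i for i, m in enumerate(GLYCAEMIC_INDICATORS)}

    Lam = np.zeros((p, 12), dtype=dtype)       # loadings onto growth factors
    Ld = np.zeros((p, nT), dtype=dtype)        # loadings onto delta_t
    d0 = np.zeros(p, dtype=dtype)              # deterministic mean offsets
    dW = np.zeros((p, q), dtype=dtype)         # deterministic covariate slopes
    th = np.zeros(p, dtype=dtype)

    elapsed = spec.elapsed_years
    cov_pos = {c: j for j, c in enumerate(spec.covariates)}
    for r, (m, t) in enumerate(imap.positions):
        th[r] = params.theta[measure_idx[m]]
        if m in glyc_idx:
            j = glyc_idx[m]
            Lam[r] = params.lam[j] * basis["glycaemia"][t]
            Ld[r, t] = params.lam[j]
            d0[r] = params.nu[j]
            for c_i, cname in enumerate(spec.indicator_covariates):
                k = params.kappa[j, c_i]
                if cname == "age_at_phase":
                    # centred baseline age + elapsed years: the elapsed part is
                    # a constant per phase, the rest rides on the age covariate
                    d0[r] = d0[r] + k * elapsed[t]
                    if "age_base_c" in cov_pos:
                        dW[r, cov_pos["age_base_c"]] += k
                elif cname in cov_pos:
                    dW[r, cov_pos[cname]] += k
        else:
            Lam[r] = basis[m][t]

    M0 = Lam @ A0 + d0
    Mw = Lam @ Aw + dW
    Sigma = Lam @ Phi @ Lam.T + params.omega * (Ld @ Ld.T) + np.diag(th)
    return M0, Mw, Sigma


def implied_moments(params: ParameterSet, covariate_profile, spec: ModelSpec) -> MomentStructure:
    """Exact mean and covariance of the observed vector for one profile."""
    params.validate(spec)
    w = np.asarray(covariate_profile, dtype=float)
    if w.shape != (spec.n_covariates,):
        raise ValueError(
            f"covariate profile must have length {spec.n_covariates} "
            f"(order {spec.covariates})"
        )
    M0, Mw, Sigma = moment_maps(params, spec)
    return MomentStructure(build_index_map(spec), M0 + Mw @ w, Sigma)


# ---------------------------------------------------------------------------
# packing: free parameters <-> unconstrained vector
# ---------------------------------------------------------------------------

def _chol_pack(P: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, row-wise, with log-transformed diagonal."""
    L = np.linalg.cholesky(P)
    out = []
    for i in range(P.shape[0]):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def _chol_unpack(v, k, dtype):
    L = np.zeros((k, k), dtype=dtype)
    pos = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(v[pos]) if i == j else v[pos]
            pos += 1
    return L @ L.T


def _psi_b_dim(spec: ModelSpec) -> int:
    return 3 if spec.b2_random else 2


def _layout(spec: ModelSpec):
    """(name, size) blocks of the free-parameter vector, in order."""
    q = spec.n_covariates
    kb = _psi_b_dim(spec)
    return [
        ("alpha_b", 3),
        ("Gamma_b", 3 * q),
        ("Psi_b", kb * (kb + 1) // 2),
        ("B", int(B_FREE.sum())),
        ("alpha_f", 9),
        ("Gamma_f", int(gamma_f_free_mask(spec).sum())),
        ("Psi_zeta", 45),
        ("omega", 1),
        ("lam", 2),
        ("nu", 2),
        ("kappa", 3 * len(spec.indicator_covariates)),
        ("theta", 7),
    ]


def n_free_parameters(spec: ModelSpec) -> int:
    return sum(size for _, size in _layout(spec))


def pack_parameters(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Map a valid ParameterSet to the unconstrained free-parameter vector.

    Fixed parameters (lambda_FPG, nu_FPG, structural zeros of B) are excluded;
    covariance blocks use log-diagonal Cholesky factors and variance scalars
    use logs, so every real vector unpacks to a valid ParameterSet.
    """
    params.validate(spec)
    kb = _psi_b_dim(spec)
    parts = [
        np.asarray(params.alpha_b, float),
        np.asarray(params.Gamma_b, float).ravel(),
        _chol_pack(np.asarray(params.Psi_b, float)[:kb, :kb]),
        np.asarray(params.B, float)[B_FREE],
        np.asarray(params.alpha_f, float),
        np.asarray(params.Gamma_f, float)[gamma_f_free_mask(spec)],
        _chol_pack(np.asarray(params.Psi_zeta, float)),
        np.array([np.log(params.omega)]),
        np.asarray(params.lam, float)[1:],
        np.asarray(params.nu, float)[1:],
        np.asarray(params.kappa, float).ravel(),
        np.log(np.asarray(params.theta, float)),
    ]
    return np.concatenate(parts)


def unpack_parameters(vector, spec: ModelSpec) -> ParameterSet:
    """Inverse of :func:`pack_parameters`; accepts complex input for
    complex-step differentiation of the moment maps."""
    v = np.asarray(vector)
    dtype = v.dtype if np.iscomplexobj(v) else float
    expected = n_free_parameters(spec)
    if v.shape != (expected,):
        raise ValueError(f"expected free-parameter vector of length {expected}, got {v.shape}")
    q = spec.n_covariates
    kb = _psi_b_dim(spec)
    out = {}
    pos = 0
    for name, size in _layout(spec):
        block = v[pos : pos + size]
        pos += size
        if name == "alpha_b":
            out["alpha_b"] = block.astype(dtype)
        elif name == "Gamma_b":
            out["Gamma_b"] = block.reshape(3, q).astype(dtype)
        elif name == "Psi_b":
            P = np.zeros((3, 3), dtype=dtype)
            P[:kb, :kb] = _chol_unpack(block, kb, dtype)
            out["Psi_b"] = P
        elif name == "B":
            B = np.zeros((9, 2), dtype=dtype)
            B[B_FREE] = block
            out["B"] = B
        elif name == "alpha_f":
            out["alpha_f"] = block.astype(dtype)
        elif name == "Gamma_f":
            G = np.zeros((9, q), dtype=dtype)
            G[gamma_f_free_mask(spec)] = block
            out["Gamma_f"] = G
        elif name == "Psi_zeta":
            out["Psi_zeta"] = _chol_unpack(block, 9, dtype)
        elif name == "omega":
            out["omega"] = np.exp(block[0])
        elif name == "lam":
            out["lam"] = np.concatenate([np.ones(1, dtype=dtype), block])
        elif name == "nu":
            out["nu"] = np.concatenate([np.zeros(1, dtype=dtype), block])
        elif name == "kappa":
            out["kappa"] = block.reshape(3, len(spec.indicator_covariates)).astype(dtype)
        elif name == "theta":
            out["theta"] = np.exp(block)
    return ParameterSet(**out)


def free_parameter_names(spec: ModelSpec) -> list[str]:
    """Human-readable name per entry of the packed vector."""
    q = list(spec.covariates)
    kb = _psi_b_dim(spec)
    bmi_f = ["b0", "b1", "b2"]
    names: list[str] = []
    names += [f"alpha_b[{f}]" for f in bmi_f]
    names += [f"Gamma_b[{f},{c}]" for f in bmi_f for c in q]
    names += [f"cholPsi_b[{i},{j}]" for i in range(kb) for j in range(i + 1)]
    names += [
        f"B[{ENDOGENOUS_FACTORS[i]}<-{bmi_f[j]}]"
        for i in range(9)
        for j in range(2)
        if B_FREE[i, j]
    ]
    names += [f"alpha_f[{f}]" for f in ENDOGENOUS_FACTORS]
    gmask = gamma_f_free_mask(spec)
    names += [
        f"Gamma_f[{ENDOGENOUS_FACTORS[i]},{q[j]}]"
        for i in range(9)
        for j in range(len(q))
        if gmask[i, j]
    ]
    names += [f"cholPsi_zeta[{i},{j}]" for i in range(9) for j in range(i + 1)]
    names += ["log_omega"]
    names += ["lam[glu2h]", "lam[hba1c]", "nu[glu2h]", "nu[hba1c]"]
    names += [
        f"kappa[{ind},{c}]"
        for ind in GLYCAEMIC_INDICATORS
        for c in spec.indicator_covariates
    ]
    names += [f"log_theta[{m}]" for m in MEASURES]
    assert len(names) == n_free_parameters(spec)
    return names


# ---------------------------------------------------------------------------
# JSON parameter files
# ---------------------------------------------------------------------------

def save_parameters(params: ParameterSet, path) -> None:
    doc = {
        k: (np.asarray(getattr(params, k)).tolist() if k != "omega" else float(params.omega))
        for k in params.__dataclass_fields__
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _params_from_doc(doc: Mapping) -> ParameterSet:
    kw = {}
    for k in ParameterSet.__dataclass_fields__:
        val = doc[k]
        kw[k] = float(val) if k == "omega" else np.asarray(val, dtype=float)
    return ParameterSet(**kw)


def load_parameters(path) -> ParameterSet:
    with open(path) as fh:
        return _params_from_doc(json.load(fh))


def default_parameters() -> ParameterSet:
    """Packaged default parameter set.

    Structural paths (B) and glycaemic indicator covariate coefficients
    (kappa) are the published Whitehall II point estimates; the remaining
    entries (factor means, covariate effects, covariances, loadings, residual
    variances) are documented plausible values for a middle-aged occupational
    cohort, chosen to give realistic marginal distributions.
    """
    with resources.files("metatraj.data").joinpath("default_params.json").open() as fh:
        return _params_from_doc(json.load(fh))
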