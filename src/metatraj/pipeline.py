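"""End-to-end pipeline runner: synth -> fit -> simulate -> validate.

Every artifact is stamped with the configuration hash, the seed and the
package version so any output can be regenerated exactly.  All randomness
flows from the configured seed; no stage consults wall-clock or environment
entropy.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional


from . import __version__
from .cohort import DemographicsConfig, MissingnessConfig, generate_cohort
from .estimation import FitOptions, fit
from .io import CohortTable, read_cohort, write_cohort
from .model import default_parameters, default_spec, load_parameters, save_parameters
from .risk import compare_moments, packaged_score, risk_score_comparison
from .simulate import AlertThresholds, simulate_trajectories

__all__ = ["ConfigError", "run_pipeline"]

log = logging.getLogger("metatraj")

STAGES = ("synth", "fit", "simulate", "validate")


class ConfigError(ValueError):
    pass


def _config_hash(config: dict) -> str:
    # the output location is not part of the scientific configuration
    doc = {k: v for k, v in config.items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _provenance(config: dict) -> dict:
    return {"config_hash": _config_hash(config), "seed": config.get("seed", 0),
            "package_version": __version__}


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in order; returns artifact paths.

    ``config`` keys: ``stages`` (subset of synth/fit/simulate/validate),
    ``seed``, ``out_dir``, ``n`` (cohort size), ``n_replicates``, ``params``
    (parameter JSON path, else packaged defaults), ``fit_options`` (dict),
    ``thresholds`` (dict or null to disable), ``scores`` (packaged score
    names).  Misconfiguration raises :class:`ConfigError` before any
    computation runs.
    """
    stages = list(config.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    out_dir = Path(config.get("out_dir", "."))
    seed = int(config.get("seed", 0))
    n = int(config.get("n", 500))
    n_rep = int(config.get("n_replicates", 5))

    # fail fast on inter-stage dependencies
    if "validate" in stages and "simulate" not in stages and not config.get("simulated_from"):
        raise ConfigError("validate requires the simulate stage (or 'simulated_from')")
    if ("fit" in stages or "simulate" in stages or "validate" in stages) and \
            "synth" not in stages and not config.get("cohort"):
        raise ConfigError("fit/simulate/validate require the synth stage or a 'cohort' path")

    out_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    params = load_parameters(config["params"]) if config.get("params") else default_parameters()
    spec = default_spec()
    artifacts: dict = {"provenance": prov}

    cohort: Optional[CohortTable] = None
    if "synth" in stages:
        t0 = time.perf_counter()
        thr_cfg = config.get("thresholds", "default")
        thresholds = (AlertThresholds() if thr_cfg == "default"
                      else AlertThresholds.none() if thr_cfg is None
                      else AlertThresholds(**thr_cfg))
        cohort, cohort_prov = generate_cohort(
            n, params, spec,
            demographics=DemographicsConfig(n=n),
            missingness=MissingnessConfig(**config["missingness"])
            if config.get("missingness") else MissingnessConfig(),
            thresholds=thresholds,
            seed=seed,
        )
        path = out_dir / "cohort.csv"
        write_cohort(cohort, path)
        cohort_prov.update(prov)
        (out_dir / "cohort_provenance.json").write_text(
            json.dumps(cohort_prov, indent=1, default=float) + "\n")
        log.info("synth: n_final=%d censored_positions=%d (%.1fs)",
                 cohort_prov["n_final"], cohort_prov["n_censored_positions"],
                 time.perf_counter() - t0)
        artifacts["cohort"] = str(path)
    elif config.get("cohort"):
        cohort = read_cohort(config["cohort"], spec)

    if "fit" in stages:
        t0 = time.perf_counter()
        opts = FitOptions(**config.get("fit_options", {}))
        result = fit(cohort, spec, init=params, options=opts)
        doc = {
            "loglik": result.loglik, "converged": result.converged,
            "n_iter": result.n_iter, "n_patterns": result.n_patterns,
            "n_obs": result.n_obs, "chi2": result.chi2, "df": result.df,
            "srmr": result.srmr, "cfi": result.cfi,
            "estimates": {nm: float(v) for nm, v in
                          zip(result.se_names, result.se_natural)},
            "se": ({nm: float(v) for nm, v in zip(result.se_names, result.se)}
                   if result.se is not None else None),
            **prov,
        }
        path = out_dir / "fit.json"
        path.write_text(json.dumps(doc, indent=1, default=float) + "\n")
        save_parameters(result.estimates, out_dir / "fitted_params.json")
        result.summary().to_csv(out_dir / "fit_table.csv", index=False)
        log.info("fit: loglik=%.2f converged=%s (%.1fs)", result.loglik,
                 result.converged, time.perf_counter() - t0)
        artifacts["fit"] = str(path)
        params = result.estimates   # downstream stages use the fitted model

    trajectories = None
    if "simulate" in stages:
        t0 = time.perf_counter()
        baseline = (
            cohort.frame.drop_duplicates("participant")
            .assign(age_base=lambda d: d["age_at_phase"] - d["elapsed_years"])
            [["participant", "age_base", "sex", "ethnicity", "smoking",
              "fh_diabetes", "fh_cvd"]]
            .reset_index(drop=True)
        )
        trajectories = simulate_trajectories(params, baseline, spec,
                                             n_replicates=n_rep, seed=seed + 1)
        sim_dir = out_dir / "trajectories"
        sim_dir.mkdir(exist_ok=True)
        for t in trajectories:
            t.to_frame().to_csv(sim_dir / f"replicate_{t.replicate:03d}.csv", index=False)
        log.info("simulate: %d replicates x %d participants (%.1fs)",
                 n_rep, len(baseline), time.perf_counter() - t0)
        artifacts["trajectories"] = str(sim_dir)

    if "validate" in stages:
        t0 = time.perf_counter()
        score_names = config.get(
            "scores", ["framingham_cvd_2008", "diabetes_fpg_synthetic"])
        defs = [packaged_score(s) for s in score_names]
        report = compare_moments(cohort, trajectories)
        report.risk = risk_score_comparison(cohort, trajectories, defs)
        path = out_dir / "validation.json"
        report.to_json(path)
        log.info("validate: %d moment rows, %d risk rows (%.1fs)",
                 len(report.moments), len(report.risk), time.perf_counter() - t0)
        artifacts["validation"] = str(path)

    return artifacts
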