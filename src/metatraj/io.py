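"""Cohort table container and delimited-text readers/writers.

The canonical on-disk format is a wide CSV with one row per participant-phase:
identifier and phase, elapsed years and age at phase, the five 0/1 baseline
covariates, and the seven metabolic measures (empty cell = missing).  Units
are fixed: BMI kg/m^2, glucose measures mmol/L, HbA1c %, SBP mmHg,
cholesterol mmol/L.  No unit auto-detection is attempted — callers must
supply data in these units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import MEASURES, ModelSpec, build_index_map, default_spec

__all__ = ["CohortTable", "COHORT_COLUMNS", "read_cohort", "write_cohort"]

COVARIATE_COLUMNS = ("sex", "ethnicity", "smoking", "fh_diabetes", "fh_cvd")
COHORT_COLUMNS = (
    ("participant", "phase", "elapsed_years", "age_at_phase")
    + COVARIATE_COLUMNS
    + MEASURES
)


class CohortError(ValueError):
    """Raised when a cohort table violates its invariants."""


@dataclass
class CohortTable:
    """Longitudinal participant-by-phase records with explicit missingness.

    Wraps a :class:`pandas.DataFrame` in the canonical wide layout.  The
    frame is validated on construction: (participant, phase) pairs unique,
    phases within 1..n_phases, covariates constant within participant, and
    measures absent where the model spec declares them unavailable.
    """

    frame: pd.DataFrame
    spec: ModelSpec = None

    def __post_init__(self):
        if self.spec is None:
            self.spec = default_spec()
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.frame
        missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortError(f"cohort table lacks columns {missing_cols}")
        if len(df) == 0:
            return
        dup = df.duplicated(subset=["participant", "phase"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            rec = df.iloc[row]
            raise CohortError(
                f"duplicate (participant, phase) = ({rec['participant']}, "
                f"{rec['phase']}) at row {row}"
            )
        phases = df["phase"].to_numpy()
        if phases.min() < 1 or phases.max() > self.spec.n_phases:
            bad = int(np.flatnonzero((phases < 1) | (phases > self.spec.n_phases))[0])
            raise CohortError(f"phase out of range 1..{self.spec.n_phases} at row {bad}")
        for c in COVARIATE_COLUMNS:
            nun = df.groupby("participant")[c].nunique(dropna=False)
            if (nun > 1).any():
                pid = nun.index[nun > 1][0]
                raise CohortError(f"covariate {c!r} varies within participant {pid}")
        for m in MEASURES:
            for t in range(self.spec.n_phases):
                if not self.spec.availability[m][t]:
                    vals = df.loc[df["phase"] == t + 1, m]
                    if vals.notna().any():
                        row = int(vals.notna().idxmax())
                        raise CohortError(
                            f"{m} recorded at phase {t + 1} (row {row}) but the "
                            "model spec marks it unavailable"
                        )

    # -- conversions --------------------------------------------------------
    @property
    def participants(self) -> np.ndarray:
        return self.frame["participant"].unique()

    def __len__(self) -> int:
        return len(self.participants)

    def to_matrices(self, spec: Optional[ModelSpec] = None):
        """Pivot to (Y, W): values matrix in index-map order (NaN = missing)
        and the baseline covariate matrix in ``spec.covariates`` order."""
        spec = spec or self.spec
        imap = build_index_map(spec)
        df = self.frame
        pids = df["participant"].unique()
        pid_row = {pid: i for i, pid in enumerate(pids)}
        n = len(pids)
        Y = np.full((n, len(imap)), np.nan)
        W = np.zeros((n, spec.n_covariates))
        first = df.drop_duplicates("participant").set_index("participant")
        for j, c in enumerate(spec.covariates):
            if c == "age_base_c":
                base_age = first["age_at_phase"] - first["elapsed_years"]
                W[:, j] = base_age.loc[pids].to_numpy() - spec.age_center
            else:
                W[:, j] = first[c].loc[pids].to_numpy()
        rows = df["participant"].map(pid_row).to_numpy()
        phase0 = df["phase"].to_numpy() - 1
        for m in MEASURES:
            vals = df[m].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            for t in range(spec.n_phases):
                if not spec.availability[m][t]:
                    continue
                pos = imap.index(m, t)
                sel = ok & (phase0 == t)
                Y[rows[sel], pos] = vals[sel]
        return Y, W

    @classmethod
    def from_matrices(cls, Y, W, spec: Optional[ModelSpec] = None,
                      participants=None) -> "CohortTable":
        """Inverse of :meth:`to_matrices` (age reconstructed from the centred
        baseline-age covariate when present)."""
        spec = spec or default_spec()
        imap = build_index_map(spec)
        Y = np.asarray(Y, float)
        W = np.asarray(W, float)
        n = Y.shape[0]
        if participants is None:
            participants = np.arange(1, n + 1)
        cov = {c: W[:, j] for j, c in enumerate(spec.covariates)}
        age_base = cov.get("age_base_c", np.zeros(n)) + spec.age_center
        records = []
        for t in range(spec.n_phases):
            rec = {
                "participant": participants,
                "phase": t + 1,
                "elapsed_years": spec.elapsed_years[t],
                "age_at_phase": age_base + spec.elapsed_years[t],
            }
            for c in COVARIATE_COLUMNS:
                rec[c] = cov.get(c, np.zeros(n)).astype(int)
            for m in MEASURES:
                rec[m] = (
                    Y[:, imap.index(m, t)]
                    if spec.availability[m][t]
                    else np.full(n, np.nan)
                )
            records.append(pd.DataFrame(rec))
        frame = (
            pd.concat(records, ignore_index=True)
            .sort_values(["participant", "phase"], kind="stable")
            .reset_index(drop=True)
        )
        return cls(frame=frame, spec=spec)

    def drop_empty_participants(self) -> tuple["CohortTable", int]:
        """Remove participants contributing no metabolic observation."""
        df = self.frame
        any_obs = df[list(MEASURES)].notna().any(axis=1)
        has_data = df.assign(_obs=any_obs).groupby("participant")["_obs"].transform("any")
        dropped = df.loc[~has_data, "participant"].nunique()
        out = CohortTable(frame=df[has_data].reset_index(drop=True), spec=self.spec)
        return out, int(dropped)


def read_cohort(path, spec: Optional[ModelSpec] = None) -> CohortTable:
    """Read a wide cohort CSV; empty cells are missing values.

    Invariant violations raise :class:`CohortError` with row-numbered
    messages.
    """
    spec = spec or default_spec()
    df = pd.read_csv(path, float_precision="round_trip")
    for c in COHORT_COLUMNS:
        if c not in df.columns:
            raise CohortError(f"cohort file {path} lacks column {c!r}")
        if c not in ("participant",):
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            if bad.any():
                raise CohortError(
                    f"non-numeric value in column {c!r} at row {int(bad.idxmax())}"
                )
            df[c] = pd.to_numeric(df[c], errors="coerce")
    df["phase"] = df["phase"].astype(int)
    for c in COVARIATE_COLUMNS:
        df[c] = df[c].astype(int)
    return CohortTable(frame=df[list(COHORT_COLUMNS)], spec=spec)


def write_cohort(table: CohortTable, path) -> None:
    """Write the canonical wide CSV (round-trip stable to the byte)."""
    df = table.frame[list(COHORT_COLUMNS)]
    df.to_csv(path, index=False, na_rep="")
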