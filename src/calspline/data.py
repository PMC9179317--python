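"""Pooled matched case-control dataset container.

A pooling project combines several matched (or nested) case-control
studies.  Each study is measured either at the common *reference
laboratory* (biomarker ``X`` observed for everyone) or at its own
*local laboratory* (biomarker ``W`` observed for everyone, ``X``
observed only for the controls re-assayed at the reference laboratory,
the *calibration subset*).  Matched sets ("strata") are the unit the
conditional likelihood conditions on; each must contain at least one
case and one control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["PooledDataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("study", "stratum", "case", "local_value")
OPTIONAL_COLUMNS = ("reference_value", "in_calibration")


@dataclass
class PooledDataset:
    """Subject-level pooled data, one row per subject.

    Parameters
    ----------
    table
        DataFrame with columns ``study``, ``stratum``, ``case`` (0/1),
        ``local_value`` (W), ``reference_value`` (X, NaN when not
        re-assayed), ``in_calibration`` (bool), plus covariate columns.
    covariates
        Names of the confounder columns Z included in the risk model.
    reference_studies
        Studies whose measurements are already on the reference scale
        (no calibration needed).  If None, a study is inferred to be a
        reference-laboratory study when every subject has a
        ``reference_value`` and no subject carries a calibration flag.
    """

    table: pd.DataFrame
    covariates: tuple[str, ...] = ()
    reference_studies: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        self.reference_studies = frozenset(self.reference_studies)
        self._validate()

    # ------------------------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        covariates=None,
        reference_studies=None,
    ) -> "PooledDataset":
        """Normalize a raw frame and build a validated dataset."""
        df = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        if "reference_value" not in df.columns:
            df["reference_value"] = np.nan
        if "in_calibration" not in df.columns:
            df["in_calibration"] = False
        df["local_value"] = pd.to_numeric(df["local_value"], errors="coerce")
        df["reference_value"] = pd.to_numeric(df["reference_value"], errors="coerce")
        case = pd.to_numeric(df["case"], errors="coerce")
        if not case.isin([0, 1]).all():
            bad = df.index[~case.isin([0, 1])].tolist()[:5]
            raise ValidationError(f"case column must be 0/1; offending rows: {bad}")
        df["case"] = case.astype(np.int8)
        df["in_calibration"] = (
            pd.to_numeric(df["in_calibration"], errors="coerce").fillna(0).astype(bool)
        )
        if covariates is None:
            known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
            covariates = tuple(c for c in df.columns if c not in known)
        for c in covariates:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        if reference_studies is None:
            ref = []
            for sid, grp in df.groupby("study", sort=False):
                if grp["reference_value"].notna().all() and not grp["in_calibration"].any():
                    ref.append(sid)
            reference_studies = frozenset(ref)
        return cls(df, tuple(covariates), frozenset(reference_studies))

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        df = self.table
        for col in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"missing column {col!r}")
        for c in self.covariates:
            if c not in df.columns:
                raise ValidationError(f"missing covariate column {c!r}")
            if not np.isfinite(df[c].to_numpy(dtype=float)).all():
                raise ValidationError(f"covariate {c!r} contains non-finite values")
        if not df["case"].isin([0, 1]).all():
            raise ValidationError("case column must be binary 0/1")
        unknown_ref = self.reference_studies - set(df["study"])
        if unknown_ref:
            raise ValidationError(f"reference_studies not in data: {sorted(unknown_ref)}")
        # stratum composition
        grp = df.groupby(["study", "stratum"], sort=False)["case"]
        n_cases = grp.sum()
        n_tot = grp.size()
        no_case = n_cases[n_cases == 0]
        if len(no_case):
            raise ValidationError(f"strata without a case: {no_case.index.tolist()[:5]}")
        no_ctrl = n_cases[n_cases == n_tot]
        if len(no_ctrl):
            raise ValidationError(f"strata without a control: {no_ctrl.index.tolist()[:5]}")
        # laboratory status
        for sid, g in df.groupby("study", sort=False):
            if sid in self.reference_studies:
                if g["reference_value"].isna().any():
                    raise ValidationError(
                        f"reference-laboratory study {sid!r} has missing reference_value"
                    )
            else:
                if g["local_value"].isna().any():
                    raise ValidationError(
                        f"local-laboratory study {sid!r} has missing local_value"
                    )
        flagged = df[df["in_calibration"]]
        if (flagged["case"] == 1).any():
            bad = flagged.index[flagged["case"] == 1].tolist()[:5]
            raise ValidationError(
                f"calibration subset must contain controls only; case rows: {bad}"
            )
        if flagged["reference_value"].isna().any() or flagged["local_value"].isna().any():
            raise ValidationError(
                "calibration-flagged subjects need both local and reference values"
            )

    # ------------------------------------------------------------------
    @property
    def study_ids(self) -> list:
        return list(pd.unique(self.table["study"]))

    @property
    def local_studies(self) -> list:
        """Studies requiring calibration, in order of appearance."""
        return [s for s in self.study_ids if s not in self.reference_studies]

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def n_strata(self) -> int:
        return self.table.groupby(["study", "stratum"], sort=False).ngroups

    def study_table(self, study_id) -> pd.DataFrame:
        out = self.table[self.table["study"] == study_id]
        if out.empty:
            raise KeyError(f"no such study: {study_id!r}")
        return out

    def z_matrix(self) -> np.ndarray:
        if not self.covariates:
            return np.empty((len(self.table), 0))
        return self.table[list(self.covariates)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)
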