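"""Feature loading, nuisance-covariate residualization and reference z-scoring.

The pipeline's first analytic stage: each of the 76 morphometric features is
regressed (ordinary least squares) on intercept + age + gender + eTIV, and
the residuals are z-scored with the per-feature mean and standard deviation
of the reference group (the cognitively unimpaired patients), so that every
subject's profile is expressed in units of normal-group variability.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, FeatureSchema


def load_feature_table(
    path: str | Path, schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Load and validate a tab-separated morphometric feature table.

    The file must have a ``subject_id`` column plus exactly the schema's
    feature columns (any order; returned in canonical order). Missing,
    extra or duplicated columns and non-numeric cells are reported
    explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'subject_id' column")
    cols = [c for c in df.columns if c != "subject_id"]
    expected = set(schema.feature_names)
    dupes = sorted({c for c in cols if cols.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate feature columns: {dupes}")
    missing = sorted(expected - set(cols))
    extra = sorted(set(cols) - expected)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns: {missing}")
        if extra:
            parts.append(f"unexpected columns: {extra}")
        raise ValueError(f"{path}: feature header does not match schema; " + "; ".join(parts))
    if df["subject_id"].duplicated().any():
        dup_ids = df["subject_id"][df["subject_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicated subject ids: {dup_ids}")
    df = df.set_index("subject_id")
    out = {}
    for col in schema.feature_names:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or converted.isna().any():
            where = converted.index[converted.isna()].tolist()
            raise ValueError(
                f"{path}: non-numeric or missing values in column {col!r} "
                f"at rows {where}"
            )
        out[col] = converted.astype(float)
    return pd.DataFrame(out, index=df.index)[list(schema.feature_names)]


def load_subject_table(path: str | Path) -> pd.DataFrame:
    """Load the tab-separated subject covariate/clinical table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "age", "gender", "etiv"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing required subject columns: {missing}")
    df = df.set_index("subject_id")
    bad_groups = sorted(set(df["group"]) - {"CI", "NCI"})
    if bad_groups:
        raise ValueError(f"{path}: unknown group labels: {bad_groups}")
    return df


def _design_matrix(
    subjects: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(subjects))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "gender":
            if not set(subjects["gender"]) <= {"F", "M"}:
                raise ValueError("gender column must contain only 'F'/'M'")
            cols.append((subjects["gender"] == "M").to_numpy(float))
        else:
            if cov not in subjects.columns:
                raise ValueError(f"covariate {cov!r} missing from subject table")
            vals = pd.to_numeric(subjects[cov], errors="coerce")
            if vals.isna().any():
                bad = vals.index[vals.isna()].tolist()
                raise ValueError(f"covariate {cov!r} missing/non-numeric for {bad}")
            cols.append(vals.to_numpy(float))
        names.append(cov)
    return np.column_stack(cols), names


def residualize(
    table: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "gender", "etiv"),
    per_group: bool = False,
) -> pd.DataFrame:
    """Remove linear covariate effects from every feature by OLS.

    By default the regression pools all subjects (the reference group only
    anchors the later z-scale); ``per_group=True`` fits separate models
    within each group instead. Residuals are orthogonal to every covariate
    in the fitted sample by construction.
    """
    if not set(table.index) <= set(subjects.index):
        missing = sorted(set(table.index) - set(subjects.index))
        raise ValueError(f"subjects missing covariate rows: {missing}")
    subjects = subjects.loc[table.index]
    if len(table) < len(covariates) + 2:
        raise ValueError(
            f"need at least {len(covariates) + 2} subjects to adjust for "
            f"{len(covariates)} covariates, got {len(table)}"
        )
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing feature values in columns {bad}")

    def _fit(tbl: pd.DataFrame, subs: pd.DataFrame) -> pd.DataFrame:
        X, names = _design_matrix(subs, covariates)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                "rank-deficient covariate design (collinear or constant "
                f"covariates among {names}); cannot residualize"
            )
        Y = tbl.to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return pd.DataFrame(Y - X @ beta, index=tbl.index, columns=tbl.columns)

    if not per_group:
        return _fit(table, subjects)
    parts = []
    for _, ids in subjects.groupby("group").groups.items():
        parts.append(_fit(table.loc[ids], subjects.loc[ids]))
    return pd.concat(parts).loc[table.index]


@dataclass
class ZScoreMatrix:
    """Z-scored residuals with their reference-group provenance."""

    values: pd.DataFrame  # subjects x features, unitless
    reference_ids: tuple[str, ...]
    reference_mean: pd.Series
    reference_sd: pd.Series

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)


def zscore_reference(
    residuals: pd.DataFrame, reference_ids
) -> ZScoreMatrix:
    """Z-score every subject against the reference group's mean and sd.

    The sd uses the n-1 denominator. Reference rows have column mean 0 and
    sd 1 afterwards; a zero reference sd for any feature is an error (the
    feature carries no reference variability to scale against).
    """
    reference_ids = tuple(reference_ids)
    if not reference_ids:
        raise ValueError("reference_ids is empty")
    missing = sorted(set(reference_ids) - set(residuals.index))
    if missing:
        raise ValueError(f"reference subjects not in residual matrix: {missing}")
    ref = residuals.loc[list(reference_ids)]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        raise ValueError(f"zero reference standard deviation for features: {zero}")
    z = (residuals - mean) / sd
    if not np.isfinite(z.to_numpy()).all():
        raise ValueError("non-finite z-scores produced")
    return ZScoreMatrix(
        values=z,
        reference_ids=reference_ids,
        reference_mean=mean,
        reference_sd=sd,
    )


# FreeSurfer table-stat name quirks -> canonical schema names.
_ASEG_RENAMES = {
    "Left-Thalamus-Proper": "Left-Thalamus",
    "Right-Thalamus-Proper": "Right-Thalamus",
}


def combine_freesurfer_tables(
    lh_aparc: str | Path,
    rh_aparc: str | Path,
    aseg: str | Path,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Assemble the canonical feature table from FreeSurfer stats tables.

    Accepts the tab-separated outputs of ``aparcstats2table`` (one per
    hemisphere, thickness measure, DKT atlas) and ``asegstats2table``
    (volumes), one row per subject, and returns the 76-column canonical
    table. Extra columns (e.g. eTIV, mean thickness) are ignored.
    """
    frames = []
    for path in (lh_aparc, rh_aparc):
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={df.columns[0]: "subject_id"}).set_index("subject_id")
        frames.append(df)
    aseg_df = pd.read_csv(aseg, sep="\t")
    aseg_df = aseg_df.rename(
        columns={aseg_df.columns[0]: "subject_id", **_ASEG_RENAMES}
    ).set_index("subject_id")
    frames.append(aseg_df)
    merged = pd.concat(frames, axis=1)
    missing = sorted(set(schema.feature_names) - set(merged.columns))
    if missing:
        raise ValueError(f"FreeSurfer tables missing features: {missing}")
    out = merged[list(schema.feature_names)].apply(pd.to_numeric)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values in FreeSurfer features: {bad}")
    return out
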