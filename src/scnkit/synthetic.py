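"""Synthetic two-group morphometric cohort generator.

Emulates a Parkinson's disease cohort split into cognitively impaired (CI)
and cognitively unimpaired (NCI) patients: per-subject morphometric features
(cortical thickness + subcortical volumes) with shared latent-factor
covariance, nuisance-covariate confounding (age, gender, eTIV), and two
plantable group effects —

* **atrophy**: fractional mean reduction of selected features in the CI
  group;
* **decoherence**: extra independent Gaussian noise added to every CI
  feature, which lowers inter-regional similarity and hence the coherence
  of the CI subjects' similarity networks.

The generator is fully deterministic given the config seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, FeatureSchema

#: education level labels and the years->level mapping used throughout.
EDUCATION_LEVELS = ("illiterate", "elementary", "secondary")


def education_level_from_years(years: float) -> str:
    """Map years of schooling to the coarse level used by the MMSE cutoffs.

    0 years -> illiterate, 1-6 -> elementary, >=7 -> secondary.
    """
    if years < 0:
        raise ValueError(f"education years must be >= 0, got {years}")
    if years == 0:
        return "illiterate"
    if years <= 6:
        return "elementary"
    return "secondary"


@dataclass
class SubjectRecord:
    """Covariates, clinical scales and group label for one subject."""

    subject_id: str
    group: str  # "CI" or "NCI"
    age: float  # years
    gender: str  # "F" or "M"
    duration: float  # disease duration, years
    education_years: float
    education_level: str
    mmse: float  # 0-30
    etiv: float  # mm^3
    updrs_total: float | None = None
    updrs_i: float | None = None
    updrs_ii: float | None = None
    updrs_iii: float | None = None
    hy: float | None = None
    nmss: float | None = None
    hama: float | None = None
    hamd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("CI", "NCI"):
            raise ValueError(f"group must be CI or NCI, got {self.group!r}")
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be F or M, got {self.gender!r}")
        if not 0 <= self.mmse <= 30:
            raise ValueError(f"mmse must be in [0, 30], got {self.mmse}")
        if self.etiv <= 0:
            raise ValueError(f"etiv must be positive, got {self.etiv}")
        expected = education_level_from_years(self.education_years)
        if self.education_level != expected:
            raise ValueError(
                f"education_level {self.education_level!r} inconsistent with "
                f"{self.education_years} years (expected {expected!r})"
            )


@dataclass
class CohortConfig:
    """Generative parameters of the synthetic cohort.

    Defaults mirror the study conditions the pipeline targets: 18 CI vs 33
    NCI patients, elderly (ages ~60-80), eTIV around 1.43e6 mm^3, MMSE
    simulated group-conditionally (CI 18.8 +/- 4.2, NCI 25.9 +/- 2.7).

    ``decoherence_sd`` is expressed in units of each feature's idiosyncratic
    noise sd (features mix mm and mm^3 scales, so an absolute sd would be
    meaningless): the extra independent noise added to a CI subject's
    feature has sd = decoherence_sd * noise_frac * baseline(feature).
    """

    n_ci: int = 18
    n_nci: int = 33
    seed: int = 0
    age_range: tuple[float, float] = (60.0, 80.0)
    gender_prob: float = 0.55  # probability of female
    duration_range: tuple[float, float] = (1.0, 6.0)
    education_weights: tuple[float, float, float] = (0.25, 0.50, 0.25)
    etiv_mean: float = 1.43e6  # mm^3
    etiv_sd: float = 1.7e5  # mm^3
    latent_dim: int = 4
    latent_frac: float = 0.04  # per-factor loading scale, fraction of baseline
    noise_frac: float = 0.03  # idiosyncratic noise sd, fraction of baseline
    covariate_effects: dict[str, tuple[float, float, float]] | None = None
    atrophy_effects: dict[str, float] = field(default_factory=dict)
    decoherence_sd: float = 0.0
    mmse_ci: tuple[float, float] = (18.8, 4.2)
    mmse_nci: tuple[float, float] = (25.9, 2.7)
    simulate_scales: bool = True
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        if self.n_ci < 2:
            raise ValueError(f"n_ci must be >= 2, got {self.n_ci}")
        if self.n_nci < 2:
            raise ValueError(f"n_nci must be >= 2, got {self.n_nci}")
        if not 0 <= self.gender_prob <= 1:
            raise ValueError(f"gender_prob must be in [0, 1], got {self.gender_prob}")
        for name in ("etiv_sd", "latent_frac", "noise_frac"):
            val = getattr(self, name)
            if val <= 0:
                raise ValueError(f"{name} must be > 0, got {val}")
        if self.mmse_ci[1] <= 0 or self.mmse_nci[1] <= 0:
            raise ValueError("mmse sds must be > 0")
        if self.decoherence_sd < 0:
            raise ValueError(f"decoherence_sd must be >= 0, got {self.decoherence_sd}")
        if self.latent_dim < 0:
            raise ValueError(f"latent_dim must be >= 0, got {self.latent_dim}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError(f"age_range must be increasing, got {self.age_range}")
        if self.duration_range[0] > self.duration_range[1]:
            raise ValueError(f"duration_range must be ordered, got {self.duration_range}")
        if abs(sum(self.education_weights) - 1.0) > 1e-9:
            raise ValueError(
                f"education_weights must sum to 1, got {self.education_weights}"
            )
        for key, frac in self.atrophy_effects.items():
            self.schema.resolve(key)  # raises KeyError for unknown ROIs
            if not 0 <= frac <= 0.5:
                raise ValueError(
                    f"atrophy fraction for {key!r} must be in [0, 0.5], got {frac}"
                )

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


# Per-hemisphere volume baselines, mm^3.
_SUBCORTICAL_BASELINES = {
    "Thalamus": 6800.0,
    "Caudate": 3500.0,
    "Putamen": 4700.0,
    "Pallidum": 1800.0,
    "Hippocampus": 3900.0,
    "Amygdala": 1600.0,
    "Accumbens-area": 550.0,
}


def feature_baselines(schema: FeatureSchema = DEFAULT_SCHEMA) -> pd.Series:
    """Deterministic healthy-elderly baseline for each feature.

    Cortical thickness baselines span 2.0-3.0 mm across the DKT regions
    (identical left/right); subcortical volumes use typical per-hemisphere
    values.
    """
    values = {}
    n_rois = len(schema.cortical_rois)
    thick = np.linspace(2.0, 3.0, n_rois)
    for hemi in schema.hemispheres:
        for i, roi in enumerate(schema.cortical_rois):
            values[f"{hemi}_{roi}_thickness"] = thick[i]
    for st in schema.subcortical_structures:
        for side in schema.sides:
            values[f"{side}-{st}"] = _SUBCORTICAL_BASELINES[st]
    return pd.Series(values).loc[list(schema.feature_names)]


def _default_covariate_effects(
    baselines: pd.Series, etiv_mean: float, schema: FeatureSchema
) -> np.ndarray:
    """Per-feature slopes on (age, male, eTIV).

    Age: ~0.2% of baseline lost per year. Gender: males +1% (beyond head
    size). eTIV: volumes scale with head size (elasticity ~0.3); thickness
    does not.
    """
    b = baselines.to_numpy()
    slopes = np.zeros((len(b), 3))
    slopes[:, 0] = -0.002 * b
    slopes[:, 1] = 0.01 * b
    is_vol = np.array([schema.is_volume(f) for f in baselines.index])
    slopes[is_vol, 2] = 0.3 * b[is_vol] / etiv_mean
    return slopes


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds far from mean in practice)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[SubjectRecord]]:
    """Generate a two-group cohort.

    Returns a (subjects x 76 features) DataFrame indexed by subject id and
    the matching list of :class:`SubjectRecord`. Each feature is
    baseline + loading . latent factors + covariate slopes . (age, gender,
    eTIV) + Gaussian noise; CI subjects additionally receive the planted
    atrophy (fractional reduction) and decoherence (extra independent
    noise).
    """
    cfg = config
    schema = cfg.schema
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_ci + cfg.n_nci
    groups = np.array(["CI"] * cfg.n_ci + ["NCI"] * cfg.n_nci)
    ids = [f"sub-{i + 1:03d}" for i in range(n)]

    age = rng.uniform(*cfg.age_range, n)
    female = rng.random(n) < cfg.gender_prob
    duration = rng.uniform(cfg.duration_range[0], cfg.duration_range[1], n)
    edu_level = rng.choice(EDUCATION_LEVELS, size=n, p=cfg.education_weights)
    edu_years = np.where(
        edu_level == "illiterate",
        0,
        np.where(
            edu_level == "elementary",
            rng.integers(1, 7, n),
            rng.integers(7, 13, n),
        ),
    ).astype(float)
    etiv = _truncated_normal(
        rng, cfg.etiv_mean, cfg.etiv_sd, 1e5, np.inf, n
    )
    mmse = np.empty(n)
    ci_mask = groups == "CI"
    mmse[ci_mask] = _truncated_normal(
        rng, cfg.mmse_ci[0], cfg.mmse_ci[1], 0, 30, ci_mask.sum()
    )
    mmse[~ci_mask] = _truncated_normal(
        rng, cfg.mmse_nci[0], cfg.mmse_nci[1], 0, 30, (~ci_mask).sum()
    )

    baselines = feature_baselines(schema)
    b = baselines.to_numpy()
    p = len(b)

    slopes = _default_covariate_effects(baselines, cfg.etiv_mean, schema)
    if cfg.covariate_effects:
        idx = {f: i for i, f in enumerate(baselines.index)}
        for key, (ba, bg, be) in cfg.covariate_effects.items():
            for feat in schema.resolve(key):
                slopes[idx[feat]] = (ba, bg, be)

    # latent factors shared across features induce inter-regional covariance
    loadings = rng.normal(0.0, cfg.latent_frac, (p, cfg.latent_dim)) * b[:, None]
    factors = rng.normal(0.0, 1.0, (n, cfg.latent_dim))

    age_c = age - np.mean(cfg.age_range)
    etiv_c = etiv - cfg.etiv_mean
    male = (~female).astype(float)
    covar = np.column_stack([age_c, male, etiv_c])

    noise_sd = cfg.noise_frac * b
    values = (
        b[None, :]
        + factors @ loadings.T
        + covar @ slopes.T
        + rng.normal(0.0, 1.0, (n, p)) * noise_sd[None, :]
    )

    # planted group effects, applied to CI rows only
    if cfg.atrophy_effects:
        reduction = np.ones(p)
        idx = {f: i for i, f in enumerate(baselines.index)}
        for key, frac in cfg.atrophy_effects.items():
            for feat in schema.resolve(key):
                reduction[idx[feat]] *= 1.0 - frac
        values[ci_mask] *= reduction[None, :]
    if cfg.decoherence_sd > 0:
        extra = cfg.decoherence_sd * noise_sd
        values[ci_mask] += rng.normal(
            0.0, 1.0, (ci_mask.sum(), p)
        ) * extra[None, :]

    table = pd.DataFrame(values, index=pd.Index(ids, name="subject_id"),
                         columns=list(baselines.index))

    records = []
    for i in range(n):
        scales: dict[str, float | None] = dict.fromkeys(
            ("updrs_total", "updrs_i", "updrs_ii", "updrs_iii",
             "hy", "nmss", "hama", "hamd"),
            None,
        )
        if cfg.simulate_scales:
            u1 = max(0.0, rng.normal(10.5, 6.0))
            u2 = max(0.0, rng.normal(11.0, 6.0))
            u3 = max(0.0, rng.normal(25.0, 12.0))
            scales = {
                "updrs_i": round(u1, 0),
                "updrs_ii": round(u2, 0),
                "updrs_iii": round(u3, 0),
                "updrs_total": round(u1 + u2 + u3 + max(0.0, rng.normal(7.0, 4.0)), 0),
                "hy": float(rng.choice([1.0, 1.5, 2.0, 2.5, 3.0],
                                       p=[0.1, 0.2, 0.4, 0.2, 0.1])),
                "nmss": round(float(np.exp(rng.normal(3.5, 0.8))), 0),
                "hama": round(float(np.exp(rng.normal(2.2, 0.6))), 0),
                "hamd": round(float(np.exp(rng.normal(2.2, 0.6))), 0),
            }
        records.append(
            SubjectRecord(
                subject_id=ids[i],
                group=str(groups[i]),
                age=round(float(age[i]), 2),
                gender="F" if female[i] else "M",
                duration=round(float(duration[i]), 2),
                education_years=float(edu_years[i]),
                education_level=str(edu_level[i]),
                mmse=round(float(mmse[i]), 1),
                etiv=round(float(etiv[i]), 1),
                **scales,
            )
        )
    return table, records


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (one row per subject, indexed by id)."""
    if not records:
        raise ValueError("no subject records given")
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("subject_id")


def write_cohort(
    table: pd.DataFrame,
    records: list[SubjectRecord],
    directory: str | Path,
) -> tuple[Path, Path]:
    """Write the feature and subject tables as TSV; returns the two paths.

    Numeric feature values round-trip at full precision through
    :func:`scnkit.prep.load_feature_table`.
    """
    if len(table) == 0 or not records:
        raise ValueError("refusing to write an empty cohort")
    rec_ids = [r.subject_id for r in records]
    if list(table.index) != rec_ids:
        raise ValueError("feature table and subject records disagree on subject ids")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fpath = directory / "features.tsv"
    spath = directory / "subjects.tsv"
    table.to_csv(fpath, sep="\t", float_format=None)
    records_to_frame(records).to_csv(spath, sep="\t")
    return fpath, spath
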