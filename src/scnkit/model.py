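"""Model/Results interface tying the pipeline stages together.

:class:`StructuralCovarianceModel` is constructed from a morphometric
feature table and a subject table (or a synthetic cohort config) together
with the analysis settings; :meth:`StructuralCovarianceModel.fit` runs

    residualize -> reference z-score -> similarity networks -> density
    thresholding -> (admission sweep) -> topology metrics -> AUC ->
    covariate-adjusted group comparison with FDR

and returns a :class:`StructuralCovarianceResults` carrying every
intermediate and final table, a text ``summary()``, plotting helpers and a
``save()`` that writes the tab-separated output bundle plus a
reproducibility manifest. All randomness derives from the single model
seed, so a rerun with the same inputs reproduces every number bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import metrics as gm
from . import network as net
from . import stats as st
from .prep import load_feature_table, load_subject_table, residualize, zscore_reference
from .schema import DEFAULT_SCHEMA, FeatureSchema
from .synthetic import CohortConfig, generate_cohort, records_to_frame

GLOBAL_METRICS = ("sigma", "lambda", "gamma", "assortativity", "eglob", "eloc")
NODAL_METRICS = ("gamma", "eloc", "degree", "betweenness")
_NULL_GLOBALS = {"sigma", "lambda", "gamma"}


class StructuralCovarianceModel:
    """Individual structural-covariance-network analysis of a two-group cohort.

    Parameters
    ----------
    features
        Subjects x features table in the canonical schema (mm / mm^3).
    subjects
        Covariate/clinical table indexed by subject id with at least
        ``group`` (CI/NCI), ``age``, ``gender``, ``etiv``.
    density_range
        Either an explicit ``(lo, hi)`` on the grid (default the study's
        admitted 0.10-0.34) or ``"auto"`` to run the three-criteria
        admission sweep over the whole grid.
    n_nulls, swaps_per_edge
        Degree-preserving null-ensemble size and rewiring intensity used
        for the normalized metrics (and the admission sweep).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        subjects: pd.DataFrame,
        *,
        schema: FeatureSchema = DEFAULT_SCHEMA,
        density_grid=net.DEFAULT_DENSITY_GRID,
        density_range=(0.10, 0.34),
        criteria: net.AdmissionCriteria = net.AdmissionCriteria(),
        adjust_covariates: tuple[str, ...] = ("age", "gender", "etiv"),
        compare_covariates: tuple[str, ...] = ("age", "gender"),
        logistic_covariates: tuple[str, ...] = ("age", "gender", "duration"),
        global_metrics: tuple[str, ...] = GLOBAL_METRICS,
        nodal_metrics: tuple[str, ...] = NODAL_METRICS,
        per_group_residualize: bool = False,
        admission_aggregate: str = "mean",
        n_nulls: int = 20,
        swaps_per_edge: int = 10,
        modularity_restarts: int = 10,
        seed: int = 0,
    ) -> None:
        missing = sorted(set(features.index) - set(subjects.index))
        if missing:
            raise ValueError(f"subjects table missing rows for: {missing}")
        bad = sorted(set(global_metrics) - set(GLOBAL_METRICS))
        if bad:
            raise ValueError(f"unknown global metrics: {bad}")
        bad = sorted(set(nodal_metrics) - set(NODAL_METRICS))
        if bad:
            raise ValueError(f"unknown nodal metrics: {bad}")
        expected = set(schema.feature_names)
        got = set(features.columns)
        if got != expected:
            raise ValueError(
                f"feature table does not match schema: missing "
                f"{sorted(expected - got)}, extra {sorted(got - expected)}"
            )
        self.features = features[list(schema.feature_names)]
        self.subjects = subjects.loc[features.index]
        self.schema = schema
        self.density_grid = tuple(float(d) for d in density_grid)
        self.density_range = density_range
        self.criteria = criteria
        self.adjust_covariates = tuple(adjust_covariates)
        self.compare_covariates = tuple(compare_covariates)
        self.logistic_covariates = tuple(logistic_covariates)
        self.global_metrics = tuple(global_metrics)
        self.nodal_metrics = tuple(nodal_metrics)
        self.per_group_residualize = per_group_residualize
        self.admission_aggregate = admission_aggregate
        self.n_nulls = n_nulls
        self.swaps_per_edge = swaps_per_edge
        self.modularity_restarts = modularity_restarts
        self.seed = seed

    # ------------------------------------------------------------------ #
    @classmethod
    def from_tables(
        cls, features_path, subjects_path, *, schema: FeatureSchema = DEFAULT_SCHEMA, **kwargs
    ) -> "StructuralCovarianceModel":
        """Build the model from the on-disk TSV tables."""
        features = load_feature_table(features_path, schema)
        subjects = load_subject_table(subjects_path)
        return cls(features, subjects, schema=schema, **kwargs)

    @classmethod
    def from_synthetic(cls, config: CohortConfig, **kwargs) -> "StructuralCovarianceModel":
        """Build the model on a freshly generated synthetic cohort."""
        table, records = generate_cohort(config)
        kwargs.setdefault("seed", config.seed)
        return cls(table, records_to_frame(records), schema=config.schema, **kwargs)

    # ------------------------------------------------------------------ #
    def _stage_seeds(self) -> dict[str, int]:
        """Split the master seed into independent per-stage seeds."""
        ss = np.random.SeedSequence(self.seed)
        names = ("admission", "nulls")
        children = ss.spawn(len(names))
        return {
            name: int(child.generate_state(1)[0] % 2**31)
            for name, child in zip(names, children)
        }

    def fit(self) -> "StructuralCovarianceResults":
        stage = "feature preparation"
        try:
            seeds = self._stage_seeds()
            residuals = residualize(
                self.features,
                self.subjects,
                covariates=self.adjust_covariates,
                per_group=self.per_group_residualize,
            )
            reference_ids = tuple(
                self.subjects.index[self.subjects["group"] == "NCI"]
            )
            if not reference_ids:
                raise ValueError("no NCI (reference) subjects in the cohort")
            zmat = zscore_reference(residuals, reference_ids)

            stage = "network construction"
            ensembles = []
            for sid in zmat.values.index:
                w = net.similarity_network(zmat.values.loc[sid], subject_id=str(sid))
                ensembles.append(net.threshold_binarize(w, self.density_grid))

            stage = "density admission"
            if self.density_range == "auto":
                drange = net.determine_density_range(
                    ensembles,
                    criteria=self.criteria,
                    aggregate=self.admission_aggregate,
                    seed=seeds["admission"],
                    n_nulls=self.n_nulls,
                    swaps_per_edge=self.swaps_per_edge,
                    restarts=self.modularity_restarts,
                )
                bounds = drange.bounds
                diagnostics = drange.diagnostics
            else:
                bounds = (float(self.density_range[0]), float(self.density_range[1]))
                for b in bounds:
                    if not any(abs(b - d) <= 1e-9 for d in self.density_grid):
                        raise ValueError(f"density-range bound {b} is not on the grid")
                diagnostics = None

            stage = "topology metrics"
            admitted = [
                d for d in self.density_grid if bounds[0] - 1e-9 <= d <= bounds[1] + 1e-9
            ]
            curves, nodal_curves = self._metric_curves(ensembles, admitted, seeds["nulls"])

            stage = "AUC aggregation"
            auc = pd.DataFrame(
                {
                    metric: {
                        sid: gm.auc_over_density(vals.loc[sid], admitted, bounds)
                        for sid in vals.index
                    }
                    for metric, vals in curves.items()
                }
            )
            auc.index.name = "subject_id"
            auc = auc[list(self.global_metrics)]
            nodal_auc = {
                metric: pd.DataFrame(
                    {
                        node: {
                            sid: gm.auc_over_density(df.loc[sid, node], admitted, bounds)
                            for sid in df.index.get_level_values(0).unique()
                        }
                        for node in self.schema.feature_names
                    }
                )
                for metric, df in nodal_curves.items()
            }

            stage = "group statistics"
            two_groups = self.subjects["group"].nunique() == 2
            global_tests = nodal_tests = cohort = ratio_tests = None
            logistic = None
            if two_groups:
                global_tests = _tests_frame(
                    st.compare_auc_metrics(
                        auc, self.subjects, covariates=self.compare_covariates
                    )
                )
                nodal_tests = {
                    metric: _tests_frame(
                        st.compare_auc_metrics(
                            nodal_auc[metric],
                            self.subjects,
                            covariates=self.compare_covariates,
                        )
                    )
                    for metric in nodal_auc
                }
                cohort = st.cohort_table(self.subjects)
                ratio_tests, logistic = self._volumetrics()
        except Exception as err:
            raise RuntimeError(f"pipeline failed during {stage}: {err}") from err

        return StructuralCovarianceResults(
            model=self,
            zscores=zmat,
            ensembles=ensembles,
            density_bounds=bounds,
            admitted_densities=tuple(admitted),
            admission_diagnostics=diagnostics,
            metric_curves=curves,
            nodal_curves=nodal_curves,
            auc=auc,
            nodal_auc=nodal_auc,
            global_tests=global_tests,
            nodal_tests=nodal_tests,
            cohort_summary=cohort,
            ratio_tests=ratio_tests,
            logistic_results=logistic,
            stage_seeds=seeds,
        )

    # ------------------------------------------------------------------ #
    def _metric_curves(self, ensembles, admitted, null_seed):
        needs_nulls = bool(_NULL_GLOBALS & set(self.global_metrics)) or (
            "gamma" in self.nodal_metrics
        )
        n_sub = len(ensembles)
        n_den = len(admitted)
        null_seeds = np.random.SeedSequence(null_seed).generate_state(n_sub * n_den)
        sids = [e.subject_id for e in ensembles]
        curves = {
            m: pd.DataFrame(np.nan, index=sids, columns=admitted)
            for m in self.global_metrics
        }
        nodal_index = pd.MultiIndex.from_product(
            [sids, admitted], names=["subject_id", "density"]
        )
        nodal_curves = {
            m: pd.DataFrame(
                np.nan, index=nodal_index, columns=list(self.schema.feature_names)
            )
            for m in self.nodal_metrics
        }
        for si, ens in enumerate(ensembles):
            for di, d in enumerate(admitted):
                A = ens.adjacency(d)
                row = {}
                if {"eglob", "eloc"} & set(self.global_metrics) or (
                    "eloc" in self.nodal_metrics
                ):
                    eglob, eloc, nodal_eloc = gm.efficiencies(A)
                    row["eglob"] = eglob
                    row["eloc"] = eloc
                    if "eloc" in self.nodal_metrics:
                        nodal_curves["eloc"].loc[(ens.subject_id, d)] = nodal_eloc
                if "assortativity" in self.global_metrics:
                    row["assortativity"] = gm.assortativity(A)
                if needs_nulls:
                    s = int(null_seeds[si * n_den + di] % 2**31)
                    nulls = gm.random_reference(
                        A,
                        n_nulls=self.n_nulls,
                        swaps_per_edge=self.swaps_per_edge,
                        seed=s,
                    )
                    gamma, lam, sigma = gm.normalized_smallworld(A, nulls)
                    row.update(gamma=gamma, sigma=sigma)
                    row["lambda"] = lam
                    if "gamma" in self.nodal_metrics:
                        c_i = gm.nodal_clustering(A)
                        c_null = np.mean(
                            [gm.nodal_clustering(g) for g in nulls.graphs], axis=0
                        )
                        with np.errstate(divide="ignore", invalid="ignore"):
                            nodal_gamma = np.where(c_null > 0, c_i / c_null, np.nan)
                        nodal_curves["gamma"].loc[(ens.subject_id, d)] = nodal_gamma
                if {"degree", "betweenness"} & set(self.nodal_metrics):
                    deg, btw = gm.centralities(A)
                    if "degree" in self.nodal_metrics:
                        nodal_curves["degree"].loc[(ens.subject_id, d)] = deg
                    if "betweenness" in self.nodal_metrics:
                        nodal_curves["betweenness"].loc[(ens.subject_id, d)] = btw
                for m in self.global_metrics:
                    if m in row:
                        curves[m].loc[ens.subject_id, d] = row[m]
        # nodal gamma can be nan where a null node never closes a triangle;
        # AUC needs finite values, so fill those nodes with 0 normalization
        if "gamma" in nodal_curves:
            nodal_curves["gamma"] = nodal_curves["gamma"].fillna(0.0)
        return curves, nodal_curves

    def _volumetrics(self):
        ratios = st.subcortical_ratio_table(self.features, self.subjects)
        groups = self.subjects.loc[ratios.index, "group"]
        rows = []
        ors = []
        data = pd.concat([ratios, self.subjects.loc[ratios.index]], axis=1)
        for structure in ratios.columns:
            res = st.compare_variable(ratios[structure], groups, variable=structure)
            rows.append(res)
            try:
                ors.append(
                    st.logistic_adjusted(
                        data,
                        data["group"],
                        predictor=structure,
                        covariates=self.logistic_covariates,
                    )
                )
            except ValueError:
                pass  # separation at small n is reported by omission
        ratio_tests = _tests_frame(rows)
        ratio_tests["p_fdr"] = st.fdr_correct(ratio_tests["p"])
        logistic = pd.DataFrame(
            [
                {
                    "predictor": o.predictor,
                    "B": o.coef,
                    "OR": o.odds_ratio,
                    "ci_low": o.ci_low,
                    "ci_high": o.ci_high,
                    "p": o.p_value,
                }
                for o in ors
            ]
        )
        if len(logistic):
            logistic = logistic.set_index("predictor")
        return ratio_tests, logistic

    def config_dict(self) -> dict:
        return {
            "n_subjects": int(len(self.features)),
            "density_grid": list(self.density_grid),
            "density_range": (
                "auto" if self.density_range == "auto" else list(self.density_range)
            ),
            "criteria": {
                "min_connected_fraction": self.criteria.min_connected_fraction,
                "min_modularity": self.criteria.min_modularity,
                "min_sigma": self.criteria.min_sigma,
                "connectivity": self.criteria.connectivity,
            },
            "adjust_covariates": list(self.adjust_covariates),
            "compare_covariates": list(self.compare_covariates),
            "logistic_covariates": list(self.logistic_covariates),
            "global_metrics": list(self.global_metrics),
            "nodal_metrics": list(self.nodal_metrics),
            "per_group_residualize": self.per_group_residualize,
            "admission_aggregate": self.admission_aggregate,
            "n_nulls": self.n_nulls,
            "swaps_per_edge": self.swaps_per_edge,
            "modularity_restarts": self.modularity_restarts,
            "seed": self.seed,
        }


def _tests_frame(results: list[st.TestResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "variable": r.variable,
                "test": r.test,
                "CI": r.group_summaries.get("CI", ""),
                "NCI": r.group_summaries.get("NCI", ""),
                "statistic": r.statistic,
                "p": r.p_value,
                "p_fdr": r.p_adjusted,
            }
            for r in results
        ]
    )
    return df.set_index("variable")


@dataclass
class StructuralCovarianceResults:
    """Fitted pipeline outputs (see :class:`StructuralCovarianceModel`)."""

    model: StructuralCovarianceModel
    zscores: object
    ensembles: list
    density_bounds: tuple[float, float]
    admitted_densities: tuple[float, ...]
    admission_diagnostics: pd.DataFrame | None
    metric_curves: dict[str, pd.DataFrame]  # metric -> subjects x densities
    nodal_curves: dict[str, pd.DataFrame]
    auc: pd.DataFrame  # subjects x global metrics
    nodal_auc: dict[str, pd.DataFrame]
    global_tests: pd.DataFrame | None
    nodal_tests: dict[str, pd.DataFrame] | None
    cohort_summary: pd.DataFrame | None
    ratio_tests: pd.DataFrame | None
    logistic_results: pd.DataFrame | None
    stage_seeds: dict[str, int] = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    def curves_long(self) -> pd.DataFrame:
        """Tidy (subject_id, metric, density, value) global-metric curves."""
        parts = []
        for metric, df in self.metric_curves.items():
            long = df.reset_index(names="subject_id").melt(
                id_vars="subject_id", var_name="density", value_name="value"
            )
            long.insert(1, "metric", metric)
            parts.append(long)
        return pd.concat(parts, ignore_index=True)

    def auc_long(self) -> pd.DataFrame:
        long = self.auc.reset_index().melt(
            id_vars="subject_id", var_name="metric", value_name="auc"
        )
        return long

    def summary(self) -> str:
        """Human-readable report of the fitted analysis."""
        m = self.model
        lo, hi = self.density_bounds
        lines = [
            "Individual structural covariance network analysis",
            "=" * 51,
            f"subjects: {len(m.features)} "
            f"(CI {int((m.subjects['group'] == 'CI').sum())} / "
            f"NCI {int((m.subjects['group'] == 'NCI').sum())}), "
            f"nodes: {m.schema.n_features}",
            f"admitted density range: {lo:.2f}-{hi:.2f} "
            f"({len(self.admitted_densities)} densities)",
            f"null ensemble: {m.n_nulls} degree-preserving graphs per network",
            "",
            "Global metric AUCs over the admitted range "
            "(group comparison adjusted for "
            + ", ".join(m.compare_covariates)
            + "):",
        ]
        if self.global_tests is not None:
            df = self.global_tests.copy()
            for _, r in df.iterrows():
                lines.append(
                    f"  {r.name:>13}:  CI {r['CI']:>18}  NCI {r['NCI']:>18}  "
                    f"t = {r['statistic']:+.3f}  P = {r['p']:.3f}  "
                    f"P(FDR) = {r['p_fdr']:.3f}"
                )
        else:
            means = self.auc.mean()
            for metric, val in means.items():
                lines.append(f"  {metric:>13}: mean AUC {val:.4f}")
        if self.nodal_tests:
            sig = {
                metric: int((df["p_fdr"] < 0.05).sum())
                for metric, df in self.nodal_tests.items()
            }
            lines.append("")
            lines.append(
                "Nodal metrics with FDR-significant group differences: "
                + ", ".join(f"{k}: {v}/{len(self.model.schema.feature_names)}"
                            for k, v in sig.items())
            )
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def plot_metric(self, metric: str, ax=None):
        """Group-mean metric-vs-density curves (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if metric not in self.metric_curves:
            raise KeyError(f"no curve for metric {metric!r}")
        if ax is None:
            _, ax = plt.subplots()
        df = self.metric_curves[metric]
        groups = self.model.subjects.loc[df.index, "group"]
        for g, color in (("CI", "tab:red"), ("NCI", "tab:blue")):
            sub = df[groups == g]
            if len(sub):
                ax.plot(df.columns, sub.mean(axis=0), label=g, color=color)
        ax.set_xlabel("network density")
        ax.set_ylabel(metric)
        ax.legend()
        return ax

    # ------------------------------------------------------------------ #
    def save(self, outdir) -> Path:
        """Write the tab-separated output bundle and the run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.curves_long().to_csv(outdir / "metric_curves.tsv", sep="\t", index=False)
        self.auc_long().to_csv(outdir / "metric_auc.tsv", sep="\t", index=False)
        for metric, df in self.nodal_auc.items():
            df.to_csv(outdir / f"nodal_auc_{metric}.tsv", sep="\t")
        if self.global_tests is not None:
            self.global_tests.to_csv(outdir / "global_tests.tsv", sep="\t")
        if self.nodal_tests:
            for metric, df in self.nodal_tests.items():
                df.to_csv(outdir / f"nodal_tests_{metric}.tsv", sep="\t")
        if self.cohort_summary is not None:
            self.cohort_summary.to_csv(outdir / "cohort_table.tsv", sep="\t")
        if self.ratio_tests is not None:
            self.ratio_tests.to_csv(outdir / "volume_ratio_tests.tsv", sep="\t")
        if self.logistic_results is not None and len(self.logistic_results):
            self.logistic_results.to_csv(outdir / "logistic_or.tsv", sep="\t")
        if self.admission_diagnostics is not None:
            self.admission_diagnostics.to_csv(
                outdir / "density_diagnostics.tsv", sep="\t", index=False
            )
        config = self.model.config_dict()
        manifest = {
            "scnkit_version": __version__,
            "config": config,
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()
            ).hexdigest(),
            "stage_seeds": self.stage_seeds,
            "density_bounds": list(self.density_bounds),
            "n_admitted_densities": len(self.admitted_densities),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        return outdir
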