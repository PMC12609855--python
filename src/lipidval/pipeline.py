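"""End-to-end study replica: cohort -> scoring -> validation -> report bundle.

``run_validation`` executes the whole temporal-validation workflow from a
single YAML-able configuration: cohort synthesis (or CSV load) and
eligibility filtering, endpoint simulation under configurable calibration
drift, discrimination/calibration assessment, logistic recalibration,
decision-curve analysis, minimum-sample-size calculation, case-mix/refit/
imputation benchmarking, and subgroup fairness. Every table is written as
machine-readable CSV/JSON next to its figure, and a manifest with SHA-256
checksums plus the seeds and configuration hash makes a run reproducible and
auditable. Stage failures abort with the stage name in the message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import benchmarking, cohort as cohort_mod, dca, fairness, models
from . import performance, plots, samplesize, update
from .exceptions import LipidvalError, ParameterError, SchemaError


@dataclass
class StudyConfig:
    """Declarative description of one validation run."""

    endpoint: str = "nonhdl"
    cohort_file: str | None = None           # CSV path; else synthesise
    cohort_spec: dict = field(default_factory=dict)
    model_file: str | None = None            # JSON/YAML path; else shipped
    apply_eligibility: bool = True
    drift_intercept: float = 0.0
    drift_slope: float = 1.0
    recalibration_method: str = "joint"
    dca_grid: dict = field(default_factory=dict)   # start/stop/step
    run_samplesize: bool = True
    benchmark_B: int = 1000
    run_benchmark: bool = True
    run_fairness: bool = True
    fairness_covariates: list = field(default_factory=list)
    calibration_bins: int = 10
    seed: int = 0
    outdir: str = "lipidval_report"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        doc = yaml.safe_load(open(path, "r", encoding="utf-8").read()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    """In-memory handles to every stage output plus the on-disk artifacts."""

    config: StudyConfig
    cohort: pd.DataFrame
    exclusion_log: pd.DataFrame
    model: models.LogisticModel
    validation: performance.ValidationReport
    recalibration: update.RecalibrationResult
    decision_curve: dca.DecisionCurve
    samplesize: samplesize.SampleSizeResult | None
    benchmarks: list
    fairness_table: pd.DataFrame | None
    artifacts: dict = field(default_factory=dict)


def _percent(events: int, n: int, decimals: int = 1) -> float:
    """Prevalence as the percentage a study report would print."""
    if n <= 0:
        raise ParameterError("n must be positive")
    return round(100.0 * events / n, decimals)


def _load_or_generate_cohort(config: StudyConfig):
    if config.cohort_file is not None:
        path = Path(config.cohort_file)
        if not path.exists():
            raise ParameterError(f"cohort file not found: {path}")
        return cohort_mod.read_cohort(path)
    spec = cohort_mod.CohortSpec(**{"seed": config.seed, **config.cohort_spec})
    return cohort_mod.generate_cohort(spec)


def _resolve_model(config: StudyConfig) -> models.LogisticModel:
    if config.model_file is not None:
        return models.load_model(config.model_file)
    return models.load_shipped(config.endpoint)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage label."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, LipidvalError):
                exc.args = (f"[stage:{name}] {exc}",)
            return False
    return _Ctx()


def run_validation(config: StudyConfig, write: bool = True) -> ReportBundle:
    """Execute all enabled stages; deterministic given config (incl. seed)."""
    with _stage("cohort"):
        cohort = _load_or_generate_cohort(config)
        model = _resolve_model(config)
        if config.apply_eligibility:
            cohort, exclusion_log = cohort_mod.apply_eligibility(cohort)
        else:
            exclusion_log = pd.DataFrame(columns=["id", "reason"])
        ycol = cohort_mod.event_column(config.endpoint)
        if ycol not in cohort.columns:
            sim = cohort_mod.OutcomeSimSpec(
                true_model=model,
                drift_intercept=config.drift_intercept,
                drift_slope=config.drift_slope,
                endpoint=config.endpoint,
                seed=config.seed + 1,
            )
            cohort = cohort_mod.simulate_outcomes(cohort, sim)

    with _stage("performance"):
        report = performance.validate(cohort, model, config.endpoint,
                                      bins=config.calibration_bins)

    with _stage("recalibration"):
        recal = update.recalibrate(model, cohort, config.endpoint,
                                   method=config.recalibration_method)

    with _stage("decision_curve"):
        y = cohort[ycol].to_numpy()
        p = models.predicted_probability(model, cohort)
        grid = dca.default_grid(**config.dca_grid) if config.dca_grid else None
        curve = dca.decision_curve(y, p, grid)

    ss_result = None
    if config.run_samplesize:
        with _stage("samplesize"):
            spec = (samplesize.LDL_SIZING if config.endpoint == "ldl"
                    else samplesize.NONHDL_SIZING)
            ss_result = samplesize.validation_sample_size(spec)

    benchmarks: list = []
    if config.run_benchmark:
        with _stage("benchmarking"):
            benchmarks = benchmarking.strategy_matrix(
                cohort, model, config.endpoint,
                B=config.benchmark_B, seed=config.seed + 2,
            )

    fair_tab = None
    if config.run_fairness:
        with _stage("fairness"):
            if config.fairness_covariates:
                defs = [fairness.SubgroupDefinition(c) if isinstance(c, str)
                        else fairness.SubgroupDefinition(**c)
                        for c in config.fairness_covariates]
            else:
                defs = fairness.default_definitions(cohort)
            fair_tab = fairness.fairness_report(cohort, model, defs,
                                                config.endpoint)

    bundle = ReportBundle(
        config=config, cohort=cohort, exclusion_log=exclusion_log,
        model=model, validation=report, recalibration=recal,
        decision_curve=curve, samplesize=ss_result, benchmarks=benchmarks,
        fairness_table=fair_tab,
    )
    if write:
        with _stage("report"):
            _write_bundle(bundle)
    return bundle


#: Integer-coded columns that are nominal, not continuous.
_CATEGORICAL_COLUMNS = ("male", "isco_code", "y_ldl", "y_nonhdl")


def describe_cohorts(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame,
                     tests: dict | None = None) -> pd.DataFrame:
    """Descriptive comparison table of two cohorts on their shared columns.

    Continuous columns report mean (SD) with an independent-sample t-test by
    default ("ranksum" opts into Wilcoxon); binary/categorical columns report
    counts (%) with Fisher's exact test (chi-squared beyond 2x2). The test
    per column is declared, not inferred from a normality test.
    """
    shared = [c for c in cohort_a.columns if c in cohort_b.columns
              and c not in ("id", "icd10_codes", "lipid_meds")]
    if not shared:
        raise SchemaError("cohorts share no comparable columns")
    tests = tests or {}
    rows = []
    for col in shared:
        a, b = cohort_a[col], cohort_b[col]
        is_categorical = (
            col in _CATEGORICAL_COLUMNS
            or not pd.api.types.is_numeric_dtype(a)
            or set(pd.unique(pd.concat([a, b]))) <= {0, 1}
        )
        if is_categorical:
            table = pd.crosstab(
                np.repeat(["a", "b"], [len(a), len(b)]),
                pd.concat([a, b], ignore_index=True),
            )
            if table.shape == (2, 2):
                _, pval = stats.fisher_exact(table.to_numpy())
                test_name = "fisher"
            else:
                _, pval, _, _ = stats.chi2_contingency(table.to_numpy())
                test_name = "chi2"
            pct_a = 100 * a.mean() if pd.api.types.is_numeric_dtype(a) else np.nan
            pct_b = 100 * b.mean() if pd.api.types.is_numeric_dtype(b) else np.nan
            rows.append({"column": col, "type": "categorical",
                         "summary_a": f"{pct_a:.1f}%" if pct_a == pct_a else "(counts)",
                         "summary_b": f"{pct_b:.1f}%" if pct_b == pct_b else "(counts)",
                         "test": test_name, "p_value": float(pval)})
        else:
            which = tests.get(col, "t")
            if which == "ranksum":
                _, pval = stats.ranksums(a, b)
            elif which == "t":
                _, pval = stats.ttest_ind(a, b, equal_var=False)
            else:
                raise ParameterError(f"test {which!r} for column {col!r}")
            rows.append({"column": col, "type": "continuous",
                         "summary_a": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                         "summary_b": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                         "test": which, "p_value": float(pval)})
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < 0.05
    return out


# ---------------------------------------------------------------------------
# Bundle serialisation
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_bundle(bundle: ReportBundle) -> None:
    outdir = Path(bundle.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    ycol = cohort_mod.event_column(cfg.endpoint)
    y = bundle.cohort[ycol].to_numpy()
    p = models.predicted_probability(bundle.model, bundle.cohort)

    files: dict[str, Path] = {}

    cohort_mod.write_cohort(bundle.cohort, outdir / "cohort.csv")
    files["cohort"] = outdir / "cohort.csv"
    cohort_mod.write_exclusion_log(bundle.exclusion_log,
                                   outdir / "exclusion_log.csv")
    files["exclusion_log"] = outdir / "exclusion_log.csv"

    metrics = performance.report_to_dict(bundle.validation)
    metrics["prevalence_percent"] = _percent(bundle.validation.events,
                                             bundle.validation.n)
    (outdir / "validation.json").write_text(json.dumps(metrics, indent=2))
    files["validation"] = outdir / "validation.json"
    bundle.validation.curve.points.to_csv(outdir / "calibration_curve.csv",
                                          index=False)
    files["calibration_curve"] = outdir / "calibration_curve.csv"

    recal = bundle.recalibration
    models.save_model(recal.updated_model, outdir / "updated_model.json")
    files["updated_model"] = outdir / "updated_model.json"
    (outdir / "updated_equation.txt").write_text(
        update.emit_equation(recal.updated_model), encoding="utf-8"
    )
    files["updated_equation"] = outdir / "updated_equation.txt"
    (outdir / "recalibration.json").write_text(json.dumps({
        "alpha": recal.alpha, "beta": recal.beta, "method": recal.method,
        "post": performance.report_to_dict(recal.post_metrics),
    }, indent=2))
    files["recalibration"] = outdir / "recalibration.json"

    bundle.decision_curve.to_frame().to_csv(outdir / "decision_curve.csv",
                                            index=False)
    files["decision_curve"] = outdir / "decision_curve.csv"

    if bundle.samplesize is not None:
        ss = bundle.samplesize
        (outdir / "samplesize.json").write_text(json.dumps({
            "n_cstat": ss.n_cstat, "n_slope": ss.n_slope, "n_oe": ss.n_oe,
            "n_required": ss.n_required, "diagnostics": ss.diagnostics,
        }, indent=2))
        files["samplesize"] = outdir / "samplesize.json"

    if bundle.benchmarks:
        benchmarking.matrix_to_frame(bundle.benchmarks).to_csv(
            outdir / "benchmark_matrix.csv", index=False
        )
        files["benchmark_matrix"] = outdir / "benchmark_matrix.csv"

    if bundle.fairness_table is not None:
        bundle.fairness_table.to_csv(outdir / "fairness.csv", index=False)
        files["fairness"] = outdir / "fairness.csv"

    plots.roc_figure(y, p, outdir / "roc.png")
    files["roc_figure"] = outdir / "roc.png"
    plots.calibration_figure(bundle.validation, outdir / "calibration.png")
    files["calibration_figure"] = outdir / "calibration.png"
    plots.decision_curve_figure(bundle.decision_curve, outdir / "dca.png")
    files["dca_figure"] = outdir / "dca.png"

    config_doc = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "seed": cfg.seed,
        "artifacts": {k: {"file": v.name, "sha256": _sha256(v)}
                      for k, v in files.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    files["manifest"] = outdir / "manifest.json"
    bundle.artifacts = {k: str(v) for k, v in files.items()}
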