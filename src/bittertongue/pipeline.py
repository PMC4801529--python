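"""End-to-end bitterness calibration pipeline.

Stages: screen assessor scores (Grubbs), assemble the sensor matrix,
select the number of latent variables (RCS plateau), fit the robust
calibration, map and classify outliers, retrain on the cleaned set with
the outlier fraction set to zero (classical path), and benchmark all four
methods (robust PLS, MLR, classical PLS, LSSVM) before and after
screening.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import benchmarks, diagnostics, ingest, panel, selection
from .dataset import Dataset
from .robust import equation_original_form, rsimpls_fit

log = logging.getLogger("bittertongue")


@dataclass
class PipelineConfig:
    """Pipeline settings; every field can be overridden from a YAML file."""

    features_path: str = None  # wide sensor-matrix CSV
    replicates_path: str = None  # long replicate CSV (alternative input)
    response_path: str = None  # per-sample response CSV
    assessor_path: str = None  # long assessor CSV (alternative input)
    seed: int = 0
    alpha: float = 0.75
    k: int = None  # fixed number of latent variables; None = select
    k_max: int = None
    gammas: tuple = (0.0, 0.5, 1.0)
    plateau_tol: float = 0.05
    sr_cutoff: float = 2.5
    sd_quantile: float = 0.975
    grubbs_alpha: float = 0.05
    n_last_replicates: int = 4
    exclude_classes: tuple = ("bad_leverage", "vertical")
    manual_exclude: tuple = ()
    manual_include: tuple = ()
    lssvm_reg_grid: tuple = benchmarks.DEFAULT_REG_GRID
    lssvm_width_grid: tuple = benchmarks.DEFAULT_WIDTH_GRID
    run_benchmarks: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gammas", "exclude_classes", "manual_exclude",
                    "manual_include", "lssvm_reg_grid", "lssvm_width_grid"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def echo(self) -> str:
        doc = asdict(self)
        for k, v in doc.items():
            if isinstance(v, tuple):
                doc[k] = list(v)
        return yaml.safe_dump(doc, sort_keys=True)


@dataclass
class ComparisonReport:
    """Aggregated pipeline output."""

    config_echo: str
    chosen_k: int
    selection_curve: selection.SelectionCurve
    pre_model: object
    post_model: object
    diagnostics: diagnostics.DiagnosticsResult
    excluded_ids: list
    retained_n: int
    benchmark_results: list
    panel_removals: dict = field(default_factory=dict)

    def benchmark_table(self):
        return benchmarks.results_table(self.benchmark_results)

    def format_text(self) -> str:
        lines = []
        pre_eq = equation_original_form(self.pre_model)
        post_eq = equation_original_form(self.post_model)
        lines.append("bittertongue comparison report")
        lines.append("==============================")
        lines.append("")
        lines.append(f"latent variables (RCS plateau, gamma=0.5): k = {self.chosen_k}")
        lines.append(f"argmin-RCS k: {self.selection_curve.argmin_k}")
        lines.append("")
        lines.append("selection curve (gamma=0.5):")
        curve = self.selection_curve.curve(0.5)
        for _, row in curve.iterrows():
            lines.append(
                f"  k={int(row['k'])}  R-RMSE={row['r_rmse']:.4f}  "
                f"R-RMSECV={row['r_rmsecv']:.4f}  RCS={row['rcs']:.4f}"
            )
        lines.append("")
        lines.append("outlier map:")
        lines.append(
            f"  cutoffs: |Sr| > {self.diagnostics.sr_cutoff:.4g}, "
            f"SD > {self.diagnostics.sd_cutoff:.4f}"
        )
        for label in diagnostics.LABELS[1:]:
            ids = [
                str(i)
                for i, lab in zip(self.diagnostics.ids, self.diagnostics.labels)
                if lab == label
            ]
            lines.append(f"  {label}: {', '.join(ids) if ids else '(none)'}")
        lines.append(f"  excluded: {', '.join(map(str, self.excluded_ids)) or '(none)'}")
        lines.append(f"  retained samples: {self.retained_n}")
        lines.append("")
        lines.append("full-data robust calibration (original sensor units):")
        lines.append(f"  {pre_eq.format()}")
        lines.append(f"  robust residual scale s = {self.pre_model.residual_scale:.4f}")
        lines.append("")
        lines.append("post-screen calibration (outlier fraction set to 0):")
        lines.append(f"  {post_eq.format()}")
        lines.append(f"  residual scale s = {self.post_model.residual_scale:.4f}")
        if self.benchmark_results:
            lines.append("")
            lines.append("benchmark (LOOCV):")
            for r in self.benchmark_results:
                lines.append(
                    f"  {r.method:6s} {r.dataset_variant:11s} "
                    f"RMSECV={r.rmsecv:.4f}  R2_CV={r.r2_cv:.4f}"
                )
        lines.append("")
        lines.append("config:")
        lines.extend("  " + ln for ln in self.config_echo.splitlines())
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.txt").write_text(self.format_text())
        self.selection_curve.to_csv(outdir / "selection_curve.csv")
        self.diagnostics.to_csv(outdir / "outlier_map.csv")
        if self.benchmark_results:
            self.benchmark_table().to_csv(
                outdir / "benchmark.csv", index=False, float_format="%.10g"
            )
        (outdir / "model_equation.txt").write_text(
            "pre_screen:  " + equation_original_form(self.pre_model).format() + "\n"
            "post_screen: " + equation_original_form(self.post_model).format() + "\n"
        )
        self.pre_model.save(outdir / "model_pre_screen.json")
        self.post_model.save(outdir / "model_post_screen.json")


def count_retained(n_total: int, excluded_ids) -> int:
    """Samples left after exclusion; ids must be distinct and in 1..n_total."""
    excluded = list(excluded_ids)
    if len(set(excluded)) != len(excluded):
        raise ValueError("excluded ids are not distinct")
    for i in excluded:
        if not 1 <= int(i) <= n_total:
            raise ValueError(f"excluded id {i} outside 1..{n_total}")
    retained = n_total - len(excluded)
    if retained == 0:
        import warnings

        warnings.warn("all samples excluded: nothing left to fit", stacklevel=2)
    return retained


def load_dataset(config: PipelineConfig) -> tuple[Dataset, dict]:
    """Assemble the Dataset from the configured input files.

    Returns the dataset and the per-sample Grubbs removal log (empty when
    the response file already holds per-sample means).
    """
    removals: dict = {}
    if config.replicates_path:
        series = ingest.read_replicates(config.replicates_path)
        feats = ingest.assemble_matrix(series, n_last=config.n_last_replicates)
    elif config.features_path:
        feats = ingest.read_sensor_matrix(config.features_path)
    else:
        raise ValueError("config needs features_path or replicates_path")

    if config.assessor_path:
        table = panel.read_assessor_scores(config.assessor_path)
        records, removals = panel.screen_panel_table(table, alpha=config.grubbs_alpha)
        resp = records
    elif config.response_path:
        import pandas as pd

        resp = pd.read_csv(config.response_path)
    else:
        raise ValueError("config needs response_path or assessor_path")

    ycol = "mean" if "mean" in resp.columns else "bitterness"
    merged = feats.merge(
        resp[["sample_id", ycol]], on="sample_id", how="left", validate="1:1"
    )
    unmatched = merged.loc[merged[ycol].isna(), "sample_id"].tolist()
    if unmatched:
        raise ValueError(f"no response for sample ids {unmatched}")
    sensors = [c for c in feats.columns if c != "sample_id"]
    ds = Dataset(
        merged[sensors].to_numpy(float),
        merged[ycol].to_numpy(float),
        ids=merged["sample_id"].to_numpy(),
        sensor_names=sensors,
    )
    return ds, removals


def _select_k(dataset: Dataset, config: PipelineConfig, *, alpha: float):
    k_cap = min(dataset.p, dataset.n - 2)
    k_max = min(config.k or config.k_max or k_cap, k_cap)
    return selection.select_num_components(
        dataset.X,
        dataset.y,
        k_max,
        gammas=config.gammas,
        plateau_tol=config.plateau_tol,
        alpha=alpha,
        seed=config.seed,
    )


def compare_methods(
    dataset: Dataset,
    excluded_ids,
    config: PipelineConfig = None,
    *,
    hyperparams: dict = None,
    seed: int = None,
) -> list:
    """Benchmark the four methods on the pre- and post-screen variants.

    LSSVM is retuned and the PLS/robust-PLS component count re-selected
    per variant unless fixed values are supplied via ``hyperparams``
    (keys ``pls``, ``rpls``, ``lssvm`` with per-method dicts).
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    hyperparams = dict(hyperparams or {})
    results = []
    variants = [
        ("pre_screen", dataset),
        ("post_screen", dataset.drop_ids(excluded_ids)),
    ]
    for variant, ds in variants:
        t0 = time.perf_counter()
        if "pls" in hyperparams:
            k_pls = hyperparams["pls"]["k"]
        else:
            k_pls = _select_k_generic(ds, config, alpha=1.0)
        if "rpls" in hyperparams:
            k_rpls = hyperparams["rpls"]["k"]
        else:
            k_rpls = _select_k_generic(ds, config, alpha=config.alpha)
        if "lssvm" in hyperparams:
            hp_lssvm = dict(hyperparams["lssvm"])
        else:
            hp_lssvm, _ = benchmarks.tune_lssvm(
                ds.X,
                ds.y,
                config.lssvm_reg_grid,
                config.lssvm_width_grid,
                seed=seed,
            )
        for method, hp in (
            ("rpls", {"k": k_rpls, "alpha": config.alpha}),
            ("mlr", {}),
            ("pls", {"k": k_pls}),
            ("lssvm", hp_lssvm),
        ):
            results.append(
                benchmarks.evaluate_method(
                    ds.X, ds.y, method, hp, seed=seed, dataset_variant=variant
                )
            )
        log.info(
            "benchmarked %s variant (n=%d) in %.1fs",
            variant,
            ds.n,
            time.perf_counter() - t0,
        )
    return results


def _select_k_generic(ds: Dataset, config: PipelineConfig, *, alpha: float) -> int:
    if config.k is not None:
        return min(config.k, ds.n - 2, ds.p)
    return _select_k(ds, config, alpha=alpha).chosen_k


def run_pipeline(
    config: PipelineConfig, dataset: Dataset = None, outdir=None
) -> ComparisonReport:
    """Run the full analysis; optionally pass an in-memory dataset.

    Returns a :class:`ComparisonReport`; if ``outdir`` is given, the
    report and its CSV tables are written there (byte-identical across
    reruns with the same config, inputs and seed).
    """
    t_start = time.perf_counter()
    removals: dict = {}
    if dataset is None:
        dataset, removals = load_dataset(config)
        log.info("loaded dataset: n=%d, p=%d", dataset.n, dataset.p)

    log.info("selecting number of latent variables (alpha=%.2f)", config.alpha)
    curve = _select_k(dataset, config, alpha=config.alpha)
    chosen_k = min(config.k, dataset.n - 2, dataset.p) if config.k else curve.chosen_k
    log.info("chosen k = %d (argmin k = %d)", chosen_k, curve.argmin_k)

    pre_model = rsimpls_fit(
        dataset.X,
        dataset.y,
        chosen_k,
        alpha=config.alpha,
        seed=config.seed,
        sr_threshold=config.sr_cutoff,
        sd_quantile=config.sd_quantile,
        sensor_names=dataset.sensor_names,
    )
    diag = diagnostics.diagnose_model(
        pre_model,
        dataset.X,
        dataset.y,
        ids=dataset.ids,
        sr_cutoff=config.sr_cutoff,
        sd_quantile=config.sd_quantile,
    )
    excluded = [i for i in diag.flagged_ids(config.exclude_classes)]
    excluded += [i for i in config.manual_exclude if i not in excluded]
    excluded = [i for i in excluded if i not in set(config.manual_include)]
    excluded = sorted(excluded)
    retained_n = count_retained(dataset.n, excluded)
    log.info("excluded %d samples: %s", len(excluded), excluded)

    retained = dataset.drop_ids(excluded)
    post_model = rsimpls_fit(
        retained.X,
        retained.y,
        min(chosen_k, retained.n - 2),
        alpha=1.0,  # outlier fraction set to 0 on the cleaned set
        seed=config.seed,
        sensor_names=retained.sensor_names,
    )

    bench = []
    if config.run_benchmarks:
        bench = compare_methods(dataset, excluded, config)

    report = ComparisonReport(
        config_echo=config.echo(),
        chosen_k=chosen_k,
        selection_curve=curve,
        pre_model=pre_model,
        post_model=post_model,
        diagnostics=diag,
        excluded_ids=excluded,
        retained_n=retained_n,
        benchmark_results=bench,
        panel_removals=removals,
    )
    if outdir is not None:
        report.write(outdir)
    log.info("pipeline finished in %.1fs", time.perf_counter() - t_start)
    return report


def configure_logging(verbose: bool = True, stream=sys.stderr) -> None:
    handler = logging.StreamHandler(stream)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
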