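"""End-to-end orchestration: exclusion cascade, QC, scoring, fitting, reporting.

The pipeline wires the modules together in the study's narrative order:

1. participant exclusion cascade (measured at 12 months -> white-European
   ethnicity -> genotype QC pass -> no diabetes medication),
2. SNP and individual genotype QC, HWE evaluation, same-locus LD report,
3. mean imputation and the genetic predisposition score,
4. trait derivation (change scores and log-ratio outcomes),
5. the sequence of selected regressions and the chain graph,
6. prediction queries (e.g. outcome ratios at GPS quartiles),

and writes deterministic TSV/DOT/JSON artifacts so a run can be reproduced
byte-for-byte from its report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chaingraph import (
    PredictionQuery,
    build_graph,
    fit_all,
    predict_outcome_ratio,
    symmetric_associations,
    validate_ordering,
    variance_explained,
)
from .config import (
    default_config,
    interaction_candidates_from_config,
    ordering_from_config,
)
from .errors import ConfigurationError, SchemaError
from .genotyping import (
    GenotypeMatrix,
    SnpPanel,
    apply_individual_qc,
    apply_snp_qc,
    compute_gps,
    hwe_qc,
    impute_missing_mean,
    read_genotype_csv,
    read_panel,
    same_locus_ld,
)
from .synthetic import SyntheticConfig, generate_cohort, recovery_metrics, true_graph
from .traits import derive_changes

__all__ = [
    "ExclusionStep",
    "ExclusionCascade",
    "DEFAULT_FILTERS",
    "apply_exclusions",
    "genotype_qc",
    "RunReport",
    "run_pipeline",
    "benchmark_recovery",
]


@dataclass
class ExclusionStep:
    name: str
    retained: int
    excluded: int


@dataclass
class ExclusionCascade:
    initial: int
    steps: list[ExclusionStep] = field(default_factory=list)

    @property
    def final_retained(self) -> int:
        return self.steps[-1].retained if self.steps else self.initial

    def validate(self) -> None:
        previous = self.initial
        for step in self.steps:
            if step.retained + step.excluded != previous:
                raise ConfigurationError(
                    f"cascade step {step.name!r} does not conserve counts"
                )
            previous = step.retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": s.name, "retained": s.retained, "excluded": s.excluded}
                for s in self.steps
            ]
        )


FilterFn = Callable[[pd.DataFrame, dict], pd.Series]


def _require_flag(df: pd.DataFrame, column: str) -> pd.Series:
    if column not in df.columns:
        raise ConfigurationError(f"exclusion filter needs missing column {column!r}")
    return df[column].astype(bool)


DEFAULT_FILTERS: list[tuple[str, FilterFn]] = [
    ("measured_12m", lambda df, ctx: _require_flag(df, "measured_12m")),
    (
        "white_european",
        lambda df, ctx: _require_flag(df, "ethnicity_white_european"),
    ),
    (
        "genotype_qc",
        lambda df, ctx: pd.Series(df.index.isin(ctx["qc_pass_ids"]), index=df.index),
    ),
    (
        "no_t2dm_medication",
        lambda df, ctx: ~_require_flag(df, "t2dm_medication"),
    ),
]


def apply_exclusions(
    cohort: pd.DataFrame,
    qc_pass_ids: Sequence,
    filters: Sequence[tuple[str, FilterFn]] = tuple(DEFAULT_FILTERS),
) -> tuple[pd.DataFrame, ExclusionCascade]:
    """Apply the ordered participant filters and record the cascade."""
    cascade = ExclusionCascade(initial=len(cohort))
    ctx = {"qc_pass_ids": set(qc_pass_ids)}
    current = cohort
    for name, fn in filters:
        keep = fn(current, ctx)
        retained = current[keep]
        cascade.steps.append(
            ExclusionStep(
                name=name,
                retained=len(retained),
                excluded=len(current) - len(retained),
            )
        )
        current = retained
    cascade.validate()
    return current, cascade


def genotype_qc(
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    *,
    call_rate_threshold: float = 0.95,
    max_failed_snps: int = 3,
    hwe_alpha: float = 0.05,
    hwe_tests: int | None = None,
):
    """SNP call-rate filter, individual filter, HWE evaluation, LD report."""
    matrix = genotypes.restrict_snps(
        [s for s in panel.snp_ids if s in genotypes.counts.columns]
    )
    matrix, snp_report = apply_snp_qc(matrix, call_rate_threshold)
    matrix, indiv_report = apply_individual_qc(matrix, max_failed_snps)
    n_tests = hwe_tests if hwe_tests is not None else len(panel)
    matrix, hwe_report = hwe_qc(matrix, hwe_alpha, n_tests)
    report = snp_report.merge(indiv_report).merge(hwe_report)
    report.ld_pairs = same_locus_ld(matrix, panel)
    return matrix, report


@dataclass
class RunReport:
    """Everything needed to rerun an analysis identically."""

    config: dict
    seed: int
    version: str
    cascade: ExclusionCascade
    model_n: dict[str, int]
    r_squared: dict[str, float]
    predictions: list[dict]
    artifacts: dict[str, str]

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "cascade": [
                {"step": s.name, "retained": s.retained, "excluded": s.excluded}
                for s in self.cascade.steps
            ],
            "model_n": self.model_n,
            "r_squared": self.r_squared,
            "predictions": self.predictions,
            "artifacts": self.artifacts,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _coefficient_table(fits: dict) -> pd.DataFrame:
    rows = []
    for response in sorted(fits):
        fit = fits[response]
        for term in fit.terms:
            for col in fit.term_cols[term.name]:
                rows.append(
                    {
                        "response": response,
                        "term": term.name,
                        "column": col,
                        "coef": fit.params.loc[col, "coef"],
                        "se": fit.params.loc[col, "se"],
                        "p": fit.params.loc[col, "p"],
                        "term_p": fit.term_p[term.name],
                        "n": fit.n,
                        "r_squared": fit.r_squared,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["response", "term", "column", "coef", "se", "p", "term_p", "n", "r_squared"],
    )
    for col in ("coef", "se", "p", "term_p", "r_squared"):
        table[col] = table[col].map(lambda v: float(f"{v:.10g}"))
    return table


def _prediction_queries(cfg: dict, fits: dict, data: pd.DataFrame) -> list[dict]:
    """Evaluate configured quartile-style prediction queries."""
    results = []
    for spec in cfg.get("predictions", []):
        target, vary = spec["target"], spec["vary"]
        fit = fits.get(target)
        if fit is None:
            continue
        used = {v for t in fit.terms for v in t.variables}
        if vary not in used:
            continue
        values: dict[str, float | str] = {}
        ordering_vars = cfg["ordering"]["variables"]
        for var in used:
            meta = ordering_vars.get(var, {})
            if meta.get("type") == "categorical":
                values[var] = meta["reference"]
            else:
                values[var] = float(data[var].mean())
        quartiles = {
            "lower_quartile": float(data[vary].quantile(0.25)),
            "median": float(data[vary].quantile(0.50)),
            "upper_quartile": float(data[vary].quantile(0.75)),
            "mean": float(data[vary].mean()),
        }
        for at in spec.get("at", ["lower_quartile", "upper_quartile"]):
            point = quartiles[at] if isinstance(at, str) else float(at)
            q = PredictionQuery(target=target, values={**values, vary: point})
            res = predict_outcome_ratio(fit, q)
            results.append(
                {
                    "target": target,
                    "vary": vary,
                    "at": at,
                    "value": point,
                    "ratio": res.ratio,
                    "percent_change": res.percent_change,
                }
            )
    return results


def run_pipeline(
    phenotype_file,
    genotype_file,
    panel_file,
    config: dict | None = None,
    outdir=None,
    seed: int = 0,
) -> RunReport:
    """Execute the full analysis and write its artifacts.

    Deterministic: identical inputs, config and seed produce byte-identical
    coefficient tables and DOT output.
    """
    cfg = config or default_config()
    outdir = Path(outdir) if outdir is not None else None

    panel = read_panel(panel_file)
    genotypes = read_genotype_csv(genotype_file, panel)
    try:
        pheno = pd.read_csv(phenotype_file, index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise SchemaError(f"phenotype ingestion: {exc}") from exc

    qc = cfg["qc"]
    matrix, qc_report = genotype_qc(
        genotypes,
        panel,
        call_rate_threshold=qc["call_rate_threshold"],
        max_failed_snps=qc["max_failed_snps"],
        hwe_alpha=qc["hwe_alpha"],
        hwe_tests=qc["hwe_tests"],
    )

    cohort, cascade = apply_exclusions(pheno, qc_pass_ids=matrix.individuals)

    gps = compute_gps(impute_missing_mean(matrix.restrict_individuals(
        [i for i in matrix.individuals if i in cohort.index]
    )))
    cohort = cohort.join(gps.scores.rename("gps"))

    tr = cfg["traits"]
    derived = derive_changes(
        cohort,
        insulin_conversion=tr["insulin_conversion"],
        calibration=(tr["calibration_ir"], tr["calibration_b"]),
        fat_energy_density=tr["fat_energy_density"],
        energy_unit=tr["energy_unit"],
    )
    data = derived.data

    ordering = ordering_from_config(cfg)
    validate_ordering(ordering, data.columns)
    alphas = cfg["alphas"]
    fits = fit_all(
        ordering,
        data,
        selection_alpha=alphas["selection"],
        interaction_candidates=interaction_candidates_from_config(cfg),
    )
    undirected = symmetric_associations(ordering, data, alphas["edge"])
    graph = build_graph(fits, undirected, ordering, alphas["edge"])

    predictions = _prediction_queries(cfg, fits, data)
    coef_table = _coefficient_table(fits)

    artifacts: dict[str, str] = {}
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        coef_table.to_csv(outdir / "coefficients.tsv", sep="\t", index=False)
        (outdir / "graph.dot").write_text(graph.to_dot())
        (outdir / "graph.json").write_text(graph.to_json())
        derived.write_tsv(outdir / "derived.tsv")
        derived.exclusions.to_csv(outdir / "trait_exclusions.tsv", sep="\t", index=False)
        cascade.to_frame().to_csv(outdir / "cascade.tsv", sep="\t", index=False)
        qc_report.write_tsv(outdir / "qc")
        (outdir / "qc" / "qc.log").write_text("\n".join(qc_report.log_lines()) + "\n")
        artifacts = {
            "coefficients": str(outdir / "coefficients.tsv"),
            "graph_dot": str(outdir / "graph.dot"),
            "graph_json": str(outdir / "graph.json"),
            "derived": str(outdir / "derived.tsv"),
            "cascade": str(outdir / "cascade.tsv"),
        }

    report = RunReport(
        config=cfg,
        seed=seed,
        version=__version__,
        cascade=cascade,
        model_n={r: fits[r].n for r in sorted(fits)},
        r_squared={r: variance_explained(fits[r]) for r in sorted(fits)},
        predictions=predictions,
        artifacts=artifacts,
    )
    if outdir is not None:
        (outdir / "run_report.json").write_text(report.to_json())
    return report


def fit_synthetic(
    config: SyntheticConfig,
    analysis_config: dict | None = None,
):
    """Generate a cohort, run derivation + fitting, and return
    (estimated graph, truth graph, fits, truth)."""
    cfg = analysis_config or default_config()
    cohort, truth = generate_cohort(config)
    cohort = cohort.join(
        compute_gps(impute_missing_mean(truth.genotypes)).scores.rename("gps")
    )
    derived = derive_changes(cohort)
    data = derived.data
    ordering = ordering_from_config(cfg)
    alphas = cfg["alphas"]
    candidates = interaction_candidates_from_config(cfg)
    fits = fit_all(ordering, data, alphas["selection"], candidates)
    undirected = symmetric_associations(ordering, data, alphas["edge"])
    estimated = build_graph(fits, undirected, ordering, alphas["edge"])
    return estimated, true_graph(truth), fits, truth


def benchmark_recovery(
    n_values: Sequence[int] = (2000,),
    effect_scales: Sequence[float] = (1.0,),
    replicates: int = 200,
    seed: int = 20_001,
    analysis_config: dict | None = None,
    collect_coefficients: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Structure-recovery benchmark over a grid of n and effect scale.

    Per cell, ``replicates`` synthetic cohorts are generated with distinct
    seeds derived from ``seed`` and scored against the planted graph; the
    cell row reports mean edge TPR, the spurious-edge rate, coefficient
    RMSE, and per-edge recovery fractions.  ``collect_coefficients`` names
    (response, term) pairs whose fitted coefficient, SE and 2-SE coverage of
    the planted value are also summarised.
    """
    cfg = analysis_config or default_config()
    candidates = interaction_candidates_from_config(cfg)
    rows = []
    for n in n_values:
        for scale in effect_scales:
            tprs, fprs, rmses = [], [], []
            edge_hits: dict[tuple[str, str], int] = {}
            coef_cov: dict[tuple[str, str], list[int]] = {
                key: [] for key in collect_coefficients
            }
            coef_est: dict[tuple[str, str], list[float]] = {
                key: [] for key in collect_coefficients
            }
            truth_keys = None
            for rep in range(replicates):
                rep_seed = (seed + 7919 * rep + 104729 * (n + int(100 * scale))) % (2**31)
                sc = SyntheticConfig(n=n, seed=rep_seed, effect_scale=scale)
                estimated, tgraph, fits, truth = fit_synthetic(sc, cfg)
                metrics = recovery_metrics(estimated, tgraph, candidates)
                if not np.isnan(metrics.tpr):
                    tprs.append(metrics.tpr)
                fprs.append(metrics.fpr)
                rmses.append(metrics.rmse)
                truth_keys = {e.key: e for e in tgraph.directed_edges}
                est_keys = estimated.directed_keys()
                for key in truth_keys:
                    edge_hits[key] = edge_hits.get(key, 0) + (key in est_keys)
                for response, term_name in collect_coefficients:
                    fit = fits[response]
                    term = fit.term(term_name)
                    true_coef = _lookup_true_coef(truth, response, term_name)
                    if term is None:
                        coef_cov[(response, term_name)].append(0)
                        continue
                    col = fit.term_cols[term_name][0]
                    est = float(fit.params.loc[col, "coef"])
                    se = float(fit.params.loc[col, "se"])
                    coef_est[(response, term_name)].append(est)
                    coef_cov[(response, term_name)].append(
                        int(abs(est - true_coef) <= 2 * se)
                    )
            row = {
                "n": n,
                "effect_scale": scale,
                "replicates": replicates,
                "tpr": float(np.mean(tprs)) if tprs else float("nan"),
                "fpr": float(np.mean(fprs)),
                "rmse": float(np.mean(rmses)),
                "min_edge_recovery": (
                    min(edge_hits.values()) / replicates if edge_hits else float("nan")
                ),
            }
            for key, hits in sorted(edge_hits.items()):
                row[f"recover[{key[0]}->{key[1]}]"] = hits / replicates
            for key in collect_coefficients:
                cov = coef_cov[key]
                row[f"coef_cov[{key[0]}:{key[1]}]"] = float(np.mean(cov)) if cov else float("nan")
                est = coef_est[key]
                row[f"coef_mean[{key[0]}:{key[1]}]"] = float(np.mean(est)) if est else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def _lookup_true_coef(truth, response: str, term_name: str) -> float:
    model = truth.models[response]
    if ":" in term_name:
        key = tuple(sorted(term_name.split(":")))
        return float(model.interactions.get(key, 0.0))
    coef = model.mains.get(term_name, 0.0)
    if isinstance(coef, dict):
        if len(coef) != 1:
            raise ConfigurationError(f"{term_name}: block coefficients are per-level")
        coef = next(iter(coef.values()))
    return float(coef)
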