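"""End-to-end discovery -> testing -> external-validation orchestration.

The discovery workflow mirrors the published design: standardize arrays,
collapse probes (when probe-level), select the extreme-outcome discovery
subset (favorable: alive and relapse-free beyond the horizon; fatal: dead
with relapse within it), screen differential genes, run the weighted-voting
cross-validation to size and pick the signature, fit the Cox risk score
with its median cutoff, and evaluate every dataset with the survival
suite.  The fitted model (weights + cutoff) is frozen; validation never
refits anything.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .diffexp import differential_expression, select_differential
from .risk import CoxRiskScore, RiskScoreResults, multivariable_adjustment
from .survival import (
    harrell_c,
    kaplan_meier,
    log_rank,
    survival_at,
    time_dependent_roc,
)
from .voting import WeightedVoting, classification_metrics

__all__ = [
    "PipelineConfig",
    "DiscoverySplit",
    "split_discovery",
    "DatasetEvaluation",
    "evaluate_dataset",
    "DiscoveryReport",
    "run_discovery",
    "run_validation",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the discovery pipeline (defaults follow the study design)."""

    alpha: float = 0.01
    n_folds: int = 5
    n_repeats: int = 100
    optimal_n_tolerance: float = 1.0
    horizon: float = 5.0
    seed: int = 0
    standardize: bool = True
    #: override the curve-chosen signature size (None = use optimal N)
    signature_size: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("n_folds >= 2 and n_repeats >= 1 required")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.optimal_n_tolerance < 0:
            raise ValueError("optimal_n_tolerance must be non-negative")


@dataclass(frozen=True)
class DiscoverySplit:
    """Partition of a cohort by the extreme-outcome discovery rule."""

    favorable: list[str]
    fatal: list[str]
    testing: list[str]

    @property
    def discovery(self) -> list[str]:
        return self.favorable + self.fatal


def split_discovery(annotation: pd.DataFrame, horizon: float = 5.0) -> DiscoverySplit:
    """Favorable / fatal / testing split of a cohort.

    favorable: alive, relapse-free, followed strictly beyond the horizon;
    fatal: dead with relapse strictly within the horizon; testing:
    everyone else (including patients exactly at the horizon, whose status
    at the boundary is indeterminate).  The three sets partition the
    cohort.
    """
    if "vital_status" not in annotation.columns:
        raise ValueError("annotation must carry vital_status for the discovery split")
    rio.validate_annotation(annotation)
    alive = annotation["vital_status"] == "alive"
    favorable = alive & (annotation["relapse"] == 0) & (annotation["rfs_time"] > horizon)
    fatal = (
        (annotation["vital_status"] == "dead")
        & (annotation["relapse"] == 1)
        & (annotation["rfs_time"] < horizon)
    )
    testing = ~(favorable | fatal)
    return DiscoverySplit(
        favorable=annotation.index[favorable].tolist(),
        fatal=annotation.index[fatal].tolist(),
        testing=annotation.index[testing].tolist(),
    )


@dataclass
class DatasetEvaluation:
    """Survival evaluation of one scored cohort."""

    name: str
    n: int
    assignments: pd.DataFrame = field(repr=False)
    km_rates: dict  # {group: {year: RFS rate}}
    logrank_p: float | None
    cox_table: pd.DataFrame | None = field(repr=False, default=None)
    auc: float | None = None
    c_index: float | None = None
    notes: list[str] = field(default_factory=list)


def evaluate_dataset(
    risk: RiskScoreResults,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    name: str,
    horizon: float = 5.0,
    rate_years: tuple[float, ...] = (3.0, 5.0),
) -> DatasetEvaluation:
    """Score, group and evaluate a cohort against a frozen risk model."""
    missing = pd.Index(risk.genes).difference(expression.index)
    if len(missing) > 0:
        raise ValueError(f"dataset lacks signature genes: {missing.tolist()}")
    annotation = annotation.reindex(expression.columns)
    assignments = risk.assign(expression)
    time = annotation["rfs_time"].to_numpy()
    event = annotation["event"].to_numpy()
    notes: list[str] = []

    km_rates: dict[str, dict[float, float]] = {}
    for group in ("high-risk", "low-risk"):
        mask = (assignments["group"] == group).to_numpy()
        if mask.sum() == 0:
            notes.append(f"no patients in {group} group")
            continue
        curve = kaplan_meier(time[mask], event[mask])
        km_rates[group] = {yr: survival_at(curve, yr) for yr in rate_years}

    logrank_p: float | None = None
    if assignments["group"].nunique() == 2:
        logrank_p = log_rank(assignments["group"].to_numpy(), time, event).p
    else:
        notes.append("log-rank skipped: single risk group")

    cox_table = None
    try:
        cox_table = multivariable_adjustment(annotation, assignments["group"])
    except Exception as exc:  # convergence/collinearity reported, not hidden
        notes.append(f"Cox adjustment failed: {exc}")

    auc = None
    try:
        auc = time_dependent_roc(
            assignments["score"].to_numpy(), time, event, horizon=horizon
        ).auc
    except ValueError as exc:
        notes.append(f"time-dependent ROC unavailable: {exc}")

    c_index = None
    try:
        c_index = harrell_c(assignments["score"].to_numpy(), time, event).c_index
    except ValueError as exc:
        notes.append(f"C-index unavailable: {exc}")
    return DatasetEvaluation(
        name=name,
        n=len(annotation),
        assignments=assignments,
        km_rates=km_rates,
        logrank_p=logrank_p,
        cox_table=cox_table,
        auc=auc,
        c_index=c_index,
        notes=notes,
    )


@dataclass
class DiscoveryReport:
    """Everything the discovery run produced."""

    status: str
    config: PipelineConfig
    split: DiscoverySplit
    de_results: pd.DataFrame = field(repr=False)
    de_genes: list[str] = field(default_factory=list)
    error_curve: pd.Series | None = field(repr=False, default=None)
    optimal_n: int | None = None
    frequencies: pd.Series | None = field(repr=False, default=None)
    signature: list[str] = field(default_factory=list)
    voting_metrics: dict | None = None
    risk: RiskScoreResults | None = None
    evaluations: dict[str, DatasetEvaluation] = field(default_factory=dict)


def run_discovery(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    probe_map: pd.Series | None = None,
    outdir=None,
) -> DiscoveryReport:
    """Run the full discovery workflow on one cohort.

    ``expression`` may be probe-level when ``probe_map`` is given (probes
    are averaged per gene before standardization).  Deterministic for a
    fixed config: the only randomness is the cross-validation partitioning,
    driven by ``config.seed``.
    """
    annotation = annotation.reindex(expression.columns)
    if probe_map is not None:
        expression = rio.collapse_probes(expression, probe_map)
    if config.standardize:
        expression = rio.zscore_standardize(expression)

    split = split_discovery(annotation, horizon=config.horizon)
    if len(split.fatal) < 2 or len(split.favorable) < 2:
        raise ValueError(
            "discovery split too small: "
            f"{len(split.favorable)} favorable, {len(split.fatal)} fatal"
        )
    disc_expr = expression[split.discovery]
    labels = pd.Series(
        [sid in set(split.fatal) for sid in split.discovery],
        index=split.discovery,
        name="relapse",
    )

    de_results = differential_expression(disc_expr, labels, alpha=config.alpha)
    de_genes = select_differential(de_results, alpha=config.alpha)
    if len(de_genes) < 2:
        return DiscoveryReport(
            status="no-differential-genes",
            config=config,
            split=split,
            de_results=de_results,
            de_genes=de_genes,
        )

    model = WeightedVoting(disc_expr.loc[de_genes], labels)
    cv = model.cross_validate(
        n_folds=config.n_folds, n_repeats=config.n_repeats, seed=config.seed
    )
    optimal_n = (
        config.signature_size
        if config.signature_size is not None
        else cv.select_optimal_n(config.optimal_n_tolerance)
    )
    selection = cv.select_signature(optimal_n)

    voting_fit = WeightedVoting(disc_expr.loc[selection.selected], labels).fit()
    scores = voting_fit.decision_scores(disc_expr)
    voting_metrics = classification_metrics(
        labels.to_numpy(), voting_fit.predict(disc_expr).to_numpy(), scores.to_numpy()
    )

    risk = CoxRiskScore(
        disc_expr, annotation.loc[split.discovery], selection.selected
    ).fit()

    evaluations = {
        "discovery": evaluate_dataset(
            risk, disc_expr, annotation.loc[split.discovery], "discovery",
            horizon=config.horizon,
        )
    }
    if len(split.testing) >= 10:
        evaluations["testing"] = evaluate_dataset(
            risk, expression[split.testing], annotation.loc[split.testing],
            "testing", horizon=config.horizon,
        )

    report = DiscoveryReport(
        status="ok",
        config=config,
        split=split,
        de_results=de_results,
        de_genes=de_genes,
        error_curve=cv.error_curve,
        optimal_n=optimal_n,
        frequencies=selection.frequencies,
        signature=selection.selected,
        voting_metrics=voting_metrics,
        risk=risk,
        evaluations=evaluations,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def run_validation(
    risk: RiskScoreResults,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    name: str = "validation",
    horizon: float = 5.0,
    standardize: bool = True,
    outdir=None,
) -> DatasetEvaluation:
    """Evaluate a frozen risk model on an external cohort (never refits)."""
    annotation = annotation.reindex(expression.columns)
    if standardize:
        expression = rio.zscore_standardize(expression)
    evaluation = evaluate_dataset(risk, expression, annotation, name, horizon=horizon)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        evaluation.assignments.rename_axis("sample_id").to_csv(
            outdir / f"assignments_{name}.tsv", sep="\t"
        )
        (outdir / f"evaluation_{name}.json").write_text(
            json.dumps(_evaluation_dict(evaluation), indent=2)
        )
    return evaluation


# -- report persistence ----------------------------------------------------


def _evaluation_dict(ev: DatasetEvaluation) -> dict:
    return {
        "name": ev.name,
        "n": ev.n,
        "km_rates": {g: {str(y): v for y, v in d.items()} for g, d in ev.km_rates.items()},
        "logrank_p": ev.logrank_p,
        "auc": ev.auc,
        "c_index": ev.c_index,
        "notes": ev.notes,
    }


def write_report(report: DiscoveryReport, outdir) -> None:
    """Persist every table of a discovery run plus a JSON/markdown summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.de_results.rename_axis("gene_id").to_csv(outdir / "de_results.tsv", sep="\t")
    summary: dict = {
        "status": report.status,
        "config": asdict(report.config),
        "split": {
            "favorable": len(report.split.favorable),
            "fatal": len(report.split.fatal),
            "testing": len(report.split.testing),
        },
        "de_genes": report.de_genes,
    }
    if report.status == "ok":
        report.error_curve.rename_axis("N").to_csv(outdir / "cv_error_curve.tsv", sep="\t")
        report.frequencies.rename_axis("gene_id").to_csv(
            outdir / "signature_frequencies.tsv", sep="\t"
        )
        report.risk.save(outdir)
        for name, ev in report.evaluations.items():
            ev.assignments.rename_axis("sample_id").to_csv(
                outdir / f"assignments_{name}.tsv", sep="\t"
            )
            if ev.cox_table is not None:
                ev.cox_table.to_csv(outdir / f"cox_{name}.tsv", sep="\t", index=False)
        summary.update(
            {
                "optimal_n": report.optimal_n,
                "signature": report.signature,
                "voting_metrics": report.voting_metrics,
                "risk_cutoff": report.risk.cutoff,
                "risk_weights": report.risk.weights.to_dict(),
                "evaluations": {
                    name: _evaluation_dict(ev) for name, ev in report.evaluations.items()
                },
            }
        )
    (outdir / "report.json").write_text(json.dumps(summary, indent=2))
    (outdir / "report.md").write_text(render_markdown(report))


def render_markdown(report: DiscoveryReport) -> str:
    lines = [
        "# Relapse-signature discovery report",
        "",
        f"status: **{report.status}**  |  seed: {report.config.seed}",
        "",
        f"- discovery split: {len(report.split.favorable)} favorable + "
        f"{len(report.split.fatal)} fatal (testing n={len(report.split.testing)})",
        f"- differential genes (Bonferroni p < {report.config.alpha}): "
        f"{len(report.de_genes)}",
    ]
    if report.status != "ok":
        lines.append("")
        lines.append(
            "The differential screen found too few genes to build a classifier; "
            "the pipeline stopped before model fitting."
        )
        return "\n".join(lines) + "\n"
    vm = report.voting_metrics or {}
    fmt = lambda v: "NA" if v is None else f"{100 * v:.1f}%"  # noqa: E731
    vote_auc = "NA" if vm.get("auc") is None else f"{vm['auc']:.3f}"
    lines += [
        f"- optimal signature size N = {report.optimal_n}",
        f"- signature: {', '.join(report.signature)}",
        f"- discovery classification: accuracy {fmt(vm.get('accuracy'))}, "
        f"sensitivity {fmt(vm.get('sensitivity'))}, "
        f"specificity {fmt(vm.get('specificity'))}, "
        f"AUC {vote_auc}",
        f"- risk-score cutoff (discovery median): {report.risk.cutoff:.4f}",
        "",
        "| dataset | n | log-rank p | AUC@horizon | C-index |",
        "|---|---|---|---|---|",
    ]
    for name, ev in report.evaluations.items():
        p = "NA" if ev.logrank_p is None else f"{ev.logrank_p:.3g}"
        auc = "NA" if ev.auc is None else f"{ev.auc:.3f}"
        ci = "NA" if ev.c_index is None else f"{ev.c_index:.3f}"
        lines.append(f"| {name} | {ev.n} | {p} | {auc} | {ci} |")
    return "\n".join(lines) + "\n"
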