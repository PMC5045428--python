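"""Cox proportional-hazards risk score for a gene signature.

The prognostic model is the linear risk score

    RiskScore(sample) = sum_i  Exp_i * w_i

where ``w_i`` are the coefficients of the signature genes fitted *jointly*
in a multivariate Cox regression on the discovery cohort, and ``Exp_i`` the
(standardized) expression values.  Patients are dichotomized at the median
discovery score; the cutoff is frozen with the model and reused unchanged
on testing and external cohorts.

Model/results idiom::

    res = CoxRiskScore(expression, annotation, genes).fit()
    res.weights, res.cutoff          # the frozen model
    assignments = res.assign(expression_new)   # score + high/low group

Cox fits are delegated to :mod:`lifelines` (Efron tie handling, Wald
tests); non-convergence (e.g. monotone likelihood under complete
separation) propagates as an explicit error rather than being clipped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "fit_cox",
    "hr_from_coef",
    "risk_score",
    "CoxRiskScore",
    "RiskScoreResults",
    "multivariable_adjustment",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


def fit_cox(time, event, covariates: pd.DataFrame) -> pd.DataFrame:
    """Multivariate Cox PH fit; one row per covariate.

    Returns columns ``coef``, ``se``, ``hr``, ``ci_lower``, ``ci_upper``
    (95%, normal approximation on the log scale) and Wald ``p``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if (time < 0).any():
        raise ValueError("survival times must be non-negative")
    if event.sum() == 0:
        raise ValueError("need at least one observed event")
    frame = covariates.copy()
    frame["__T"] = time
    frame["__E"] = event
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(frame, duration_col="__T", event_col="__E")
    coef = cph.params_
    se = cph.standard_errors_
    table = pd.DataFrame({"coef": coef, "se": se})
    hr, lo, hi = hr_from_coef(table["coef"].to_numpy(), table["se"].to_numpy())
    table["hr"] = hr
    table["ci_lower"] = lo
    table["ci_upper"] = hi
    table["p"] = cph.summary["p"]
    table.index.name = "term"
    return table


def hr_from_coef(coef, se=None):
    """Hazard ratio (and 95% CI when ``se`` is given) from a log-hazard coef."""
    hr = np.exp(np.asarray(coef, dtype=float))
    if se is None:
        return hr
    se = np.asarray(se, dtype=float)
    if (se < 0).any():
        raise ValueError("standard errors must be non-negative")
    with np.errstate(over="ignore"):
        lo = np.exp(np.asarray(coef, dtype=float) - Z_95 * se)
        hi = np.exp(np.asarray(coef, dtype=float) + Z_95 * se)
    return hr, lo, hi


def risk_score(weights: pd.Series, expression: pd.DataFrame) -> pd.Series:
    """Linear score per sample: dot product of gene weights and expression."""
    missing = weights.index.difference(expression.index)
    if len(missing) > 0:
        raise ValueError(f"expression lacks signature genes: {missing.tolist()}")
    sub = expression.loc[weights.index]
    return pd.Series(
        weights.to_numpy() @ sub.to_numpy(), index=expression.columns, name="risk_score"
    )


class CoxRiskScore:
    """Risk-score model builder for a fixed gene signature.

    Parameters
    ----------
    expression:
        Discovery gene-by-sample matrix, standardized by the same
        convention that will be applied to any validation cohort.
    annotation:
        Clinical table with ``rfs_time`` and ``event`` for the same samples.
    genes:
        The signature gene ids (must be rows of ``expression``).
    """

    def __init__(self, expression: pd.DataFrame, annotation: pd.DataFrame, genes) -> None:
        genes = list(genes)
        missing = set(genes) - set(expression.index)
        if missing:
            raise ValueError(f"signature genes absent from expression: {sorted(missing)}")
        if list(expression.columns) != list(annotation.index):
            annotation = annotation.reindex(expression.columns)
            if annotation["rfs_time"].isna().any():
                raise ValueError("annotation does not cover all expression samples")
        self.expression = expression
        self.annotation = annotation
        self.genes = genes

    def fit(self) -> "RiskScoreResults":
        """Joint multivariate Cox fit of the signature; median-score cutoff.

        Also fits each gene's univariate Cox model for reporting (the
        univariate coefficients are *not* the score weights).
        """
        covariates = self.expression.loc[self.genes].T
        time = self.annotation["rfs_time"].to_numpy()
        event = self.annotation["event"].to_numpy()
        multivariate = fit_cox(time, event, covariates)
        univariate = pd.concat(
            [fit_cox(time, event, covariates[[gene]]) for gene in self.genes]
        )
        weights = multivariate["coef"].copy()
        weights.index.name = "gene_id"
        scores = risk_score(weights, self.expression)
        cutoff = float(np.median(scores.to_numpy()))
        return RiskScoreResults(
            model=self,
            weights=weights,
            cutoff=cutoff,
            multivariate=multivariate,
            univariate=univariate,
            discovery_scores=scores,
        )


@dataclass
class RiskScoreResults:
    """A frozen risk-score model plus its Cox fit tables.

    ``cutoff`` is the median discovery score; :meth:`assign` never
    recomputes it.
    """

    model: CoxRiskScore | None
    weights: pd.Series
    cutoff: float
    multivariate: pd.DataFrame | None = None
    univariate: pd.DataFrame | None = None
    discovery_scores: pd.Series | None = field(default=None, repr=False)

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def score(self, expression: pd.DataFrame) -> pd.Series:
        return risk_score(self.weights, expression)

    def assign(self, expression: pd.DataFrame) -> pd.DataFrame:
        """Score samples and split at the frozen cutoff.

        ``group`` is ``high-risk`` when score > cutoff, ``low-risk``
        otherwise (scores exactly at the cutoff go to low-risk).  Emits a
        warning when the input does not look per-sample standardized, since
        a cutoff transferred across cohorts presumes a shared scale.
        """
        col_means = expression.mean(axis=0)
        if len(expression.index) >= 30 and col_means.abs().max() > 0.5:
            warnings.warn(
                "expression columns are far from zero mean; the frozen cutoff "
                "assumes per-sample Z-scored input",
                RuntimeWarning,
                stacklevel=2,
            )
        scores = self.score(expression)
        group = np.where(scores.to_numpy() > self.cutoff, "high-risk", "low-risk")
        return pd.DataFrame({"score": scores, "group": group}, index=scores.index)

    def summary(self) -> str:
        lines = [
            "Cox risk-score model",
            f"  signature size: {len(self.weights)}   cutoff (discovery median): {self.cutoff:.4f}",
            "",
            "Multivariate weights:",
            self.weights.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.univariate is not None:
            lines += ["", "Univariate Cox fits:", self.univariate.to_string(
                float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.weights.rename("weight").to_csv(directory / "risk_model.tsv", sep="\t")
        meta = {
            "cutoff": self.cutoff,
            "genes": self.genes,
            "standardization": "per-sample z-score",
        }
        (directory / "risk_model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "RiskScoreResults":
        directory = Path(directory)
        weights = pd.read_csv(directory / "risk_model.tsv", sep="\t", index_col=0)["weight"]
        meta = json.loads((directory / "risk_model.json").read_text())
        weights.index.name = "gene_id"
        return cls(model=None, weights=weights, cutoff=float(meta["cutoff"]))


def multivariable_adjustment(
    annotation: pd.DataFrame,
    groups: pd.Series,
    include_univariate: bool = True,
) -> pd.DataFrame:
    """Cox regression of RFS on the risk group adjusted for clinical covariates.

    Covariates follow the conventional coding: signature high- vs low-risk,
    age >65 vs <=65, male vs female, tumor stage relative to stage I
    (reference row with HR 1.000), ever- vs never-smoker (unknown smoking
    dropped from the fit).  Returns a long table with one row per term and
    analysis type (``univariate`` / ``multivariate``).
    """
    groups = pd.Series(groups).reindex(annotation.index)
    if groups.isna().any():
        raise ValueError("risk group missing for some samples")
    work = annotation.copy()
    work["__highrisk"] = (groups == "high-risk").astype(float)
    work["__age_gt65"] = (work["age"] > 65).astype(float)
    work["__male"] = (work["gender"] == "M").astype(float)
    work["__smoker"] = work["smoking"].map({"ever": 1.0, "never": 0.0})
    stage_levels = [s for s in ("II", "III", "IV") if (work["stage"] == s).any()]
    for level in stage_levels:
        work[f"__stage_{level}"] = (work["stage"] == level).astype(float)

    keep = work["__smoker"].notna()
    work = work.loc[keep]
    terms = {
        "lncRNA signature: high vs low risk": ["__highrisk"],
        "age: >65 vs <=65": ["__age_gt65"],
        "gender: male vs female": ["__male"],
        "smoking: ever vs never": ["__smoker"],
    }
    if stage_levels:
        terms["stage"] = [f"__stage_{level}" for level in stage_levels]
    time = work["rfs_time"].to_numpy()
    event = work["event"].to_numpy()

    rows = []

    def harvest(fit: pd.DataFrame, analysis: str, wanted: dict[str, list[str]]) -> None:
        for label, cols in wanted.items():
            if label == "stage":
                rows.append(
                    {
                        "variable": "stage", "contrast": "I", "analysis": analysis,
                        "hr": 1.0, "ci_lower": np.nan, "ci_upper": np.nan,
                        "p": np.nan, "reference": True,
                    }
                )
                for col in cols:
                    level = col.removeprefix("__stage_")
                    r = fit.loc[col]
                    rows.append(
                        {
                            "variable": "stage", "contrast": f"{level} vs I",
                            "analysis": analysis, "hr": r["hr"],
                            "ci_lower": r["ci_lower"], "ci_upper": r["ci_upper"],
                            "p": r["p"], "reference": False,
                        }
                    )
            else:
                variable, contrast = label.split(": ")
                r = fit.loc[cols[0]]
                rows.append(
                    {
                        "variable": variable, "contrast": contrast, "analysis": analysis,
                        "hr": r["hr"], "ci_lower": r["ci_lower"],
                        "ci_upper": r["ci_upper"], "p": r["p"], "reference": False,
                    }
                )

    if include_univariate:
        for label, cols in terms.items():
            fit = fit_cox(time, event, work[cols])
            harvest(fit, "univariate", {label: cols})
    all_cols = [c for cols in terms.values() for c in cols]
    fit = fit_cox(time, event, work[all_cols])
    harvest(fit, "multivariate", terms)
    return pd.DataFrame(rows)
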