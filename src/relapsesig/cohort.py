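"""Synthetic lung-adenocarcinoma cohort generator.

Emulates the statistical structure that the signature-discovery analysis
assumes, so every downstream stage can be exercised without external data:

* two latent patient classes (relapse-prone vs relapse-free) at a
  configurable mixing fraction;
* a small set of *informative* genes whose class means are shifted by
  ``effect_size`` standardized units (half shifted up in the relapse-prone
  class, half down, mimicking risky and protective transcripts), against a
  background of null genes;
* recurrence-free survival drawn from an exponential proportional-hazards
  model whose log hazard is a linear function of the informative genes,
  right-censored by independent uniform dropout and an administrative
  horizon;
* clinical covariates (age, gender, stage, smoking) drawn from the
  marginal frequencies of the published discovery cohort.

The observed relapse label is derived from the realized composite event
(recurrence or death), so the ``alive > 5 years without relapse`` /
``dead within 5 years with relapse`` discovery-selection rule applies
directly to simulated patients.

No generative model is published for these data; the distributional
choices here are explicit stand-ins, documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import validate_annotation, validate_expression

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort", "simulate_probe_level"]

# Discovery-cohort covariate marginals (fractions) used as defaults.
AGE_LE65_FRACTION = 0.769
MALE_FRACTION = 0.456
STAGE_FRACTIONS = {"I": 0.769, "II": 0.231}
NEVER_SMOKER_FRACTION = 0.512


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the discovery-cohort design: 121 patients with a
    27.3% relapse-prone fraction, nine informative genes shifted by two
    standardized units between classes, an exponential baseline hazard of
    0.08 events/year and a ten-year follow-up window.
    """

    n_patients: int = 121
    n_genes: int = 200
    n_informative: int = 9
    effect_size: float = 2.0
    within_class_sd: float = 1.0
    relapse_fraction: float = 33 / 121
    baseline_hazard: float = 0.08
    #: log-hazard weight per informative gene; None derives
    #: ``0.4 * effect_size`` with the sign of each gene's class shift.
    beta_link: Sequence[float] | None = None
    censor_horizon: float = 10.0
    #: probability that a patient with an observed composite event has died
    #: (the rest relapsed but are alive at last follow-up)
    death_given_event: float = 0.55
    probes_per_gene: int = 1
    probe_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0 or self.probes_per_gene < 1:
            raise ValueError("counts must be positive (probes_per_gene >= 1)")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must lie in [0, n_genes]")
        if not 0 < self.relapse_fraction < 1:
            raise ValueError("relapse_fraction must lie in (0, 1)")
        if self.within_class_sd <= 0:
            raise ValueError("within_class_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")
        if self.probe_jitter_sd < 0:
            raise ValueError("probe_jitter_sd must be non-negative")
        if not 0 <= self.death_given_event <= 1:
            raise ValueError("death_given_event must lie in [0, 1]")
        if self.beta_link is not None and len(self.beta_link) != self.n_informative:
            raise ValueError("beta_link must have one weight per informative gene")

    def shift_signs(self) -> np.ndarray:
        """+1/-1 direction of each informative gene's relapse-class shift."""
        return np.where(np.arange(self.n_informative) % 2 == 0, 1.0, -1.0)

    def resolved_beta(self) -> np.ndarray:
        if self.beta_link is not None:
            return np.asarray(self.beta_link, dtype=float)
        return 0.4 * self.effect_size * self.shift_signs()


@dataclass(frozen=True)
class SyntheticCohort:
    """A simulated expression matrix, clinical table and ground truth."""

    expression: pd.DataFrame
    annotation: pd.DataFrame
    #: per informative gene: its class-mean shift and log-hazard weight
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False)

    def __post_init__(self) -> None:
        validate_expression(self.expression)
        validate_annotation(self.annotation)
        if list(self.expression.columns) != list(self.annotation.index):
            raise ValueError("expression sample ids must equal annotation sample ids")
        if not set(self.truth.index) <= set(self.expression.index):
            raise ValueError("truth gene ids must be a subset of expression gene ids")

    @property
    def informative_genes(self) -> list[str]:
        return list(self.truth.index)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"LNC{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort; bit-reproducible for a given config (incl. seed).

    Latent class membership is Bernoulli(``relapse_fraction``); informative
    genes are Normal(+/- effect_size/2, within_class_sd) by class and null
    genes Normal(0, within_class_sd).  The composite event time is
    Exponential with rate ``baseline_hazard * exp(sum beta_link * x)``, the
    observed time is its minimum with Uniform(0, censor_horizon) dropout and
    the horizon itself, and the relapse label records whether the composite
    event was observed.  Vital status marks a ``death_given_event`` fraction
    of eventful patients as dead (the remainder relapsed but were alive at
    last follow-up), so the favorable/fatal discovery-selection rule leaves
    a non-trivial testing set.
    """
    rng = np.random.default_rng(config.seed)
    n, g, k = config.n_patients, config.n_genes, config.n_informative

    latent = rng.random(n) < config.relapse_fraction
    expr = rng.normal(0.0, config.within_class_sd, size=(g, n))
    signs = config.shift_signs()
    shifts = signs * config.effect_size / 2.0
    # informative genes occupy the first k rows; class means at +/- shift
    expr[:k, :] += np.where(latent[None, :], shifts[:, None], -shifts[:, None])

    beta = config.resolved_beta()
    log_hr = beta @ expr[:k, :] if k else np.zeros(n)
    rate = config.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)
    dropout = rng.uniform(0.0, config.censor_horizon, size=n)
    censor_time = np.minimum(dropout, config.censor_horizon)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    age = np.where(
        rng.random(n) < AGE_LE65_FRACTION,
        rng.integers(45, 66, size=n),
        rng.integers(66, 81, size=n),
    )
    gender = np.where(rng.random(n) < MALE_FRACTION, "M", "F")
    stage = rng.choice(
        list(STAGE_FRACTIONS), size=n, p=list(STAGE_FRACTIONS.values())
    )
    smoking = np.where(rng.random(n) < NEVER_SMOKER_FRACTION, "never", "ever")
    dead = (event == 1) & (rng.random(n) < config.death_given_event)

    genes = _gene_ids(g)
    samples = _sample_ids(n)
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    annotation = pd.DataFrame(
        {
            "relapse": event,
            "rfs_time": observed,
            "event": event,
            "age": age.astype(int),
            "gender": gender,
            "stage": stage,
            "smoking": smoking,
            "vital_status": np.where(dead, "dead", "alive"),
            "latent_class": latent.astype(int),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = pd.DataFrame(
        {"shift": signs * config.effect_size, "beta": beta},
        index=pd.Index(genes[:k], name="gene_id"),
    )
    return SyntheticCohort(expression, annotation, truth, config)


def simulate_probe_level(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, SyntheticCohort]:
    """Expand a simulated cohort to probe-level rows plus a probe->gene map.

    Each gene contributes ``probes_per_gene`` probe rows equal to the gene
    value plus independent Normal(0, probe_jitter_sd) jitter.  Averaging
    probes per gene (``collapse_probes``) recovers the gene matrix up to the
    jitter mean.
    """
    cohort = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    p = config.probes_per_gene
    gene_values = cohort.expression.to_numpy()
    probes = np.repeat(gene_values, p, axis=0)
    if config.probe_jitter_sd > 0:
        probes = probes + rng.normal(0.0, config.probe_jitter_sd, size=probes.shape)
    probe_ids = [
        f"{gene}_probe{j + 1}" for gene in cohort.expression.index for j in range(p)
    ]
    probe_matrix = pd.DataFrame(
        probes, index=pd.Index(probe_ids, name="gene_id"), columns=cohort.expression.columns
    )
    probe_map = pd.Series(
        np.repeat(cohort.expression.index.to_numpy(), p), index=probe_ids, name="gene_id"
    )
    return probe_matrix, probe_map, cohort


def null_config(**overrides) -> SimulationConfig:
    """A no-signal configuration: no class shift and no survival link."""
    base = SimulationConfig(effect_size=0.0, **overrides)
    return replace(base, beta_link=[0.0] * base.n_informative)
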