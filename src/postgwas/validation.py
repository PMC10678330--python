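"""Resampling negative controls for the prioritization workflow.

The workflow is validated by replacing each of its two selection steps with
random draws and comparing overlap rates against orthogonal knowledgebases
(mouse-knockout abnormalities, drug-gene interactions):

* ``stage1_random`` — draw prioritized-set-sized gene samples from the
  annotated universe and run the full hub-gene selection on each;
* ``stage2_random`` — draw key-set-sized samples directly from the
  prioritized genes (hub selection skipped);
* ``stage2_low_degree`` — as above, but restricted to genes with few
  connections (degree < 2 by default) in the prioritized-set network.

Each scheme is repeated ``n_trials`` times (10 by default) with trial seeds
``seed, seed + 1, ...``; trial overlap rates are summarized as median and
sample standard deviation and compared with the observed workflow rate by a
t test with ``n_trials - 1`` degrees of freedom.

Two test forms are offered.  ``"one-sample"`` (default) tests whether the
trial *mean* equals the observed rate — ``t = (mean - obs) / (s / sqrt(n))``
— which is the natural reading of comparing one observed workflow against
ten resampled controls, and is very powerful; note that under a true null
(observed exchangeable with the trials) it over-rejects, because the
observed value carries its own sampling noise.  ``"prediction"`` divides by
``s * sqrt(1 + 1/n)`` instead, testing whether the observed value is an
outlier with respect to the trial distribution; it holds its nominal
type-I level under exchangeability and is the form used for calibration
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateTestError, ParameterError, SamplingError, ValidationError
from .network import build_ppi_graph, compute_centralities, select_key_genes

__all__ = [
    "ValidationConfig",
    "NegativeControlContext",
    "TrialResults",
    "ValidationReport",
    "overlap_rate",
    "run_negative_control",
    "compare_observed_to_null",
    "summarize_trials",
    "build_validation_report",
    "TrialSummary",
]

Scheme = Literal["stage1_random", "stage2_random", "stage2_low_degree"]


@dataclass(frozen=True)
class ValidationConfig:
    """Negative-control settings; defaults are the full-scale study values."""

    n_trials: int = 10
    universe_size: int = 14_937
    stage1_sample_size: int = 1_372
    stage2_sample_size: int = 74
    low_degree_max: int = 1  # "degree < 2"
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 2:
            raise ParameterError("n_trials must be >= 2")
        if self.stage1_sample_size > self.universe_size:
            raise ParameterError("stage1_sample_size cannot exceed universe_size")
        for name in ("stage1_sample_size", "stage2_sample_size"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.low_degree_max < 0:
            raise ParameterError("low_degree_max must be >= 0")


@dataclass
class NegativeControlContext:
    """Everything a resampling scheme needs from the pipeline run."""

    universe: frozenset[str]
    prioritized: frozenset[str]
    ppi_edges: pd.DataFrame  # full edge table (protein1, protein2, score)
    references: dict[str, frozenset[str]]  # e.g. {"knockout": ..., "drug": ...}
    score_min: float = 0.4
    top_k: int = 100


@dataclass
class TrialResults:
    scheme: str
    trial_sets: list[frozenset[str]]
    rates: dict[str, list[float]]  # reference name -> per-trial overlap rate


class TrialSummary(NamedTuple):
    median: float
    sd: float
    degenerate: bool


@dataclass(frozen=True)
class ValidationReport:
    scheme: str
    reference: str
    observed_count: int
    observed_rate: float
    trial_rates: tuple[float, ...]
    trial_median: float
    trial_sd: float
    t_stat: float
    p_two_sided: float
    test_method: str


def overlap_rate(genes: set[str], reference_genes: set[str]) -> tuple[int, float]:
    """Count and proportion of ``genes`` present in ``reference_genes``."""
    if not genes:
        raise ValidationError("cannot compute an overlap rate for an empty gene set")
    count = len(set(genes) & set(reference_genes))
    return count, count / len(genes)


def _key_genes_for(sample: set[str], ctx: NegativeControlContext) -> frozenset[str]:
    net = build_ppi_graph(ctx.ppi_edges, sample, score_min=ctx.score_min)
    table = compute_centralities(net)
    return select_key_genes(table, k=ctx.top_k).key_genes


def run_negative_control(
    scheme: Scheme, config: ValidationConfig, ctx: NegativeControlContext
) -> TrialResults:
    """Run one resampling scheme; returns trial gene sets and overlap rates."""
    if scheme == "stage1_random":
        pool = sorted(ctx.universe)
        size = config.stage1_sample_size
    elif scheme == "stage2_random":
        pool = sorted(ctx.prioritized)
        size = config.stage2_sample_size
    elif scheme == "stage2_low_degree":
        from .evidence import normalize_symbol

        net = build_ppi_graph(ctx.ppi_edges, set(ctx.prioritized), score_min=ctx.score_min)
        deg = net.degree()  # keyed by normalized symbols
        pool = sorted(
            g
            for g in ctx.prioritized
            if deg.get(normalize_symbol(g), 0) <= config.low_degree_max
        )
        size = config.stage2_sample_size
    else:
        raise ParameterError(f"unknown scheme {scheme!r}")
    if len(pool) < size:
        raise SamplingError(
            f"scheme {scheme!r}: pool of {len(pool)} genes is smaller than the "
            f"requested sample of {size}"
        )

    trial_sets: list[frozenset[str]] = []
    rates: dict[str, list[float]] = {name: [] for name in ctx.references}
    for t in range(config.n_trials):
        rng = np.random.default_rng(config.seed + t)
        sample = set(rng.choice(pool, size=size, replace=False).tolist())
        if scheme == "stage1_random":
            genes = _key_genes_for(sample, ctx)
            if not genes:  # a draw whose induced network has no hubs at all
                genes = frozenset(sample)
        else:
            genes = frozenset(sample)
        trial_sets.append(frozenset(genes))
        for name, ref in ctx.references.items():
            _, rate = overlap_rate(set(genes), set(ref))
            rates[name].append(rate)
    return TrialResults(scheme=scheme, trial_sets=trial_sets, rates=rates)


def compare_observed_to_null(
    observed_rate: float,
    trial_rates,
    method: Literal["one-sample", "prediction"] = "one-sample",
) -> tuple[float, float]:
    """t test of the trial rates against the observed workflow rate.

    Returns ``(t, p_two_sided)`` with ``df = n - 1``.  See the module
    docstring for the two test forms.
    """
    x = np.asarray(list(trial_rates), dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateTestError("need at least two trials")
    s = x.std(ddof=1)
    if s < 1e-12:  # exactly-repeated rates up to float rounding
        raise DegenerateTestError(
            "zero variance across trials; increase n_trials or sample sizes"
        )
    if method == "one-sample":
        denom = s / np.sqrt(n)
    elif method == "prediction":
        denom = s * np.sqrt(1.0 + 1.0 / n)
    else:
        raise ParameterError(f"unknown test method {method!r}")
    t = float((x.mean() - observed_rate) / denom)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, min(p, 1.0)


def summarize_trials(trial_rates) -> TrialSummary:
    """Sample median and standard deviation (n-1 denominator) of the trials."""
    x = np.asarray(list(trial_rates), dtype=float)
    if x.size == 0:
        raise ValidationError("need at least one trial")
    if x.size == 1:
        return TrialSummary(median=float(x[0]), sd=0.0, degenerate=True)
    return TrialSummary(median=float(np.median(x)), sd=float(x.std(ddof=1)), degenerate=False)


def build_validation_report(
    scheme: str,
    reference: str,
    observed_genes: set[str],
    reference_genes: set[str],
    trial_rates,
    method: Literal["one-sample", "prediction"] = "one-sample",
) -> ValidationReport:
    """Assemble the per-scheme, per-reference comparison report."""
    count, rate = overlap_rate(observed_genes, reference_genes)
    summary = summarize_trials(trial_rates)
    t, p = compare_observed_to_null(rate, trial_rates, method=method)
    return ValidationReport(
        scheme=scheme,
        reference=reference,
        observed_count=count,
        observed_rate=rate,
        trial_rates=tuple(float(r) for r in trial_rates),
        trial_median=summary.median,
        trial_sd=summary.sd,
        t_stat=t,
        p_two_sided=p,
        test_method=method,
    )
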