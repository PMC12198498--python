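"""Ranking the eight fitted models per gene by weighted corrected AIC.

The raw penalized log-likelihoods of the eight models are not comparable
because every model estimates its own error variances, so goodness of fit
is measured by the squared sum of residuals (SSR) over conditions, species
and pooled points.  Models are ranked by the corrected Akaike index

    A = 2 k + SSR / mu + (2 k^2 + 2 k) / (n - k - 1)

with k the model's parameter count, n the number of pooled observations and
mu a simulation-calibrated weight trading fit quality against complexity
(mu = 0.01 by default).  The model minimising A is selected; its
Same/Any pattern yields the per-rate differential-kinetics calls.

By default n is the number of observations actually fit (conditions x
species x pools, i.e. 80 for a standard two-condition run); it can be
overridden through :class:`~diffgek.config.SelectionConfig`.

The module also provides the upper-tail hypergeometric test used to ask
whether differential-kinetics genes overlap a differential-expression gene
set more than expected by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import SelectionConfig
from .fitting import FitResult
from .models import MODEL_ORDER, RATES, ModelSpec
from .pooling import GeneTimeCourse

__all__ = [
    "SelectionResult",
    "compute_ssr",
    "aicc",
    "select_model",
    "overlap_test",
]


@dataclass(frozen=True)
class SelectionResult:
    """Per-gene outcome of the eight-model comparison."""

    gene: str
    aicc_per_model: dict[str, float]
    ssr_per_model: dict[str, float]
    k_per_model: dict[str, int]
    best_model: ModelSpec
    rate_calls: dict[str, bool]
    n_data: int
    mu: float
    excluded: tuple[str, ...] = ()

    @property
    def best_name(self) -> str:
        return self.best_model.name

    @property
    def is_differential(self) -> bool:
        return any(self.rate_calls.values())

    def to_row(self) -> dict:
        row = {"gene": self.gene, "best_model": self.best_name}
        for r in RATES:
            row[f"{r}_differential"] = self.rate_calls[r]
        for m in MODEL_ORDER:
            row[f"aicc_{m}"] = self.aicc_per_model.get(m, np.nan)
        for m in MODEL_ORDER:
            row[f"ssr_{m}"] = self.ssr_per_model.get(m, np.nan)
        row["n"] = self.n_data
        row["mu"] = self.mu
        row["excluded"] = ",".join(self.excluded)
        return row


def compute_ssr(fit: FitResult, data: dict[str, GeneTimeCourse]) -> float:
    """Squared sum of residuals of a fit against pooled observations.

    Sums (observed - predicted)^2 over conditions, both species and every
    pooled point.  ``data`` values may be replicate lists (samples mode).
    """
    ssr = 0.0
    for cond, courses in data.items():
        if cond not in fit.predicted:
            raise ValueError(f"fit has no predictions for condition '{cond}'")
        pred = fit.predicted[cond]
        cl = courses if isinstance(courses, (list, tuple)) else [courses]
        for course in cl:
            if course.n_pools != pred.n_pools:
                raise ValueError(
                    "observed and predicted courses have different lengths"
                )
            ru = course.u_obs - pred.u_obs
            rs = course.s_obs - pred.s_obs
            ssr += float(np.dot(ru, ru) + np.dot(rs, rs))
    return ssr


def aicc(ssr: float, k: int, n: int, mu: float, convention: str = "divide") -> float:
    """Weighted corrected Akaike index 2k + SSR/mu + (2k^2 + 2k)/(n - k - 1).

    ``convention`` selects how the SSR is weighted by mu: ``"divide"``
    (default) or ``"multiply"``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if n - k - 1 == 0:
        raise ZeroDivisionError(
            f"AICc correction term (2k^2+2k)/(n-k-1) is singular at n={n}, k={k}"
        )
    if convention == "divide":
        fit_term = ssr / mu
    elif convention == "multiply":
        fit_term = ssr * mu
    else:
        raise ValueError("convention must be 'divide' or 'multiply'")
    return 2.0 * k + fit_term + (2.0 * k * k + 2.0 * k) / (n - k - 1)


def _default_n(data) -> int:
    """Observations actually fit: per condition, 2 species x pools x replicates."""
    n = 0
    for courses in data.values():
        cl = courses if isinstance(courses, (list, tuple)) else [courses]
        n += sum(2 * c.n_pools for c in cl)
    return n


def select_model(
    fits: dict[str, FitResult],
    data: dict[str, GeneTimeCourse],
    mu: float | None = None,
    n: int | None = None,
    gene: str = "",
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Pick the best of the eight candidate models for one gene.

    Failed fits are excluded (and recorded); ties at exactly equal index are
    broken toward the smaller parameter count, then fixed M1..M8 order.

    Raises
    ------
    ValueError
        If every fit failed, leaving the gene unclassifiable.
    """
    cfg = config or SelectionConfig()
    mu = cfg.mu if mu is None else float(mu)
    if n is None:
        n = cfg.n_override if cfg.n_override is not None else _default_n(data)

    aicc_pm: dict[str, float] = {}
    ssr_pm: dict[str, float] = {}
    k_pm: dict[str, int] = {}
    excluded = []
    for name in sorted(fits, key=lambda m: MODEL_ORDER.index(m) if m in MODEL_ORDER else 99):
        fit = fits[name]
        if not fit.success or fit.best_params is None:
            excluded.append(name)
            continue
        ssr = compute_ssr(fit, data)
        k = fit.model.k
        aicc_pm[name] = aicc(ssr, k, n, mu, cfg.mu_convention)
        ssr_pm[name] = ssr
        k_pm[name] = k
    if not aicc_pm:
        raise ValueError(f"gene '{gene}' unclassifiable: all 8 fits failed")

    best_name = min(
        aicc_pm,
        key=lambda m: (
            aicc_pm[m],
            k_pm[m],
            MODEL_ORDER.index(m) if m in MODEL_ORDER else 99,
        ),
    )
    best = fits[best_name].model
    return SelectionResult(
        gene=gene,
        aicc_per_model=aicc_pm,
        ssr_per_model=ssr_pm,
        k_per_model=k_pm,
        best_model=best,
        rate_calls=best.rate_calls,
        n_data=n,
        mu=mu,
        excluded=tuple(excluded),
    )


def selection_table(results) -> pd.DataFrame:
    """Tidy per-gene selection table (one row per gene)."""
    return pd.DataFrame([r.to_row() for r in results])


def overlap_test(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two gene sets.

    Probability of drawing an overlap at least as large as observed when
    ``len(set_a)`` genes are sampled without replacement from ``universe``
    and compared against ``set_b``.  Both sets must be subsets of the
    universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("gene universe must be non-empty")
    a = set(set_a)
    b = set(set_b)
    if not a <= uni or not b <= uni:
        raise ValueError("both gene sets must be subsets of the universe")
    k = len(a & b)
    return float(hypergeom.sf(k - 1, len(uni), len(a), len(b)))
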