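"""Closed-form marginal likelihoods and Bayes factors for conjugate count models.

All computations stay in the natural-log domain via log-gamma: the equality
Bayes factors of interest reach magnitudes around exp(-480), far outside
double range on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, xlogy
from scipy.stats import beta as beta_dist

__all__ = [
    "CountData",
    "PriorSpec",
    "log_multivariate_beta",
    "log_mult_bf_equality",
    "log_binom_bf_equality",
    "log_binom_bf_equality_point",
    "log_equality_group_bf",
    "posterior_summary",
]


@dataclass(frozen=True, eq=False)
class CountData:
    """Observed category counts; ``n`` (trials) present only for binomials."""

    x: np.ndarray
    labels: tuple[str, ...]
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x))
        if self.n is not None:
            object.__setattr__(self, "n", np.asarray(self.n))
        if len(self.x) < 1 or len(self.labels) != len(self.x):
            raise ValueError("labels and counts must have equal positive length")
        if np.any(self.x < 0):
            raise ValueError("counts must be non-negative")
        if self.n is not None:
            if len(self.n) != len(self.x) or np.any(self.n <= 0):
                raise ValueError("trials must be positive and match counts")
            if np.any(self.x > self.n):
                raise ValueError("successes cannot exceed trials")

    @classmethod
    def from_counts(cls, x, labels=None, n=None) -> "CountData":
        x = np.asarray(x)
        if labels is None:
            labels = tuple(str(i + 1) for i in range(len(x)))
        return cls(x=x, labels=tuple(str(lv) for lv in labels),
                   n=None if n is None else np.asarray(n))

    @property
    def n_categories(self) -> int:
        return len(self.x)

    @property
    def family(self) -> str:
        return "multinomial" if self.n is None else "binomial"

    @property
    def x_total(self) -> int:
        return int(self.x.sum())

    @property
    def n_total(self) -> int | None:
        return None if self.n is None else int(self.n.sum())


@dataclass(frozen=True, eq=False)
class PriorSpec:
    """Dirichlet concentrations (multinomial) or per-category Beta(a, b) pairs."""

    family: str
    a: np.ndarray
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        if self.b is not None:
            object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.family not in ("multinomial", "binomial"):
            raise ValueError(f"unknown family '{self.family}'")
        if np.any(self.a <= 0):
            raise ValueError("concentration parameters must be positive")
        if self.family == "binomial":
            if self.b is None or len(self.b) != len(self.a) or np.any(self.b <= 0):
                raise ValueError("binomial prior requires positive b of same length")

    @classmethod
    def uniform(cls, k: int, family: str = "multinomial") -> "PriorSpec":
        if family == "binomial":
            return cls(family, np.ones(k), np.ones(k))
        return cls(family, np.ones(k))

    @property
    def n_categories(self) -> int:
        return len(self.a)


def log_multivariate_beta(alpha: np.ndarray) -> float:
    """log B(alpha) = sum(log Gamma(alpha_k)) - log Gamma(sum alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    return float(gammaln(alpha).sum() - gammaln(alpha.sum()))


def _check_dims(data: CountData, prior: PriorSpec) -> None:
    if data.n_categories != prior.n_categories:
        raise ValueError("data and prior dimensions disagree")
    if data.family != prior.family:
        raise ValueError("data and prior families disagree")


def log_mult_bf_equality(data: CountData, prior: PriorSpec, p0) -> float:
    """log BF_0e of the multinomial point null theta = p0 vs the encompassing model.

    BF_0e = B(alpha) / B(alpha + x) * prod_k p0_k^{x_k}.  A zero predicted
    proportion with a positive observed count returns -inf (the null is
    falsified outright).
    """
    _check_dims(data, prior)
    p0 = np.asarray(p0, dtype=float)
    if len(p0) != data.n_categories:
        raise ValueError("p0 dimension mismatch")
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-12:
        raise ValueError("p0 must be a probability vector summing to 1")
    loglik = xlogy(data.x, p0).sum()  # -inf when p0_k == 0 and x_k > 0
    return (
        log_multivariate_beta(prior.a)
        - log_multivariate_beta(prior.a + data.x)
        + float(loglik)
    )


def log_binom_bf_equality(data: CountData, prior: PriorSpec) -> float:
    """log BF_0e of "all binomial proportions equal" vs the encompassing model.

    Collapsing the K independent Beta(a_k, b_k) priors onto a shared theta
    subtracts K - 1 from the summed concentration parameters, so a uniform
    prior per category collapses back to a uniform prior on the shared rate.
    """
    _check_dims(data, prior)
    k = data.n_categories
    a_c = prior.a.sum() - (k - 1)
    b_c = prior.b.sum() - (k - 1)
    if a_c <= 0 or b_c <= 0:
        raise ValueError("collapsed prior parameters must stay positive")
    xp, np_ = data.x_total, data.n_total
    return float(
        betaln(xp + a_c, np_ - xp + b_c)
        - betaln(a_c, b_c)
        + betaln(prior.a, prior.b).sum()
        - betaln(data.x + prior.a, data.n - data.x + prior.b).sum()
    )


def log_binom_bf_equality_point(data: CountData, prior: PriorSpec, theta0: float) -> float:
    """log BF_02e of "all proportions equal theta0" vs the encompassing model."""
    _check_dims(data, prior)
    if not 0.0 < theta0 < 1.0:
        raise ValueError("theta0 must lie strictly inside (0, 1)")
    xp, np_ = data.x_total, data.n_total
    return float(
        betaln(prior.a, prior.b).sum()
        - betaln(prior.a + data.x, prior.b + data.n - data.x).sum()
        + xp * np.log(theta0)
        + (np_ - xp) * np.log1p(-theta0)
    )


def log_equality_group_bf(data: CountData, prior: PriorSpec, group) -> float:
    """log BF_1e of tying the proportions in ``group`` equal, vs encompassing.

    Binomial: the all-equal collapse formula restricted to the group's
    categories.  Multinomial: by Dirichlet aggregation the within-group
    composition phi follows Dirichlet(alpha_g) independent of the rest, and
    the Savage-Dickey ratio of the uniform composition gives

        log BF_1e = log B(alpha_g) - log B(alpha_g + x_g) + sum_g x_k log(1/m).

    This reduces exactly to :func:`log_mult_bf_equality` with p0 = (1/K, ...)
    when the group spans all K categories.
    """
    _check_dims(data, prior)
    group = tuple(group)
    if len(group) < 2:
        raise ValueError("equality group needs at least two members")
    idx = list(group)
    if prior.family == "binomial":
        sub_data = CountData(data.x[idx], tuple(data.labels[i] for i in idx), data.n[idx])
        sub_prior = PriorSpec("binomial", prior.a[idx], prior.b[idx])
        return log_binom_bf_equality(sub_data, sub_prior)
    a_g, x_g = prior.a[idx], data.x[idx]
    m = len(idx)
    return (
        log_multivariate_beta(a_g)
        - log_multivariate_beta(a_g + x_g)
        - x_g.sum() * np.log(m)
    )


def posterior_summary(data: CountData, prior: PriorSpec, level: float = 0.95) -> pd.DataFrame:
    """Per-category posterior medians and central credible intervals.

    Binomial: quantiles of Beta(a_k + x_k, b_k + n_k - x_k).  Multinomial:
    quantiles of the marginal Beta(a_k + x_k, a_+ + x_+ - a_k - x_k) of the
    Dirichlet posterior.
    """
    _check_dims(data, prior)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if prior.family == "binomial":
        a_post = prior.a + data.x
        b_post = prior.b + data.n - data.x
    else:
        a_post = prior.a + data.x
        b_post = a_post.sum() - a_post
    tail = (1.0 - level) / 2.0
    return pd.DataFrame(
        {
            "median": beta_dist.ppf(0.5, a_post, b_post),
            "lower": beta_dist.ppf(tail, a_post, b_post),
            "upper": beta_dist.ppf(1.0 - tail, a_post, b_post),
        },
        index=pd.Index(data.labels, name="category"),
    )
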