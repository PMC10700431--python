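"""Informed-hypothesis Bayes factors for multinomial and binomial counts.

The public surface follows the model/results idiom: a model object holds the
counts, the prior and the parsed hypothesis; ``fit`` runs the analytic
equality part and the per-section bridge-sampling inequality part and
returns an :class:`InformedResults` carrying the assembled Bayes factor,
its error measure and the per-section breakdown.

The combined Bayes factor of an informed hypothesis H_r against the
encompassing hypothesis H_e factorizes as

    log BF_re = log BF_1e + log BF_2e|1e,

where BF_1e is the (closed-form) Bayes factor of the equality constraints
and BF_2e|1e the conditional Bayes factor of the inequality constraints
given the equalities, obtained as the difference of the bridge-estimated
log normalizing constants of the constrained posterior and prior densities
of the collapsed problem.  Independent '&'-sections contribute additively
on the log scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import conjugate
from .bridge import BridgeResult, bridge_logml
from .conjugate import CountData, PriorSpec
from .restrictions import RestrictionList, parse_hypothesis, split_restriction
from .sampling import sample_constrained

__all__ = [
    "BF_TYPES",
    "MultinomialInformedModel",
    "BinomialInformedModel",
    "InformedResults",
    "mult_bf_informed",
    "binom_bf_informed",
    "posterior_model_probabilities",
    "bf_ratio",
]

BF_TYPES = (
    "BFre", "BFer", "LogBFre", "LogBFer",
    "BFr0", "BF0r", "LogBFr0", "LogBF0r",
)


@dataclass(eq=False)
class _SectionResult:
    """Bridge output for one independent section of the hypothesis."""

    labels: tuple[str, ...]
    prior: BridgeResult
    posterior: BridgeResult

    @property
    def log_bf(self) -> float:
        return self.posterior.logml - self.prior.logml

    @property
    def re2(self) -> float:
        return self.prior.re2 + self.posterior.re2


class _InformedModel:
    """Shared machinery of the multinomial and binomial informed models."""

    def __init__(self, data: CountData, prior: PriorSpec,
                 hypothesis, factor_levels=None):
        if factor_levels is not None:
            data = CountData(data.x, tuple(str(lv) for lv in factor_levels), data.n)
        self.data = data
        self.prior = prior
        if isinstance(hypothesis, RestrictionList):
            self.restriction = hypothesis
        else:
            self.restriction = parse_hypothesis(hypothesis, data.labels)
        self.equality_groups, self.problem = split_restriction(
            self.restriction, data, prior
        )

    # -- analytic pieces -------------------------------------------------

    def log_bf_equality(self) -> float:
        return sum(
            conjugate.log_equality_group_bf(self.data, self.prior, g)
            for g in self.equality_groups
        )

    def log_bf_null(self) -> float:
        """log BF_0e of the equal-all null against the encompassing model."""
        if self.prior.family == "multinomial":
            k = self.data.n_categories
            return conjugate.log_mult_bf_equality(
                self.data, self.prior, np.full(k, 1.0 / k)
            )
        return conjugate.log_binom_bf_equality(self.data, self.prior)

    def posterior_summary(self, level: float = 0.95):
        return conjugate.posterior_summary(self.data, self.prior, level)

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        seed=None,
        bf_type: str = "LogBFre",
        n_draws: int = 12_000,
        n_burn: int = 500,
        n_chains: int = 8,
        thinning: int = 1,
        tolerance: float = 1e-10,
        max_iterations: int = 1000,
    ) -> "InformedResults":
        """Estimate the informed-vs-encompassing Bayes factor.

        ``seed`` drives every random stream (one independent substream per
        section and target plus one for the proposal draws); identical calls
        return identical results.
        """
        if bf_type not in BF_TYPES:
            raise ValueError(f"bf_type must be one of {BF_TYPES}")
        ss = np.random.SeedSequence(seed)
        sections = []
        for sub in self.problem.section_problems():
            child = ss.spawn(1)[0]
            keys = child.spawn(4)
            results = {}
            for target, skey, bkey in (
                ("prior", keys[0], keys[1]),
                ("posterior", keys[2], keys[3]),
            ):
                draws = sample_constrained(
                    sub, target=target, n_draws=n_draws, n_burn=n_burn,
                    seed=skey, n_chains=n_chains, thinning=thinning,
                )
                results[target] = bridge_logml(
                    draws, tolerance=tolerance,
                    max_iterations=max_iterations, seed=bkey,
                )
            sections.append(_SectionResult(
                labels=sub.labels, prior=results["prior"],
                posterior=results["posterior"],
            ))
        return InformedResults(
            model=self,
            bf_type=bf_type,
            log_bf_equality=self.log_bf_equality(),
            sections=sections,
            seed=seed,
            n_draws=n_draws,
        )


class MultinomialInformedModel(_InformedModel):
    """Informed hypothesis on multinomial category proportions.

    Parameters
    ----------
    x
        Observed category counts.
    hypothesis
        Constraint string (or token vector, or parsed
        :class:`~ordbf.restrictions.RestrictionList`) in the
        ``< > = , &`` dialect.
    a
        Dirichlet concentration parameters; default all one (uniform).
    factor_levels
        Category labels; default ``"1".."K"``.
    """

    def __init__(self, x, hypothesis, a=None, factor_levels=None):
        x = np.asarray(x)
        data = CountData.from_counts(x, labels=factor_levels)
        a = np.ones(len(x)) if a is None else np.asarray(a, float)
        super().__init__(data, PriorSpec("multinomial", a), hypothesis)

    @classmethod
    def from_dataframe(cls, df, hypothesis, a=None,
                       label_col="label", count_col="x"):
        return cls(df[count_col].to_numpy(), hypothesis, a=a,
                   factor_levels=df[label_col].astype(str).tolist())


class BinomialInformedModel(_InformedModel):
    """Informed hypothesis on independent binomial success probabilities."""

    def __init__(self, x, n, hypothesis, a=None, b=None, factor_levels=None):
        x, n = np.asarray(x), np.asarray(n)
        data = CountData.from_counts(x, labels=factor_levels, n=n)
        a = np.ones(len(x)) if a is None else np.asarray(a, float)
        b = np.ones(len(x)) if b is None else np.asarray(b, float)
        super().__init__(data, PriorSpec("binomial", a, b), hypothesis)

    @classmethod
    def from_dataframe(cls, df, hypothesis, a=None, b=None,
                       label_col="label", count_col="x", trial_col="n"):
        return cls(df[count_col].to_numpy(), df[trial_col].to_numpy(),
                   hypothesis, a=a, b=b,
                   factor_levels=df[label_col].astype(str).tolist())


@dataclass(eq=False)
class InformedResults:
    """Assembled Bayes factor for an informed hypothesis.

    ``log_bf_re`` is the log Bayes factor of the informed hypothesis against
    the encompassing hypothesis; ``bayes_factor`` converts it to any of the
    supported types (the r-vs-0 types divide out the equal-all null).
    """

    model: _InformedModel
    bf_type: str
    log_bf_equality: float
    sections: list
    seed: object
    n_draws: int

    @property
    def log_bf_inequality(self) -> float:
        """log BF_2e|1e: conditional inequality part, summed over sections."""
        return float(sum(s.log_bf for s in self.sections))

    @property
    def log_bf_re(self) -> float:
        return float(self.log_bf_equality + self.log_bf_inequality)

    @property
    def re2(self) -> float:
        """Combined squared relative error of the bridge estimates (approximate:
        independent log-scale errors added in quadrature)."""
        return float(sum(s.re2 for s in self.sections))

    @property
    def percentage_error(self) -> float:
        return 100.0 * float(np.sqrt(self.re2))

    @property
    def converged(self) -> bool:
        return all(s.prior.converged and s.posterior.converged for s in self.sections)

    def log_bf_null(self) -> float:
        return self.model.log_bf_null()

    def bayes_factor(self, bf_type: str | None = None) -> float:
        bf_type = self.bf_type if bf_type is None else bf_type
        if bf_type not in BF_TYPES:
            raise ValueError(f"bf_type must be one of {BF_TYPES}")
        log_re = self.log_bf_re
        if bf_type in ("BFr0", "BF0r", "LogBFr0", "LogBF0r"):
            log_val = log_re - self.log_bf_null()
        else:
            log_val = log_re
        if bf_type in ("BFer", "LogBFer", "BF0r", "LogBF0r"):
            log_val = -log_val
        return float(log_val) if bf_type.startswith("Log") else float(np.exp(log_val))

    def posterior_summary(self, level: float = 0.95):
        return self.model.posterior_summary(level)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Informed-hypothesis Bayes factor ({m.prior.family} model)",
            f"  Hypothesis : {m.restriction.to_string()}",
            f"  Counts     : {np.asarray(m.data.x).tolist()}"
            + (f" of {np.asarray(m.data.n).tolist()}" if m.data.n is not None else ""),
            "",
            f"  log BF equality (analytic)          : {self.log_bf_equality: .4f}",
            f"  log BF inequality | equality (bridge): {self.log_bf_inequality: .4f}",
            f"  log BF_re                            : {self.log_bf_re: .4f}",
            f"  {self.bf_type:<12} : {self.bayes_factor(): .6g}",
            f"  bridge percentage error              : {self.percentage_error: .3f}%",
        ]
        for s in self.sections:
            lines.append(
                f"    section {'<'.join(s.labels)}: "
                f"logml prior {s.prior.logml: .4f} "
                f"({s.prior.n_iterations} it), posterior "
                f"{s.posterior.logml: .4f} ({s.posterior.n_iterations} it)"
            )
        if not self.converged:
            lines.append("  WARNING: a bridge iteration did not converge")
        post = self.posterior_summary()
        lines.append("")
        lines.append("  Posterior medians [95% CI] under the encompassing model:")
        for lab, row in post.iterrows():
            lines.append(
                f"    {lab:>10}: {row['median']:.4f} "
                f"[{row['lower']:.4f}, {row['upper']:.4f}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        m = self.model
        return {
            "family": m.prior.family,
            "hypothesis": m.restriction.to_string(),
            "x": np.asarray(m.data.x).tolist(),
            "n": None if m.data.n is None else np.asarray(m.data.n).tolist(),
            "a": np.asarray(m.prior.a).tolist(),
            "b": None if m.prior.b is None else np.asarray(m.prior.b).tolist(),
            "labels": list(m.data.labels),
            "bf_type": self.bf_type,
            "bf": self.bayes_factor(),
            "log_bf_re": self.log_bf_re,
            "log_bf_equality": self.log_bf_equality,
            "log_bf_inequality": self.log_bf_inequality,
            "percentage_error": self.percentage_error,
            "converged": self.converged,
            "seed": self.seed,
            "n_draws": self.n_draws,
            "sections": [
                {
                    "labels": list(s.labels),
                    "logml_prior": s.prior.logml,
                    "logml_posterior": s.posterior.logml,
                    "log_bf": s.log_bf,
                    "percentage_error": 100.0 * float(np.sqrt(s.re2)),
                }
                for s in self.sections
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def plot_posterior(self, ax=None, level: float = 0.95, expected=None):
        """Posterior medians and credible intervals per category."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        post = self.posterior_summary(level)
        x = np.arange(len(post))
        ax.errorbar(
            x, post["median"],
            yerr=[post["median"] - post["lower"], post["upper"] - post["median"]],
            fmt="o", color="black", capsize=3,
        )
        if expected is not None:
            ax.plot(x, expected, "s", color="crimson", label="expected")
            ax.legend()
        ax.set_xticks(x, post.index)
        ax.set_ylabel("proportion")
        return ax


def mult_bf_informed(
    x, Hr, a=None, factor_levels=None, bf_type: str = "LogBFre",
    seed=None, **sampler_options,
) -> InformedResults:
    """Evaluate an informed hypothesis on multinomial parameters.

    Thin functional wrapper over
    :class:`MultinomialInformedModel(...).fit(...)`.
    """
    model = MultinomialInformedModel(x, Hr, a=a, factor_levels=factor_levels)
    return model.fit(seed=seed, bf_type=bf_type, **sampler_options)


def binom_bf_informed(
    x, n, Hr, a=None, b=None, factor_levels=None, bf_type: str = "LogBFre",
    seed=None, **sampler_options,
) -> InformedResults:
    """Evaluate an informed hypothesis on independent binomial parameters."""
    model = BinomialInformedModel(x, n, Hr, a=a, b=b, factor_levels=factor_levels)
    return model.fit(seed=seed, bf_type=bf_type, **sampler_options)


def posterior_model_probabilities(
    log_bfs: Sequence[float], prior_probs: Sequence[float] | None = None
) -> np.ndarray:
    """Posterior model probabilities from log Bayes factors vs a common reference.

    Every entry of ``log_bfs`` must be a log BF against the same encompassing
    hypothesis (include 0.0 for the encompassing model itself).  Normalization
    is done with log-sum-exp, so hopeless models (log BF around -480) do not
    underflow the others.
    """
    log_bfs = np.asarray(log_bfs, dtype=float)
    if prior_probs is None:
        prior_probs = np.full(len(log_bfs), 1.0 / len(log_bfs))
    prior_probs = np.asarray(prior_probs, dtype=float)
    if len(prior_probs) != len(log_bfs) or np.any(prior_probs < 0) or \
            abs(prior_probs.sum() - 1.0) > 1e-10:
        raise ValueError("prior model probabilities must be a probability vector")
    with np.errstate(divide="ignore"):
        log_w = log_bfs + np.log(prior_probs)
    return np.exp(log_w - logsumexp(log_w))


def bf_ratio(log_bf_r1e: float, log_bf_r2e: float) -> float:
    """log BF_r1r2 between two informed hypotheses sharing an encompassing prior."""
    return float(log_bf_r1e - log_bf_r2e)
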