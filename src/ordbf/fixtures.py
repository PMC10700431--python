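"""Packaged example datasets, prior presets and a synthetic count generator.

Two worked datasets ship with the package:

``greek_fiscal``
    First-digit counts of N = 1,497 numbers from Greek fiscal statistics
    (1999-2010), the classic substrate for a Benford test: under Benford's
    law digit d leads with proportion log10((d + 1) / d).
``birnbaum``
    Stochastic-dominance violation counts of N = 1,212 online gambling-task
    participants, split by gender (m/f) and education level (1 = doctorate
    ... 4 = less than bachelor's).

The journals dataset (statistical reporting errors across eight psychology
journals) is distributed only as an empty CSV template plus schema, since
its counts are not reproduced here; analyses can be run on a user-supplied
CSV with the same columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .conjugate import CountData, PriorSpec

__all__ = ["Fixture", "load_fixture", "simulate_counts", "benford_proportions",
           "journals_template", "FIXTURE_NAMES"]


def benford_proportions(k: int = 9) -> np.ndarray:
    """Expected leading-digit proportions log10((d + 1) / d), d = 1..k."""
    d = np.arange(1, k + 1)
    return np.log10((d + 1) / d)


@dataclass(eq=False)
class Fixture:
    """A packaged dataset with prior presets and the hypotheses studied on it."""

    name: str
    data: CountData
    priors: dict = field(default_factory=dict)
    hypotheses: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = {"label": list(self.data.labels), "x": self.data.x.tolist()}
        if self.data.n is not None:
            cols["n"] = self.data.n.tolist()
        return pd.DataFrame(cols)


def _greek_fiscal() -> Fixture:
    x = np.array([509, 353, 177, 114, 77, 77, 53, 73, 64])
    labels = tuple(str(d) for d in range(1, 10))
    data = CountData(x, labels)
    priors = {
        "uniform": PriorSpec("multinomial", np.ones(9)),
        "benford": PriorSpec("multinomial", np.array([16, 10, 7, 5, 4, 3, 3, 3, 2], float)),
        "decreasing": PriorSpec("multinomial", np.array([10, 9, 8, 7, 6, 5, 4, 3, 2], float)),
        "centered": PriorSpec("multinomial", np.full(9, 6.0)),
        "fraud": PriorSpec("multinomial", np.array([12, 6, 6, 6, 6, 6, 6, 3, 3], float)),
    }
    hypotheses = {
        "decreasing": "1 > 2 > 3 > 4 > 5 > 6 > 7 > 8 > 9",
        "fraud": "1 > 2 = 3 = 4 = 5 = 6 = 7 > 8 , 9",
    }
    expected = {"benford_p0": benford_proportions(9), "equal_p0": np.full(9, 1 / 9)}
    return Fixture("greek_fiscal", data, priors, hypotheses, expected)


def _birnbaum() -> Fixture:
    labels = ("m1", "m2", "m3", "m4", "f1", "f2", "f3", "f4")
    x = np.array([39, 42, 102, 98, 22, 60, 134, 198])
    n = np.array([80, 88, 195, 163, 54, 108, 206, 318])
    data = CountData(x, labels, n)
    priors = {"uniform": PriorSpec("binomial", np.ones(8), np.ones(8))}
    hypotheses = {
        "gender": "m1 , m2 , m3 , m4 < f1 , f2 , f3 , f4",
        "education": "m1 , f1 < m2 , f2 < m3 , f3 < m4 , f4",
        "interleaved": "m1 < f1 < m2 < f2 < m3 < f3 < m4 < f4",
    }
    return Fixture("birnbaum", data, priors, hypotheses)


def _benford_proportions_fixture() -> Fixture:
    p = benford_proportions(9)
    # stored as a pseudo-count fixture for convenience in tests/CLI listings
    data = CountData(np.zeros(9, dtype=int), tuple(str(d) for d in range(1, 10)))
    fx = Fixture("benford_proportions", data)
    fx.expected["p"] = p
    return fx


_LOADERS = {
    "greek_fiscal": _greek_fiscal,
    "birnbaum": _birnbaum,
    "benford_proportions": _benford_proportions_fixture,
}
FIXTURE_NAMES = tuple(_LOADERS)


def load_fixture(name: str) -> Fixture:
    """Load a packaged dataset by name (see :data:`FIXTURE_NAMES`)."""
    try:
        return _LOADERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture '{name}'; available: {', '.join(FIXTURE_NAMES)}"
        ) from None


def journals_template() -> pd.DataFrame:
    """Empty CSV schema for the journals reporting-error dataset.

    Columns: ``label`` (journal), ``x`` (articles with at least one
    inconsistency), ``n`` (articles with null-hypothesis tests).  Users can
    fill it from the original source and feed it to the CLI or
    :meth:`BinomialInformedModel.from_dataframe`.
    """
    with resources.files("ordbf.data").joinpath("journals_template.csv").open() as fh:
        return pd.read_csv(fh)


def simulate_counts(theta, n, family: str = "multinomial", seed=None) -> CountData:
    """Synthetic counts for property tests and power checks.

    Multinomial: one draw of ``n`` total observations over categories with
    probabilities ``theta``.  Binomial: independent successes out of per-
    category trials ``n`` with success probabilities ``theta``.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta entries must lie in [0, 1]")
    if family == "multinomial":
        if abs(theta.sum() - 1.0) > 1e-9:
            raise ValueError("multinomial theta must sum to 1")
        x = rng.multinomial(int(n), theta)
        return CountData.from_counts(x)
    if family == "binomial":
        n = np.broadcast_to(np.asarray(n, dtype=int), theta.shape).copy()
        if np.any(n <= 0):
            raise ValueError("trial counts must be positive")
        x = rng.binomial(n, theta)
        return CountData.from_counts(x, n=n)
    raise ValueError(f"unknown family '{family}'")
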