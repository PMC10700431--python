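import numpy as np
import pytest

from ordbf.conjugate import CountData, PriorSpec
from ordbf.restrictions import parse_hypothesis, split_restriction


def make_problem(hyp, k, family="multinomial", x=None, n=None, a=None, b=None,
                 labels=None):
    """Parse + split a hypothesis into its collapsed inequality problem."""
    x = np.zeros(k, dtype=int) if x is None else np.asarray(x)
    if family == "binomial" and n is None:
        n = np.maximum(x, 1)
    data = CountData.from_counts(x, labels=labels, n=n)
    if family == "binomial":
        prior = PriorSpec("binomial",
                          np.ones(k) if a is None else np.asarray(a, float),
                          np.ones(k) if b is None else np.asarray(b, float))
    else:
        prior = PriorSpec("multinomial",
                          np.ones(k) if a is None else np.asarray(a, float))
    rl = parse_hypothesis(hyp, data.labels)
    groups, problem = split_restriction(rl, data, prior)
    return data, prior, groups, problem


@pytest.fixture(scope="session")
def greek_counts():
    return np.array([509, 353, 177, 114, 77, 77, 53, 73, 64])


@pytest.fixture(scope="session")
def birnbaum_counts():
    x = np.array([39, 42, 102, 98, 22, 60, 134, 198])
    n = np.array([80, 88, 195, 163, 54, 108, 206, 318])
    labels = ("m1", "m2", "m3", "m4", "f1", "f2", "f3", "f4")
    return x, n, labels
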