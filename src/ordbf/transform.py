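"""Bijective stick-breaking / probit map between the order-constrained
probability space and the unconstrained real line.

Each chain element is processed from smallest to largest; within a free
group, members are processed in their fixed parse order.  A coordinate is
mapped through

    theta_k = (u_k - l_k) * Phi(xi_k) + l_k,      xi_k = Phi^{-1}((theta_k - l_k)/(u_k - l_k)),

where the lower bound l_k is the largest per-category mean of the previous
element (0 for the first) and the upper bound u_k is 1 for binomials.  For
multinomials the bounds act on per-category means eta_k = theta_k / m_k of
(possibly merged, size m_k) categories, the largest element is the remainder
of the stick, and u_k is the exact feasibility bound: the largest value that
still allows the remaining stick to be completed with unplaced free-group
peers at their lower bound and all later elements above the current
element's running maximum.  Because every bound depends only on earlier
coordinates the Jacobian is triangular and its log-determinant accumulates
as sum of log(m_k) + log(u_k - l_k) + log phi(xi_k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, ndtr, ndtri, xlog1py, xlogy

from .conjugate import log_multivariate_beta
from .restrictions import CollapsedProblem
from .sampling import ConstrainedSamples

__all__ = ["TransformedDraws", "to_real", "to_probability", "log_target_density_real"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _log_normal_pdf(xi: np.ndarray) -> np.ndarray:
    return -0.5 * xi * xi - _LOG_SQRT_2PI


@dataclass(frozen=True)
class _Part:
    coord: int
    size: float
    elem: int


def _plan(problem: CollapsedProblem) -> list[_Part]:
    rl = problem.restriction
    if len(rl.sections) != 1:
        raise ValueError(
            "the stick-breaking transform is defined per section; "
            "decompose multi-section problems first"
        )
    parts = [
        _Part(p[0], float(problem.group_sizes[p[0]]), e)
        for e, el in enumerate(rl.sections[0])
        for p in el.parts
    ]
    if len(parts) != problem.n_categories:
        raise ValueError("every category must appear in the restriction")
    if problem.family == "multinomial" and len(parts) < 2:
        raise ValueError("multinomial transform needs at least two categories")
    return parts


def n_real_dims(problem: CollapsedProblem) -> int:
    """Dimension of the real-line image: K for binomial, K - 1 for multinomial."""
    k = problem.n_categories
    return k if problem.family == "binomial" else k - 1


@dataclass(eq=False)
class TransformedDraws:
    """Draws mapped to the real line, with bounds trace and log-Jacobian."""

    xi: np.ndarray            # (n, d)
    log_jacobian: np.ndarray  # (n,)
    lower: np.ndarray         # (n, d) bounds on the per-category-mean scale
    upper: np.ndarray
    problem: CollapsedProblem


def _walk(problem: CollapsedProblem, n: int, get_eta):
    """Shared sequential pass.

    ``get_eta(step, l, u)`` returns the per-category mean of the part placed
    at ``step`` given its bounds; the walk tracks the remaining stick and the
    running element maximum and returns bookkeeping arrays.
    """
    parts = _plan(problem)
    binomial = problem.family == "binomial"
    d = n_real_dims(problem)
    lower = np.empty((n, d))
    upper = np.empty((n, d))
    theta = np.empty((n, problem.n_categories))
    remaining = np.ones(n)
    prev_max = np.zeros(n)
    cur_max = np.full(n, -np.inf)
    cur_elem = parts[0].elem

    # total sizes of parts after position i: peers in the same element / later elements
    sizes = np.array([p.size for p in parts])
    elems = np.array([p.elem for p in parts])
    for step, part in enumerate(parts):
        if part.elem != cur_elem:
            prev_max = np.where(np.isfinite(cur_max), cur_max, prev_max)
            cur_max = np.full(n, -np.inf)
            cur_elem = part.elem
        l = prev_max if part.elem > 0 else np.zeros(n)
        if binomial:
            u = np.ones(n)
        elif step == len(parts) - 1:
            # remainder of the stick: no free coordinate
            eta = remaining / part.size
            theta[:, part.coord] = remaining
            break
        else:
            rest = slice(step + 1, None)
            peers = (elems[rest] == part.elem)
            m_peers = sizes[rest][peers].sum()
            m_later = sizes[rest][~peers].sum()
            c1 = (remaining - m_peers * l) / (part.size + m_later)
            if np.all(np.isinf(cur_max) & (cur_max < 0)):
                u = c1
            else:
                placed_max = np.where(np.isfinite(cur_max), cur_max, -np.inf)
                c2 = (remaining - m_peers * l - m_later * placed_max) / part.size
                u = np.where(c1 >= placed_max, c1, c2)
        lower[:, step] = l
        upper[:, step] = u
        eta = get_eta(step, l, u)
        theta[:, part.coord] = eta * (part.size if not binomial else 1.0)
        if not binomial:
            remaining = remaining - theta[:, part.coord]
        cur_max = np.maximum(cur_max, eta)
    return parts, theta, lower, upper


def to_probability(
    xi: np.ndarray, problem: CollapsedProblem, target: str = "prior"
) -> ConstrainedSamples:
    """Forward map: real-line draws to constrained probability draws.

    Every finite input lands strictly inside the restricted region by
    construction.
    """
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    if xi.shape[1] != n_real_dims(problem):
        raise ValueError("xi has wrong dimension for this problem")

    def get_eta(step, l, u):
        return l + (u - l) * ndtr(xi[:, step])

    _, theta, _, _ = _walk(problem, len(xi), get_eta)
    return ConstrainedSamples(
        draws=theta, target=target, problem=problem,
        seed=None, n_burn=0, n_chains=1,
    )


def forward_log_jacobian(xi: np.ndarray, problem: CollapsedProblem):
    """Forward map returning (theta, log |dtheta/dxi|) per row."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    n = len(xi)
    logjac = np.zeros(n)

    def get_eta(step, l, u):
        z = xi[:, step]
        logjac[:] += np.log(u - l) + _log_normal_pdf(z)
        return l + (u - l) * ndtr(z)

    parts, theta, _, _ = _walk(problem, n, get_eta)
    if problem.family == "multinomial":
        logjac += sum(np.log(p.size) for p in parts[:-1])
    return theta, logjac


def to_real(samples: ConstrainedSamples) -> TransformedDraws:
    """Inverse map: constrained probability draws to the real line.

    Raises ``ValueError`` naming the first offending row if a draw sits on
    (or numerically beyond) a truncation boundary, where Phi^{-1} diverges.
    """
    problem = samples.problem
    draws = np.atleast_2d(samples.draws)
    n = len(draws)
    d = n_real_dims(problem)
    xi = np.empty((n, d))
    parts = _plan(problem)
    binomial = problem.family == "binomial"

    def get_eta(step, l, u):
        part = parts[step]
        eta = draws[:, part.coord] / (1.0 if binomial else part.size)
        ratio = (eta - l) / (u - l)
        bad = ~((ratio > 0.0) & (ratio < 1.0))
        if np.any(bad):
            raise ValueError(
                f"draw {int(np.argmax(bad))} lies on a transform boundary "
                f"at coordinate {part.coord}"
            )
        xi[:, step] = ndtri(ratio)
        return eta

    _, _, lower, upper = _walk(problem, n, get_eta)
    log_jac = np.zeros(n)
    for step, part in enumerate(parts if binomial else parts[:-1]):
        log_jac += np.log(upper[:, step] - lower[:, step])
        log_jac += _log_normal_pdf(xi[:, step])
        if not binomial:
            log_jac += np.log(part.size)
    return TransformedDraws(
        xi=xi, log_jacobian=log_jac, lower=lower, upper=upper, problem=problem
    )


def log_target_density_real(
    xi: np.ndarray, problem: CollapsedProblem, target: str = "prior"
) -> np.ndarray:
    """Log unnormalized constrained density on the real line, per row.

    The value is the normalized conjugate (encompassing) log-density at
    theta(xi) plus the log-Jacobian of the map; its normalizing constant
    over R^d is exactly the constrained region's probability mass, which the
    bridge sampler estimates.
    """
    theta, logjac = forward_log_jacobian(xi, problem)
    a, b = problem.target_params(target)
    if problem.family == "binomial":
        logpdf = (
            xlogy(a - 1.0, theta) + xlog1py(b - 1.0, -theta) - betaln(a, b)
        ).sum(axis=1)
    else:
        logpdf = xlogy(a - 1.0, theta).sum(axis=1) - log_multivariate_beta(a)
    return logpdf + logjac
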