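"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, textbook
recursions, one-dimensional quadrature) and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def naive_log_partial_likelihood(time, event, group, beta_fn):
    """Direct double-loop Cox log partial likelihood.

    ``beta_fn`` maps a time to the log hazard ratio at that time.
    Breslow convention: every event contributes its own factor with the
    full risk set {j : X_j >= X_i} in the denominator.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    total = 0.0
    for i in range(time.size):
        if event[i] != 1:
            continue
        b = beta_fn(time[i])
        num = group[i] * b
        denom = 0.0
        for j in range(time.size):
            if time[j] >= time[i]:
                denom += np.exp(group[j] * b)
        total += num - np.log(denom)
    return total


def cox_de_boor(knots, degree, i, t):
    """Textbook Cox-de Boor recursion for the i-th B-spline basis function."""
    knots = np.asarray(knots, float)
    if degree == 0:
        # half-open spans; the last nonzero span is closed on the right
        if knots[i] <= t < knots[i + 1]:
            return 1.0
        if t == knots[-1] and knots[i] < knots[i + 1] == knots[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + degree] > knots[i]:
        left = (t - knots[i]) / (knots[i + degree] - knots[i]) * cox_de_boor(
            knots, degree - 1, i, t
        )
    right = 0.0
    if knots[i + degree + 1] > knots[i + 1]:
        right = (knots[i + degree + 1] - t) / (
            knots[i + degree + 1] - knots[i + 1]
        ) * cox_de_boor(knots, degree - 1, i + 1, t)
    return left + right


def constant_beta_posterior_by_quadrature(ds, sigma2=1.0, L=10.0, n_grid=10001):
    """P(eta=1 | D) for a single constant basis function, by 1-D quadrature.

    With one basis function equal to 1 everywhere, the alternative is an
    ordinary constant log hazard ratio gamma, so the marginal likelihood
    of the alternative is a one-dimensional integral over the truncated
    normal prior.  The inclusion indicator's prior odds are 1 (q is
    uniform), hence P(eta=1|D) = m1 / (m1 + P0).
    """
    from scipy.special import logsumexp, ndtr

    time, event, group = ds.time, ds.event, ds.group
    grid = np.linspace(-L, L, n_grid)
    c_L = ndtr(L / np.sqrt(sigma2)) - ndtr(-L / np.sqrt(sigma2))
    log_prior = (
        -0.5 * grid**2 / sigma2
        - 0.5 * np.log(2 * np.pi * sigma2)
        - np.log(c_L)
    )
    ll = np.array(
        [
            naive_log_partial_likelihood(time, event, group, lambda t, g=g: g)
            for g in grid
        ]
    )
    dx = grid[1] - grid[0]
    log_m1 = logsumexp(ll + log_prior) + np.log(dx)
    log_p0 = naive_log_partial_likelihood(time, event, group, lambda t: 0.0)
    return 1.0 / (1.0 + np.exp(log_p0 - log_m1))


def hypergeometric_log_rank(time, event, group):
    """Brute-force log rank statistic from explicit 2x2 tables."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    u = 0.0
    v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        y = at_risk.sum()
        y1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        u += d1 - d * y1 / y
        if y > 1:
            v += d * (y1 / y) * (1 - y1 / y) * (y - d) / (y - 1)
    return u, v
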