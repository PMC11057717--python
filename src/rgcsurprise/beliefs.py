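"""Internal belief models assigning p(flash | history).

Four model families are provided:

* **Fixed Markov** (order 1 or 2): transition probabilities
  ``theta_i = p(x_t = 1 | context i)`` are known constants.  The order-1
  model has two parameters (theta_0, theta_1); the order-2 model four.
* **Adaptive leaky beta-Bernoulli**: transition probabilities are
  inferred online.  A beta prior ``Beta(alpha0_i, beta0_i)`` per context
  is combined with leaky (exponentially forgotten) transition counts; the
  posterior-predictive is the pseudo-count ratio

      p(x_t = 1 | x_{t-1} = i, ...) = (n~_{i->1} + alpha0_i)
                                      / (n~_{i->1} + n~_{i->0} + alpha0_i + beta0_i)

  where ``n~_{i->j} = sum_k (1-eta)^k [x_{t-k}=j][x_{t-1-k}=i]`` is the
  leak-discounted number of observed i->j transitions.  The leak ``eta``
  approximates exact inference under slowly changing statistics while
  keeping the updates linear.
* **Dynamic belief reference**: exact Bayesian filtering on a discretized
  theta grid, assuming the transition probabilities redraw from the prior
  with a fixed probability at every step.  Serves as the reference the
  leaky model approximates.

Pseudo-count bookkeeping: ``BeliefState.alpha[i]`` stores
``alpha0_i + n~_{i->1}`` (likewise beta), so the predictive is simply
``alpha_i / (alpha_i + beta_i)`` and the no-observation fixed point of the
leak is the prior itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.signal import lfilter
from scipy.stats import beta as beta_dist

DEFAULT_ETA = 0.2


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovParams:
    """Fixed transition probabilities for a binary Markov model.

    ``theta`` maps context -> p(flash | context).  Order-1 contexts are
    0 and 1 (previous bin); order-2 contexts are pairs
    ``(x_{t-2}, x_{t-1})`` over {0,1}^2.
    """

    order: int
    theta: Mapping

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")
        theta = dict(self.theta)
        expected = (
            {0, 1} if self.order == 1 else {(a, b) for a in (0, 1) for b in (0, 1)}
        )
        if set(theta) != expected:
            raise ValueError(f"theta must have contexts {sorted(expected)}")
        for k, v in theta.items():
            if not (0.0 < v < 1.0):
                raise ValueError(f"theta[{k}] must be in (0, 1), got {v}")
        object.__setattr__(self, "theta", theta)


@dataclass(frozen=True)
class BeliefPrior:
    """Per-context beta prior (alpha0_i, beta0_i) plus the leak eta."""

    alpha0: Mapping[int, float]
    beta0: Mapping[int, float]
    eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        a, b = dict(self.alpha0), dict(self.beta0)
        if set(a) != {0, 1} or set(b) != {0, 1}:
            raise ValueError("alpha0 and beta0 must map contexts {0, 1}")
        for i in (0, 1):
            if a[i] <= 0 or b[i] <= 0:
                raise ValueError("alpha0 and beta0 must be strictly positive")
        if not (0.0 <= self.eta < 1.0):
            raise ValueError(f"eta must be in [0, 1), got {self.eta}")
        object.__setattr__(self, "alpha0", a)
        object.__setattr__(self, "beta0", b)

    def prior_mean(self, context: int) -> float:
        return self.alpha0[context] / (self.alpha0[context] + self.beta0[context])


@dataclass(frozen=True)
class BeliefState:
    """Effective pseudo-counts per context; alpha[i] = alpha0_i + n~_{i->1}."""

    alpha: Mapping[int, float]
    beta: Mapping[int, float]
    prev_x: int | None = None

    def __post_init__(self) -> None:
        a, b = dict(self.alpha), dict(self.beta)
        for i in (0, 1):
            if a[i] < 0 or b[i] < 0:
                raise ValueError("pseudo-counts must be nonnegative")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)


# ---------------------------------------------------------------------------
# fixed Markov models
# ---------------------------------------------------------------------------

def markov_prob(params: MarkovParams, context, x: int) -> float:
    """p(x | context) under a fixed Markov model.

    ``context`` is the most recent history: an int (or length->=1 sequence)
    for order 1, a length->=2 sequence ``(..., x_{t-2}, x_{t-1})`` for
    order 2 (only the trailing ``order`` symbols are used).
    """
    if x not in (0, 1):
        raise ValueError(f"x must be 0 or 1, got {x}")
    if params.order == 1:
        key = context if isinstance(context, (int, np.integer)) else context[-1]
        if isinstance(key, (tuple, list)) or key not in (0, 1):
            raise ValueError("order-1 context must end in 0 or 1")
    else:
        if isinstance(context, (int, np.integer)) or len(context) < 2:
            raise ValueError("order-2 context needs at least 2 symbols")
        key = (int(context[-2]), int(context[-1]))
    theta = params.theta[key]
    return theta if x == 1 else 1.0 - theta


def markov_predictive_sequence(params: MarkovParams, x: np.ndarray) -> np.ndarray:
    """Vectorized p(x_t = 1 | history) along a binary sequence.

    Entry t is defined for t >= order; earlier entries use a zero-padded
    context (warmup bins, excluded from likelihoods downstream).
    """
    x = np.asarray(x, dtype=np.int64)
    T = x.size
    padded = np.concatenate((np.zeros(params.order, dtype=np.int64), x))
    if params.order == 1:
        lut = np.array([params.theta[0], params.theta[1]])
        ctx = padded[:T]  # x_{t-1}, zero-padded
        return lut[ctx]
    lut = np.array(
        [params.theta[(a, b)] for a in (0, 1) for b in (0, 1)]
    )  # index 2a + b
    ctx = 2 * padded[:T] + padded[1 : T + 1]  # (x_{t-2}, x_{t-1})
    return lut[ctx]


# ---------------------------------------------------------------------------
# adaptive leaky beta-Bernoulli model
# ---------------------------------------------------------------------------

def init_state(prior: BeliefPrior) -> BeliefState:
    """State before any observation: the leak's fixed point (the prior)."""
    return BeliefState(alpha=dict(prior.alpha0), beta=dict(prior.beta0), prev_x=None)


def update_state(state: BeliefState, x_t: int, prior: BeliefPrior) -> BeliefState:
    """One observation step of the leaky update.

    Both contexts decay toward their prior (pure exponential forgetting);
    the active context ``i = prev_x`` additionally gains the unit count for
    the observed transition.  The first observation only sets ``prev_x``.
    """
    if x_t not in (0, 1):
        raise ValueError(f"x_t must be 0 or 1, got {x_t}")
    if state.prev_x is None:
        return replace(state, prev_x=int(x_t))
    eta = prior.eta
    alpha, beta = dict(state.alpha), dict(state.beta)
    for i in (0, 1):
        alpha[i] = (1.0 - eta) * alpha[i] + eta * prior.alpha0[i]
        beta[i] = (1.0 - eta) * beta[i] + eta * prior.beta0[i]
    i = state.prev_x
    if x_t == 1:
        alpha[i] += 1.0
    else:
        beta[i] += 1.0
    return BeliefState(alpha=alpha, beta=beta, prev_x=int(x_t))


def predictive_prob(state: BeliefState, context: int) -> float:
    """Posterior-predictive p(x_t = 1 | context) from the pseudo-counts."""
    if context not in (0, 1):
        raise ValueError(f"context must be 0 or 1, got {context}")
    a, b = state.alpha[context], state.beta[context]
    return a / (a + b)


def effective_counts_bruteforce(history, eta: float, i: int, j: int) -> float:
    """Leak-discounted transition count n~_{i->j} by direct summation.

    Computes ``sum_k (1-eta)^k [x_{t-k} = j][x_{t-1-k} = i]`` over the whole
    history (k = 0 is the most recent transition).  Independent oracle for
    the recursive update.
    """
    x = np.asarray(getattr(history, "bins", history), dtype=np.int64)
    if x.size < 2:
        raise ValueError("history must contain at least 2 bins")
    total = 0.0
    T = x.size
    for k in range(T - 1):
        total += (1.0 - eta) ** k * float(x[T - 1 - k] == j) * float(x[T - 2 - k] == i)
    return total


def leaky_transition_counts(x: np.ndarray, eta: float) -> np.ndarray:
    """Leaky counts n~_{i->j}[t] for all 4 transitions along a sequence.

    Returns an array of shape (T, 2, 2): entry ``[t, i, j]`` is the
    discounted count of i->j transitions among those ending at bins <= t.
    The recursion ``n~[t] = (1-eta) n~[t-1] + e[t]`` (with ``e[t]`` the
    indicator of the transition ending at bin t) is evaluated as an IIR
    filter, which makes downstream likelihoods O(T) vectorized.
    """
    x = np.asarray(x, dtype=np.int64)
    T = x.size
    out = np.zeros((T, 2, 2))
    if T < 2:
        return out
    prev, cur = x[:-1], x[1:]
    for i in (0, 1):
        for j in (0, 1):
            e = ((prev == i) & (cur == j)).astype(float)
            out[1:, i, j] = lfilter([1.0], [1.0, -(1.0 - eta)], e)
    return out


def adaptive_predictive_sequence(prior: BeliefPrior, x: np.ndarray) -> np.ndarray:
    """Vectorized p(x_t = 1 | history) under the adaptive leaky model.

    Entry 0 (no context) uses the context-0 prior mean; it is a warmup bin.
    """
    x = np.asarray(x, dtype=np.int64)
    T = x.size
    counts = leaky_transition_counts(x, prior.eta)
    a0 = np.array([prior.alpha0[0], prior.alpha0[1]])
    b0 = np.array([prior.beta0[0], prior.beta0[1]])
    p = np.empty(T)
    p[0] = prior.prior_mean(0)
    if T > 1:
        ctx = x[:-1]
        t_prev = np.arange(T - 1)  # counts available before observing x_t
        n1 = counts[t_prev, ctx, 1]
        n0 = counts[t_prev, ctx, 0]
        p[1:] = (n1 + a0[ctx]) / (n1 + n0 + a0[ctx] + b0[ctx])
    return p


# ---------------------------------------------------------------------------
# dynamic belief reference (grid filter)
# ---------------------------------------------------------------------------

def dynamic_grid_predict(
    history,
    prior: BeliefPrior,
    change_prob: float = 0.01,
    grid_size: int = 200,
) -> np.ndarray:
    """Exact-inference reference: Bayesian filtering over a theta grid.

    Per context i, maintains a posterior over ``theta_i`` on ``grid_size``
    cell midpoints in (0, 1), initialized from the beta prior.  At every
    step the posterior mixes with the prior with weight ``change_prob``
    (the chance the world redrew its transition probabilities), then the
    observed transition's Bernoulli likelihood is applied and the posterior
    renormalized.  Returns p(x_t = 1 | past) per bin (bin 0 = prior mean,
    context 0, as a warmup value).

    With ``change_prob = 0`` this reduces to conjugate (non-leaky)
    beta-Bernoulli updating up to grid error; with ``change_prob = 1`` the
    predictive is the prior mean at every step.
    """
    if not (0.0 <= change_prob <= 1.0):
        raise ValueError(f"change_prob must be in [0, 1], got {change_prob}")
    if grid_size < 50:
        raise ValueError(f"grid_size must be >= 50, got {grid_size}")
    x = np.asarray(getattr(history, "bins", history), dtype=np.int64)
    T = x.size
    edges = np.linspace(0.0, 1.0, grid_size + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    w_prior = {}
    w = {}
    for i in (0, 1):
        cdf = beta_dist.cdf(edges, prior.alpha0[i], prior.beta0[i])
        wp = np.diff(cdf)
        wp = wp / wp.sum()
        w_prior[i] = wp
        w[i] = wp.copy()
    p = np.empty(T)
    p[0] = float(np.dot(w[0], mids))
    for t in range(1, T):
        i = int(x[t - 1])
        for c in (0, 1):
            w[c] = (1.0 - change_prob) * w[c] + change_prob * w_prior[c]
        p[t] = float(np.dot(w[i], mids))
        lik = mids if x[t] == 1 else 1.0 - mids
        w[i] = w[i] * lik
        w[i] = w[i] / w[i].sum()
    return p
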