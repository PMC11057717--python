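"""Scikit-learn style estimators for surprise-encoding cell models.

Each estimator represents one model family and is fit to a single cell's
recording by maximum likelihood under Poisson noise,

    L = sum_t n_t log f_t - f_t     (n_t! constant omitted),

maximized over the encoder gain/bias and the belief-model parameters with
multi-start local optimization (default 50 random starts).  ``X`` is the
binned binary stimulus of shape (T,); ``y`` the spike counts, either one
sweep of shape (T,) or repeats stacked as (R, T).  Leading warmup bins
without a full stimulus context are excluded from the likelihood.

Estimators follow the sklearn contract: ``get_params``/``set_params``,
``fit`` returning self, fitted attributes with trailing underscores,
``predict`` returning per-bin firing rates and ``score`` the Poisson
log-likelihood.

Parameters are optimized in unconstrained space (logit for transition
probabilities, log for prior pseudo-counts); random starts are drawn as
theta ~ U(0.05, 0.95), log alpha0, log beta0 ~ U(log 0.1, log 1e4),
a ~ U(0, 5), b ~ U(-5, 2), chosen to bracket plausible fitted values.
The start stream is sequential in the seed, so increasing ``n_starts``
only appends starts (best log-likelihood is monotone in ``n_starts``).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .beliefs import DEFAULT_ETA, BeliefPrior, MarkovParams, leaky_transition_counts
from .encoder import CellModel, EncoderParams, clamp_prob, predict_rates
from .stimulus import as_binned

RATE_FLOOR = 1e-10
_LOGIT_BOUND = 12.0
_LOG_COUNT_BOUNDS = (np.log(1e-3), np.log(1e6))
_GAIN_BOUNDS = (-50.0, 50.0)
_BIAS_BOUNDS = (-50.0, 20.0)

M2_CONTEXTS = ((0, 0), (0, 1), (1, 0), (1, 1))  # (x_{t-2}, x_{t-1})


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _validate_xy(X, y, n_warmup):
    x = as_binned(X).bins.astype(np.int64)
    y = np.asarray(y)
    if y.ndim == 1:
        y = y[None, :]
    if y.ndim != 2 or y.shape[1] != x.size:
        raise ValueError(
            f"counts must have shape (T,) or (R, T) with T={x.size}, got {y.shape}"
        )
    if np.any(y < 0):
        raise ValueError("spike counts must be nonnegative")
    if x.size < n_warmup + 2:
        raise ValueError("stimulus too short for this model order")
    n_total = y.sum(axis=0).astype(float)  # counts summed over repeats
    return x, n_total, y.shape[0]


class _SurpriseModelBase(BaseEstimator):
    """Shared multi-start Poisson ML machinery."""

    _n_warmup = 1

    def __init__(self, n_starts=50, random_state=None, maxiter=400):
        self.n_starts = n_starts
        self.random_state = random_state
        self.maxiter = maxiter

    # subclass interface -------------------------------------------------
    def _prepare(self, x):
        """Precompute stimulus-dependent quantities shared by all evals."""
        raise NotImplementedError

    def _predictive(self, z, prep):
        """p(x_t = 1 | context) at the valid bins, from packed params z."""
        raise NotImplementedError

    def _draw_start(self, rng):
        raise NotImplementedError

    def _bounds(self):
        raise NotImplementedError

    def _unpack(self, z):
        """Packed params -> CellModel."""
        raise NotImplementedError

    # fitting ------------------------------------------------------------
    def fit(self, X, y):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        x, n_total, n_repeats = _validate_xy(X, y, self._n_warmup)
        w = self._n_warmup
        xt = x[w:]
        n_valid = n_total[w:]
        prep = self._prepare(x)

        def negloglik(z):
            p1 = self._predictive(z, prep)
            p_obs = clamp_prob(np.where(xt == 1, p1, 1.0 - p1))
            s = -np.log(p_obs)
            lam = np.maximum(_softplus(z[-2] * s + z[-1]), RATE_FLOOR)
            return -(n_valid @ np.log(lam) - n_repeats * lam.sum())

        rng = np.random.default_rng(self.random_state)
        bounds = self._bounds()
        best = None
        start_logliks = []
        any_success = False
        for _ in range(self.n_starts):
            z0 = self._draw_start(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = minimize(
                    negloglik,
                    z0,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": self.maxiter},
                )
            start_logliks.append(-res.fun)
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res

        self.converged_ = any_success
        if not any_success:
            warnings.warn(
                f"{type(self).__name__}: no optimizer start converged; "
                "returning the best non-converged result",
                RuntimeWarning,
                stacklevel=2,
            )
        self.start_logliks_ = np.asarray(start_logliks)
        self.cell_ = self._unpack(best.x)
        self._set_fitted_params(best.x)
        self.gain_ = float(best.x[-2])
        self.bias_ = float(best.x[-1])
        # reported loglik re-evaluated through the public prediction path
        lam = predict_rates(self.cell_, x)[w:]
        self.loglik_ = float(n_valid @ np.log(np.maximum(lam, RATE_FLOOR)) - n_repeats * lam.sum())
        self.n_repeats_ = n_repeats
        return self

    def _set_fitted_params(self, z):
        raise NotImplementedError

    # prediction ---------------------------------------------------------
    def predict(self, X):
        """Per-bin firing rates (spikes per 120 ms bin) along a stimulus."""
        self._check_fitted()
        return predict_rates(self.cell_, X)

    def score(self, X, y):
        """Poisson log-likelihood of counts under the fitted model."""
        self._check_fitted()
        x, n_total, n_repeats = _validate_xy(X, y, self._n_warmup)
        w = self._n_warmup
        lam = np.maximum(predict_rates(self.cell_, x)[w:], RATE_FLOOR)
        return float(n_total[w:] @ np.log(lam) - n_repeats * lam.sum())

    def _check_fitted(self):
        if not hasattr(self, "cell_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted yet")

    @property
    def n_warmup(self):
        return self._n_warmup


class FixedSurpriseModel(_SurpriseModelBase):
    """Fixed (order-1 Markov) surprise model: 2 transition probs + gain/bias.

    The surprise of a bin depends only on the previous bin, so the model
    can emit at most four distinct firing rates.
    """

    _n_warmup = 1

    def _prepare(self, x):
        return {"ctx": x[:-1]}

    def _predictive(self, z, prep):
        theta = _expit(z[:2])
        return theta[prep["ctx"]]

    def _draw_start(self, rng):
        theta = rng.uniform(0.05, 0.95, size=2)
        a = rng.uniform(0.0, 5.0)
        b = rng.uniform(-5.0, 2.0)
        return np.concatenate((_logit(theta), [a, b]))

    def _bounds(self):
        return [(-_LOGIT_BOUND, _LOGIT_BOUND)] * 2 + [_GAIN_BOUNDS, _BIAS_BOUNDS]

    def _unpack(self, z):
        theta = _expit(z[:2])
        return CellModel(
            belief=MarkovParams(order=1, theta={0: theta[0], 1: theta[1]}),
            encoder=EncoderParams(a=float(z[-2]), b=float(z[-1])),
        )

    def _set_fitted_params(self, z):
        theta = _expit(z[:2])
        self.theta_ = {0: float(theta[0]), 1: float(theta[1])}


class Markov2SurpriseModel(_SurpriseModelBase):
    """Order-2 Markov surprise model: 4 transition probs + gain/bias."""

    _n_warmup = 2

    def _prepare(self, x):
        # context index 2*x_{t-2} + x_{t-1} at valid bins t >= 2
        return {"ctx": 2 * x[:-2] + x[1:-1]}

    def _predictive(self, z, prep):
        theta = _expit(z[:4])
        return theta[prep["ctx"]]

    def _draw_start(self, rng):
        theta = rng.uniform(0.05, 0.95, size=4)
        a = rng.uniform(0.0, 5.0)
        b = rng.uniform(-5.0, 2.0)
        return np.concatenate((_logit(theta), [a, b]))

    def _bounds(self):
        return [(-_LOGIT_BOUND, _LOGIT_BOUND)] * 4 + [_GAIN_BOUNDS, _BIAS_BOUNDS]

    def _unpack(self, z):
        theta = _expit(z[:4])
        mapping = {ctx: float(theta[2 * ctx[0] + ctx[1]]) for ctx in M2_CONTEXTS}
        return CellModel(
            belief=MarkovParams(order=2, theta=mapping),
            encoder=EncoderParams(a=float(z[-2]), b=float(z[-1])),
        )

    def _set_fitted_params(self, z):
        theta = _expit(z[:4])
        self.theta_ = {ctx: float(theta[2 * ctx[0] + ctx[1]]) for ctx in M2_CONTEXTS}


class AdaptiveSurpriseModel(_SurpriseModelBase):
    """Adaptive leaky beta-Bernoulli surprise model.

    Fits the per-context beta prior (alpha0_i, beta0_i) plus gain/bias;
    the leak ``eta`` is held fixed (shared across cells).  With
    ``reduced=True`` the prior mean is pinned to 1/2 (alpha0_i = beta0_i),
    leaving one strength parameter per context.

    The leaky transition counts depend only on (stimulus, eta), so they
    are precomputed once per fit; each likelihood evaluation is pure
    vectorized arithmetic.
    """

    _n_warmup = 1

    def __init__(self, eta=DEFAULT_ETA, reduced=False, n_starts=50, random_state=None, maxiter=400):
        super().__init__(n_starts=n_starts, random_state=random_state, maxiter=maxiter)
        self.eta = eta
        self.reduced = reduced

    def _prepare(self, x):
        counts = leaky_transition_counts(x, self.eta)
        ctx = x[:-1]
        t_prev = np.arange(x.size - 1)
        return {
            "ctx": ctx,
            "n1": counts[t_prev, ctx, 1],
            "n0": counts[t_prev, ctx, 0],
        }

    def _prior_arrays(self, z):
        if self.reduced:
            v = np.exp(z[:2])
            return v, v
        return np.exp(z[:2]), np.exp(z[2:4])

    def _predictive(self, z, prep):
        a0, b0 = self._prior_arrays(z)
        ctx = prep["ctx"]
        n1, n0 = prep["n1"], prep["n0"]
        return (n1 + a0[ctx]) / (n1 + n0 + a0[ctx] + b0[ctx])

    def _n_prior_params(self):
        return 2 if self.reduced else 4

    def _draw_start(self, rng):
        logc = rng.uniform(np.log(0.1), np.log(1e4), size=self._n_prior_params())
        a = rng.uniform(0.0, 5.0)
        b = rng.uniform(-5.0, 2.0)
        return np.concatenate((logc, [a, b]))

    def _bounds(self):
        return [_LOG_COUNT_BOUNDS] * self._n_prior_params() + [_GAIN_BOUNDS, _BIAS_BOUNDS]

    def _unpack(self, z):
        a0, b0 = self._prior_arrays(z)
        prior = BeliefPrior(
            alpha0={0: float(a0[0]), 1: float(a0[1])},
            beta0={0: float(b0[0]), 1: float(b0[1])},
            eta=self.eta,
        )
        return CellModel(
            belief=prior, encoder=EncoderParams(a=float(z[-2]), b=float(z[-1]))
        )

    def _set_fitted_params(self, z):
        a0, b0 = self._prior_arrays(z)
        self.alpha0_ = {0: float(a0[0]), 1: float(a0[1])}
        self.beta0_ = {0: float(b0[0]), 1: float(b0[1])}
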