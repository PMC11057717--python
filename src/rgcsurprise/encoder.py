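"""Surprise -> firing rate -> Poisson spike counts.

A cell's firing rate in bin t is a static nonlinearity applied to the
surprise of the realized bin outcome:

    s_t      = -log p(x_t | history, theta)
    lambda_t = softplus(a * s_t + b)

with gain ``a`` and bias ``b`` fitted per cell and the softplus
``log(1 + e^x)`` fixed.  Spike counts are Poisson with mean lambda_t.

Probabilities are clamped to [1e-12, 1 - 1e-12] before the log so the
surprise stays finite even at degenerate fitted transition probabilities.
Bin 0 (and bin 1 for the order-2 Markov model) has no full context; its
rate is computed from a zero-padded context / prior-mean predictive and
is excluded from likelihoods and analyses (see ``CellModel.n_warmup``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .beliefs import (
    BeliefPrior,
    MarkovParams,
    adaptive_predictive_sequence,
    markov_predictive_sequence,
)
from .stimulus import as_binned

P_CLIP = 1e-12


@dataclass(frozen=True)
class EncoderParams:
    """Gain ``a`` and bias ``b`` of the rate nonlinearity."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("gain and bias must be finite")


@dataclass(frozen=True)
class CellModel:
    """Full generative model of one cell: belief model + encoder.

    ``belief`` is a MarkovParams (fixed / Markov-2) or a BeliefPrior
    (adaptive leaky model).
    """

    belief: Union[MarkovParams, BeliefPrior]
    encoder: EncoderParams

    @property
    def kind(self) -> str:
        if isinstance(self.belief, BeliefPrior):
            return "adaptive"
        return "fixed" if self.belief.order == 1 else "markov2"

    @property
    def n_warmup(self) -> int:
        """Leading bins without a full context, excluded from likelihoods."""
        if isinstance(self.belief, MarkovParams):
            return self.belief.order
        return 1


def clamp_prob(p) -> np.ndarray:
    return np.clip(p, P_CLIP, 1.0 - P_CLIP)


def surprise(p_x, x_t) -> np.ndarray:
    """Surprise -log p(x_t); ``p_x`` is p(x_t = 1), scalar or array."""
    p = clamp_prob(np.asarray(p_x, dtype=float))
    x = np.asarray(x_t)
    return np.where(x == 1, -np.log(p), -np.log(1.0 - p))[()]


def softplus(x) -> np.ndarray:
    """Overflow-safe log(1 + e^x)."""
    x = np.asarray(x, dtype=float)
    return (np.logaddexp(0.0, x))[()]


def rate(s, enc: EncoderParams) -> np.ndarray:
    """Firing rate softplus(a*s + b); monotone in s for a > 0."""
    return softplus(enc.a * np.asarray(s, dtype=float) + enc.b)


def predictive_sequence(belief, x: np.ndarray) -> np.ndarray:
    """p(x_t = 1 | history) per bin for any belief model."""
    if isinstance(belief, BeliefPrior):
        return adaptive_predictive_sequence(belief, x)
    return markov_predictive_sequence(belief, x)


def predict_rates(cell: CellModel, stim) -> np.ndarray:
    """Per-bin firing rates of a cell run causally along a stimulus."""
    stim = as_binned(stim)
    if len(stim) < 2:
        raise ValueError("stimulus must contain at least 2 bins")
    x = stim.bins
    p1 = predictive_sequence(cell.belief, x)
    s = surprise(p1, x)
    return rate(s, cell.encoder)


def sample_counts(rates, seed) -> np.ndarray:
    """Independent Poisson spike counts per bin, reproducible under seed."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite and strictly positive")
    rng = np.random.default_rng(seed)
    return rng.poisson(rates)
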