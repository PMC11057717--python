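"""Maximum-likelihood fitting wrappers and model comparison.

Thin functional layer over the sklearn-style estimators in
``rgcsurprise.models``: ``fit_cell`` fits one cell with multi-start
Poisson ML, ``poisson_loglik`` is the likelihood primitive,
``compare_fits`` runs the paired per-cell correlation comparison with a
two-sided Wilcoxon signed-rank test.

The likelihood is computed on raw per-bin counts (summed across repeats);
history-conditioned means are used only for reporting correlations
between model prediction and data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, wilcoxon

from .analysis import _pearson, history_conditioned_means
from .encoder import CellModel, predict_rates
from .models import (
    AdaptiveSurpriseModel,
    FixedSurpriseModel,
    Markov2SurpriseModel,
    RATE_FLOOR,
)
from .stimulus import as_binned

MODEL_KINDS = ("fixed", "markov2", "adaptive", "adaptive_reduced")
DEFAULT_CORRELATION_DEPTH = 8


@dataclass(frozen=True)
class FitResult:
    """Outcome of one multi-start ML fit of a single cell."""

    model_kind: str
    params: CellModel
    loglik: float
    n_starts: int
    start_logliks: np.ndarray
    correlation: float
    converged: bool
    n_warmup: int


def make_estimator(model_kind: str, n_starts: int = 50, seed=None, eta: float | None = None):
    """Construct the estimator class for a model-kind label."""
    if model_kind == "fixed":
        return FixedSurpriseModel(n_starts=n_starts, random_state=seed)
    if model_kind == "markov2":
        return Markov2SurpriseModel(n_starts=n_starts, random_state=seed)
    if model_kind in ("adaptive", "adaptive_reduced"):
        kwargs = {} if eta is None else {"eta": eta}
        return AdaptiveSurpriseModel(
            reduced=(model_kind == "adaptive_reduced"),
            n_starts=n_starts,
            random_state=seed,
            **kwargs,
        )
    raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")


def poisson_loglik(counts, rates) -> float:
    """Poisson log-likelihood sum_t n_t log f_t - f_t (n_t! omitted)."""
    n = np.asarray(counts, dtype=float)
    f = np.asarray(rates, dtype=float)
    if n.shape != f.shape:
        raise ValueError(f"length mismatch: counts {n.shape} vs rates {f.shape}")
    if np.any(n < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(f <= 0):
        raise ValueError("rates must be strictly positive")
    return float(np.sum(n * np.log(f) - f))


def evaluate_loglik(stim, counts, cell: CellModel) -> float:
    """Re-evaluate the fit likelihood of a cell model (warmup bins excluded)."""
    x = as_binned(stim)
    y = np.asarray(counts)
    if y.ndim == 1:
        y = y[None, :]
    w = cell.n_warmup
    lam = np.maximum(predict_rates(cell, x)[w:], RATE_FLOOR)
    n_total = y.sum(axis=0).astype(float)[w:]
    return float(n_total @ np.log(lam) - y.shape[0] * lam.sum())


def prediction_correlation(
    cell: CellModel, stim, counts, depth: int = DEFAULT_CORRELATION_DEPTH
) -> float:
    """Pearson r between model and data on depth-``depth`` history means.

    Both the empirical mean counts and the model's mean rates are
    conditioned on the 2^depth terminal histories; r is computed over the
    histories observed in the data (deepest tree level).
    """
    stim = as_binned(stim)
    rates = predict_rates(cell, stim)
    tree_data = history_conditioned_means(counts, stim, n=depth)
    tree_model = history_conditioned_means(rates, stim, n=depth)
    common = sorted(
        set(tree_data.depth_nodes(depth)) & set(tree_model.depth_nodes(depth))
    )
    a = [tree_data.nodes[h].mean_response for h in common]
    b = [tree_model.nodes[h].mean_response for h in common]
    return _pearson(a, b)


def fit_cell(
    stim,
    counts,
    model_kind: str,
    n_starts: int = 50,
    seed=None,
    eta: float | None = None,
    correlation_depth: int = DEFAULT_CORRELATION_DEPTH,
) -> FitResult:
    """Multi-start Poisson-ML fit of one cell under one model family.

    ``counts`` is (T,) or (R, T).  Returns the best start; a fit where no
    start converged is flagged via ``converged=False`` (and a warning),
    never silently dropped.
    """
    est = make_estimator(model_kind, n_starts=n_starts, seed=seed, eta=eta)
    est.fit(stim, counts)
    corr = prediction_correlation(est.cell_, stim, counts, depth=correlation_depth)
    return FitResult(
        model_kind=model_kind,
        params=est.cell_,
        loglik=est.loglik_,
        n_starts=n_starts,
        start_logliks=est.start_logliks_,
        correlation=corr,
        converged=est.converged_,
        n_warmup=est.n_warmup,
    )


@dataclass(frozen=True)
class FitComparison:
    """Paired per-cell correlation comparison between two model families."""

    corr_a: np.ndarray
    corr_b: np.ndarray
    statistic: float
    pvalue: float
    n_cells: int
    degenerate: bool
    reliable: bool


def compare_fits(results_a, results_b) -> FitComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-cell correlations.

    ``results_a``/``results_b`` are per-cell FitResults (same cells, same
    order).  Zero differences are discarded (standard signed-rank
    procedure); with all-zero differences the test is degenerate and
    reported as such (p = 1).  With fewer than 6 cells the p-value is
    flagged unreliable.
    """
    ca = np.asarray([r.correlation for r in results_a], dtype=float)
    cb = np.asarray([r.correlation for r in results_b], dtype=float)
    if ca.shape != cb.shape:
        raise ValueError("result lists must cover the same cells")
    n = ca.size
    diffs = ca - cb
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return FitComparison(ca, cb, 0.0, 1.0, n, True, n >= 6)
    stat, p = wilcoxon(ca, cb, zero_method="wilcox", alternative="two-sided")
    # signed statistic: rank-sum of positive minus negative differences
    ranks = rankdata(np.abs(nonzero))
    signed = float(np.sum(ranks[nonzero > 0]) - np.sum(ranks[nonzero < 0]))
    return FitComparison(ca, cb, signed, float(p), n, False, n >= 6)
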