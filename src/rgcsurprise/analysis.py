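"""Descriptive and diagnostic analyses of flash-sequence responses.

Tree-plots index the mean response by the exact terminal stimulus history
(the most recent d bins, including the current one), branching by history
depth; the top branch — k consecutive flashes then a silence — is the
omitted stimulus response (OSR) curve.  Additional diagnostics: per-depth
correlation between data and model trees, per-depth branching distance,
PSTH computation and OSR detection on millisecond spike times, refractory
QC, and summaries of fitted beta priors (prior mean ratio, prior strength,
strong/weak split).

History tuples follow the package convention: element 0 is the OLDEST bin,
element -1 the current bin.  All depths of a tree are computed over the
same bin range (t >= depth_max) so the parent/child conservation
invariants hold exactly; unobserved histories are reported as missing,
never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .stimulus import as_binned

STRONG_PRIOR_LOG_THRESHOLD = 7.0
OSR_WINDOW_MS = (60.0, 180.0)
OSR_BASELINE_FACTOR = 2.0
REFRACTORY_MS = 2.0


@dataclass(frozen=True)
class TreeNode:
    mean_response: float
    n_obs: int


@dataclass(frozen=True)
class TreePlot:
    """Mean response per terminal stimulus history.

    ``nodes`` maps history tuples (oldest first, last element = current
    bin) of length 1..depth_max to (mean response, number of observed
    bins).  Unobserved histories are absent.
    """

    depth_max: int
    nodes: Mapping[tuple, TreeNode]

    def at(self, history) -> TreeNode | None:
        return self.nodes.get(tuple(int(v) for v in history))

    def depth_nodes(self, depth: int) -> dict[tuple, TreeNode]:
        return {h: nd for h, nd in self.nodes.items() if len(h) == depth}

    def ending_in(self, symbol: int) -> dict[tuple, TreeNode]:
        """Subset of nodes whose current bin is ``symbol`` (0 or 1)."""
        return {h: nd for h, nd in self.nodes.items() if h[-1] == symbol}


@dataclass(frozen=True)
class Psth:
    """Trial-averaged response on a fine time grid (spikes per bin)."""

    bin_ms: float
    values: np.ndarray
    window_ms: tuple
    n_repeats: int
    alignment: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("PSTH values must be nonnegative")
        object.__setattr__(self, "values", v)

    def times_ms(self) -> np.ndarray:
        """Bin-center times relative to the alignment event."""
        lo, _ = self.window_ms
        return lo + (np.arange(self.values.size) + 0.5) * self.bin_ms


def compute_psth(
    spike_times_ms: Sequence[Sequence[float]],
    align_ms: float,
    window_ms: tuple,
    bin_ms: float = 5.0,
    alignment: str = "",
) -> Psth:
    """Mean spike count per ``bin_ms`` bin across repeats, aligned to an event."""
    if len(spike_times_ms) < 1:
        raise ValueError("need at least one repeat")
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError("empty PSTH window")
    n_bins = int(math.ceil((hi - lo) / bin_ms))
    edges = lo + np.arange(n_bins + 1) * bin_ms
    acc = np.zeros(n_bins)
    for rep in spike_times_ms:
        rel = np.asarray(rep, dtype=float) - align_ms
        acc += np.histogram(rel, bins=edges)[0]
    return Psth(
        bin_ms=bin_ms,
        values=acc / len(spike_times_ms),
        window_ms=(float(lo), float(hi)),
        n_repeats=len(spike_times_ms),
        alignment=alignment,
    )


def history_conditioned_means(counts, stim, n: int = 8) -> TreePlot:
    """Tree-plot of mean responses conditioned on the last-d-bin history.

    ``counts`` is a response per bin — spike counts (one sweep or repeats
    stacked as (R, T), averaged across repeats) or model rates.  For every
    history h of length d <= n, the mean response over all bins t >= n
    whose trailing d bins equal h.  Using the common range t >= n for all
    depths makes the parent/child conservation invariants exact.
    """
    stim = as_binned(stim)
    x = stim.bins.astype(np.int64)
    y = np.asarray(counts, dtype=float)
    if y.ndim == 2:
        y = y.mean(axis=0)
    if y.shape != x.shape:
        raise ValueError("counts and stimulus must have the same length")
    if not (1 <= n <= 20):
        raise ValueError("history depth n must be in [1, 20]")
    T = x.size
    if T <= n:
        raise ValueError("stimulus shorter than the requested history depth")
    t0 = n  # common bin range for all depths (also skips warmup bin 0)
    # code[t] for depth d: integer formed by bins t-d+1..t, oldest most significant
    nodes: dict[tuple, TreeNode] = {}
    code = np.zeros(T - t0, dtype=np.int64)
    resp = y[t0:]
    for d in range(1, n + 1):
        code = code + (x[t0 - d + 1 : T - d + 1].astype(np.int64) << (d - 1))
        order = np.argsort(code, kind="stable")
        sorted_code = code[order]
        sorted_resp = resp[order]
        uniq, start_idx = np.unique(sorted_code, return_index=True)
        sums = np.add.reduceat(sorted_resp, start_idx)
        cnts = np.diff(np.append(start_idx, sorted_code.size))
        for u, s, c in zip(uniq, sums, cnts):
            h = tuple((int(u) >> (d - 1 - b)) & 1 for b in range(d))
            nodes[h] = TreeNode(mean_response=float(s / c), n_obs=int(c))
    return TreePlot(depth_max=n, nodes=nodes)


def osr_curve(tree: TreePlot, k_max: int) -> dict[int, float | None]:
    """Mean response after k consecutive flashes followed by one silence.

    The top branch of the tree-plot: history (1,)*k + (0,).  Missing
    (unobserved) branches map to None.
    """
    if tree.depth_max < k_max + 1:
        raise ValueError("tree depth must be at least k_max + 1")
    out: dict[int, float | None] = {}
    for k in range(1, k_max + 1):
        node = tree.at((1,) * k + (0,))
        out[k] = None if node is None else node.mean_response
    return out


def _pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def tree_correlation_by_depth(
    tree_data: TreePlot, tree_model: TreePlot
) -> dict[int, float | None]:
    """Pearson r between two trees' node means, separately per depth.

    Only nodes observed in both trees enter; depths with fewer than 3
    common nodes yield None.
    """
    depth = min(tree_data.depth_max, tree_model.depth_max)
    out: dict[int, float | None] = {}
    for d in range(1, depth + 1):
        common = sorted(
            set(tree_data.depth_nodes(d)) & set(tree_model.depth_nodes(d))
        )
        if len(common) < 3:
            out[d] = None
            continue
        a = [tree_data.nodes[h].mean_response for h in common]
        b = [tree_model.nodes[h].mean_response for h in common]
        r = _pearson(a, b)
        out[d] = None if np.isnan(r) else r
    return out


def branching_distance(tree: TreePlot, signed: bool = False) -> dict[int, float | None]:
    """Per-depth mean difference between sibling branches.

    Siblings at depth d share the most recent d-1 bins and differ in the
    oldest (d-th past) bin.  For each such pair the difference
    mean(flash-sibling) - mean(silence-sibling) is taken (absolute value
    unless ``signed``), then averaged over pairs.  Depths with no complete
    sibling pair yield None.
    """
    out: dict[int, float | None] = {}
    for d in range(2, tree.depth_max + 1):
        diffs = []
        for h, node in tree.depth_nodes(d).items():
            if h[0] != 1:
                continue
            sib = tree.at((0,) + h[1:])
            if sib is None:
                continue
            delta = node.mean_response - sib.mean_response
            diffs.append(delta if signed else abs(delta))
        out[d] = float(np.mean(diffs)) if diffs else None
    return out


def qc_refractory(spike_times_ms, refractory_ms: float = REFRACTORY_MS) -> float:
    """Fraction of inter-spike intervals shorter than the refractory period.

    Cells are kept when the fraction is below 1%.
    """
    t = np.sort(np.asarray(spike_times_ms, dtype=float))
    if t.size < 2:
        return 0.0
    isi = np.diff(t)
    return float(np.mean(isi < refractory_ms))


def detect_osr(
    psth: Psth,
    omitted_flash_ms: float,
    window_ms: tuple = OSR_WINDOW_MS,
    baseline_factor: float = OSR_BASELINE_FACTOR,
    baseline_span_ms: float = 120.0,
) -> dict:
    """Detect an omitted stimulus response in a PSTH.

    Positive iff the PSTH maximum within ``window_ms`` after the omitted
    flash exceeds ``baseline_factor`` times the baseline, where the
    baseline is the mean over the preceding inter-flash interval
    (``baseline_span_ms`` before the omission).  Returns a dict with keys
    ``detected``, ``peak``, ``peak_ms``, ``baseline``.
    """
    # bin-center times relative to the omitted flash (omitted_flash_ms is on
    # the same clock as the PSTH alignment event)
    rel = psth.times_ms() - omitted_flash_ms
    in_win = (rel >= window_ms[0]) & (rel <= window_ms[1])
    base_win = (rel >= -baseline_span_ms) & (rel < 0)
    if not in_win.any():
        raise ValueError("PSTH does not cover the post-omission window")
    peak_idx = np.argmax(np.where(in_win, psth.values, -np.inf))
    peak = float(psth.values[peak_idx])
    baseline = float(psth.values[base_win].mean()) if base_win.any() else 0.0
    if baseline > 0:
        detected = peak > baseline_factor * baseline
    else:
        detected = peak > 0
    return {
        "detected": bool(detected),
        "peak": peak,
        "peak_ms": float(rel[peak_idx]),
        "baseline": baseline,
    }


def prior_summary(
    fits, log_threshold: float = STRONG_PRIOR_LOG_THRESHOLD
) -> list[dict]:
    """Summaries of fitted beta priors per cell.

    ``fits`` is a sequence of objects exposing ``alpha0``/``beta0``
    context maps (BeliefPrior, fitted AdaptiveSurpriseModel via
    ``alpha0_``/``beta0_``, or FitResult whose params hold a BeliefPrior).
    Reports per context i the prior-mean ratio alpha_i/beta_i and strength
    alpha_i + beta_i, plus log(alpha_1 + beta_1) and the strong/weak label
    from the log-strength threshold (default 7).
    """
    rows = []
    for idx, f in enumerate(fits):
        prior = _extract_prior(f)
        row = {"cell": idx}
        for i in (0, 1):
            a, b = prior.alpha0[i], prior.beta0[i]
            row[f"ratio_{i}"] = a / b
            row[f"strength_{i}"] = a + b
        row["log_strength_1"] = math.log(row["strength_1"])
        row["label"] = "strong" if row["log_strength_1"] > log_threshold else "weak"
        rows.append(row)
    return rows


def _extract_prior(obj):
    from .beliefs import BeliefPrior  # local to avoid cycles in type-only use

    if isinstance(obj, BeliefPrior):
        return obj
    if hasattr(obj, "alpha0_"):
        return BeliefPrior(alpha0=obj.alpha0_, beta0=obj.beta0_)
    params = getattr(obj, "params", None)
    belief = getattr(params, "belief", None)
    if isinstance(belief, BeliefPrior):
        return belief
    raise TypeError(f"cannot extract a beta prior from {type(obj).__name__}")


def short_vs_long_history_correlation(counts, stim, short: int = 2, long: int = 10):
    """Correlation between short- and long-history conditioned responses.

    Builds the depth-``long`` node means and pairs each with the
    depth-``short`` mean of its most recent ``short`` bins (broadcast over
    descendants).  r = 1 iff responses depend only on the last ``short``
    bins; smaller values indicate longer-range history dependence.
    Returns None when fewer than 3 depth-``long`` nodes are observed or
    the correlation is degenerate.
    """
    tree = history_conditioned_means(counts, stim, n=long)
    deep = tree.depth_nodes(long)
    xs, ys = [], []
    for h, node in deep.items():
        shallow = tree.at(h[-short:])
        if shallow is None:
            continue
        xs.append(shallow.mean_response)
        ys.append(node.mean_response)
    if len(ys) < 3:
        return None
    r = _pearson(xs, ys)
    return None if np.isnan(r) else r
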