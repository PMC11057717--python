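"""Stochastic flash-sequence stimuli.

The stimulus is a sequence of full-field flashes and silences on a 120 ms
grid.  Flashes arrive in runs whose lengths follow a (shifted) negative
binomial distribution with mean 7, separated by silent runs with geometric
lengths of mean 9 bins.  Three clustering conditions (p = 0.98, 0.8, 0.01)
share the same mean run length and are presented as consecutive blocks.

Conventions
-----------
* Run lengths live on {1, 2, ...}: a zero-length run is meaningless.
  Flash runs are ``1 + NB(r, p)`` in the number-of-failures
  parameterization (mean ``r (1-p)/p``), so ``r = (mean - 1) p / (1-p)``.
  Silence runs are geometric on {1, 2, ...} with success probability
  ``1/mean``.
* Time bins are half-open ``[t*bin_ms, (t+1)*bin_ms)``, 0-based, in ms.
* Binary histories are enumerated by binary counting with the OLDEST bin
  as the most significant digit, so tree-plots are reproducible
  bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

BIN_MS = 120
FLASH_MS = 40
GAP_MS = 80

DEFAULT_FLASH_MEAN = 7.0
DEFAULT_SILENCE_MEAN = 9.0
DEFAULT_P_CONDITIONS = (0.98, 0.8, 0.01)


@dataclass(frozen=True)
class RunLengthParams:
    """Distribution of run lengths for one stimulus state.

    Parameters
    ----------
    kind : {"flash", "silence"}
        Flash runs are shifted negative binomial; silence runs geometric.
    p : float
        NB success probability (flash) — ignored for silence runs, where
        the geometric success probability is ``1 / mean_runs``.
    mean_runs : float
        Target mean run length (>= 1).
    """

    kind: str
    p: float
    mean_runs: float
    r: float = field(init=False, default=float("nan"))

    def __post_init__(self) -> None:
        if self.kind not in ("flash", "silence"):
            raise ValueError(f"kind must be 'flash' or 'silence', got {self.kind!r}")
        if not (0.0 < self.p < 1.0) or not np.isfinite(self.p):
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if not np.isfinite(self.mean_runs) or self.mean_runs <= 0:
            raise ValueError(f"mean_runs must be positive, got {self.mean_runs}")
        if self.kind == "flash":
            object.__setattr__(self, "r", nb_size_for_mean(self.p, self.mean_runs))


@dataclass(frozen=True)
class BinnedStimulus:
    """Binary flash (1) / silence (0) sequence on a fixed time grid."""

    bins: np.ndarray
    bin_ms: float = BIN_MS

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=np.int8)
        if bins.ndim != 1:
            raise ValueError("bins must be one-dimensional")
        if not np.isin(bins, (0, 1)).all():
            raise ValueError("bins must contain only 0 and 1")
        object.__setattr__(self, "bins", bins)

    def __len__(self) -> int:
        return int(self.bins.size)

    def __iter__(self) -> Iterator[int]:
        return iter(self.bins.tolist())

    def run_lengths(self) -> tuple[list[int], list[int]]:
        """Decompose into (flash_runs, silence_runs) in order of occurrence."""
        x = self.bins
        if x.size == 0:
            return [], []
        change = np.flatnonzero(np.diff(x)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [x.size]))
        flash, silence = [], []
        for s, e in zip(starts, ends):
            (flash if x[s] == 1 else silence).append(int(e - s))
        return flash, silence


@dataclass(frozen=True)
class FlashSchedule:
    """Millisecond flash-onset times; each flash lasts 40 ms with an 80 ms gap."""

    onsets_ms: np.ndarray
    flash_ms: float = FLASH_MS
    gap_ms: float = GAP_MS

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_ms, dtype=float)
        if onsets.ndim != 1:
            raise ValueError("onsets_ms must be one-dimensional")
        if onsets.size and onsets[0] < 0:
            raise ValueError("negative flash onsets are not allowed")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("flash onsets must be strictly increasing")
        object.__setattr__(self, "onsets_ms", onsets)


def nb_size_for_mean(p: float, target_mean: float) -> float:
    """Size parameter r of the shifted negative binomial with the given mean.

    Run lengths are ``1 + NB(r, p)`` where NB counts failures before the
    r-th success (mean ``r (1-p)/p``), so the run mean is
    ``1 + r (1-p)/p`` and ``r = (target_mean - 1) p / (1-p)``.
    """
    if not np.isfinite(p) or not (0.0 < p < 1.0):
        raise ValueError(f"p must be a finite probability in (0, 1), got {p}")
    if not np.isfinite(target_mean) or target_mean < 1.0:
        raise ValueError(f"target_mean must be >= 1 (runs have length >= 1), got {target_mean}")
    return (target_mean - 1.0) * p / (1.0 - p)


def sample_runs(params: RunLengthParams, n_runs: int, seed) -> np.ndarray:
    """Draw ``n_runs`` run lengths (each >= 1), reproducibly under ``seed``.

    ``seed`` may be an int, a SeedSequence, or a Generator.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    rng = np.random.default_rng(seed)
    if params.kind == "flash":
        if params.r == 0.0:  # degenerate mean-1 runs
            return np.ones(n_runs, dtype=np.int64)
        return 1 + rng.negative_binomial(params.r, params.p, size=n_runs)
    return rng.geometric(1.0 / params.mean_runs, size=n_runs)


def build_stimulus(
    flash_runs: Sequence[int], silence_runs: Sequence[int], bin_ms: float = BIN_MS
) -> BinnedStimulus:
    """Interleave flash and silence runs, beginning with a flash run."""
    flash_runs = list(flash_runs)
    silence_runs = list(silence_runs)
    if not flash_runs or not silence_runs:
        raise ValueError("both run lists must be nonempty")
    if any(r < 1 for r in flash_runs) or any(r < 1 for r in silence_runs):
        raise ValueError("every run length must be >= 1")
    if not len(flash_runs) - len(silence_runs) in (0, 1):
        raise ValueError(
            "alternation requires len(flash_runs) - len(silence_runs) in {0, 1}"
        )
    parts = []
    for i, f in enumerate(flash_runs):
        parts.append(np.ones(f, dtype=np.int8))
        if i < len(silence_runs):
            parts.append(np.zeros(silence_runs[i], dtype=np.int8))
    return BinnedStimulus(np.concatenate(parts), bin_ms=bin_ms)


def binarize(schedule: FlashSchedule, bin_ms: float = BIN_MS, n_bins: int | None = None) -> BinnedStimulus:
    """Discretize a flash schedule: bin t = 1 iff an onset falls in [t*bin, (t+1)*bin)."""
    onsets = schedule.onsets_ms
    if n_bins is None:
        if onsets.size == 0:
            raise ValueError("cannot infer n_bins from an empty schedule")
        n_bins = int(onsets[-1] // bin_ms) + 1
    bins = np.zeros(n_bins, dtype=np.int8)
    idx = (onsets // bin_ms).astype(int)
    idx = idx[idx < n_bins]
    bins[idx] = 1
    return BinnedStimulus(bins, bin_ms=bin_ms)


def schedule_from_binned(stim: BinnedStimulus) -> FlashSchedule:
    """Place one flash onset at the start of every flash bin (inverse of binarize)."""
    onsets = np.flatnonzero(stim.bins) * float(stim.bin_ms)
    return FlashSchedule(onsets)


def enumerate_histories(n: int) -> list[tuple[int, ...]]:
    """All binary sequences of length n, ordered by binary counting.

    The OLDEST bin is the most significant digit; element -1 of each tuple
    is the most recent bin.
    """
    if not (1 <= n <= 20):
        raise ValueError(f"n must be in [1, 20], got {n}")
    return [
        tuple((k >> (n - 1 - b)) & 1 for b in range(n)) for k in range(2**n)
    ]


def generate_stimulus(
    minutes: float,
    p: float,
    mean_flash: float = DEFAULT_FLASH_MEAN,
    mean_silence: float = DEFAULT_SILENCE_MEAN,
    seed=None,
    bin_ms: float = BIN_MS,
) -> BinnedStimulus:
    """Generate ``minutes`` of stimulus for one clustering condition ``p``.

    Runs are drawn until the bin budget is reached, then truncated.
    """
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    n_bins = int(round(minutes * 60_000 / bin_ms))
    rng = np.random.default_rng(seed)
    fp = RunLengthParams("flash", p, mean_flash)
    sp = RunLengthParams("silence", 0.5, mean_silence)
    # expected bins per flash+silence cycle = mean_flash + mean_silence
    n_cycles = max(8, int(1.5 * n_bins / (mean_flash + mean_silence)) + 8)
    while True:
        flash = sample_runs(fp, n_cycles, rng)
        silence = sample_runs(sp, n_cycles, rng)
        if flash.sum() + silence.sum() >= n_bins:
            break
        n_cycles *= 2
    full = build_stimulus(flash.tolist(), silence.tolist(), bin_ms=bin_ms)
    return BinnedStimulus(full.bins[:n_bins], bin_ms=bin_ms)


def generate_condition_blocks(
    minutes_per_block: float = 20.0,
    p_conditions: Sequence[float] = DEFAULT_P_CONDITIONS,
    mean_flash: float = DEFAULT_FLASH_MEAN,
    mean_silence: float = DEFAULT_SILENCE_MEAN,
    seed=None,
    bin_ms: float = BIN_MS,
) -> BinnedStimulus:
    """Concatenate one block per clustering condition (default p = 0.98, 0.8, 0.01).

    Matches the experimental protocol of presenting the three conditions in
    consecutive blocks and pooling the responses.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(len(p_conditions))
    blocks = [
        generate_stimulus(minutes_per_block, p, mean_flash, mean_silence, seed=c, bin_ms=bin_ms)
        for p, c in zip(p_conditions, children)
    ]
    return BinnedStimulus(np.concatenate([b.bins for b in blocks]), bin_ms=bin_ms)


def as_binned(stim) -> BinnedStimulus:
    """Coerce an array-like of 0/1 (or a BinnedStimulus) to BinnedStimulus."""
    if isinstance(stim, BinnedStimulus):
        return stim
    return BinnedStimulus(np.asarray(stim))
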