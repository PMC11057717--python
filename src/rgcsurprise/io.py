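"""Plain-text serialization: stimuli and counts as CSV, models/configs as JSON.

All times are in ms, probabilities unrounded; every writer embeds enough
metadata (bin size, generator parameters, seed) to reproduce the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beliefs import DEFAULT_ETA, BeliefPrior, MarkovParams
from .encoder import CellModel, EncoderParams
from .models import M2_CONTEXTS
from .stimulus import BinnedStimulus


def write_stimulus_csv(stim: BinnedStimulus, path, meta: dict | None = None) -> None:
    """Stimulus as CSV (bin_index, x) plus a sidecar JSON metadata block."""
    path = Path(path)
    df = pd.DataFrame({"bin_index": np.arange(len(stim)), "x": stim.bins})
    df.to_csv(path, index=False)
    meta = dict(meta or {})
    meta.setdefault("bin_ms", stim.bin_ms)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_stimulus_csv(path) -> BinnedStimulus:
    path = Path(path)
    df = pd.read_csv(path)
    bin_ms = 120
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        bin_ms = json.loads(sidecar.read_text()).get("bin_ms", 120)
    return BinnedStimulus(df["x"].to_numpy(), bin_ms=bin_ms)


def write_counts_csv(counts: np.ndarray, path) -> None:
    """Spike counts as CSV: one row per repeat, one column per bin."""
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[None, :]
    pd.DataFrame(
        counts, columns=[f"bin_{t}" for t in range(counts.shape[1])]
    ).to_csv(path, index=False)


def read_counts_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy()


def model_to_dict(cell: CellModel, kind: str | None = None) -> dict:
    """CellModel -> JSON-ready dict {model, theta | alpha0/beta0, eta, a, b}."""
    out = {"a": cell.encoder.a, "b": cell.encoder.b}
    belief = cell.belief
    if isinstance(belief, MarkovParams):
        out["model"] = "fixed" if belief.order == 1 else "markov2"
        if belief.order == 1:
            out["theta"] = [belief.theta[0], belief.theta[1]]
        else:
            out["theta"] = [belief.theta[c] for c in M2_CONTEXTS]
    elif isinstance(belief, BeliefPrior):
        out["model"] = kind or "adaptive"
        out["alpha0"] = [belief.alpha0[0], belief.alpha0[1]]
        out["beta0"] = [belief.beta0[0], belief.beta0[1]]
        out["eta"] = belief.eta
    else:
        raise TypeError(f"cannot serialize belief of type {type(belief).__name__}")
    return out


def model_from_dict(d: dict) -> CellModel:
    kind = d["model"]
    enc = EncoderParams(a=float(d["a"]), b=float(d["b"]))
    if kind == "fixed":
        theta = d["theta"]
        belief = MarkovParams(order=1, theta={0: theta[0], 1: theta[1]})
    elif kind == "markov2":
        theta = d["theta"]
        belief = MarkovParams(order=2, theta=dict(zip(M2_CONTEXTS, theta)))
    elif kind in ("adaptive", "adaptive_reduced"):
        belief = BeliefPrior(
            alpha0={0: d["alpha0"][0], 1: d["alpha0"][1]},
            beta0={0: d["beta0"][0], 1: d["beta0"][1]},
            eta=float(d.get("eta", DEFAULT_ETA)),
        )
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return CellModel(belief=belief, encoder=enc)


def write_model_json(cell: CellModel, path, kind: str | None = None, extra: dict | None = None) -> None:
    d = model_to_dict(cell, kind=kind)
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_model_json(path) -> CellModel:
    return model_from_dict(json.loads(Path(path).read_text()))
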