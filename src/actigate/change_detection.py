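"""Signal-magnitude-area computation and the classifier gate.

SMA is the mean over a window of the summed absolute tri-axial accelerations,

    SMA = (1/n) * sum_i (|x_i| + |y_i| + |z_i|),

computed on the TOTAL acceleration. It is a cheap proxy for physical-activity
intensity, so a jump in SMA between consecutive windows signals a plausible
activity change. The gate sends a window to the classifier when

* it is the first window of the stream (no SMA history exists), or
* |SMA(t) - SMA(t-1)| >= T (a change fired), or
* ``force_interval`` windows elapsed since the last classifier call (periodic
  forcing guards against activities whose SMA levels coincide).

Otherwise the previous prediction is carried over. With 50%-overlap windows
the SMA is taken over the newest half of each window — exactly the stride of
fresh samples — so each raw sample contributes to exactly one SMA value and
change resolution is one stride.

The change rule uses the absolute difference: transitions to lower-intensity
activities (standing to sitting, standing to lying down) must fire the gate
just as increases do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from actigate.preprocessing import SignalWindow

DEFAULT_THRESHOLD = 0.2
DEFAULT_FORCE_INTERVAL = 30

CLASSIFY_CHANGE = "classify_change"
CLASSIFY_FORCED = "classify_forced"
CARRY_OVER = "carry_over"


@dataclass
class SMASeries:
    """Per-window SMA values, with a flag recording the half-window option."""

    values: np.ndarray
    half_window: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("SMA values cannot be negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GateDecision:
    window_index: int
    verdict: str
    sma_delta: float | None  # absent only for the first window

    @property
    def invokes_classifier(self) -> bool:
        return self.verdict in (CLASSIFY_CHANGE, CLASSIFY_FORCED)


def compute_sma(window: SignalWindow | np.ndarray, use_half: bool = True) -> float:
    """SMA of one window's total acceleration.

    With ``use_half`` the newest ``ceil(w/2)`` samples are used and the
    divisor is that count.
    """
    total = window.total if isinstance(window, SignalWindow) else np.asarray(window, dtype=float)
    if total.size == 0:
        raise ValueError("cannot compute SMA of an empty window")
    if use_half:
        n = math.ceil(total.shape[0] / 2)
        total = total[-n:]
    return float(np.abs(total).sum() / total.shape[0])


def sma_series(
    windows: Sequence[SignalWindow | np.ndarray], use_half: bool = True
) -> SMASeries:
    return SMASeries(
        values=np.array([compute_sma(w, use_half=use_half) for w in windows]),
        half_window=use_half,
    )


#: absolute slack so that a difference exactly at the threshold fires even
#: when binary floating point puts it a few ulp short (0.3 - 0.1 < 0.2)
_BOUNDARY_EPS = 1e-12


def decide(sma_t: float, sma_prev: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """``True`` (new activity) iff ``|sma_t - sma_prev| >= threshold``.

    The comparison is ``>=``: a difference exactly at the threshold fires.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return abs(sma_t - sma_prev) >= threshold - _BOUNDARY_EPS


def gate(
    series: SMASeries,
    threshold: float = DEFAULT_THRESHOLD,
    force_interval: int = DEFAULT_FORCE_INTERVAL,
) -> list[GateDecision]:
    """Per-window verdicts: classify on change, periodically, or carry over.

    The forcing counter measures windows elapsed since the last classifier
    invocation of either kind and resets on every invocation.
    """
    if force_interval < 1:
        raise ValueError(f"force_interval must be >= 1, got {force_interval}")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    decisions: list[GateDecision] = []
    last_call = 0
    for i, value in enumerate(series.values):
        if i == 0:
            verdict, delta = CLASSIFY_CHANGE, None
        else:
            delta = float(value - series.values[i - 1])
            if abs(delta) >= threshold - _BOUNDARY_EPS:
                verdict = CLASSIFY_CHANGE
            elif i - last_call >= force_interval:
                verdict = CLASSIFY_FORCED
            else:
                verdict = CARRY_OVER
        if verdict != CARRY_OVER:
            last_call = i
        decisions.append(GateDecision(window_index=i, verdict=verdict, sma_delta=delta))
    return decisions


def gate_trace_frame(series: SMASeries, decisions: Sequence[GateDecision]) -> pd.DataFrame:
    """Tabular gate trace (window_index, sma, sma_delta, verdict) for export."""
    return pd.DataFrame(
        {
            "window_index": [d.window_index for d in decisions],
            "sma": series.values[: len(decisions)],
            "sma_delta": [d.sma_delta for d in decisions],
            "verdict": [d.verdict for d in decisions],
        }
    )
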