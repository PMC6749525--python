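"""Body/gravity separation, magnitudes and sliding-window segmentation.

The raw accelerometer signal (``total`` acceleration) mixes the quasi-static
gravity contribution with the dynamic movement of the body. A third-order
high-pass Butterworth filter with a 0.3 Hz cutoff removes the gravity
component, yielding ``body`` acceleration. Filtering is applied zero-phase
(forward-backward) to whole contiguous runs before any windowing, so window
edges carry no filter transients and body/total channels stay aligned.

Segmentation uses a fixed-size overlapping sliding window (FOSW): window
length ``w`` samples (default 90 = 4.5 s at 20 Hz) advancing by stride
``round(w * (1 - overlap))`` (45 for the default 50% overlap). Windows never
straddle a run boundary; trailing samples that cannot fill a window are
dropped. ``overlap=0`` gives the non-overlapping (FNSW) variant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from actigate.signal_io import ContiguousRun

DEFAULT_FS = 20.0
DEFAULT_WINDOW_SECONDS = 4.5
DEFAULT_OVERLAP = 0.5
DEFAULT_CUTOFF_HZ = 0.3
DEFAULT_FILTER_ORDER = 3


@dataclass
class SignalWindow:
    """One fixed-length segment with total and body acceleration channels."""

    total: np.ndarray  # (w, 3) m/s²
    body: np.ndarray  # (w, 3) m/s²
    subject_id: str
    start_index: int
    true_label: str | None = None

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=np.float64)
        self.body = np.asarray(self.body, dtype=np.float64)
        if self.total.shape != self.body.shape or self.total.ndim != 2 or self.total.shape[1] != 3:
            raise ValueError(
                f"total and body must share shape (w, 3); got {self.total.shape} and {self.body.shape}"
            )

    @property
    def w(self) -> int:
        return self.total.shape[0]


def highpass_body(
    run: ContiguousRun | np.ndarray,
    fs: float = DEFAULT_FS,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """High-pass filter a run's total acceleration into body acceleration.

    Zero-phase Butterworth filtering applied per run, never across run
    boundaries. Returns an array of the same shape as the input samples.
    """
    xyz = run.xyz if isinstance(run, ContiguousRun) else np.asarray(run, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} Hz must exceed twice the cutoff {cutoff} Hz")
    b, a = _signal.butter(order, cutoff, btype="highpass", fs=fs)
    # forward-backward filtering needs warm-up samples at both ends
    min_len = 3 * (order + 1) + 1
    if len(xyz) < min_len:
        raise ValueError(
            f"run of {len(xyz)} samples is too short to filter; need at least {min_len}"
        )
    # Remove the per-run mean first (the high-pass maps it to zero anyway) and
    # fit the filter's initial conditions to the data (Gustafsson). With a
    # cutoff this far below the sampling rate, reflected-padding start-up
    # transients would otherwise decay too slowly and bleed into the windows.
    centred = xyz - xyz.mean(axis=0)
    return _signal.filtfilt(b, a, centred, axis=0, method="gust")


def magnitude(series: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of an (n, 3) acceleration series."""
    series = np.asarray(series, dtype=float)
    return np.linalg.norm(series, axis=-1)


def fosw_starts(n_samples: int, w: int, overlap: float) -> np.ndarray:
    """Start offsets of fixed-size (overlapping) sliding windows.

    Stride is ``round(w * (1 - overlap))``; windows start at 0, stride,
    2*stride, ... while they fit entirely inside the run.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    if w < 1:
        raise ValueError(f"window length must be >= 1, got {w}")
    if n_samples < w:
        return np.empty(0, dtype=int)
    stride = int(round(w * (1 - overlap)))
    stride = max(stride, 1)
    return np.arange(0, n_samples - w + 1, stride)


def segment_fosw(
    samples: np.ndarray, w: int, overlap: float = DEFAULT_OVERLAP
) -> list[np.ndarray]:
    """Slice an (n, d) sample array into fixed-size overlapping windows."""
    samples = np.asarray(samples)
    return [samples[s : s + w] for s in fosw_starts(len(samples), w, overlap)]


def majority_label(labels: np.ndarray) -> str:
    """Most frequent label; ties broken toward the lexicographically smallest."""
    counts = Counter(map(str, labels))
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def segment_run(
    run: ContiguousRun,
    fs: float = DEFAULT_FS,
    w: int | None = None,
    overlap: float = DEFAULT_OVERLAP,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> list[SignalWindow]:
    """Filter a run and cut it into :class:`SignalWindow` objects.

    The whole run is high-pass filtered first, then windowed, so no window
    carries filter edge transients. Windows that span an activity transition
    are labelled with the majority label of their samples. Runs too short to
    hold a single window yield an empty list.
    """
    if w is None:
        w = int(round(window_seconds * fs))
    if len(run) < w:
        return []
    body = highpass_body(run, fs=fs, cutoff=cutoff, order=order)
    windows = []
    for s in fosw_starts(len(run), w, overlap):
        windows.append(
            SignalWindow(
                total=run.xyz[s : s + w],
                body=body[s : s + w],
                subject_id=run.subject_id,
                start_index=int(s),
                true_label=majority_label(run.labels[s : s + w]),
            )
        )
    return windows
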