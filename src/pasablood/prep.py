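"""Replicate-trace I/O, baseline shifting, averaging and steady-state selection.

Traces are uniformly sampled intensity time series (time in ms, intensity in
arbitrary units after baseline shift, volts raw).  The preparation pipeline is
fixed: average the raw replicates pointwise, shift the averaged trace so its
minimum is exactly zero, then mark the leading trigger-jitter window
(default 0.5 ms) as non-steady so that no feature is computed from it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("PA", "AS")

_TIME_RTOL = 1e-6


def _check_modality(modality: str) -> str:
    if modality not in MODALITIES:
        raise ValueError(
            f"unknown modality {modality!r}; expected one of {MODALITIES}"
        )
    return modality


@dataclass(frozen=True)
class SignalTrace:
    """One uniformly sampled intensity trace.

    Attributes
    ----------
    t : ndarray
        Time axis in milliseconds, starting at 0 with constant step ``dt``.
    y : ndarray
        Intensity samples (volts raw; arbitrary units after baseline shift).
    dt : float
        Sampling interval in milliseconds.
    modality : str
        ``"PA"`` (photoacoustic) or ``"AS"`` (absorption spectroscopy).
    """

    t: np.ndarray
    y: np.ndarray
    dt: float
    modality: str

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        _check_modality(self.modality)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(t) == 0:
            raise ValueError("empty trace")
        if len(t) > 1:
            steps = np.diff(t)
            if np.any(steps <= 0):
                row = int(np.argmax(steps <= 0)) + 1
                raise ValueError(f"time axis not strictly increasing at row {row}")
            if not np.allclose(steps, self.dt, rtol=_TIME_RTOL, atol=self.dt * _TIME_RTOL):
                row = int(np.argmax(~np.isclose(steps, self.dt, rtol=_TIME_RTOL))) + 1
                raise ValueError(f"non-uniform time grid near row {row}")

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def duration(self) -> float:
        """Total covered duration in ms (n_samples * dt)."""
        return self.n_samples * self.dt


@dataclass(frozen=True)
class ReplicateSet:
    """The repeated traces recorded for one subject and modality."""

    subject_id: str
    modality: str
    traces: tuple

    def __post_init__(self) -> None:
        _check_modality(self.modality)
        traces = tuple(self.traces)
        object.__setattr__(self, "traces", traces)
        if len(traces) == 0:
            raise ValueError("a ReplicateSet needs at least one trace")
        n0, dt0 = traces[0].n_samples, traces[0].dt
        for i, tr in enumerate(traces):
            if tr.n_samples != n0:
                raise ValueError(
                    f"replicate {i + 1} has {tr.n_samples} samples, expected {n0}"
                )
            if not np.isclose(tr.dt, dt0):
                raise ValueError(f"replicate {i + 1} has mismatched dt")

    @property
    def n_replicates(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class AveragedSignal:
    """A replicate-averaged trace plus the steady-state start marker."""

    trace: SignalTrace
    n_replicates: int
    steady_start_index: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.steady_start_index < self.trace.n_samples):
            raise ValueError(
                f"steady_start_index {self.steady_start_index} outside "
                f"[0, {self.trace.n_samples})"
            )

    @property
    def steady_t(self) -> np.ndarray:
        return self.trace.t[self.steady_start_index:]

    @property
    def steady_y(self) -> np.ndarray:
        return self.trace.y[self.steady_start_index:]


def read_replicates(path) -> ReplicateSet:
    """Read a replicate CSV (``time_ms,rep1..repK``) written by this package.

    Leading ``#`` comment lines may carry ``subject=`` and ``modality=``
    metadata; without them the subject id defaults to the file stem and the
    modality to PA.
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        for tok in line[1:].split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                meta[k] = v
    df = pd.read_csv(io.StringIO(text), comment="#")
    if "time_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_ms'")
    rep_cols = [c for c in df.columns if c != "time_ms"]
    if not rep_cols:
        raise ValueError(f"{path}: no replicate columns")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: NaN cell at data row {row}")
    t = df["time_ms"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = float(np.median(np.diff(t)))
    modality = meta.get("modality", "PA")
    traces = tuple(
        SignalTrace(t=t, y=df[c].to_numpy(float), dt=dt, modality=modality)
        for c in rep_cols
    )
    return ReplicateSet(
        subject_id=meta.get("subject", path.stem), modality=modality, traces=traces
    )


def write_replicates(path, repset: ReplicateSet, header_comment: str | None = None) -> None:
    """Write a ReplicateSet as ``time_ms,rep1..repK`` CSV with metadata comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time_ms": repset.traces[0].t}
    for i, tr in enumerate(repset.traces, start=1):
        cols[f"rep{i}"] = tr.y
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# subject={repset.subject_id} modality={repset.modality}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def shift_baseline(trace: SignalTrace) -> SignalTrace:
    """Shift intensities so the trace minimum is exactly 0 a.u.

    A raw photoacoustic trace spanning −1…0.5 V becomes 0…1.5 a.u.; an
    absorption-spectroscopy trace spanning −100…20 V becomes 0…120 a.u.
    Idempotent: a trace whose minimum is already 0 is returned unchanged in
    value.
    """
    if trace.n_samples == 0:
        raise ValueError("cannot baseline-shift an empty trace")
    if not np.all(np.isfinite(trace.y)):
        raise ValueError("trace contains non-finite values")
    return replace(trace, y=trace.y - trace.y.min())


def average_replicates(repset: ReplicateSet) -> AveragedSignal:
    """Pointwise arithmetic mean across replicates (noise ∝ 1/sqrt(K))."""
    ys = np.stack([tr.y for tr in repset.traces])
    mean = ys.mean(axis=0)
    tr0 = repset.traces[0]
    return AveragedSignal(
        trace=replace(tr0, y=mean), n_replicates=repset.n_replicates
    )


def select_steady_state(avg: AveragedSignal, discard_ms: float = 0.5) -> AveragedSignal:
    """Exclude the leading trigger-jitter window from feature computation.

    The trigger switching-time error is about 0.5 ms, so by default the first
    0.5 ms of the averaged trace is marked non-steady.  The time axis is kept;
    only ``steady_start_index`` moves.
    """
    duration = avg.trace.duration
    if discard_ms < 0:
        raise ValueError("discard_ms must be nonnegative")
    if discard_ms >= duration:
        raise ValueError(
            f"discard_ms={discard_ms} must be smaller than the trace duration {duration}"
        )
    idx = int(round(discard_ms / avg.trace.dt))
    return replace(avg, steady_start_index=idx)


def preprocess_replicates(repset: ReplicateSet, discard_ms: float = 0.5) -> AveragedSignal:
    """Average -> baseline-shift -> steady-state selection, in that fixed order."""
    avg = average_replicates(repset)
    shifted = replace(avg, trace=shift_baseline(avg.trace))
    return select_steady_state(shifted, discard_ms=discard_ms)
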