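"""Spike trains and the plain-text exchange format.

A spike train is the sorted list of event times (seconds) of one unit over a
recording of known duration.  The on-disk format is two whitespace- or
comma-delimited columns, ``time_s unit_label``, an optional header line, one
row per spike.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "read_spike_trains", "write_spike_trains"]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted event times of a single unit.

    Parameters
    ----------
    times
        Event times in seconds, strictly increasing, all within ``[0, duration]``.
    duration
        Recording length T in seconds.
    label
        Opaque unit identifier.
    """

    times: np.ndarray
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("spike times must lie in [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in spk/s."""
        return self.n_spikes / self.duration

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)


def read_spike_trains(path_or_buf, duration: float | None = None) -> dict[str, SpikeTrain]:
    """Read spike trains from the two-column text format.

    Rows are ``time_s unit_label`` (whitespace or comma delimited); a header
    is skipped if the first field does not parse as a number.  Rows are
    grouped by label and sorted.  If *duration* is None it is taken as the
    latest spike time over all units.
    """
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf) as fh:
            text = fh.read()
    else:
        text = path_or_buf.read()
    times: dict[str, list[float]] = {}
    for i, line in enumerate(io.StringIO(text)):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"line {i + 1}: expected 'time_s unit_label'")
        try:
            t = float(parts[0])
        except ValueError:
            if i == 0:
                continue  # header
            raise
        times.setdefault(parts[1], []).append(t)
    if not times:
        raise ValueError("no spikes found")
    if duration is None:
        duration = max(max(v) for v in times.values())
    return {
        lab: SpikeTrain(np.sort(np.asarray(v)), duration=duration, label=lab)
        for lab, v in sorted(times.items())
    }


def write_spike_trains(path_or_buf, trains) -> None:
    """Write spike trains (iterable of :class:`SpikeTrain`) in time order."""
    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append((t, tr.label))
    rows.sort()
    text = "time_s unit_label\n" + "".join(f"{t:.6f} {lab}\n" for t, lab in rows)
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    else:
        path_or_buf.write(text)
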