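"""Count series, dichotomous (telegraph) series and residence sequences.

The hydration count N(t) is reduced to a two-state process N'(t): "on" (+1)
whenever the count exceeds its time average for that site, "off" (-1)
otherwise.  Run-length encoding of N'(t) yields the residence (sojourn)
times analysed downstream.  Boundary runs are flagged as censored: the
observation window truncates them, so they are length-biased and excluded
from distribution fits, but they are retained when rasterizing back for
spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ON = 1
OFF = -1


@dataclass
class CountSeries:
    """Integer hydration counts at a fixed sampling interval."""

    values: np.ndarray
    dt: float = 1.0
    site_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size and self.values.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DichotomousSeries:
    """+/-1 state sequence with the threshold used to build it."""

    states: np.ndarray
    dt: float = 1.0
    threshold: float = float("nan")
    site_id: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.size == 0:
            raise ValueError("states must be nonempty")
        if not np.all(np.abs(self.states) == 1):
            raise ValueError("states must be +1 or -1")

    def __len__(self) -> int:
        return self.states.size


@dataclass
class ResidenceSequence:
    """Alternating sojourn durations with state labels and censoring flags.

    ``durations`` are in ps (run length x dt); ``states`` alternate strictly
    between +1 and -1.  The first and last runs touch the window boundary
    and carry censoring flags.
    """

    durations: np.ndarray
    states: np.ndarray
    dt: float = 1.0
    censored_first: bool = True
    censored_last: bool = True

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.durations.shape != self.states.shape:
            raise ValueError("durations and states must have equal length")
        if self.durations.size and np.any(np.diff(self.states) == 0):
            raise ValueError("states must strictly alternate")

    def __len__(self) -> int:
        return self.durations.size

    def interior(self) -> "ResidenceSequence":
        """Drop censored boundary runs (for fitting and correlations)."""
        lo = 1 if self.censored_first else 0
        hi = len(self) - 1 if self.censored_last else len(self)
        return ResidenceSequence(
            self.durations[lo:hi],
            self.states[lo:hi],
            dt=self.dt,
            censored_first=False,
            censored_last=False,
        )

    def by_state(self, state: int) -> np.ndarray:
        return self.durations[self.states == state]


def dichotomize(counts: CountSeries) -> DichotomousSeries:
    """Threshold a count series at its own mean.

    Frames with value strictly above the mean are "on" (+1); frames at or
    below the mean — including every frame of a constant series — are
    "off" (-1).  The strict inequality makes integer ties deterministic.
    """
    if len(counts) == 0:
        raise ValueError("cannot dichotomize an empty series")
    threshold = float(np.mean(counts.values))
    states = np.where(counts.values > threshold, ON, OFF).astype(np.int8)
    return DichotomousSeries(states, dt=counts.dt, threshold=threshold, site_id=counts.site_id)


def extract_residences(d: DichotomousSeries) -> ResidenceSequence:
    """Run-length encode a dichotomous series into sojourn durations (ps)."""
    s = d.states
    change = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [s.size]])
    durations = (ends - starts) * d.dt
    states = s[starts]
    return ResidenceSequence(durations, states, dt=d.dt, censored_first=True, censored_last=True)


def rasterize(r: ResidenceSequence, threshold: float = float("nan")) -> DichotomousSeries:
    """Inverse of :func:`extract_residences`: expand runs back to frames."""
    n_frames = np.round(r.durations / r.dt).astype(int)
    if np.any(n_frames < 1):
        raise ValueError("every duration must cover at least one frame")
    states = np.repeat(r.states, n_frames)
    return DichotomousSeries(states, dt=r.dt, threshold=threshold)
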