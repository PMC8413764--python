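"""Temporal properties of discrete connectivity-state sequences.

Given a per-subject state vector (the sequence of cluster labels assigned
to its sliding windows), three summary properties characterise how the
subject moves through connectivity states over the scan:

* fractional windows — percent of windows spent in each state;
* mean dwell time — average length, in windows, of uninterrupted runs
  of a state (0 if the state never occurs);
* number of transitions — count of label changes along the vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TemporalProperties:
    """Per-subject temporal summary of a state vector.

    Per-state arrays are indexed ``state - 1`` for states ``1..k``.
    """

    k: int
    fractional_windows: np.ndarray  # percent, sums to 100
    mean_dwell_time: np.ndarray  # windows; 0 for unvisited states
    n_transitions: int
    run_counts: np.ndarray = field(default=None)  # runs per state


def run_length_encode(states) -> list[tuple[int, int]]:
    """Encode a label vector as ``[(state, run_length), ...]``.

    Concatenating the runs reproduces the input exactly.
    """
    s = np.asarray(states)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("state vector must be a non-empty 1-D sequence")
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    bounds = np.concatenate(([0], change, [s.size]))
    return [(int(s[b]), int(e - b)) for b, e in zip(bounds[:-1], bounds[1:])]


def temporal_properties(states, k: int) -> TemporalProperties:
    """Compute fractional windows, mean dwell time, and transitions.

    Parameters
    ----------
    states : sequence of int
        State labels in ``1..k``, one per window.
    k : int
        Number of states. Unvisited states get fraction 0 and dwell 0.
    """
    s = np.asarray(states, dtype=int)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("state vector must be a non-empty 1-D sequence")
    if s.min() < 1 or s.max() > k:
        raise ValueError(f"state labels must lie in 1..{k}")
    runs = run_length_encode(s)
    occupancy = np.zeros(k)
    dwell_total = np.zeros(k)
    run_counts = np.zeros(k, dtype=int)
    for state, length in runs:
        occupancy[state - 1] += length
        dwell_total[state - 1] += length
        run_counts[state - 1] += 1
    frac = 100.0 * occupancy / s.size
    with np.errstate(invalid="ignore"):
        dwell = np.where(run_counts > 0, dwell_total / np.maximum(run_counts, 1), 0.0)
    return TemporalProperties(
        k=k,
        fractional_windows=frac,
        mean_dwell_time=dwell,
        n_transitions=len(runs) - 1,
        run_counts=run_counts,
    )
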