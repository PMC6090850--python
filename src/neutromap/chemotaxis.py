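"""Trajectory analytics for under-agarose chemotaxis assays.

Cells are tracked as (time, x, y) positions around a fixed chemoattractant
uncaging spot.  The central statistic is the *angular bias*: each step's
angle to the source (0 deg = straight at it, 180 deg = straight away) is
mapped to a score of 90 minus that angle, scores are averaged within each
cell and then across cells.  Perfect chemotaxis scores 90; uniformly random
motion has expectation 0; perfectly repelled motion scores -90.  A mixed-
population simulation resamples empirical responder step angles for a
fraction of cells and draws uniform angles for the rest, reproducing the
logic of comparing a partially-differentiated cell line with primary
neutrophils.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "DirectionalitySummary",
    "step_angles",
    "angular_bias",
    "mean_speed",
    "direction_histogram",
    "simulate_mixed_population",
    "mixture_expected_counts",
]

#: columns required in a track table
TRACK_COLUMNS = ("cell_id", "time_s", "x_um", "y_um")


@dataclass
class TrackSet:
    """Time-ordered cell positions with a gradient source and stimulus time.

    Parameters
    ----------
    tracks
        DataFrame with columns ``cell_id``, ``time_s``, ``x_um``, ``y_um``.
        Times must be strictly increasing within each cell, with at least
        two points per cell.
    source
        (x, y) position of the chemoattractant uncaging spot, in microns.
    stimulus_time
        Uncaging time in seconds.  The "before" window is [start,
        stimulus_time); the stimulus frame itself belongs to "after".
    """

    tracks: pd.DataFrame
    source: tuple[float, float]
    stimulus_time: float

    def __post_init__(self) -> None:
        for col in TRACK_COLUMNS:
            if col not in self.tracks.columns:
                raise ValueError(f"track table missing column {col!r}")
        # canonical order: contiguous per-cell blocks, time-sorted
        self.tracks = self.tracks.sort_values(
            ["cell_id", "time_s"], kind="stable"
        ).reset_index(drop=True)
        sizes = self.tracks.groupby("cell_id").size()
        if (sizes < 2).any():
            bad = sizes.index[sizes < 2][0]
            raise ValueError(f"cell {bad!r} has fewer than 2 points")
        dt = self.tracks.groupby("cell_id", sort=False)["time_s"].diff()
        if (dt.dropna() <= 0).any():
            bad = self.tracks.loc[dt.dropna().index[dt.dropna() <= 0][0], "cell_id"]
            raise ValueError(f"cell {bad!r} has non-increasing times")

    @property
    def cell_ids(self) -> list:
        return list(pd.unique(self.tracks["cell_id"]))

    @property
    def time_range(self) -> tuple[float, float]:
        t = self.tracks["time_s"]
        return float(t.min()), float(t.max())

    def window_before(self) -> tuple[float, float]:
        return -np.inf, self.stimulus_time

    def window_after(self) -> tuple[float, float]:
        return self.stimulus_time, np.inf


@dataclass(frozen=True)
class DirectionalitySummary:
    """Population angular bias with per-cell values."""

    angular_bias: float                  # degrees in [-90, 90]
    per_cell: pd.Series                  # per-cell mean bias
    n_cells: int
    window: tuple[float, float]


def _steps_in_window(ts: TrackSet, window: tuple[float, float] | None) -> pd.DataFrame:
    """Table of steps (consecutive position pairs) starting within [w0, w1).

    A step is assigned to a window by its start time, so the windows
    [start, stimulus) and [stimulus, end] partition the steps and the step
    taken at the uncaging frame belongs to "after".  Columns: cell_id,
    t0, t1, x0, y0, x1, y1.
    """
    if window is None:
        w0, w1 = -np.inf, np.inf
    else:
        w0, w1 = window
    df = ts.tracks
    cid = df["cell_id"].to_numpy()
    same_cell = cid[1:] == cid[:-1]
    t = df["time_s"].to_numpy(dtype=float)
    x = df["x_um"].to_numpy(dtype=float)
    y = df["y_um"].to_numpy(dtype=float)
    keep = same_cell & (t[:-1] >= w0) & (t[:-1] < w1)
    return pd.DataFrame(
        {
            "cell_id": cid[:-1][keep],
            "t0": t[:-1][keep],
            "t1": t[1:][keep],
            "x0": x[:-1][keep],
            "y0": y[:-1][keep],
            "x1": x[1:][keep],
            "y1": y[1:][keep],
        }
    )


def _angles_to_source(steps: pd.DataFrame, source) -> pd.DataFrame:
    """Per-step absolute angle (deg) between displacement and source direction.

    Zero-length displacements and steps starting exactly at the source are
    dropped (the angle is undefined there).
    """
    sx, sy = source
    dx = steps["x1"] - steps["x0"]
    dy = steps["y1"] - steps["y0"]
    ux = sx - steps["x0"]
    uy = sy - steps["y0"]
    nd = np.hypot(dx, dy)
    ns = np.hypot(ux, uy)
    ok = (nd > 0) & (ns > 0)
    cos = np.clip((dx * ux + dy * uy)[ok] / (nd * ns)[ok], -1.0, 1.0)
    out = steps.loc[ok, ["cell_id"]].copy()
    out["angle"] = np.degrees(np.arccos(cos))
    return out


def step_angles(ts: TrackSet, window: tuple[float, float] | None = None) -> np.ndarray:
    """Per-step angles to the source in degrees, 0 = toward, 180 = away.

    A step belongs to the window if its start time lies in [w0, w1).
    Zero-length displacements (and steps starting exactly at the source)
    are skipped.
    """
    steps = _steps_in_window(ts, window)
    angles = _angles_to_source(steps, ts.source)["angle"].to_numpy()
    if angles.size == 0:
        warnings.warn("no usable steps in window", stacklevel=2)
    return angles


def angular_bias(
    ts: TrackSet,
    window: tuple[float, float] | None = None,
    per_cell: bool = True,
) -> DirectionalitySummary:
    """Population angular bias toward the gradient source.

    Each step scores 90 minus its angle to the source.  With
    ``per_cell=True`` (default) scores are averaged within each cell first
    and the population value is the mean over cells; otherwise all steps
    are pooled with equal weight.
    """
    steps = _steps_in_window(ts, window)
    angled = _angles_to_source(steps, ts.source)
    if angled.empty:
        raise ValueError("no usable cells in window")
    scores = 90.0 - angled["angle"]
    cell_means = scores.groupby(angled["cell_id"]).mean()
    bias = float(cell_means.mean()) if per_cell else float(scores.mean())
    win = window if window is not None else ts.time_range
    return DirectionalitySummary(bias, cell_means, len(cell_means), tuple(win))


def mean_speed(ts: TrackSet, window: tuple[float, float] | None = None) -> float:
    """Mean cell speed in um/min over a time window.

    Per-cell speed is the total path length of in-window steps divided by
    the elapsed time they span; the population value is the mean over
    cells.  Zero-displacement steps contribute zero length but their time
    still elapses.
    """
    steps = _steps_in_window(ts, window)
    if steps.empty:
        raise ValueError("no steps in window")
    steps = steps.assign(length=np.hypot(steps["x1"] - steps["x0"], steps["y1"] - steps["y0"]))
    grouped = steps.groupby("cell_id")
    elapsed = grouped["t1"].max() - grouped["t0"].min()
    if (elapsed <= 0).any():
        bad = elapsed.index[elapsed <= 0][0]
        raise ValueError(f"cell {bad!r} has zero elapsed time in window")
    speeds = grouped["length"].sum() / elapsed * 60.0
    return float(speeds.mean())


def direction_histogram(angles, n_bins: int = 18) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of step angles over [0, 180] with equal-width bins.

    Returns (counts, bin_edges); the last bin is closed on the right so
    counts always sum to the number of angles.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    counts, edges = np.histogram(angles, bins=n_bins, range=(0.0, 180.0))
    return counts, edges


def simulate_mixed_population(
    responder_angles,
    f_responder: float,
    n_cells: int,
    steps_per_cell: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate step angles for a population with a responding subfraction.

    Each simulated cell is a responder with probability ``f_responder``.
    Responder step angles are resampled with replacement from the supplied
    empirical sample (e.g. primary-neutrophil steps); non-responder angles
    are uniform on [0, 180].  Returns (angles, responder flag per cell).
    """
    responder_angles = np.asarray(responder_angles, dtype=float)
    if responder_angles.size == 0:
        raise ValueError("responder angle sample is empty")
    if not 0.0 <= f_responder <= 1.0:
        raise ValueError("f_responder must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    responder = rng.random(n_cells) < f_responder
    angles = np.empty((n_cells, steps_per_cell), dtype=float)
    for i in range(n_cells):
        if responder[i]:
            angles[i] = rng.choice(responder_angles, size=steps_per_cell, replace=True)
        else:
            angles[i] = rng.uniform(0.0, 180.0, size=steps_per_cell)
    return angles.ravel(), responder


def mixture_expected_counts(
    responder_angles,
    f_responder: float,
    n_bins: int,
    n_total: int,
) -> np.ndarray:
    """Closed-form expected histogram of the mixed population.

    Expected counts are ``n_total * (f * p_responder + (1 - f) / n_bins)``
    where ``p_responder`` is the empirical responder bin distribution.
    """
    counts, _ = direction_histogram(responder_angles, n_bins)
    p_resp = counts / counts.sum()
    p = f_responder * p_resp + (1.0 - f_responder) / n_bins
    return n_total * p
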