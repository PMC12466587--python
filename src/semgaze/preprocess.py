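"""Gaze cleaning and assignment of samples to rotating meaning options.

Raw per-sample gaze streams (degrees of visual angle, screen-centered,
time-aligned to sentence onset) are cleaned in three steps: right-eye
selection with per-sample left-eye substitution, exclusion of off-screen
samples and of samples during saccades (angular speed > 25 deg/s), and
assignment of each retained sample to the meaning option whose expanded
bounding box contains it at that moment.

Conventions, chosen once and kept deterministic:

* velocity uses centered finite differences with per-sample dt; the first
  and last samples use one-sided differences;
* bounding boxes are axis-aligned around the option center, one character
  size wider on every side than the label glyphs: width
  ``(label_length + 2) * char_size``, height ``3 * char_size``; the
  boundary counts as inside;
* a sample inside several boxes goes to the nearest box center; exact
  distance ties break to the lower option index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import OptionLayout

__all__ = [
    "ScreenSpec",
    "FilterReport",
    "ChoiceSeries",
    "select_eye",
    "angular_speed",
    "filter_gaze",
    "option_box_at",
    "assign_choices",
]

SACCADE_THRESHOLD = 25.0   # deg/s


@dataclass(frozen=True)
class ScreenSpec:
    """Half-extents of the display in degrees of visual angle.

    Defaults derive from a 72 x 45 cm monitor viewed at 100 cm:
    atan(36/100) = 19.8 deg, atan(22.5/100) = 12.7 deg.
    """

    half_width: float = 19.8
    half_height: float = 12.7

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.half_height <= 0:
            raise ValueError("screen half-extents must be positive")


@dataclass
class FilterReport:
    """Exclusion counts from :func:`filter_gaze`, by reason."""

    n_input: int
    n_invalid: int
    n_offscreen: int
    n_saccade: int
    n_retained: int


@dataclass
class ChoiceSeries:
    """Per-sample meaning choice: option index 0-3, or -1 for none."""

    times: np.ndarray
    choice: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.choice):
            raise ValueError("times and choice must have equal length")

    def crop(self, t0: float, t1: float) -> "ChoiceSeries":
        m = (self.times >= t0) & (self.times < t1)
        return ChoiceSeries(self.times[m], self.choice[m])


def select_eye(right: pd.DataFrame | None, left: pd.DataFrame | None) -> pd.DataFrame:
    """Merge binocular streams: right eye by default, left substituted per
    sample where the right sample is missing or invalid.

    Returns a frame on the union of timestamps with a ``source_eye`` column
    ('R' or 'L'); samples missing/invalid in both eyes keep ``valid = 0``
    and are dropped by :func:`filter_gaze`.
    """
    frames = []
    if right is not None and len(right):
        frames.append(right.assign(_eye="R"))
    if left is not None and len(left):
        frames.append(left.assign(_eye="L"))
    if not frames:
        raise ValueError("both eye streams are empty")

    r = frames[0] if frames[0]["_eye"].iloc[0] == "R" else None
    l = next((f for f in frames if f["_eye"].iloc[0] == "L"), None)
    if r is None:
        out = l.drop(columns="_eye").copy()
        out["source_eye"] = "L"
        return out.reset_index(drop=True)
    if l is None:
        out = r.drop(columns="_eye").copy()
        out["source_eye"] = "R"
        return out.reset_index(drop=True)

    merged = pd.merge(
        r.drop(columns="_eye"),
        l.drop(columns="_eye"),
        on="time_s",
        how="outer",
        suffixes=("_r", "_l"),
        sort=True,
    )
    r_ok = merged["valid_r"].fillna(0).astype(int) == 1
    l_ok = merged["valid_l"].fillna(0).astype(int) == 1
    use_left = ~r_ok & l_ok
    out = pd.DataFrame({"time_s": merged["time_s"]})
    out["x_deg"] = np.where(use_left, merged["x_deg_l"], merged["x_deg_r"])
    out["y_deg"] = np.where(use_left, merged["y_deg_l"], merged["y_deg_r"])
    out["eye"] = np.where(use_left, "L", "R")
    out["valid"] = (r_ok | l_ok).astype(np.int8)
    out["source_eye"] = np.where(use_left, "L", "R")
    return out.reset_index(drop=True)


def angular_speed(times: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample angular speed (deg/s), centered differences inside and
    one-sided at the ends."""
    n = len(times)
    v = np.zeros(n)
    if n < 2:
        return v
    if n > 2:
        dt = times[2:] - times[:-2]
        disp = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2])
        with np.errstate(divide="ignore", invalid="ignore"):
            v[1:-1] = np.where(dt > 0, disp / dt, np.inf)
    d0 = times[1] - times[0]
    v[0] = np.hypot(x[1] - x[0], y[1] - y[0]) / d0 if d0 > 0 else np.inf
    d1 = times[-1] - times[-2]
    v[-1] = np.hypot(x[-1] - x[-2], y[-1] - y[-2]) / d1 if d1 > 0 else np.inf
    return v


def filter_gaze(
    samples: pd.DataFrame,
    screen: ScreenSpec = ScreenSpec(),
    velocity_threshold: float = SACCADE_THRESHOLD,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop invalid, off-screen and saccadic samples.

    Samples must be time-sorted.  A sample is excluded if it is flagged
    invalid, lies outside the screen (|x| > half_width or |y| > half_height),
    or its centered-difference angular speed exceeds ``velocity_threshold``.
    """
    t = samples["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("samples must be time-sorted")
    n_input = len(samples)
    valid = samples["valid"].to_numpy() == 1 if "valid" in samples else np.ones(n_input, bool)
    work = samples.loc[valid].reset_index(drop=True)
    n_invalid = n_input - len(work)

    t = work["time_s"].to_numpy(dtype=float)
    x = work["x_deg"].to_numpy(dtype=float)
    y = work["y_deg"].to_numpy(dtype=float)

    offscreen = (np.abs(x) > screen.half_width) | (np.abs(y) > screen.half_height)
    if len(work) < 2:
        warnings.warn("fewer than 2 samples: velocity filter skipped", stacklevel=2)
        saccadic = np.zeros(len(work), dtype=bool)
    else:
        saccadic = angular_speed(t, x, y) > velocity_threshold
    keep = ~offscreen & ~saccadic
    retained = work.loc[keep].reset_index(drop=True)
    report = FilterReport(
        n_input=n_input,
        n_invalid=n_invalid,
        n_offscreen=int(offscreen.sum()),
        n_saccade=int((saccadic & ~offscreen).sum()),
        n_retained=len(retained),
    )
    return retained, report


def _box_half_sizes(layout: OptionLayout) -> np.ndarray:
    """Half-width/half-height (4, 2) of the expanded bounding boxes."""
    w = (np.asarray(layout.label_lengths, dtype=float) + 2.0) * layout.char_size
    h = np.full(4, 3.0 * layout.char_size)
    return np.stack([w, h], axis=1) / 2.0


def option_box_at(t: float, option_index: int, layout: OptionLayout):
    """Axis-aligned bounding box (xmin, xmax, ymin, ymax) of one option at
    time ``t``, expanded by one character size on every side."""
    if not 0 <= option_index <= 3:
        raise IndexError("option_index must be in 0..3")
    cx, cy = layout.centers_at(np.asarray(t, dtype=float))[..., option_index, :].T
    hw, hh = _box_half_sizes(layout)[option_index]
    return float(cx) - hw, float(cx) + hw, float(cy) - hh, float(cy) + hh


def assign_choices(
    samples: pd.DataFrame, layout: OptionLayout
) -> tuple[ChoiceSeries, float]:
    """Assign each retained sample to the option whose box contains it.

    Inside exactly one box -> that option; inside several -> nearest box
    center (ties to the lower index); inside none -> -1.  Also returns the
    assignment rate (assigned / retained samples).
    """
    t = samples["time_s"].to_numpy(dtype=float)
    xy = samples[["x_deg", "y_deg"]].to_numpy(dtype=float)
    n = len(t)
    if n == 0:
        return ChoiceSeries(t, np.empty(0, dtype=np.int16)), float("nan")

    centers = layout.centers_at(t)                  # (n, 4, 2)
    half = _box_half_sizes(layout)                  # (4, 2)
    delta = np.abs(xy[:, None, :] - centers)        # (n, 4, 2)
    inside = np.all(delta <= half[None, :, :], axis=2)

    dist2 = np.sum((xy[:, None, :] - centers) ** 2, axis=2)
    dist2 = np.where(inside, dist2, np.inf)
    choice = np.argmin(dist2, axis=1).astype(np.int16)   # ties -> lower index
    choice[~inside.any(axis=1)] = -1

    rate = float(np.mean(choice >= 0))
    return ChoiceSeries(t, choice), rate
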