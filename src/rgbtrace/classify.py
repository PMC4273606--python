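"""Colour calling: brightness, thresholding, 7-class assignment, hue.

A measured cell is assigned the colour class given by the channels whose
mean intensity reaches the channel threshold (default 40 on the 8-bit
scale); cells whose luma-weighted perceived brightness falls below the
autofluorescence threshold (default 40) are treated as unlabelled
background.  Hue — the intensity-ratio angle, stable within a clone —
supports grouping cells into putative clones by circular single-linkage
clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.colors import rgb_to_hsv

from .model import ClassDistribution, class_of_pattern

#: Luma weights of the RGB→grayscale conversion (ITU-R BT.601).
BRIGHTNESS_WEIGHTS = (0.299, 0.587, 0.114)

DEFAULT_CHANNEL_THRESHOLD = 40.0
DEFAULT_BRIGHTNESS_THRESHOLD = 40.0

CALL_COLUMNS = ["cell_id", "brightness", "color_class",
                "hue_deg", "saturation"]


def perceived_brightness(r, g, b):
    """Luma-weighted grayscale value 0.299·R + 0.587·G + 0.114·B.

    Accepts scalars or arrays; inputs must be non-negative.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(r < 0) or np.any(g < 0) or np.any(b < 0):
        raise ValueError("intensities must be non-negative")
    wr, wg, wb = BRIGHTNESS_WEIGHTS
    out = wr * r + wg * g + wb * b
    return float(out) if out.ndim == 0 else out


def hue_saturation(r: float, g: float, b: float) -> tuple[float, float]:
    """Standard hexcone hue (degrees in [0, 360)) and saturation in [0, 1].

    Hue is invariant under scaling (r, g, b) by any positive constant —
    the property that makes it a clonal watermark.  Black input has no
    hue and raises.
    """
    if min(r, g, b) < 0:
        raise ValueError("intensities must be non-negative")
    m = max(r, g, b)
    if m <= 0:
        raise ValueError("hue is undefined for black (0, 0, 0)")
    h, s, _ = rgb_to_hsv(np.array([r, g, b]) / m)
    return (float(h) * 360.0) % 360.0, float(s)


@dataclass
class ColorCall:
    """Colour-class call for one cell."""

    cell_id: int
    brightness: float
    channel_calls: tuple[bool, bool, bool]
    color_class: str
    hue_deg: float  # NaN when unlabelled
    saturation: float

    @property
    def labelled(self) -> bool:
        return self.color_class != "unlabelled"


def classify_cell(r: float, g: float, b: float,
                  channel_threshold: float = DEFAULT_CHANNEL_THRESHOLD,
                  autofluor_brightness: float = DEFAULT_BRIGHTNESS_THRESHOLD,
                  cell_id: int = 0) -> ColorCall:
    """Call the colour class of one cell from its mean channel intensities.

    A channel is present when its intensity reaches ``channel_threshold``;
    the class is the pattern of present channels.  A cell with no channel
    present, or with perceived brightness below ``autofluor_brightness``,
    is unlabelled (non-specific autofluorescence).
    """
    if min(r, g, b) < 0 or max(r, g, b) > 255:
        raise ValueError("intensities must lie in [0, 255]")
    brightness = perceived_brightness(r, g, b)
    calls = (r >= channel_threshold, g >= channel_threshold,
             b >= channel_threshold)
    cls = class_of_pattern(*calls)
    if brightness < autofluor_brightness:
        cls = "unlabelled"
        calls = (False, False, False)
    if cls == "unlabelled":
        hue, sat = math.nan, math.nan
    else:
        hue, sat = hue_saturation(r, g, b)
    return ColorCall(cell_id=cell_id, brightness=float(brightness),
                     channel_calls=calls, color_class=cls,
                     hue_deg=hue, saturation=sat)


def classify_table(table: pd.DataFrame,
                   channel_threshold: float = DEFAULT_CHANNEL_THRESHOLD,
                   autofluor_brightness: float = DEFAULT_BRIGHTNESS_THRESHOLD,
                   include_excluded: bool = False) -> pd.DataFrame:
    """Classify every (non-excluded) row of an intensity table.

    Expects columns ``cell_id, intensity_r, intensity_g, intensity_b`` and
    optionally ``excluded``; excluded rows are skipped unless requested.
    """
    rows = []
    for _, row in table.iterrows():
        if not include_excluded and bool(row.get("excluded", False)):
            continue
        call = classify_cell(row["intensity_r"], row["intensity_g"],
                             row["intensity_b"],
                             channel_threshold=channel_threshold,
                             autofluor_brightness=autofluor_brightness,
                             cell_id=int(row["cell_id"]))
        rows.append((call.cell_id, call.brightness, call.color_class,
                     call.hue_deg, call.saturation))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def class_distribution(calls) -> ClassDistribution:
    """Tally colour classes (list of :class:`ColorCall` or a call table)."""
    if isinstance(calls, pd.DataFrame):
        labels = calls["color_class"]
    else:
        labels = [c.color_class for c in calls]
    return ClassDistribution.from_classes(labels)


def _circular_gap_clusters(hues: np.ndarray, tol: float) -> np.ndarray:
    """Exact single-linkage on the circle: split at sorted gaps > tol."""
    order = np.argsort(hues, kind="stable")
    sorted_h = hues[order]
    n = len(sorted_h)
    gaps = np.diff(sorted_h)
    wrap_gap = 360.0 - (sorted_h[-1] - sorted_h[0])
    labels_sorted = np.zeros(n, dtype=int)
    labels_sorted[1:] = np.cumsum(gaps > tol)
    if wrap_gap <= tol and labels_sorted[-1] != 0:
        labels_sorted[labels_sorted == labels_sorted[-1]] = 0
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def cluster_by_hue(calls, hue_tolerance_deg: float,
                   min_brightness: float = DEFAULT_BRIGHTNESS_THRESHOLD) -> pd.DataFrame:
    """Group cells into putative clones by hue proximity.

    Single-linkage clustering on circular hue distance, cut at
    ``hue_tolerance_deg``: two cells share a clone group whenever a chain
    of cells links them with consecutive hue gaps within tolerance.  On
    the circle this is exactly a split of the sorted hues at gaps larger
    than the tolerance (including the wrap-around gap).  Cells below
    ``min_brightness``, or without a defined hue, stay unassigned
    (clone_id −1).  Clone ids are assigned in increasing order of each
    cluster's lowest member hue, making the labelling order-independent.
    """
    if not (0 < hue_tolerance_deg < 180):
        raise ValueError("hue tolerance must be in (0, 180) degrees")
    if isinstance(calls, pd.DataFrame):
        frame = calls
    else:
        frame = pd.DataFrame(
            [(c.cell_id, c.brightness, c.hue_deg) for c in calls],
            columns=["cell_id", "brightness", "hue_deg"])
    hues = frame["hue_deg"].to_numpy(dtype=float)
    bright = frame["brightness"].to_numpy(dtype=float)
    ok = (bright >= min_brightness) & np.isfinite(hues)
    clone = np.full(len(frame), -1, dtype=int)
    if ok.sum():
        raw = _circular_gap_clusters(hues[ok] % 360.0, hue_tolerance_deg)
        # deterministic ids ordered by lowest member hue
        min_hue = {lab: (hues[ok] % 360.0)[raw == lab].min()
                   for lab in np.unique(raw)}
        rank = {lab: i for i, lab in
                enumerate(sorted(min_hue, key=min_hue.get))}
        clone[ok] = [rank[lab] for lab in raw]
    return pd.DataFrame({"cell_id": frame["cell_id"].to_numpy(),
                         "clone_id": clone})


def scatter3d_export(table: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table for the 3-D intensity scatter (r, g, b axes,
    brightness colour-coded, class annotated).

    ``table`` and ``calls`` must cover identical cell ids.
    """
    t_ids = list(table["cell_id"]) if len(table) else []
    c_ids = list(calls["cell_id"]) if len(calls) else []
    if sorted(t_ids) != sorted(c_ids):
        raise ValueError("intensity table and calls cover different cell ids")
    cols = ["cell_id", "r", "g", "b", "brightness", "class"]
    if not t_ids:
        return pd.DataFrame(columns=cols)
    merged = table.merge(calls, on="cell_id")
    out = pd.DataFrame({
        "cell_id": merged["cell_id"],
        "r": merged["intensity_r"],
        "g": merged["intensity_g"],
        "b": merged["intensity_b"],
        "brightness": merged["brightness"],
        "class": merged["color_class"],
    })
    return out[cols]
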