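"""Per-cell intensity quantification from a 3-channel image and label mask.

Given a raster and an integer label mask, measure the mean intensity of
each cell body in the red, green and blue channels — the per-cell (R, G, B)
values that feed colour classification.  A minimal threshold/connected-
components segmenter is included so the pipeline runs end-to-end on
synthetic scenes; real masks may come from any external segmentation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as _cc_label

log = logging.getLogger(__name__)

INTENSITY_COLUMNS = ["cell_id", "intensity_r", "intensity_g", "intensity_b",
                     "area_px", "excluded", "exclude_reason"]


def rescale_to_8bit(image: np.ndarray, how: str = "dtype",
                    percentile: float = 99.9) -> np.ndarray:
    """Map an image onto the 8-bit-equivalent scale [0, 255].

    ``how="dtype"`` divides integer images by their dtype maximum (the
    default, so a 16-bit acquisition maps linearly onto [0, 255]);
    ``how="percentile"`` scales the given upper percentile to 255;
    ``how="none"`` passes through.  Float images are assumed to already be
    on the 8-bit scale and pass through under ``"dtype"``.
    """
    img = np.asarray(image)
    if how == "none":
        return img.astype(np.float64)
    if how == "percentile":
        top = np.percentile(img, percentile)
        if top <= 0:
            return img.astype(np.float64)
        log.info("rescaling by percentile %.2f (=%.3f) to [0, 255]",
                 percentile, top)
        return np.clip(img.astype(np.float64) * (255.0 / top), 0, 255)
    if how == "dtype":
        if np.issubdtype(img.dtype, np.integer):
            info = np.iinfo(img.dtype)
            if info.max != 255:
                log.info("rescaling %s image by dtype range %d to [0, 255]",
                         img.dtype, info.max)
            return img.astype(np.float64) * (255.0 / info.max)
        return img.astype(np.float64)
    raise ValueError("how must be 'dtype', 'percentile' or 'none'")


def measure_cells(image: np.ndarray, mask: np.ndarray,
                  labels=None, rescale: str = "dtype") -> pd.DataFrame:
    """Mean per-channel intensity of every labelled cell body.

    Parameters
    ----------
    image
        (rows, cols, 3) raster, channel order (R, G, B).
    mask
        Integer label raster of the same spatial shape; 0 is background.
    labels
        Optional explicit label ids to report.  Ids absent from the mask
        appear as excluded rows (reason ``"empty label"``) rather than
        being dropped.  Default: all nonzero labels present in the mask.
    rescale
        Intensity rescaling mode, see :func:`rescale_to_8bit`.

    Returns one row per label with mean intensities in [0, 255], pixel
    area, and exclusion flags (initially clear except for empty labels).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (rows, cols, 3)")
    if mask.shape != image.shape[:2]:
        raise ValueError("mask and image spatial shapes must match")
    if np.any(mask < 0):
        raise ValueError("mask labels must be non-negative integers")
    img = rescale_to_8bit(image, how=rescale)

    present = np.unique(mask)
    present = present[present > 0]
    wanted = present if labels is None else np.asarray(sorted(labels))
    rows = []
    if present.size:
        areas = ndimage.sum_labels(np.ones_like(mask, dtype=np.int64),
                                   labels=mask, index=present)
        means = [ndimage.mean(img[..., c], labels=mask, index=present)
                 for c in range(3)]
        by_label = {int(lab): (float(means[0][i]), float(means[1][i]),
                               float(means[2][i]), int(areas[i]))
                    for i, lab in enumerate(present)}
    else:
        by_label = {}
    for lab in wanted:
        lab = int(lab)
        if lab in by_label:
            r, g, b, area = by_label[lab]
            rows.append((lab, r, g, b, area, False, ""))
        else:
            rows.append((lab, np.nan, np.nan, np.nan, 0, True, "empty label"))
    return pd.DataFrame(rows, columns=INTENSITY_COLUMNS)


def exclude_ambiguous(table: pd.DataFrame, mask: np.ndarray,
                      min_area: float = 1, max_area: float = np.inf,
                      border_policy: str = "exclude") -> pd.DataFrame:
    """Flag cells that are not individually distinguishable.

    Labels with area outside ``[min_area, max_area]`` (an oversize region
    is the proxy for merged/overlapping bodies) or touching the image
    border (when ``border_policy="exclude"``) are flagged with a reason;
    rows are retained, never dropped.  Exclusion counts are logged.
    """
    if min_area <= 0 or max_area <= 0:
        raise ValueError("area bounds must be positive")
    if border_policy not in ("exclude", "keep"):
        raise ValueError("border_policy must be 'exclude' or 'keep'")
    mask = np.asarray(mask)
    border_labels: set[int] = set()
    if border_policy == "exclude":
        border = np.concatenate([mask[0, :], mask[-1, :],
                                 mask[:, 0], mask[:, -1]])
        border_labels = set(int(v) for v in np.unique(border)) - {0}

    out = table.copy()
    reasons = []
    for _, row in out.iterrows():
        why = []
        if row["excluded"] and row["exclude_reason"]:
            why.append(str(row["exclude_reason"]))
        if not why or "empty" not in why[0]:
            if row["area_px"] < min_area:
                why.append(f"area {row['area_px']:.0f} < min {min_area}")
            elif row["area_px"] > max_area:
                why.append(f"area {row['area_px']:.0f} > max {max_area} "
                           "(possible merged bodies)")
            if int(row["cell_id"]) in border_labels:
                why.append("touches image border")
        reasons.append("; ".join(why))
    out["exclude_reason"] = reasons
    out["excluded"] = [bool(r) for r in reasons]
    n_exc = int(out["excluded"].sum())
    log.info("exclude_ambiguous: %d of %d cells flagged", n_exc, len(out))
    return out


def segment_simple(image: np.ndarray, threshold: float,
                   min_area: int = 1, rescale: str = "dtype") -> np.ndarray:
    """Baseline segmentation: channel-max threshold + connected components.

    Pixels whose maximum over the three channels reaches ``threshold``
    are foreground; 8-connected components smaller than ``min_area``
    pixels are removed and labels renumbered consecutively.  Deterministic.
    """
    if not (0 < threshold < 255):
        raise ValueError("threshold must be in (0, 255)")
    img = rescale_to_8bit(np.asarray(image), how=rescale)
    fg = img.max(axis=2) >= threshold
    labels = _cc_label(fg, connectivity=2)
    if min_area > 1 and labels.max() > 0:
        ids, areas = np.unique(labels[labels > 0], return_counts=True)
        small = set(int(i) for i, a in zip(ids, areas) if a < min_area)
        if small:
            labels[np.isin(labels, list(small))] = 0
    # renumber 1..k in raster-scan order of first appearance
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.uint16)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def match_labels(seg_mask: np.ndarray, truth_mask: np.ndarray) -> dict[int, int]:
    """Map each segmented label to the truth label with maximal overlap.

    Labels overlapping only background map to 0.
    """
    seg = np.asarray(seg_mask)
    truth = np.asarray(truth_mask)
    if seg.shape != truth.shape:
        raise ValueError("masks must share shape")
    mapping: dict[int, int] = {}
    for lab in np.unique(seg):
        if lab == 0:
            continue
        under = truth[seg == lab]
        vals, counts = np.unique(under, return_counts=True)
        mapping[int(lab)] = int(vals[np.argmax(counts)])
    return mapping
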