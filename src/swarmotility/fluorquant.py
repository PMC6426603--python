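"""Per-cell two-channel fluorescence quantification.

Cells are segmented on a reference (phase-like) image, size-filtered,
and their total fluorescence is integrated per channel after background
and autofluorescence subtraction.  The CheZ-mCherry / CheY-mYFP ratio
per cell, and its shift between conditions, quantifies relative
phosphatase expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from . import stats as wstats

logger = logging.getLogger(__name__)

__all__ = [
    "segment_cells",
    "filter_by_size",
    "cell_fluorescence",
    "measure_cells",
    "expression_ratio",
]


def segment_cells(
    image: np.ndarray,
    min_area: int = 20,
    split_touching: bool = True,
    max_single_area: float | None = None,
) -> np.ndarray:
    """Segment cells by Otsu threshold + connected components.

    Connected components larger than ``max_single_area`` (default:
    twice the median component area, i.e. plausibly a touching pair)
    are split by a watershed on the distance transform seeded at the
    strongest distance maxima.  Splitting is deliberately conservative:
    rod-shaped single cells have ridge-like distance transforms that
    naive peak seeding would fragment.  Returns an integer label image
    (0 = background); an image with no foreground yields all zeros.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=int)
    thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any():
        return np.zeros(img.shape, dtype=int)
    labels = cc_label(fg)
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    if split_touching and ids.size:
        ref_area = (
            max_single_area
            if max_single_area is not None
            else 2.0 * float(np.median(areas))
        )
        next_label = int(labels.max()) + 1
        for cid, area in zip(ids, areas):
            if area <= ref_area:
                continue
            mask = labels == cid
            dist = ndi.distance_transform_edt(mask)
            n_expect = max(2, int(round(area / max(ref_area / 2.0, 1.0))))
            peaks = peak_local_max(
                dist, min_distance=3, num_peaks=n_expect, exclude_border=False
            )
            if len(peaks) < 2:
                continue
            markers = np.zeros(img.shape, dtype=int)
            for i, (r, c) in enumerate(peaks, start=1):
                markers[r, c] = i
            pieces = watershed(-dist, markers, mask=mask)
            labels[mask] = pieces[mask] + next_label
            next_label += int(pieces.max()) + 1
    # drop specks and renumber consecutively
    out = np.zeros(img.shape, dtype=int)
    next_id = 1
    for lab in np.unique(labels[labels > 0]):
        mask = labels == lab
        if mask.sum() >= min_area:
            out[mask] = next_id
            next_id += 1
    return out


def filter_by_size(labels: np.ndarray, k_sd: float = 3.0) -> tuple[np.ndarray, dict]:
    """Drop cells whose area deviates more than ``k_sd`` SD from the mean.

    Returns the filtered label image (labels preserved, not renumbered)
    and a report with the discarded fraction.
    """
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if ids.size < 5:
        raise ValueError("need >= 5 cells for a meaningful size filter")
    mean = counts.mean()
    sd = counts.std(ddof=1)
    keep = np.abs(counts - mean) <= k_sd * sd if sd > 0 else np.ones(ids.size, bool)
    out = labels.copy()
    for cid in ids[~keep]:
        out[labels == cid] = 0
    report = {
        "n_cells": int(ids.size),
        "n_discarded": int((~keep).sum()),
        "discarded_fraction": float((~keep).mean()),
        "area_mean": float(mean),
        "area_sd": float(sd),
    }
    return out, report


def cell_fluorescence(
    mask: np.ndarray,
    channel: np.ndarray,
    background: float | None = None,
    autofluorescence: float = 0.0,
    full_labels: np.ndarray | None = None,
) -> float:
    """Total background- and autofluorescence-corrected signal in one cell.

    total = Σ_mask (pixel − background) − autofluorescence.  If
    ``background`` is None it defaults to the median of non-cell pixels
    (using ``full_labels`` to exclude all cells if given, else the
    mask).  Negative corrected totals are clipped to zero with a
    warning.
    """
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(channel, dtype=float)
    if mask.shape != img.shape:
        raise ValueError("mask does not match image shape")
    if not mask.any():
        raise ValueError("empty mask")
    if background is None:
        outside = (full_labels == 0) if full_labels is not None else ~mask
        background = float(np.median(img[outside]))
    if background < 0 or autofluorescence < 0:
        raise ValueError("background and autofluorescence must be >= 0")
    total = float(np.sum(img[mask] - background) - autofluorescence)
    if total < 0:
        logger.warning("negative corrected total (%.1f) clipped to 0", total)
        total = 0.0
    return total


def measure_cells(
    labels: np.ndarray,
    yfp: np.ndarray,
    cherry: np.ndarray,
    background_yfp: float | None = None,
    background_cherry: float | None = None,
    autofluorescence: float = 0.0,
) -> pd.DataFrame:
    """Per-cell totals in both channels; one row per labeled cell."""
    ids = np.unique(labels[labels > 0])
    rows = []
    for cid in ids:
        mask = labels == cid
        rows.append(
            (
                int(cid),
                int(mask.sum()),
                cell_fluorescence(mask, yfp, background_yfp, autofluorescence, labels),
                cell_fluorescence(mask, cherry, background_cherry, autofluorescence, labels),
            )
        )
    df = pd.DataFrame(rows, columns=["cell_id", "area_px", "yfp_total", "cherry_total"])
    valid = df["yfp_total"] > 0
    if (~valid).any():
        logger.warning("excluding %d cells with non-positive YFP totals",
                       int((~valid).sum()))
    df["ratio"] = np.where(valid, df["cherry_total"] / df["yfp_total"].where(valid), np.nan)
    return df


def expression_ratio(
    cells_by_condition: dict[str, pd.DataFrame],
    reference: str | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    min_cells: int = 50,
) -> dict:
    """Compare per-cell cherry/yfp expression ratios across conditions.

    Returns per-condition medians and means of the per-cell ratio, the
    shift of each condition's median relative to ``reference`` (default:
    first key), and a trajectory-permutation ANOVA p-value on the
    per-cell ratios with unit weights.
    """
    conditions = list(cells_by_condition)
    if reference is None:
        reference = conditions[0]
    values, groups = [], []
    med = {}
    mean = {}
    for cond in conditions:
        df = cells_by_condition[cond]
        r = df["ratio"].dropna().to_numpy()
        if r.size < min_cells:
            raise ValueError(
                f"condition {cond!r} has {r.size} usable cells; need >= {min_cells}"
            )
        med[cond] = float(np.median(r))
        mean[cond] = float(np.mean(r))
        values.append(r)
        groups.append(np.full(r.size, cond))
    values = np.concatenate(values)
    groups = np.concatenate(groups)
    result = wstats.permutation_pvalue(
        values, np.ones(values.size), groups, n_perm=n_perm, seed=seed
    )
    return {
        "median_ratio": med,
        "mean_ratio": mean,
        "median_shift": {c: med[c] / med[reference] for c in conditions},
        "mean_shift": {c: mean[c] / mean[reference] for c in conditions},
        "reference": reference,
        "F": result.F_observed,
        "p_value": result.p_value,
        "n_cells": int(values.size),
    }
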