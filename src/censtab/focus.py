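"""Median-focus signal quantification and circularity-filtered colony counts.

The "median focus" procedure turns a field of punctate FISH/IF foci into one
robust per-cell signal scalar:

1. foci are detected by thresholding the channel inside the nucleus mask and
   taking 8-connected components above a minimum area;
2. a fixed-size square box (even side, 10-20 px) is cut around each focus
   centroid;
3. the per-cell *median focus* is the pixel-wise median of those boxes;
4. the local background is the median of the median focus's outermost
   1-pixel ring, and the per-cell signal is the sum of the
   background-subtracted median focus (negatives retained) — capturing both
   focus intensity and size in one number.

For immunofluorescence, detection can be *anchored*: boxes are defined on a
reference channel (e.g. CENP-B, which marks centromere positions regardless
of treatment) and the same boxes quantify every other channel, yielding
per-cell signal ratios such as CENP-A/CENP-B.

Colony counting reproduces particle analysis on thresholded 8-bit plate
images: connected components whose circularity 4*pi*area/perimeter^2 falls in
[0.01, 1.00] are counted as colonies, which discards scratches and debris.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import find_contours, label as sk_label, regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "FocusDetectionParams",
    "FocusPatchSet",
    "MedianFocus",
    "detect_foci",
    "extract_patches",
    "median_focus",
    "perimeter_background",
    "focus_signal",
    "quantify_cells",
    "anchored_quantify",
    "normalize_to_control",
    "ColonyCountParams",
    "boundary_perimeter",
    "count_colonies",
]


@dataclass(frozen=True)
class FocusDetectionParams:
    """Threshold detection parameters.

    ``threshold`` is in the image's own intensity units (on 12-bit-like data
    a few hundred a.u. is typical); ``box_size`` must be even and in
    [10, 20] px as the median-focus procedure prescribes.
    """

    threshold: float = 400.0
    min_area: int = 2
    box_size: int = 14

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.box_size % 2 != 0 or not 10 <= self.box_size <= 20:
            raise ValueError("box_size must be an even integer in [10, 20]")


@dataclass
class FocusPatchSet:
    """All same-size boxes cut around one cell's foci in one channel."""

    cell_id: int
    channel: str
    patches: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class MedianFocus:
    """Pixel-wise median focus with its ring background and signal sum."""

    patch: np.ndarray
    background: float
    signal_sum: float


def detect_foci(
    channel: np.ndarray,
    nucleus_labels: np.ndarray,
    params: FocusDetectionParams,
) -> dict[int, list[tuple[float, float]]]:
    """Detect foci as thresholded 8-connected components inside nuclei.

    Returns ``{cell_id: [(row, col), ...]}`` focus centroids; a focus belongs
    to the nucleus label under its (rounded) centroid. Components smaller
    than ``min_area`` pixels are ignored.
    """
    if channel.shape != nucleus_labels.shape:
        raise ValueError("channel and nucleus mask shapes differ")
    binary = (channel >= params.threshold) & (nucleus_labels > 0)
    lab = sk_label(binary, connectivity=2)
    out: dict[int, list[tuple[float, float]]] = {
        int(i): [] for i in np.unique(nucleus_labels) if i > 0
    }
    for prop in regionprops(lab):
        if prop.area < params.min_area:
            continue
        r, c = prop.centroid
        cell = int(nucleus_labels[int(round(r)), int(round(c))])
        if cell > 0:
            out[cell].append((float(r), float(c)))
    return out


def extract_patches(
    channel: np.ndarray,
    centroids: list[tuple[float, float]],
    box_size: int,
    cell_id: int = 0,
    channel_name: str = "",
) -> FocusPatchSet:
    """Cut an even ``box_size`` square around each centroid.

    Centering convention: the centroid is rounded to the nearest pixel
    (r, c) and the box covers rows r - s/2 .. r + s/2 - 1 (half-open),
    likewise for columns. Boxes that would cross the image border are
    dropped and logged rather than padded, so ring backgrounds are never
    contaminated by padding.
    """
    if box_size % 2 != 0:
        raise ValueError("box_size must be even")
    s = box_size
    h, w = channel.shape
    patches = []
    n_dropped = 0
    for (r, c) in centroids:
        ri, ci = int(round(r)), int(round(c))
        r0, c0 = ri - s // 2, ci - s // 2
        if r0 < 0 or c0 < 0 or r0 + s > h or c0 + s > w:
            n_dropped += 1
            continue
        patches.append(channel[r0 : r0 + s, c0 : c0 + s].copy())
    if n_dropped:
        logger.info(
            "extract_patches cell=%s channel=%s dropped=%d reason=box_out_of_bounds",
            cell_id, channel_name, n_dropped,
        )
    return FocusPatchSet(cell_id=cell_id, channel=channel_name, patches=patches)


def median_focus(patchset: FocusPatchSet) -> np.ndarray:
    """Pixel-wise median across a cell's focus boxes.

    An even number of boxes uses the mean of the two central order
    statistics at each pixel.
    """
    if len(patchset) == 0:
        raise ValueError("cannot form a median focus from zero patches")
    stack = np.stack(patchset.patches, axis=0)
    return np.median(stack, axis=0)


def perimeter_background(patch: np.ndarray) -> float:
    """Median of the patch's outermost 1-pixel ring (4*(s-1) values)."""
    s0, s1 = patch.shape
    if s0 < 3 or s1 < 3:
        raise ValueError("patch must be at least 3x3 to have an interior")
    ring = np.concatenate(
        [patch[0, :], patch[-1, :], patch[1:-1, 0], patch[1:-1, -1]]
    )
    return float(np.median(ring))


def focus_signal(median_patch: np.ndarray, background: float) -> float:
    """Sum of the background-subtracted median focus; negatives retained."""
    return float((median_patch - background).sum())


def quantify_cells(
    channel: np.ndarray,
    nucleus_labels: np.ndarray,
    params: FocusDetectionParams,
    channel_name: str = "signal",
) -> pd.DataFrame:
    """Full single-channel median-focus quantification, one row per cell.

    Cells with no usable foci are skipped and reported with a reason code in
    ``df.attrs['skipped']``.
    """
    centroids = detect_foci(channel, nucleus_labels, params)
    rows, skipped = [], {}
    for cell_id, pts in sorted(centroids.items()):
        if not pts:
            skipped[cell_id] = "no_foci"
            continue
        ps = extract_patches(channel, pts, params.box_size, cell_id, channel_name)
        if len(ps) == 0:
            skipped[cell_id] = "all_boxes_out_of_bounds"
            continue
        med = median_focus(ps)
        bg = perimeter_background(med)
        rows.append(
            {
                "cell_id": cell_id,
                "n_foci": len(ps),
                "background": bg,
                "signal_sum": focus_signal(med, bg),
            }
        )
    df = pd.DataFrame(rows, columns=["cell_id", "n_foci", "background", "signal_sum"])
    df.attrs["skipped"] = skipped
    return df


def anchored_quantify(
    anchor_channel: np.ndarray,
    signal_channels: dict[str, np.ndarray],
    nucleus_labels: np.ndarray,
    params: FocusDetectionParams,
    anchor_name: str = "anchor",
) -> pd.DataFrame:
    """Quantify several channels inside boxes defined by the anchor channel.

    Foci are detected once, on ``anchor_channel`` (e.g. CENP-B); the same
    boxes then yield a median focus, ring background and signal sum for the
    anchor and for every channel in ``signal_channels``, plus the per-cell
    ratio signal/anchor. Cells with no anchor foci are skipped with reason.
    """
    for name, ch in signal_channels.items():
        if ch.shape != anchor_channel.shape:
            raise ValueError(f"channel {name!r} shape differs from anchor")
    centroids = detect_foci(anchor_channel, nucleus_labels, params)
    rows, skipped = [], {}
    for cell_id, pts in sorted(centroids.items()):
        if not pts:
            skipped[cell_id] = "no_anchor_foci"
            continue
        # keep only boxes valid in-bounds; identical boxes across channels
        anchor_ps = extract_patches(
            anchor_channel, pts, params.box_size, cell_id, anchor_name
        )
        if len(anchor_ps) == 0:
            skipped[cell_id] = "all_boxes_out_of_bounds"
            continue
        med_a = median_focus(anchor_ps)
        bg_a = perimeter_background(med_a)
        sig_a = focus_signal(med_a, bg_a)
        row = {
            "cell_id": cell_id,
            "n_foci": len(anchor_ps),
            f"{anchor_name}_background": bg_a,
            f"{anchor_name}_signal": sig_a,
        }
        for name, ch in signal_channels.items():
            ps = extract_patches(ch, pts, params.box_size, cell_id, name)
            med = median_focus(ps)
            bg = perimeter_background(med)
            sig = focus_signal(med, bg)
            row[f"{name}_background"] = bg
            row[f"{name}_signal"] = sig
            row[f"{name}_over_{anchor_name}"] = sig / sig_a if sig_a != 0 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df


def normalize_to_control(
    values: pd.Series | np.ndarray,
    conditions: pd.Series | np.ndarray,
    control_condition: str,
) -> pd.Series:
    """Divide every value by the mean of the control condition's values.

    The control condition's mean maps to exactly 1. Raises if the control is
    absent or its mean is zero.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    conditions = pd.Series(np.asarray(conditions), index=values.index)
    ctrl = values[conditions == control_condition]
    if len(ctrl) == 0:
        raise ValueError(f"control condition {control_condition!r} not present")
    m = ctrl.mean()
    if m == 0:
        raise ValueError("control condition mean is zero; cannot normalize")
    return values / m


# ---------------------------------------------------------------------------
# Colony counting
# ---------------------------------------------------------------------------

def boundary_perimeter(mask: np.ndarray) -> float:
    """Traced-outline perimeter of a binary object.

    The object's boundary is traced by marching squares at the 0.5 level on
    the zero-padded mask and the polyline lengths are summed (inner hole
    boundaries included). This is the traced-outline convention of particle
    analysis: a 1-px line of length L measures ~2L, a rasterized disk close
    to 2*pi*r.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        d = np.diff(contour, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


@dataclass(frozen=True)
class ColonyCountParams:
    """Threshold and circularity window for particle-style colony counting.

    Digital circularity of a rasterized object can slightly exceed 1, so the
    upper bound admits a small overshoot tolerance via ``circularity_slack``
    applied on top of ``circularity_max`` when filtering.
    """

    threshold: float = 128.0
    circularity_min: float = 0.01
    circularity_max: float = 1.00
    circularity_slack: float = 0.10
    min_area: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.circularity_min <= self.circularity_max:
            raise ValueError("invalid circularity bounds")


def count_colonies(
    image: np.ndarray, params: ColonyCountParams = ColonyCountParams()
) -> tuple[int, pd.DataFrame]:
    """Count colonies on a thresholded 8-bit plate image.

    Objects are 8-connected components of ``image >= threshold``; circularity
    is 4*pi*area/perimeter^2 with the traced-outline perimeter estimator (the
    particle-analysis convention). Objects within the circularity window are
    counted; everything is reported in the per-object table with a ``kept``
    flag so exclusions are auditable.
    """
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    binary = np.asarray(image, dtype=float) >= params.threshold
    lab = sk_label(binary, connectivity=2)
    rows = []
    hi = params.circularity_max + params.circularity_slack
    for prop in regionprops(lab):
        if prop.area < params.min_area:
            continue
        p = boundary_perimeter(lab == prop.label)
        circ = 4.0 * np.pi * prop.area / p**2 if p > 0 else np.inf
        kept = params.circularity_min <= circ <= hi
        rows.append(
            {
                "label": prop.label,
                "area": int(prop.area),
                "perimeter": float(p),
                "circularity": float(circ),
                "kept": bool(kept),
            }
        )
    table = pd.DataFrame(
        rows, columns=["label", "area", "perimeter", "circularity", "kept"]
    )
    count = int(table["kept"].sum()) if len(table) else 0
    return count, table
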