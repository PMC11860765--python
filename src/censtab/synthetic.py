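"""Synthetic data generators with exact ground truth.

Every generator is a pure function of its spec (including the seed): the same
spec yields bit-identical output. Each generator returns, alongside the data,
a ground-truth structure containing every quantity a downstream estimator is
expected to recover (division indices, focus amplitudes, spot voxel sets,
pairwise overlap fractions, object counts), so the quantification pipeline is
fully testable without any raw microscopy or flow-cytometry data.

Models
------
* 2D fluorescence fields: disjoint circular nuclei on a dark field, each with
  punctate foci rendered as isotropic Gaussian bumps over a flat nuclear
  background, plus additive Gaussian noise clipped at zero.
* 3D stacks: ellipsoidal nuclei in an anisotropic voxel grid (default 15
  slices spanning 10.65 um axially, 0.1 um lateral pixels) with spherical
  foci per channel; pairwise focus overlaps can be engineered to a target
  volume fraction, realized by scanning the center offset and recording the
  achieved voxel-counted fraction as truth.
* Dye-dilution flow events: per division the proliferation dye halves, so
  generation g sits at undivided_mean * peak_ratio**g; peaks are normal in
  log-fluorescence with a common CV.
* HAC-reporter flow events: a live/dead mixture in the viability channel and
  a GFP+/GFP- mixture among live events.
* Colony plates: non-overlapping disks (and optionally a 1-px streak whose
  circularity is far below the particle filter) on an 8-bit field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PackingError",
    "ImageFieldSpec",
    "ChannelSpec",
    "EngineeredOverlap",
    "StackSpec",
    "DyeDilutionSpec",
    "HacFlowSpec",
    "make_exofish_field",
    "make_stack",
    "make_dye_dilution",
    "make_hac_flow",
    "make_colony_plate",
]


class PackingError(RuntimeError):
    """Requested objects cannot be placed disjointly in the field."""


# ---------------------------------------------------------------------------
# 2D exo-FISH / IF fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageFieldSpec:
    """Geometry and signal model of a synthetic 2D fluorescence field.

    ``foci_per_cell`` may be a fixed count or an inclusive ``(lo, hi)`` range
    sampled per cell. ``focus_amplitude`` is the peak height of each Gaussian
    focus above the nuclear background, in the same arbitrary units as
    ``background_level``; ``focus_sigma`` is its isotropic SD in pixels.
    """

    width: int = 512
    height: int = 512
    n_cells: int = 20
    foci_per_cell: int | tuple[int, int] = 6
    focus_amplitude: float = 800.0
    focus_sigma: float = 1.5
    background_level: float = 120.0
    noise_sd: float = 15.0
    nucleus_radius: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.focus_amplitude < 0:
            raise ValueError("focus_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")


def _place_centers(rng, n, shape, radius, min_sep, max_tries=20000):
    """Rejection-sample ``n`` centers at pairwise distance >= ``min_sep``."""
    h, w = shape
    if 2 * radius >= min(h, w):
        raise PackingError("object radius exceeds field size")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PackingError(
                f"could only place {len(centers)} of {n} objects "
                f"(radius {radius}) in a {h}x{w} field"
            )
        tries += 1
        r = rng.uniform(radius + 1, h - radius - 1)
        c = rng.uniform(radius + 1, w - radius - 1)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep**2 for rr, cc in centers):
            centers.append((r, c))
    return centers


def make_exofish_field(spec: ImageFieldSpec):
    """Render a 2D field of nuclei with Gaussian foci.

    Returns
    -------
    image : float ndarray (height, width)
        Background inside nuclei, zero outside, foci added, noise applied.
    labels : int ndarray
        Nucleus label mask (0 = outside, 1..n_cells).
    truth : pandas.DataFrame
        One row per focus: cell_id, focus_id, row, col, amplitude. Cells
        without foci still appear in ``truth.attrs['cells']``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    radius = spec.nucleus_radius
    centers = _place_centers(rng, spec.n_cells, (h, w), radius, 2 * radius + 4)

    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    image = np.zeros((h, w), dtype=np.float64)
    for i, (cr, cc) in enumerate(centers, start=1):
        inside = (yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2
        labels[inside] = i
    image[labels > 0] = spec.background_level

    rows = []
    for i, (cr, cc) in enumerate(centers, start=1):
        if isinstance(spec.foci_per_cell, tuple):
            lo, hi = spec.foci_per_cell
            n_foci = int(rng.integers(lo, hi + 1))
        else:
            n_foci = int(spec.foci_per_cell)
        # foci sit well inside the nucleus so their boxes avoid the rim
        for j in range(n_foci):
            ang = rng.uniform(0, 2 * np.pi)
            rad = radius * 0.55 * np.sqrt(rng.uniform())
            fr, fc = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
            amp = spec.focus_amplitude
            d2 = (yy - fr) ** 2 + (xx - fc) ** 2
            image += amp * np.exp(-d2 / (2 * spec.focus_sigma**2))
            rows.append((i, j, fr, fc, amp))

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
        np.clip(image, 0.0, None, out=image)

    truth = pd.DataFrame(
        rows, columns=["cell_id", "focus_id", "row", "col", "amplitude"]
    )
    truth.attrs["cells"] = {
        i: {"row": cr, "col": cc, "radius": radius}
        for i, (cr, cc) in enumerate(centers, start=1)
    }
    return image, labels, truth


# ---------------------------------------------------------------------------
# 3D stacks for volume-overlap colocalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """A focus channel in a synthetic stack.

    ``n_spots`` random (non-engineered) spherical foci of radius
    ``spot_radius_um`` and peak ``amplitude`` are placed per nucleus, well
    separated from each other and from any engineered pair.
    """

    name: str
    n_spots: int = 0
    spot_radius_um: float = 0.25
    amplitude: float = 1500.0


@dataclass(frozen=True)
class EngineeredOverlap:
    """A spot pair with a prescribed volume-overlap fraction.

    ``fraction`` is |A intersect B| / |A| where A is the ``channel_a`` spot;
    the generator offsets B's center until the voxel-counted fraction is as
    close as the grid permits, and records the achieved value in the truth.
    """

    channel_a: str
    channel_b: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("overlap fraction must be in [0, 1]")


# 15 optical sections spanning 10.65 um; 60x objective, 0.1 um lateral pixels
_DEFAULT_SHAPE_ZYX = (15, 256, 256)
_DEFAULT_VOXEL_ZYX = (10.65 / 15, 0.1, 0.1)


@dataclass(frozen=True)
class StackSpec:
    """Geometry and content of a synthetic multi-channel Z-stack."""

    shape_zyx: tuple[int, int, int] = _DEFAULT_SHAPE_ZYX
    voxel_size_zyx: tuple[float, float, float] = _DEFAULT_VOXEL_ZYX
    n_nuclei: int = 3
    nucleus_radius_um: float = 4.0
    nucleus_z_radius_um: float = 2.5
    channels: tuple[ChannelSpec, ...] = ()
    engineered_overlaps: tuple[EngineeredOverlap, ...] = ()
    dna_channel: str = "dna"
    nucleus_intensity: float = 1000.0
    background_level: float = 100.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape_zyx):
            raise ValueError("stack shape must be positive")
        if any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError("voxel sizes must be positive")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        for ov in self.engineered_overlaps:
            if ov.channel_a not in names or ov.channel_b not in names:
                raise ValueError("engineered overlap references unknown channel")


def _ball_offsets(radius_um, voxel_zyx):
    """Voxel offsets (relative to a center voxel) covered by a sphere."""
    rz = max(1, int(np.ceil(radius_um / voxel_zyx[0])))
    ry = max(1, int(np.ceil(radius_um / voxel_zyx[1])))
    rx = max(1, int(np.ceil(radius_um / voxel_zyx[2])))
    zz, yy, xx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    d2 = (
        (zz * voxel_zyx[0]) ** 2
        + (yy * voxel_zyx[1]) ** 2
        + (xx * voxel_zyx[2]) ** 2
    )
    inside = d2 <= radius_um**2
    return np.column_stack([zz[inside], yy[inside], xx[inside]])


def _voxel_set(center, offsets, shape):
    vox = offsets + np.asarray(center, dtype=int)
    ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
    return vox[ok]


def _overlap_fraction_sets(a: np.ndarray, b: np.ndarray) -> float:
    """|a intersect b| / |a| for (N,3) integer voxel coordinate arrays."""
    if len(a) == 0:
        return 0.0
    sa = {tuple(v) for v in a}
    sb = {tuple(v) for v in b}
    return len(sa & sb) / len(sa)


def _solve_overlap_offset(offsets_a, offsets_b, target, voxel_zyx):
    """Find a lateral center offset of B realizing ~``target`` overlap of A.

    Scans the x-offset in whole voxels (overlap of digitized balls is a step
    function of the shift) and returns (offset_vox, achieved_fraction) for
    the closest achievable fraction.
    """
    if target >= 1.0:
        f = _overlap_fraction_sets(offsets_a, offsets_b)
        return np.array([0, 0, 0]), f
    max_dx = int(offsets_a[:, 2].max() - offsets_b[:, 2].min()) + 2
    best = (np.array([0, 0, max_dx]), 0.0)
    best_err = abs(target - 0.0)
    for dx in range(0, max_dx + 1):
        shifted = offsets_b + np.array([0, 0, dx])
        f = _overlap_fraction_sets(offsets_a, shifted)
        err = abs(f - target)
        if err < best_err:
            best = (np.array([0, 0, dx]), f)
            best_err = err
    if target > 0 and best[1] == 0.0:
        raise PackingError(
            f"no lateral shift of the partner spot realizes overlap ~{target}"
        )
    return best


def _paint_sphere(volume, center, radius_um, amplitude, voxel_zyx):
    """Add a spherical focus with a logistic edge profile.

    Intensity is ~``amplitude`` in the core, amplitude/2 exactly at the
    nominal radius, and decays quickly outside, so threshold-based spot
    segmentation recovers approximately the true ball.
    """
    shape = volume.shape
    rz = int(np.ceil(1.8 * radius_um / voxel_zyx[0])) + 1
    ry = int(np.ceil(1.8 * radius_um / voxel_zyx[1])) + 1
    rx = int(np.ceil(1.8 * radius_um / voxel_zyx[2])) + 1
    cz, cy, cx = center
    z0, z1 = max(0, cz - rz), min(shape[0], cz + rz + 1)
    y0, y1 = max(0, cy - ry), min(shape[1], cy + ry + 1)
    x0, x1 = max(0, cx - rx), min(shape[2], cx + rx + 1)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    d = np.sqrt(
        ((zz - cz) * voxel_zyx[0]) ** 2
        + ((yy - cy) * voxel_zyx[1]) ** 2
        + ((xx - cx) * voxel_zyx[2]) ** 2
    )
    edge = max(0.12 * radius_um, 0.02)
    volume[z0:z1, y0:y1, x0:x1] += amplitude / (1.0 + np.exp((d - radius_um) / edge))


@dataclass
class StackTruth:
    """Ground truth for a synthetic stack."""

    nucleus_labels: np.ndarray
    nucleus_centers: dict[int, tuple[int, int, int]]
    # spots[channel][spot_id] -> (N,3) voxel coordinate array
    spots: dict[str, dict[int, np.ndarray]]
    spot_nucleus: dict[str, dict[int, int]]
    # achieved engineered overlaps: (channel_a, spot_a, channel_b, spot_b, fraction)
    overlaps: list[tuple[str, int, str, int, float]] = field(default_factory=list)


def make_stack(spec: StackSpec):
    """Render a multi-channel 3D stack with engineered focus overlaps.

    Returns
    -------
    channels : dict[str, float ndarray (Z, Y, X)]
        Includes the DNA channel plus every focus channel.
    truth : StackTruth
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape_zyx
    vz = spec.voxel_size_zyx
    ry_vox = spec.nucleus_radius_um / vz[1]

    centers2d = _place_centers(
        rng, spec.n_nuclei, shape[1:], ry_vox, 2 * ry_vox + 6
    )
    zc = shape[0] // 2

    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nucleus_centers = {}
    for i, (cy, cx) in enumerate(centers2d, start=1):
        d2 = (
            ((zz - zc) * vz[0] / spec.nucleus_z_radius_um) ** 2
            + ((yy - cy) * vz[1] / spec.nucleus_radius_um) ** 2
            + ((xx - cx) * vz[2] / spec.nucleus_radius_um) ** 2
        )
        nucleus_labels[d2 <= 1.0] = i
        nucleus_centers[i] = (zc, int(round(cy)), int(round(cx)))

    channels: dict[str, np.ndarray] = {}
    dna = np.full(shape, spec.background_level, dtype=np.float64)
    dna[nucleus_labels > 0] = spec.nucleus_intensity
    channels[spec.dna_channel] = dna

    for ch in spec.channels:
        channels[ch.name] = np.full(shape, spec.background_level, dtype=np.float64)

    chan_by_name = {c.name: c for c in spec.channels}
    truth = StackTruth(
        nucleus_labels=nucleus_labels,
        nucleus_centers=nucleus_centers,
        spots={c.name: {} for c in spec.channels},
        spot_nucleus={c.name: {} for c in spec.channels},
    )
    next_id = {c.name: 1 for c in spec.channels}
    occupied: list[tuple[np.ndarray, float]] = []  # (center_vox, radius_um)

    def _min_sep_ok(center, radius_um):
        for oc, orad in occupied:
            d = np.sqrt(
                (((center - oc) * np.asarray(vz)) ** 2).sum()
            )
            if d < 2.0 * (radius_um + orad):
                return False
        return True

    def _random_spot_center(nucleus_id, radius_um, max_tries=400):
        cz0, cy0, cx0 = nucleus_centers[nucleus_id]
        for _ in range(max_tries):
            dy = rng.uniform(-0.55, 0.55) * spec.nucleus_radius_um / vz[1]
            dx = rng.uniform(-0.55, 0.55) * spec.nucleus_radius_um / vz[2]
            dz = rng.uniform(-0.45, 0.45) * spec.nucleus_z_radius_um / vz[0]
            cand = np.array(
                [int(round(cz0 + dz)), int(round(cy0 + dy)), int(round(cx0 + dx))]
            )
            if _min_sep_ok(cand, radius_um):
                return cand
        raise PackingError("could not place spot inside nucleus")

    def _add_spot(channel, center, nucleus_id):
        ch = chan_by_name[channel]
        offs = _ball_offsets(ch.spot_radius_um, vz)
        vox = _voxel_set(center, offs, shape)
        sid = next_id[channel]
        next_id[channel] += 1
        truth.spots[channel][sid] = vox
        truth.spot_nucleus[channel][sid] = nucleus_id
        _paint_sphere(channels[channel], center, ch.spot_radius_um, ch.amplitude, vz)
        occupied.append((np.asarray(center), ch.spot_radius_um))
        return sid, vox

    # engineered overlap pairs first, one nucleus each (round-robin)
    for k, ov in enumerate(spec.engineered_overlaps):
        nid = (k % spec.n_nuclei) + 1
        ch_a, ch_b = chan_by_name[ov.channel_a], chan_by_name[ov.channel_b]
        offs_a = _ball_offsets(ch_a.spot_radius_um, vz)
        offs_b = _ball_offsets(ch_b.spot_radius_um, vz)
        sep = 2.0 * (ch_a.spot_radius_um + ch_b.spot_radius_um)
        center_a = _random_spot_center(nid, ch_a.spot_radius_um + sep)
        shift, achieved = _solve_overlap_offset(offs_a, offs_b, ov.fraction, vz)
        center_b = center_a + shift
        sid_a, vox_a = _add_spot(ov.channel_a, center_a, nid)
        # partner occupies an overlapping position by construction
        offs = _ball_offsets(ch_b.spot_radius_um, vz)
        vox_b = _voxel_set(center_b, offs, shape)
        sid_b = next_id[ov.channel_b]
        next_id[ov.channel_b] += 1
        truth.spots[ov.channel_b][sid_b] = vox_b
        truth.spot_nucleus[ov.channel_b][sid_b] = nid
        _paint_sphere(
            channels[ov.channel_b], center_b, ch_b.spot_radius_um, ch_b.amplitude, vz
        )
        occupied.append((np.asarray(center_b), ch_b.spot_radius_um))
        realized = _overlap_fraction_sets(vox_a, vox_b)
        truth.overlaps.append((ov.channel_a, sid_a, ov.channel_b, sid_b, realized))

    # then the random, well-separated spots
    for ch in spec.channels:
        for nid in range(1, spec.n_nuclei + 1):
            for _ in range(ch.n_spots):
                center = _random_spot_center(nid, ch.spot_radius_um)
                _add_spot(ch.name, center, nid)

    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = channels[name] + rng.normal(
                0.0, spec.noise_sd, size=shape
            )
            np.clip(channels[name], 0.0, None, out=channels[name])

    return channels, truth


# ---------------------------------------------------------------------------
# Flow cytometry event tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DyeDilutionSpec:
    """A halving-peak proliferation-dye experiment.

    Each division halves the dye per cell (``peak_ratio`` = 0.5), so an event
    of generation g is drawn from a log-normal peak at
    ``undivided_mean * peak_ratio**g`` with coefficient of variation ``cv``.
    ``generation_weights[g]`` is the probability that an *event* (a cell in
    the analyzed population) belongs to generation g.
    """

    n_events: int = 10_000
    undivided_mean: float = 50_000.0
    cv: float = 0.10
    peak_ratio: float = 0.5
    generation_weights: tuple[float, ...] = (1.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.generation_weights, dtype=float)
        if w.size == 0:
            raise ValueError("generation_weights must be nonempty")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("generation_weights must be >= 0 and sum to 1")
        if not 0.0 < self.peak_ratio < 1.0:
            raise ValueError("peak_ratio must be in (0, 1)")
        if self.cv <= 0:
            raise ValueError("cv must be positive")

    @classmethod
    def from_division_index(
        cls,
        division_index: float,
        definition: str = "precursor_weighted",
        n_generations: int = 7,
        **kwargs,
    ) -> "DyeDilutionSpec":
        """Construct event weights whose true DI equals ``division_index``.

        Mass is split between the two adjacent generations bracketing the
        target so the chosen DI definition is satisfied exactly.
        """
        if division_index < 0 or division_index > n_generations - 1:
            raise ValueError("division_index outside representable range")
        a = int(np.floor(division_index))
        q = division_index - a
        w = np.zeros(n_generations, dtype=float)
        if definition == "event_weighted":
            w[a] = 1.0 - q
            if q > 0:
                w[a + 1] = q
        elif definition == "precursor_weighted":
            # precursor proportions (1-q, q) on generations (a, a+1); event
            # weights are precursor proportions times 2**g, renormalized
            wa = (1.0 - q) * 2.0**a
            wb = q * 2.0 ** (a + 1)
            w[a] = wa / (wa + wb)
            if q > 0:
                w[a + 1] = wb / (wa + wb)
        else:
            raise ValueError(f"unknown DI definition: {definition!r}")
        return cls(generation_weights=tuple(w), **kwargs)


def _true_division_indices(weights: np.ndarray) -> dict[str, float]:
    g = np.arange(len(weights), dtype=float)
    event = float((g * weights).sum())
    prec = weights / 2.0**g
    precursor = float((g * prec).sum() / prec.sum())
    return {"event_weighted": event, "precursor_weighted": precursor}


def make_dye_dilution(spec: DyeDilutionSpec):
    """Draw a proliferation-dye event table.

    Returns
    -------
    events : pandas.DataFrame with column 'proliferation_dye'
    truth : dict with keys 'di_precursor_weighted', 'di_event_weighted',
        'generations' (per-event labels), 'weights'.
    """
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.generation_weights, dtype=float)
    gens = rng.choice(len(w), size=spec.n_events, p=w)
    sigma_ln = np.sqrt(np.log1p(spec.cv**2))
    mu = np.log(spec.undivided_mean) + gens * np.log(spec.peak_ratio)
    intensity = np.exp(mu + rng.normal(0.0, sigma_ln, size=spec.n_events))
    events = pd.DataFrame({"proliferation_dye": intensity})
    di = _true_division_indices(w)
    truth = {
        "di_precursor_weighted": di["precursor_weighted"],
        "di_event_weighted": di["event_weighted"],
        "generations": gens,
        "weights": w,
    }
    return events, truth


@dataclass(frozen=True)
class HacFlowSpec:
    """A GFP-reporter viability-stained flow experiment.

    Live events carry low viability-dye signal; among them a fraction
    ``gfp_positive_fraction`` carries the bright GFP reporter. Intensities
    are log-normal around the stated channel means.
    """

    n_events: int = 50_000
    gfp_positive_fraction: float = 0.8
    dead_fraction: float = 0.05
    gfp_negative_mean: float = 50.0
    gfp_positive_mean: float = 5_000.0
    live_viability_mean: float = 100.0
    dead_viability_mean: float = 10_000.0
    cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.gfp_positive_fraction, self.dead_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


def make_hac_flow(spec: HacFlowSpec):
    """Draw a live/dead x GFP+/- event table.

    Returns the table (columns 'gfp', 'viability_dye') and a truth dict with
    the exact realized GFP+ fraction among live events and the hidden labels.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    dead = rng.random(n) < spec.dead_fraction
    gfp_pos = (rng.random(n) < spec.gfp_positive_fraction) & ~dead
    sigma = np.sqrt(np.log1p(spec.cv**2))

    def _draw(mean, size):
        return np.exp(np.log(mean) + rng.normal(0.0, sigma, size=size))

    viability = np.where(
        dead, _draw(spec.dead_viability_mean, n), _draw(spec.live_viability_mean, n)
    )
    gfp = np.where(
        gfp_pos, _draw(spec.gfp_positive_mean, n), _draw(spec.gfp_negative_mean, n)
    )
    events = pd.DataFrame({"gfp": gfp, "viability_dye": viability})
    n_live = int((~dead).sum())
    realized = float(gfp_pos.sum() / n_live) if n_live else float("nan")
    truth = {
        "realized_gfp_positive_fraction": realized,
        "dead": dead,
        "gfp_positive": gfp_pos,
        "n_live": n_live,
    }
    return events, truth


# ---------------------------------------------------------------------------
# Colony plates
# ---------------------------------------------------------------------------

def make_colony_plate(
    shape: tuple[int, int] = (512, 512),
    n_disks: int = 10,
    disk_radius: float = 12.0,
    thin_streak_length: int | None = None,
    foreground: int = 255,
    seed: int = 0,
):
    """Render an 8-bit plate of non-overlapping disks, optionally a streak.

    The streak is a 1-px-high horizontal line: a scratch-like artifact whose
    circularity 4*pi*A/P^2 is far below the particle filter's lower bound.

    Returns the uint8 image and a truth dict with 'n_disks', per-disk centers,
    and (if present) the streak's circularity computed from the rasterized
    object with the same traced-outline perimeter estimator the counter uses.
    """
    from .focus import boundary_perimeter
    rng = np.random.default_rng(seed)
    h, w = shape
    centers = _place_centers(rng, n_disks, (h, w), disk_radius, 2 * disk_radius + 4)
    image = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    for cr, cc in centers:
        image[(yy - cr) ** 2 + (xx - cc) ** 2 <= disk_radius**2] = foreground

    truth = {"n_disks": n_disks, "centers": centers, "streak": None}
    if thin_streak_length is not None:
        if thin_streak_length > w - 4:
            raise PackingError("streak longer than the plate")
        # find a clear row
        for _ in range(2000):
            r = int(rng.integers(1, h - 1))
            c0 = int(rng.integers(1, w - 1 - thin_streak_length))
            band = image[max(0, r - 2) : r + 3, max(0, c0 - 2) : c0 + thin_streak_length + 2]
            if band.max() == 0:
                break
        else:
            raise PackingError("could not place streak on the plate")
        image[r, c0 : c0 + thin_streak_length] = foreground
        streak_mask = np.zeros((3, thin_streak_length + 2), dtype=bool)
        streak_mask[1, 1:-1] = True
        p = boundary_perimeter(streak_mask)
        area = float(thin_streak_length)
        truth["streak"] = {
            "row": r,
            "col_start": c0,
            "length": thin_streak_length,
            "area": area,
            "perimeter": float(p),
            "circularity": float(4 * np.pi * area / p**2) if p > 0 else float("inf"),
        }
    return image, truth
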