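"""Cone outer-segment segmentation and low-resolution density maps.

Pipeline per channel: robust normalization -> suppression of small bright
features -> intensity-peak seeding -> per-seed active-contour segmentation
with validation -> cross-channel reconciliation into a cell table.
Low-resolution tiles are instead summarized by a binned density map of
S-only / M-only / co-expressing pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation as sks

from .imagetile import CHANNEL_INDEX, ImageTile
from .tables import CellTable

__all__ = [
    "Contour",
    "DensityMap",
    "normalize_channel",
    "suppress_small_features",
    "find_seed_peaks",
    "segment_from_seed",
    "reconcile_channels",
    "segment_tile",
    "density_map",
    "marginal_profile",
]


# ---------------------------------------------------------------------------
# preprocessing


def normalize_channel(tile: ImageTile, channel: str, p_low: float = 1.0, p_high: float = 99.5) -> ImageTile:
    """Rescale one channel to [0, 1] by a percentile stretch (monotone).

    A constant channel has no dynamic range: it is set to zeros and the
    tile metadata gains a ``degenerate_<channel>`` flag.
    """
    out = ImageTile(tile.pixels.copy(), tile.pixel_size_um, tile.orientation, dict(tile.metadata))
    img = out.pixels[CHANNEL_INDEX[channel]]
    lo, hi = np.percentile(img, [p_low, p_high])
    if hi - lo < 1e-12:
        out.pixels[CHANNEL_INDEX[channel]] = 0.0
        out.metadata[f"degenerate_{channel}"] = True
        return out
    out.pixels[CHANNEL_INDEX[channel]] = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    return out


def suppress_small_features(tile: ImageTile, channel: str, max_feature_px: int) -> ImageTile:
    """Attenuate bright features smaller than the given scale.

    Grayscale opening by reconstruction with a disk of radius
    ``max_feature_px``: features that cannot contain the disk are flattened
    to their surroundings while larger structures keep their intensity.
    """
    if max_feature_px < 1:
        raise ValueError("max_feature_px must be >= 1")
    out = ImageTile(tile.pixels.copy(), tile.pixel_size_um, tile.orientation, dict(tile.metadata))
    img = out.pixels[CHANNEL_INDEX[channel]].astype(np.float64)
    eroded = morphology.erosion(img, morphology.disk(max_feature_px))
    opened = morphology.reconstruction(eroded, img, method="dilation")
    out.pixels[CHANNEL_INDEX[channel]] = opened.astype(np.float32)
    return out


def find_seed_peaks(
    tile: ImageTile,
    channel: str,
    min_separation_px: int,
    min_prominence: float,
) -> np.ndarray:
    """Local intensity maxima as segmentation seeds.

    Returns an array of (row, col) pixel coordinates in deterministic
    row-major order; peaks closer than ``min_separation_px`` keep only the
    brighter one.
    """
    if min_separation_px <= 0 or min_prominence <= 0:
        raise ValueError("parameters must be > 0")
    from skimage.feature import peak_local_max

    img = tile.pixels[CHANNEL_INDEX[channel]]
    peaks = peak_local_max(
        img,
        min_distance=int(min_separation_px),
        threshold_abs=float(min_prominence),
        exclude_border=False,
    )
    if peaks.size == 0:
        return peaks.reshape(0, 2)
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    return peaks[order]


# ---------------------------------------------------------------------------
# active-contour segmentation


@dataclass
class Contour:
    vertices: np.ndarray  # closed polygon, (k, 2) array of (row, col)
    mask: np.ndarray  # boolean mask in full-tile coordinates
    area_px: float
    centroid: tuple[float, float]  # (row, col)
    source_channel: str
    mean_interior: dict = field(default_factory=dict)  # per channel


@dataclass
class Rejection:
    reason: str
    seed: tuple[int, int]


def _background_stats(img: np.ndarray) -> tuple[float, float]:
    # pixels below the median are overwhelmingly background
    bg = img[img <= np.percentile(img, 60)]
    return float(bg.mean()), float(bg.std() + 1e-12)


def segment_from_seed(
    tile: ImageTile,
    channel: str,
    seed_point: tuple[int, int],
    init_radius_um: float = 3.0,
    n_iter: int = 200,
    area_bounds_um2: tuple[float, float] = (5.0, 80.0),
    min_solidity: float = 0.8,
    bg_sigma_margin: float = 3.0,
    window_um: float = 12.0,
) -> Contour | Rejection:
    """Morphological active-contour segmentation from one seed.

    A circular level set at the seed evolves by morphological Chan-Vese on a
    local window. Validation: area within bounds, solidity above threshold,
    mean interior intensity above background by ``bg_sigma_margin`` SD, and
    no contact with the tile border (truncated outer segments are rejected).
    """
    img = tile.pixels[CHANNEL_INDEX[channel]].astype(np.float64)
    r, c = int(seed_point[0]), int(seed_point[1])
    h, w = img.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError("seed outside image")
    half = max(int(round(window_um / tile.pixel_size_um)), 3)
    r0, r1 = max(r - half, 0), min(r + half + 1, h)
    c0, c1 = max(c - half, 0), min(c + half + 1, w)
    crop = img[r0:r1, c0:c1]

    bg_mean, bg_sd = _background_stats(img)
    if img[r, c] < bg_mean + bg_sigma_margin * bg_sd:
        return Rejection("low_intensity_seed", (r, c))

    init = np.zeros_like(crop, dtype=np.int8)
    rad = max(init_radius_um / tile.pixel_size_um, 1.5)
    rr, cc = np.ogrid[: crop.shape[0], : crop.shape[1]]
    init[(rr - (r - r0)) ** 2 + (cc - (c - c0)) ** 2 <= rad**2] = 1
    ls = sks.morphological_chan_vese(crop, num_iter=n_iter, init_level_set=init, smoothing=1)

    lab, _ = ndimage.label(ls)
    seed_lab = lab[r - r0, c - c0]
    if seed_lab == 0:
        return Rejection("contour_lost_seed", (r, c))
    mask_crop = lab == seed_lab
    # refine the region to the half-maximum level of the seed peak: the
    # outer-segment boundary convention used for area measurements
    half_level = bg_mean + 0.5 * (img[r, c] - bg_mean)
    refined = mask_crop & (crop >= half_level)
    lab2, _ = ndimage.label(refined)
    if lab2[r - r0, c - c0] > 0:
        mask_crop = lab2 == lab2[r - r0, c - c0]

    # escape / border contact in full-image coordinates
    full = np.zeros(img.shape, dtype=bool)
    full[r0:r1, c0:c1] = mask_crop
    if full[0, :].any() or full[-1, :].any() or full[:, 0].any() or full[:, -1].any():
        return Rejection("touches_border", (r, c))
    if mask_crop[0, :].any() or mask_crop[-1, :].any() or mask_crop[:, 0].any() or mask_crop[:, -1].any():
        # region ran into the local window edge: treat as an escaped contour
        return Rejection("escaped_window", (r, c))

    area_px = float(mask_crop.sum())
    px_area = tile.pixel_size_um**2
    a_lo, a_hi = area_bounds_um2
    if not (a_lo <= area_px * px_area <= a_hi):
        return Rejection("area_out_of_bounds", (r, c))

    props = measure.regionprops(mask_crop.astype(np.uint8))[0]
    if props.solidity < min_solidity:
        return Rejection("low_solidity", (r, c))
    if img[full].mean() < bg_mean + bg_sigma_margin * bg_sd:
        return Rejection("low_interior_intensity", (r, c))

    contours = measure.find_contours(full.astype(float), 0.5)
    vertices = max(contours, key=len) if contours else np.empty((0, 2))
    cy, cx = ndimage.center_of_mass(full)
    mean_interior = {
        ch: float(tile.pixels[CHANNEL_INDEX[ch]][full].mean()) for ch in ("S", "M")
    }
    return Contour(vertices, full, area_px, (float(cy), float(cx)), channel, mean_interior)


def reconcile_channels(
    tile: ImageTile,
    contours_s: list[Contour],
    contours_m: list[Contour],
    iou_threshold: float = 0.3,
) -> CellTable:
    """Merge per-channel contours into one cell list.

    Contour pairs with intersection-over-union at or above the threshold
    become a single co-detected cell (union mask); unmatched contours
    become single-channel cells. Intensities are mean interior values per
    channel; centroids are converted to micrometres (row -> y, col -> x).
    """
    used_m = np.zeros(len(contours_m), dtype=bool)
    cells = []
    for cs in contours_s:
        best_iou, best_j = 0.0, -1
        for j, cm in enumerate(contours_m):
            if used_m[j]:
                continue
            inter = np.logical_and(cs.mask, cm.mask).sum()
            if inter == 0:
                continue
            union = np.logical_or(cs.mask, cm.mask).sum()
            iou = inter / union
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            used_m[best_j] = True
            mask = np.logical_or(cs.mask, contours_m[best_j].mask)
        else:
            mask = cs.mask
        cells.append(mask)
    cells.extend(cm.mask for j, cm in enumerate(contours_m) if not used_m[j])

    px = tile.pixel_size_um
    rows = []
    for i, mask in enumerate(cells):
        cy, cx = ndimage.center_of_mass(mask)
        rows.append(
            dict(
                cell_id=i,
                x_um=cx * px,
                y_um=cy * px,
                area_um2=float(mask.sum()) * px * px,
                s_intensity=float(tile.pixels[0][mask].mean()),
                m_intensity=float(tile.pixels[1][mask].mean()),
                class_label="NONE",
                fate_truth="UNKNOWN",
            )
        )
    import pandas as pd

    from .tables import CSV_COLUMNS

    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    meta = {
        "source": "experimental",
        "pixel_size_um": px,
        "strip_length_um": tile.shape[0] * px,
        "strip_width_um": tile.shape[1] * px,
    }
    return CellTable(df, meta)


def segment_tile(
    tile: ImageTile,
    min_separation_um: float = 6.0,
    min_prominence: float = 0.05,
    cell_radius_um: float = 2.5,
    iou_threshold: float = 0.3,
    **contour_kwargs,
) -> CellTable:
    """Full two-channel segmentation pipeline on a raw tile.

    Normalization and small-feature suppression feed peak seeding; every
    seed gets an independent active-contour segmentation; accepted contours
    are reconciled across channels. Intensities reported per cell are the
    mean raw (un-normalized) interior intensities. Deterministic: no
    randomness anywhere in the pipeline.
    """
    open_radius = max(int(round(cell_radius_um / 3.0 / tile.pixel_size_um)), 1)
    contours: dict[str, list[Contour]] = {}
    for ch in ("S", "M"):
        norm = normalize_channel(tile, ch)
        if norm.metadata.get(f"degenerate_{ch}"):
            contours[ch] = []
            continue
        filt = suppress_small_features(norm, ch, open_radius)
        peaks = find_seed_peaks(filt, ch, int(round(min_separation_um / tile.pixel_size_um)), min_prominence)
        accepted = []
        for seed in peaks:
            res = segment_from_seed(filt, ch, tuple(seed), **contour_kwargs)
            if isinstance(res, Contour):
                accepted.append(res)
        contours[ch] = accepted
    # report raw intensities measured on the original tile
    for ch_list in contours.values():
        for c in ch_list:
            c.mean_interior = {
                ch: float(tile.pixels[CHANNEL_INDEX[ch]][c.mask].mean()) for ch in ("S", "M")
            }
    return reconcile_channels(tile, contours["S"], contours["M"], iou_threshold)


# ---------------------------------------------------------------------------
# density maps


@dataclass
class DensityMap:
    """Binned relative densities of expressing pixels.

    Per bin: fraction of expressing pixels with S-only signal, M-only
    signal, or both; fractions sum to 1 in non-empty bins. Bin grid is
    anchored at the image origin (row 0, col 0).
    """

    d_sonly: np.ndarray
    d_monly: np.ndarray
    d_both: np.ndarray
    empty: np.ndarray
    bin_px: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.d_sonly.shape


def density_map(
    tile: ImageTile,
    bin_px: int = 25,
    signal_thresholds: tuple[float, float] | None = None,
) -> DensityMap:
    """Subdivide the tile into ``bin_px`` x ``bin_px`` blocks and compute the
    relative density of S-only, M-only and co-expressing pixels per block.

    Thresholds default to background mean + 3 SD per channel. Each non-empty
    block is normalized by its expressing-pixel count; blocks with no
    expressing pixel are flagged empty.
    """
    if bin_px < 1:
        raise ValueError("bin_px must be >= 1")
    s_img = tile.pixels[0]
    m_img = tile.pixels[1]
    if signal_thresholds is None:
        thr = []
        for img in (s_img, m_img):
            mu, sd = _background_stats(img)
            thr.append(mu + 3.0 * sd)
        signal_thresholds = (thr[0], thr[1])
    s_sig = s_img > signal_thresholds[0]
    m_sig = m_img > signal_thresholds[1]

    h, w = s_img.shape
    nr, nc = int(np.ceil(h / bin_px)), int(np.ceil(w / bin_px))

    def block_sum(arr):
        out = np.zeros((nr, nc))
        padded = np.zeros((nr * bin_px, nc * bin_px))
        padded[:h, :w] = arr
        return padded.reshape(nr, bin_px, nc, bin_px).sum(axis=(1, 3))

    n_sonly = block_sum(s_sig & ~m_sig)
    n_monly = block_sum(m_sig & ~s_sig)
    n_both = block_sum(s_sig & m_sig)
    total = n_sonly + n_monly + n_both
    empty = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(empty, 1.0, total)
        return DensityMap(n_sonly / denom, n_monly / denom, n_both / denom, empty, bin_px)


def marginal_profile(dmap: DensityMap, axis: str = "dv") -> dict[str, np.ndarray]:
    """Average binned densities over non-empty bins per row (D-V) or column (T-N)."""
    ax = 1 if axis == "dv" else 0
    valid = ~dmap.empty
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        n = valid.sum(axis=ax)
        for name, grid in (("sonly", dmap.d_sonly), ("monly", dmap.d_monly), ("both", dmap.d_both)):
            s = np.where(valid, grid, 0.0).sum(axis=ax)
            out[name] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    out["n_bins"] = n
    return out
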