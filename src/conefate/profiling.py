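"""Cell classification, D-V profiles, Hill-transition fitting and clustering.

Operates identically on experimental-style, synthetic and simulated cell
tables. The central quantitative tool is the 4-parameter Hill fit

    increasing:  f(y) = base + amplitude * y^n / (midpoint^n + y^n)
    decreasing:  f(y) = base + amplitude * midpoint^n / (midpoint^n + y^n)

whose exponent ``n`` quantifies the steepness of an expression transition
along the dorsal-ventral axis: the S-opsin expressing fraction switches with
n ~ 30, the M-opsin fraction with n ~ 2-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.cluster import HDBSCAN

from .tables import CellTable

#: default "signal present" intensity threshold (arbitrary units); roughly
#: background mean + 3 SD for the default synthetic background model
DEFAULT_INTENSITY_THRESHOLD = 10.0

#: lower bound of the S-only expression band, used by the threshold fallback
#: that separates S-only from CEC cones when no ground truth is available
S_ONLY_LOWER_BOUND = 160.0


# ---------------------------------------------------------------------------
# classification


def classify_cells(table: CellTable, tau_s: float = DEFAULT_INTENSITY_THRESHOLD,
                   tau_m: float = DEFAULT_INTENSITY_THRESHOLD) -> CellTable:
    """Assign class labels from the two intensity thresholds.

    (s > tau_s, m > tau_m) maps to S_ONLY / M_ONLY / COEXPRESSING / NONE.
    """
    if tau_s < 0 or tau_m < 0:
        raise ValueError("thresholds must be >= 0")
    out = table.copy()
    s = out.data["s_intensity"].to_numpy() > tau_s
    m = out.data["m_intensity"].to_numpy() > tau_m
    label = np.full(len(out.data), "NONE", dtype=object)
    label[s & ~m] = "S_ONLY"
    label[~s & m] = "M_ONLY"
    label[s & m] = "COEXPRESSING"
    out.data["class_label"] = label
    return out


def expressing_s(df: pd.DataFrame) -> np.ndarray:
    """Predicate: cell expresses S-opsin (by class label)."""
    return df["class_label"].isin(["S_ONLY", "COEXPRESSING"]).to_numpy()


def expressing_m(df: pd.DataFrame) -> np.ndarray:
    """Predicate: cell expresses M-opsin (by class label)."""
    return df["class_label"].isin(["M_ONLY", "COEXPRESSING"]).to_numpy()


def is_cec(df: pd.DataFrame) -> np.ndarray:
    """Predicate: cell is co-expression competent.

    Uses ground truth where present (synthetic/simulated tables); otherwise
    falls back to the intensity heuristic: expresses M, or expresses S below
    the S-only band.
    """
    fate = df["fate_truth"].to_numpy()
    if (fate != "UNKNOWN").any():
        return fate == "CEC"
    s = df["s_intensity"].to_numpy()
    m = df["m_intensity"].to_numpy()
    return (m > DEFAULT_INTENSITY_THRESHOLD) | (
        (s > DEFAULT_INTENSITY_THRESHOLD) & (s < S_ONLY_LOWER_BOUND)
    )


# ---------------------------------------------------------------------------
# profiles


@dataclass
class DensityProfile:
    """Per-bin expressing fraction (or density) along the D-V axis."""

    bin_centers_um: np.ndarray
    fraction: np.ndarray
    n_cells: np.ndarray
    bin_width_um: float
    empty: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.empty is None:
            self.empty = self.n_cells == 0

    @property
    def valid(self) -> np.ndarray:
        return ~self.empty


def fraction_profile(
    table: CellTable,
    class_predicate: Callable[[pd.DataFrame], np.ndarray],
    bin_width_um: float = 100.0,
    y_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Fraction of cells satisfying the predicate per D-V bin.

    Bins with zero cells are flagged empty and excluded from downstream fits.
    """
    df = table.data
    y = df["y_um"].to_numpy()
    if y_range is None:
        lo = 0.0 if table.strip_length_um is not None and not table.metadata.get("aligned") else float(y.min())
        hi = float(table.strip_length_um) if table.strip_length_um is not None and not table.metadata.get("aligned") else float(y.max())
    else:
        lo, hi = y_range
    n_bins = max(int(np.ceil((hi - lo) / bin_width_um)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width_um
    idx = np.clip(np.digitize(y, edges) - 1, 0, n_bins - 1)
    hit = np.asarray(class_predicate(df), dtype=bool)
    n_cells = np.bincount(idx, minlength=n_bins)
    n_hit = np.bincount(idx[hit], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_cells > 0, n_hit / np.maximum(n_cells, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, frac, n_cells, bin_width_um)


# ---------------------------------------------------------------------------
# Hill fitting


@dataclass
class HillFit:
    base: float
    amplitude: float
    midpoint_um: float
    n: float
    direction: str  # "increasing" | "decreasing"
    rss: float
    converged: bool
    degenerate: bool = False

    def predict(self, y) -> np.ndarray:
        return hill_curve(y, self.base, self.amplitude, self.midpoint_um, self.n, self.direction)

    def derivative(self, y) -> np.ndarray:
        """Analytic df/dy (per um)."""
        y = np.asarray(y, dtype=float)
        k, n = self.midpoint_um, self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            num = self.amplitude * n * k**n * np.where(y > 0, y ** (n - 1), 0.0)
            d = num / (k**n + np.where(y > 0, y**n, 0.0)) ** 2
        return d if self.direction == "increasing" else -d


def hill_curve(y, base, amplitude, midpoint, n, direction="increasing"):
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        frac = np.where(y > 0, 1.0 / (1.0 + (midpoint / np.maximum(y, 1e-300)) ** n), 0.0)
    if direction == "decreasing":
        frac = 1.0 - frac
    return base + amplitude * frac


def fit_hill(
    profile: DensityProfile | tuple[Sequence[float], Sequence[float]],
    direction: str | None = None,
    n_starts: Sequence[float] = (1.0, 5.0, 20.0, 50.0),
    n_bounds: tuple[float, float] = (0.3, 150.0),
) -> HillFit:
    """Nonlinear least-squares Hill fit over (base, amplitude, midpoint, n).

    Direction is auto-detected from the end means unless given. Multi-start
    over the Hill exponent guards against the sharp-transition local minima.
    A profile whose dynamic range is negligible is returned flagged
    degenerate with an unreliable exponent.
    """
    if isinstance(profile, DensityProfile):
        x = profile.bin_centers_um[profile.valid]
        v = profile.fraction[profile.valid]
    else:
        x = np.asarray(profile[0], dtype=float)
        v = np.asarray(profile[1], dtype=float)
        keep = np.isfinite(v)
        x, v = x[keep], v[keep]
    if x.size < 6:
        raise ValueError("need at least 6 non-empty bins to fit a Hill transition")
    order = np.argsort(x)
    x, v = x[order], v[order]

    k = max(x.size // 5, 2)
    lo_mean, hi_mean = float(np.mean(v[:k])), float(np.mean(v[-k:]))
    if direction is None:
        direction = "increasing" if hi_mean >= lo_mean else "decreasing"

    rng_v = float(np.max(v) - np.min(v))
    scale = max(abs(np.max(v)), abs(np.min(v)), 1e-12)
    degenerate = rng_v < 0.05 * scale or rng_v < 1e-12
    if degenerate:
        return HillFit(float(np.mean(v)), 0.0, float(np.median(x)), 1.0, direction, float(np.sum((v - np.mean(v)) ** 2)), False, True)

    base0 = min(lo_mean, hi_mean)
    amp0 = max(rng_v, 1e-9)
    half = base0 + amp0 / 2.0
    # first crossing of the half-maximum as midpoint guess
    vv = v if direction == "increasing" else v[::-1]
    xx = x if direction == "increasing" else x[::-1]
    above = vv >= half
    mid0 = float(xx[np.argmax(above)]) if above.any() and not above.all() else float(np.median(x))
    mid0 = min(max(mid0, x[0] + 1e-6), x[-1] - 1e-6)

    x_lo, x_hi = float(x[0]), float(x[-1])
    bounds = (
        [min(np.min(v), 0.0) - 0.1 * scale, 0.0, max(x_lo, 1e-6), n_bounds[0]],
        [np.max(v) + 0.1 * scale, 2.0 * (np.max(v) - min(np.min(v), 0.0)) + 1e-9, x_hi, n_bounds[1]],
    )

    def f(y, base, amp, mid, n):
        return hill_curve(y, base, amp, mid, n, direction)

    best = None
    for n0 in n_starts:
        p0 = [base0, amp0, mid0, float(np.clip(n0, *n_bounds))]
        try:
            popt, _ = curve_fit(f, x, v, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((f(x, *popt) - v) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return HillFit(base0, amp0, mid0, 1.0, direction, float("inf"), False, False)
    popt, rss = best
    return HillFit(float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]), direction, rss, True, False)


def transition_midpoint(fit: HillFit) -> float:
    """Position of the half-maximal change of a converged, non-degenerate fit."""
    if fit.degenerate or not fit.converged:
        raise ValueError("midpoint undefined for a degenerate or non-converged fit")
    return fit.midpoint_um


def fit_s_fraction(table: CellTable, bin_width_um: float = 100.0,
                   tau_s: float = DEFAULT_INTENSITY_THRESHOLD,
                   tau_m: float = DEFAULT_INTENSITY_THRESHOLD) -> HillFit:
    """Classify, profile and fit the S-expressing fraction transition."""
    classified = classify_cells(table, tau_s, tau_m)
    prof = fraction_profile(classified, expressing_s, bin_width_um)
    return fit_hill(prof, direction="increasing")


def fit_m_fraction(table: CellTable, bin_width_um: float = 100.0,
                   tau_s: float = DEFAULT_INTENSITY_THRESHOLD,
                   tau_m: float = DEFAULT_INTENSITY_THRESHOLD) -> HillFit:
    """Classify, profile and fit the M-expressing fraction transition."""
    classified = classify_cells(table, tau_s, tau_m)
    prof = fraction_profile(classified, expressing_m, bin_width_um)
    return fit_hill(prof, direction="decreasing")


# ---------------------------------------------------------------------------
# alignment


def align_tables(tables: Sequence[CellTable], bin_width_um: float = 100.0) -> list[CellTable]:
    """Shift each table's y so its fitted S-fraction midpoint maps to 0.

    The applied shift is recorded in the table metadata (``y_shift_um``).
    """
    out = []
    for t in tables:
        fit = fit_s_fraction(t, bin_width_um)
        mid = transition_midpoint(fit)
        shifted = t.copy()
        shifted.metadata["aligned"] = True
        shifted.metadata["y_shift_um"] = -mid
        shifted.data["y_um"] = shifted.data["y_um"] - mid
        out.append(shifted)
    return out


# ---------------------------------------------------------------------------
# joint / per-position distributions


@dataclass
class Joint2D:
    s_edges: np.ndarray
    m_edges: np.ndarray
    log10_p: np.ndarray  # masked (nan) where empty
    probability: np.ndarray
    dv_window_um: tuple[float, float] | None


def joint_distribution(
    table: CellTable,
    dv_window_um: tuple[float, float] | None = None,
    n_bins: int = 50,
) -> Joint2D:
    """Normalized joint histogram of (S, M) intensity in a D-V window."""
    df = table.data
    if dv_window_um is not None:
        lo, hi = dv_window_um
        df = df[(df["y_um"] >= lo) & (df["y_um"] < hi)]
    if len(df) == 0:
        raise ValueError("no cells in the requested D-V window")
    s = df["s_intensity"].to_numpy()
    m = df["m_intensity"].to_numpy()
    h, s_edges, m_edges = np.histogram2d(s, m, bins=n_bins)
    p = h / h.sum()
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log10(np.maximum(p, 1e-300)), np.nan)
    return Joint2D(s_edges, m_edges, logp, p, dv_window_um)


def intensity_dv_distribution(
    table: CellTable,
    class_predicate: Callable[[pd.DataFrame], np.ndarray] | None = None,
    dv_bin_um: float = 250.0,
    intensity_bins: int = 50,
    channel: str = "s",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-D-V-bin normalized intensity histogram.

    Returns (dv_bin_centers, intensity_bin_edges, matrix) where each row of
    the matrix sums to 1 over occupied D-V bins. Supports detecting per-bin
    bimodality (the two "lines of density": S-only high vs CEC low).
    """
    df = table.data
    if class_predicate is not None:
        df = df[np.asarray(class_predicate(df), dtype=bool)]
    y = df["y_um"].to_numpy()
    v = df[f"{channel}_intensity"].to_numpy()
    lo = 0.0 if not table.metadata.get("aligned") else float(y.min())
    hi = float(table.strip_length_um) if table.strip_length_um and not table.metadata.get("aligned") else float(y.max())
    n_dv = max(int(np.ceil((hi - lo) / dv_bin_um)), 1)
    dv_edges = lo + np.arange(n_dv + 1) * dv_bin_um
    i_edges = np.histogram_bin_edges(v, bins=intensity_bins)
    mat = np.zeros((n_dv, intensity_bins))
    idx = np.clip(np.digitize(y, dv_edges) - 1, 0, n_dv - 1)
    for b in range(n_dv):
        vals = v[idx == b]
        if vals.size:
            h, _ = np.histogram(vals, bins=i_edges)
            mat[b] = h / h.sum()
    centers = 0.5 * (dv_edges[:-1] + dv_edges[1:])
    return centers, i_edges, mat


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    labels: np.ndarray  # -1 = noise
    n_clusters: int
    min_cluster_size: int


def cluster_cells(table: CellTable, min_cluster_size: int | None = None) -> ClusterResult:
    """Density-based hierarchical clustering of (S, M) intensity pairs.

    Only cells expressing at least one opsin take part (cones expressing
    neither are undetectable in immunofluorescence); non-expressing cells
    get the noise label. Default minimum cluster size is 1% of the clustered
    cells. On the full default synthetic strip this separates the S-only
    manifold from the CEC manifold into exactly two clusters.
    """
    df = table.data
    if (df["class_label"] == "NONE").all():
        df = classify_cells(table).data
    keep = (df["class_label"] != "NONE").to_numpy()
    xy = df.loc[keep, ["s_intensity", "m_intensity"]].to_numpy()
    if min_cluster_size is None:
        min_cluster_size = max(int(round(0.01 * len(xy))), 5)
    if len(xy) < 2 * min_cluster_size:
        raise ValueError("too few cells for the requested min_cluster_size")
    sub_labels = HDBSCAN(min_cluster_size=min_cluster_size, allow_single_cluster=True, copy=True).fit_predict(xy)
    labels = np.full(len(df), -1, dtype=int)
    labels[keep] = sub_labels
    n_clusters = int(len(set(sub_labels[sub_labels >= 0])))
    return ClusterResult(labels, n_clusters, min_cluster_size)


# ---------------------------------------------------------------------------
# transition statistics


@dataclass
class TransitionStats:
    s_midpoint_um: float
    cec_fraction_at_midpoint: float
    cec_slope_at_midpoint: float  # fraction per um (negative: CEC declines)
    s_fit: HillFit = None  # type: ignore[assignment]
    cec_fit: HillFit = None  # type: ignore[assignment]


def transition_stats(table: CellTable, bin_width_um: float = 100.0,
                     tau_s: float = DEFAULT_INTENSITY_THRESHOLD,
                     tau_m: float = DEFAULT_INTENSITY_THRESHOLD) -> TransitionStats:
    """CEC fraction and its slope evaluated at the S-opsin transition midpoint.

    The S-expressing fraction is fitted to locate the midpoint; the CEC
    fraction among all cells is fitted with the decreasing Hill family and
    differentiated analytically at that midpoint.
    """
    s_fit = fit_s_fraction(table, bin_width_um, tau_s, tau_m)
    mid = transition_midpoint(s_fit)
    prof = fraction_profile(table, is_cec, bin_width_um)
    if np.nanstd(prof.fraction[prof.valid]) < 1e-12:
        # position-independent CEC fraction: flat curve, zero slope
        frac = float(np.nanmean(prof.fraction[prof.valid]))
        flat = HillFit(frac, 0.0, mid, 1.0, "decreasing", 0.0, True, True)
        return TransitionStats(mid, frac, 0.0, s_fit, flat)
    cec_fit = fit_hill(prof, direction="decreasing")
    frac = float(cec_fit.predict(mid))
    slope = float(cec_fit.derivative(mid))
    return TransitionStats(mid, frac, slope, s_fit, cec_fit)
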