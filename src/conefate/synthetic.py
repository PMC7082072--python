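"""Synthetic retina generator.

Produces ground-truth cell tables (and rendered two-channel image tiles)
with the statistical structure observed in adult mouse retinas:

* two cone subtypes — S-only cones with high, position-independent S-opsin
  (about 1% of cones dorsally, rising gradually to 20-30% ventrally) and
  co-expression-competent (CEC) cones;
* among CEC cones, the fraction expressing S-opsin switches on very sharply
  along the dorsal-ventral axis (Hill coefficient ~30) while the fraction
  expressing M-opsin declines gradually (Hill coefficient ~2-3);
* graded intensity means (M decreasing dorsal-to-ventral, S increasing
  roughly linearly ventral of the transition) with multiplicative
  log-normal noise;
* quasi-regular hexagonal cell packing.

All position-dependent probabilities are exposed as deterministic
interpolants so tests can compare sampled counts against exact binomial
expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .imagetile import ImageTile
from .tables import CellTable


@dataclass
class GeneratorParams:
    """Parameters of the synthetic retina; defaults encode the mean retina.

    Lengths are micrometres, intensities arbitrary units. ``y`` runs
    dorsal (0) to ventral (``strip_length_um``).
    """

    strip_length_um: float = 6000.0
    strip_width_um: float = 800.0
    mean_cell_spacing_um: float = 15.0
    jitter_frac: float = 0.15  # positional jitter, fraction of spacing

    # S-expressing fraction of CEC cones: sharp increasing Hill transition
    s_transition_midpoint_um: float = 3000.0
    s_fraction_hill_n: float = 30.0

    # M intensity decline of CEC cones (gradual; the M-expressing fraction
    # emerges from thresholding this graded mean with broad cell-to-cell
    # variability and declines with an effective Hill coefficient ~2-3)
    m_intensity_midpoint_um: float = 830.0
    m_intensity_hill_n: float = 2.0

    # S-only subtype probability: mild increasing Hill interpolant
    s_only_frac_dorsal: float = 0.01
    s_only_frac_ventral: float = 0.25
    s_only_midpoint_um: float = 3100.0
    s_only_hill_n: float = 5.0
    # optional dorsal enhancement of the S-only expression level (1 = off)
    s_only_dorsal_boost: float = 1.0

    # intensity model (arbitrary units)
    s_only_level: float = 250.0
    cec_m_max: float = 160.0
    cec_s_max: float = 100.0
    noise_cv: float = 0.25  # S channel (and area) multiplicative CV
    m_noise_cv: float = 1.3  # M channel: broad cell-to-cell variability
    background_level: float = 5.0
    expressing_threshold: float = 10.0  # intensity above which a channel counts as expressed

    mean_area_um2: float = 20.0
    area_cv: float = 0.2

    seed: int = 0

    def validate(self) -> None:
        if min(self.strip_length_um, self.strip_width_um, self.mean_cell_spacing_um) <= 0:
            raise ValueError("lengths must be positive")
        if self.mean_cell_spacing_um >= min(self.strip_length_um, self.strip_width_um):
            raise ValueError("cell spacing must be smaller than the strip dimensions")
        for name in ("s_only_frac_dorsal", "s_only_frac_ventral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("s_fraction_hill_n", "m_intensity_hill_n", "s_only_hill_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0 or self.m_noise_cv < 0:
            raise ValueError("noise CVs must be >= 0")


def _hill_increasing(y, midpoint, n):
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(y > 0, y**n / (midpoint**n + y**n), 0.0)
    return out


def s_only_probability(params: GeneratorParams, y) -> np.ndarray:
    """Probability that a cone at position ``y`` is an S-only cone.

    Monotone Hill-type interpolant normalized to hit the dorsal/ventral
    endpoint fractions exactly at y = 0 and y = strip length.
    """
    g = _hill_increasing(y, params.s_only_midpoint_um, params.s_only_hill_n)
    g_end = _hill_increasing(params.strip_length_um, params.s_only_midpoint_um, params.s_only_hill_n)
    return params.s_only_frac_dorsal + (params.s_only_frac_ventral - params.s_only_frac_dorsal) * g / g_end


def _sigma_log(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def total_s_expressing_fraction(params: GeneratorParams, y) -> np.ndarray:
    """Target fraction of ALL cones expressing S-opsin at ``y``.

    ``s_fraction_hill_n`` parameterizes this curve directly — the quantity
    the expressing-fraction Hill fit measures — with the floor set by the
    always-expressing S-only cones.
    """
    target = _hill_increasing(y, params.s_transition_midpoint_um, params.s_fraction_hill_n)
    return np.maximum(target, s_only_probability(params, y))


def cec_s_expressing_fraction(params: GeneratorParams, y) -> np.ndarray:
    """Target fraction of CEC cones whose S intensity exceeds the
    expressing threshold at ``y``.

    Derived from the total-fraction target by removing the S-only
    contribution, so that the observable S-expressing fraction follows the
    configured sharp Hill transition.
    """
    p = s_only_probability(params, y)
    target = total_s_expressing_fraction(params, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (target - p) / np.maximum(1.0 - p, 1e-12)
    return np.clip(f, 0.0, 1.0)


def cec_s_mean_intensity(params: GeneratorParams, y) -> np.ndarray:
    """Mean S intensity of CEC cones: continuous along the D-V axis.

    Built by inverting the log-normal threshold relation so that
    P(S > expressing_threshold) at each position equals the target CEC
    expressing fraction: near zero (background) dorsally, switching on
    sharply at the transition, then ramping up roughly linearly to
    ``cec_s_max`` at the ventral edge. Continuity (no on/off jump) matches
    the joint-intensity manifold seen in real retinas.
    """
    y = np.asarray(y, dtype=float)
    sigma = _sigma_log(params.noise_cv)
    tau = params.expressing_threshold
    f = cec_s_expressing_fraction(params, y)
    from scipy.special import ndtri

    z = np.clip(ndtri(np.clip(f, 1e-12, 1.0 - 1e-12)), -6.0, 3.0)
    onset = tau * np.exp(0.5 * sigma * sigma + sigma * z)
    # once the switch has saturated (F ~ 0.999), grow linearly to the
    # ventral maximum without perturbing the transition shape
    s_sat = tau * np.exp(0.5 * sigma * sigma + 3.0 * sigma)
    y_sat = params.s_transition_midpoint_um * (0.999 / 0.001) ** (1.0 / params.s_fraction_hill_n)
    span = max(params.strip_length_um - y_sat, 1e-9)
    ramp = 1.0 + (max(params.cec_s_max / s_sat, 1.0) - 1.0) * np.clip((y - y_sat) / span, 0.0, 1.0)
    return np.maximum(onset * ramp, params.background_level)


def cec_m_mean_intensity(params: GeneratorParams, y) -> np.ndarray:
    """Mean M intensity of CEC cones: high dorsally, declining gradually
    toward background ventrally (unnormalized decreasing Hill shape)."""
    y = np.asarray(y, dtype=float)
    k, n = params.m_intensity_midpoint_um, params.m_intensity_hill_n
    decline = 1.0 / (1.0 + (y / k) ** n)
    return params.background_level + (params.cec_m_max - params.background_level) * decline


def _lognormal_exceed(mean, cv, tau) -> np.ndarray:
    """P(X > tau) for log-normal X with the given mean and CV."""
    from scipy.special import ndtr

    sigma = _sigma_log(cv)
    mean = np.asarray(mean, dtype=float)
    if sigma == 0:
        return (mean > tau).astype(float)
    return ndtr((np.log(np.maximum(mean, 1e-300)) - 0.5 * sigma**2 - np.log(tau)) / sigma)


def cec_m_expressing_fraction(params: GeneratorParams, y) -> np.ndarray:
    """Exact fraction of CEC cones whose M intensity exceeds the threshold.

    Declines gradually dorsal to ventral (effective Hill coefficient ~2-3):
    the graded mean decline is smeared by the broad cell-to-cell M
    variability.
    """
    return _lognormal_exceed(cec_m_mean_intensity(params, y), params.m_noise_cv, params.expressing_threshold)


def implied_s_expressing_fraction(params: GeneratorParams, y) -> np.ndarray:
    """Exact fraction of ALL cones whose S intensity exceeds the threshold,
    computed from the realized intensity model (oracle for classified
    counts; equals the Hill target up to clipping/flooring)."""
    p = s_only_probability(params, y)
    f_cec = _lognormal_exceed(cec_s_mean_intensity(params, y), params.noise_cv, params.expressing_threshold)
    f_sonly = _lognormal_exceed(s_only_mean_intensity(params, y), params.noise_cv, params.expressing_threshold)
    return p * f_sonly + (1.0 - p) * f_cec


def s_only_mean_intensity(params: GeneratorParams, y) -> np.ndarray:
    """Mean S intensity of S-only cones (position-independent by default)."""
    y = np.asarray(y, dtype=float)
    if params.s_only_dorsal_boost == 1.0:
        return np.full(y.shape, params.s_only_level)
    frac = 1.0 - y / params.strip_length_um  # 1 dorsal -> 0 ventral
    return params.s_only_level * (1.0 + (params.s_only_dorsal_boost - 1.0) * frac)


def hex_positions(length_um, width_um, spacing_um, jitter_frac, rng) -> tuple[np.ndarray, np.ndarray]:
    """Jittered hexagonal packing filling the strip; returns (x, y) in um."""
    pitch = spacing_um * np.sqrt(3.0) / 2.0
    n_rows = max(int(width_um / pitch), 1)
    n_cols = max(int(length_um / spacing_um), 1)
    xs, ys = [], []
    for i in range(n_rows):
        offset = 0.25 if i % 2 == 0 else 0.75
        y = (np.arange(n_cols) + offset) * spacing_um
        x = np.full(n_cols, (i + 0.5) * pitch)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if jitter_frac > 0:
        x = x + rng.uniform(-jitter_frac, jitter_frac, x.size) * spacing_um
        y = y + rng.uniform(-jitter_frac, jitter_frac, y.size) * spacing_um
    x = np.clip(x, 0.0, width_um)
    y = np.clip(y, 0.0, length_um)
    return x, y


def _lognormal(rng, mean, cv):
    """Multiplicative log-normal noise with the given mean and CV."""
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return mean.copy()
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = np.log(np.maximum(mean, 1e-300)) - 0.5 * sigma * sigma
    return np.exp(rng.normal(mu, sigma))


def generate_cell_table(params: GeneratorParams) -> CellTable:
    """Sample a ground-truth synthetic retina as a :class:`CellTable`.

    Cells sit on a jittered hexagonal lattice; each is S-only with
    probability :func:`s_only_probability`, otherwise CEC. CEC cells draw
    independent Bernoulli expression of S and M from the two Hill fraction
    curves and intensities from the graded means with log-normal noise.
    ``fate_truth`` records the subtype; ``class_label`` is left for the
    profiling stage.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    x, y = hex_positions(
        params.strip_length_um, params.strip_width_um, params.mean_cell_spacing_um, params.jitter_frac, rng
    )
    n = x.size
    p_sonly = s_only_probability(params, y)
    is_sonly = rng.random(n) < p_sonly

    s_mean = np.empty(n)
    m_mean = np.empty(n)
    # S-only cones: high constitutive S, background-level M
    s_mean[is_sonly] = s_only_mean_intensity(params, y[is_sonly])
    m_mean[is_sonly] = params.background_level
    # CEC cones: continuous graded means along the D-V axis
    cec = ~is_sonly
    s_mean[cec] = cec_s_mean_intensity(params, y[cec])
    m_mean[cec] = cec_m_mean_intensity(params, y[cec])

    s_int = _lognormal(rng, s_mean, params.noise_cv)
    m_int = _lognormal(rng, m_mean, params.m_noise_cv)
    area = _lognormal(rng, np.full(n, params.mean_area_um2), params.area_cv)
    fate = np.where(is_sonly, "S_ONLY", "CEC")

    metadata = {
        "source": "synthetic",
        "strip_length_um": params.strip_length_um,
        "strip_width_um": params.strip_width_um,
        "axis": "y_um dorsal(0) -> ventral",
        "seed": int(params.seed),
    }
    return CellTable.from_arrays(x, y, s_int, m_int, area, None, fate, metadata)


def sample_retina_params(mean: GeneratorParams, sd: GeneratorParams, seed: int) -> GeneratorParams:
    """Draw a random retina: each parameter with nonzero sd is sampled from a
    normal distribution, resampled into its validity range.

    Emulates retina-to-retina variability around the mean retina. Fields
    whose sd is 0 are returned unchanged.
    """
    rng = np.random.default_rng(seed)
    out = {}
    fraction_fields = {"s_only_frac_dorsal", "s_only_frac_ventral", "m_fraction_dorsal", "m_fraction_ventral"}
    for f in fields(GeneratorParams):
        mu = getattr(mean, f.name)
        if f.name == "seed" or not isinstance(mu, float):
            out[f.name] = mu
            continue
        s = float(getattr(sd, f.name))
        if s < 0:
            raise ValueError(f"sd for {f.name} must be >= 0")
        if s == 0:
            out[f.name] = mu
            continue
        lo, hi = (0.0, 1.0) if f.name in fraction_fields else (1e-12, np.inf)
        val = rng.normal(mu, s)
        for _ in range(1000):
            if lo <= val <= hi:
                break
            val = rng.normal(mu, s)
        out[f.name] = float(np.clip(val, lo, hi))
    sampled = replace(GeneratorParams(), **out)
    sampled.validate()
    return sampled


def zero_sd_params() -> GeneratorParams:
    """All-zero sd template for :func:`sample_retina_params`."""
    p = GeneratorParams()
    for f in fields(GeneratorParams):
        if isinstance(getattr(p, f.name), float):
            setattr(p, f.name, 0.0)
    return p


def render_tiles(
    table: CellTable,
    pixel_size_um: float = 1.0,
    psf_sigma_um: float = 1.5,
    background_level: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    express_threshold: float | None = None,
) -> ImageTile:
    """Render a cell table as a two-channel image tile.

    Each cell whose channel intensity exceeds ``express_threshold``
    (default: 2x background) is drawn as an isotropic Gaussian blob with
    peak amplitude equal to its intensity; additive Gaussian noise and a
    constant background are applied. Planted ground truth (positions and
    intensities) is kept in the tile metadata.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if express_threshold is None:
        express_threshold = 2.0 * background_level
    length = table.metadata.get("strip_length_um", float(table.data["y_um"].max()) + 3 * psf_sigma_um if len(table) else 10.0)
    width = table.metadata.get("strip_width_um", float(table.data["x_um"].max()) + 3 * psf_sigma_um if len(table) else 10.0)
    h = int(np.ceil(length / pixel_size_um))
    w = int(np.ceil(width / pixel_size_um))
    img = np.zeros((2, h, w), dtype=np.float64)
    sigma_px = psf_sigma_um / pixel_size_um
    half = max(int(np.ceil(4 * sigma_px)), 2)

    rows = table.data["y_um"].to_numpy() / pixel_size_um
    cols = table.data["x_um"].to_numpy() / pixel_size_um
    intens = {0: table.data["s_intensity"].to_numpy(), 1: table.data["m_intensity"].to_numpy()}
    for ch in (0, 1):
        amp = intens[ch]
        for r0, c0, a in zip(rows, cols, amp):
            if a <= express_threshold:
                continue
            ri, ci = int(round(r0)), int(round(c0))
            r_lo, r_hi = max(ri - half, 0), min(ri + half + 1, h)
            c_lo, c_hi = max(ci - half, 0), min(ci + half + 1, w)
            if r_lo >= r_hi or c_lo >= c_hi:
                continue
            rr = np.arange(r_lo, r_hi)[:, None] - r0
            cc = np.arange(c_lo, c_hi)[None, :] - c0
            img[ch, r_lo:r_hi, c_lo:c_hi] += a * np.exp(-(rr**2 + cc**2) / (2 * sigma_px**2))

    rng = np.random.default_rng(seed)
    img += background_level
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, None)

    metadata = {
        "planted_x_um": table.data["x_um"].tolist(),
        "planted_y_um": table.data["y_um"].tolist(),
        "planted_s": table.data["s_intensity"].tolist(),
        "planted_m": table.data["m_intensity"].tolist(),
        "background_level": background_level,
        "noise_sd": noise_sd,
        "psf_sigma_um": psf_sigma_um,
        "express_threshold": express_threshold,
    }
    return ImageTile(img.astype(np.float32), pixel_size_um, "dv_rows", metadata)
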