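"""Configuration of the hybrid T3-diffusion / per-cell stochastic model.

Units: lengths in micrometres, time in simulation time units (t.u.),
concentrations in relative units (dorsal boundary = 1). Molecule counts are
integers per cell. The shipped defaults are the calibrated mean-retina
parameterization (see scripts/calibrate_defaults.py for the recipe):

* a linear dorsal->ventral T3 gradient maintained by constant-concentration
  boundaries,
* receptor binding chosen so active Thrbeta2 spans ~40 copies dorsally to
  ~0 ventrally out of 200 receptors,
* a fate race between U->S (Hill-repressed by active Thrbeta2) and U->C
  giving ~1% S-only cones dorsally and ~25% ventrally,
* opsin production/degradation giving mean S-only S-opsin counts of
  beta_S_high/phi = 200.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml


@dataclass
class SimConfig:
    # geometry (um)
    domain_length_um: float = 5000.0
    domain_width_um: float = 1000.0
    domain_depth_um: float = 5.0
    hex_spacing_um: float = 5000.0 / 330.0
    hex_row_pitch_um: float = 1000.0 / 72.0

    # T3 field
    pde_grid_spacing_um: float = 50.0
    D_T3: float = 100.0  # um^2 per t.u.
    c_dorsal: float = 1.0
    c_ventral: float = 0.0
    molecules_per_um3: float = 10.0  # voxel molecules per unit relative conc

    # cell <-> microenvironment exchange
    k_exchange_in: float = 400.0  # molecules per t.u. per unit local conc
    k_exchange_out: float = 4.0  # per molecule per t.u.

    # T3-Thrbeta2 binding
    k_on: float = 0.025
    k_off: float = 10.0
    thrb2_total: int = 200

    # fate decision (U -> S repressed by active Thrbeta2; U -> C constant)
    k_fateS_max: float = 2.0 / 3.0
    K_fate: float = 17.0
    h_fate: float = 5.0
    k_fateC: float = 2.0

    # opsin expression
    beta_S_high: float = 200.0  # constitutive S production in S-only cones
    beta_M: float = 120.0
    K_M: float = 100.0
    h_M: float = 1.0
    beta_S_cec: float = 150.0
    K_Srep: float = 12.0
    h_Srep: float = 16.0
    phi: float = 1.0  # opsin degradation

    # start cells at their local exchange/binding equilibrium (the adult
    # gradient is maintained, not developed; same principle as the field)
    init_equilibrium: bool = True

    # time stepping
    dt_macro: float = 0.05
    t_end: float = 8.0

    intensity_scale: float = 1.0  # arbitrary intensity units per molecule
    knockout_thrb2: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "D_T3", "k_exchange_in", "k_exchange_out", "k_on", "k_off",
            "k_fateS_max", "k_fateC", "beta_S_high", "beta_M", "beta_S_cec", "phi",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("h_fate", "h_M", "h_Srep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.c_dorsal < 0 or self.c_ventral < 0:
            raise ValueError("boundary concentrations must be >= 0")
        if self.thrb2_total < 0:
            raise ValueError("thrb2_total must be >= 0")
        h = self.pde_grid_spacing_um
        if self.D_T3 > 0 and self.dt_macro > h * h / (4.0 * self.D_T3):
            raise ValueError(
                "dt_macro violates the explicit-scheme stability bound h^2/(4 D)"
            )
        if min(self.domain_length_um, self.domain_width_um, self.domain_depth_um) <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.hex_spacing_um >= min(self.domain_length_um, self.domain_width_um):
            raise ValueError("hex spacing must be smaller than the domain")

    def __post_init__(self) -> None:
        self.validate()

    def with_knockout(self) -> "SimConfig":
        return replace(self, k_on=0.0, knockout_thrb2=True)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=False) if path.suffix in (".yml", ".yaml") else json.dumps(self.to_dict(), indent=1)
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)


def knockout_thrb2(config: SimConfig) -> SimConfig:
    """Receptor knockout: Thrbeta2 can never be activated (k_on = 0).

    Consequently the U->S fate reaction runs at its maximal rate everywhere,
    M-opsin production is zero, and CEC S-opsin production sits at its
    repression-free level — the simulated counterpart of the
    Thrbeta2-null retina.
    """
    return config.with_knockout()


def mean_field_summary(config: SimConfig, y: np.ndarray) -> dict[str, np.ndarray]:
    """Deterministic mean-field expectations along the D-V axis.

    Used for sanity checks and as the starting point of calibration:
    local relative T3 concentration (linear ramp), mean free-T3 copies,
    mean active receptors, and the resulting mean-field S-only probability.
    """
    y = np.asarray(y, dtype=float)
    c = config.c_dorsal + (config.c_ventral - config.c_dorsal) * y / config.domain_length_um
    t3_mean = config.k_exchange_in * c / config.k_exchange_out
    theta = config.k_on * t3_mean / (config.k_on * t3_mean + config.k_off) if config.k_off > 0 else np.ones_like(c)
    a_mean = config.thrb2_total * theta
    with np.errstate(divide="ignore"):
        repression = 1.0 / (1.0 + (a_mean / config.K_fate) ** config.h_fate)
    r_s = config.k_fateS_max * repression
    p_sonly = r_s / (r_s + config.k_fateC)
    return {"c": c, "t3_mean": t3_mean, "active_mean": a_mean, "p_sonly": p_sonly}
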