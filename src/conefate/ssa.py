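"""Per-cell stochastic reaction network and its Gillespie sampler.

Each cone runs an independent chemical-master-equation network with nine
reactions (A = active Thrbeta2, R = inactive Thrbeta2, counts per cell):

  1. T3 + R -> A                 k_on * T3 * R
  2. A -> R + T3                 k_off * A
  3. U -> S (fate)               k_fateS_max * K_fate^h / (K_fate^h + A^h)
  4. U -> C (fate)               k_fateC
  5. 0 -> S_opsin   [fate S]     beta_S_high              (constitutive)
  6. 0 -> M_opsin   [fate C]     beta_M * A^hM / (K_M^hM + A^hM)
  7. 0 -> S_opsin   [fate C]     beta_S_cec * (R/R_tot) * K_S^hS/(K_S^hS+A^hS)
  8. S_opsin -> 0                phi * S_opsin
  9. M_opsin -> 0                phi * M_opsin

Fate transitions are irreversible and first-event-wins. The local T3
concentration couples in only through the exchange step (see
:mod:`conefate.field`), so the SSA runs with a frozen microenvironment
between macro steps.

Two samplers are provided: a readable single-cell python implementation
(:func:`gillespie_advance`) used in tests against closed-form oracles, and a
numba batch kernel (:func:`advance_cells`) used by the full simulation. The
batch kernel derives one counter-based random stream per (seed, cell, macro
step), making ensembles reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .simconfig import SimConfig

N_REACTIONS = 9
FATE_U, FATE_S, FATE_C = 0, 1, 2
FATE_NAMES = {FATE_U: "UNKNOWN", FATE_S: "S_ONLY", FATE_C: "CEC"}


@dataclass
class CellState:
    fate: int = FATE_U
    t3_free: int = 0
    thrb2_inactive: int = 0
    thrb2_active: int = 0
    s_opsin: int = 0
    m_opsin: int = 0

    def check(self, thrb2_total: int) -> None:
        if min(self.t3_free, self.thrb2_inactive, self.thrb2_active, self.s_opsin, self.m_opsin) < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.thrb2_inactive + self.thrb2_active != thrb2_total:
            raise ValueError("receptor conservation violated")


def _hill_repress(a: float, k: float, h: float) -> float:
    return k**h / (k**h + a**h) if a > 0 else 1.0

def _hill_activate(a: float, k: float, h: float) -> float:
    return a**h / (k**h + a**h) if a > 0 else 0.0


def propensities(state: CellState, c_local: float, config: SimConfig) -> np.ndarray:
    """Reaction-rate vector for the nine per-cell reactions.

    ``c_local`` is accepted for interface completeness; the microenvironment
    enters only through the exchange step, not these propensities.
    """
    a = np.zeros(N_REACTIONS)
    A = float(state.thrb2_active)
    a[0] = config.k_on * state.t3_free * state.thrb2_inactive
    a[1] = config.k_off * A
    if state.fate == FATE_U:
        a[2] = config.k_fateS_max * _hill_repress(A, config.K_fate, config.h_fate)
        a[3] = config.k_fateC
    elif state.fate == FATE_S:
        a[4] = config.beta_S_high
    else:  # FATE_C
        a[5] = config.beta_M * _hill_activate(A, config.K_M, config.h_M)
        if config.thrb2_total > 0:
            a[6] = (
                config.beta_S_cec
                * (state.thrb2_inactive / config.thrb2_total)
                * _hill_repress(A, config.K_Srep, config.h_Srep)
            )
    a[7] = config.phi * state.s_opsin
    a[8] = config.phi * state.m_opsin
    return a


def _apply(state: CellState, reaction: int) -> None:
    if reaction == 0:
        state.t3_free -= 1
        state.thrb2_inactive -= 1
        state.thrb2_active += 1
    elif reaction == 1:
        state.thrb2_active -= 1
        state.thrb2_inactive += 1
        state.t3_free += 1
    elif reaction == 2:
        state.fate = FATE_S
    elif reaction == 3:
        state.fate = FATE_C
    elif reaction in (4, 6):
        state.s_opsin += 1
    elif reaction == 5:
        state.m_opsin += 1
    elif reaction == 7:
        state.s_opsin -= 1
    elif reaction == 8:
        state.m_opsin -= 1


def gillespie_advance(
    state: CellState,
    c_local: float,
    duration: float,
    config: SimConfig,
    rng: np.random.Generator,
    record_times: np.ndarray | None = None,
    record: list | None = None,
) -> CellState:
    """Exact SSA (direct method) over ``duration`` with frozen microenvironment.

    Optionally records the state at the given times (for stationary
    statistics). Mutates and returns ``state``.
    """
    t = 0.0
    rec_i = 0
    while True:
        a = propensities(state, c_local, config)
        a0 = float(a.sum())
        if a0 <= 0.0:
            break
        tau = rng.exponential(1.0 / a0)
        if t + tau > duration:
            break
        t += tau
        r = rng.random() * a0
        cum = np.cumsum(a)
        reaction = int(np.searchsorted(cum, r, side="right"))
        if record_times is not None:
            while rec_i < len(record_times) and record_times[rec_i] < t:
                record.append((state.thrb2_active, state.s_opsin, state.m_opsin))
                rec_i += 1
        _apply(state, reaction)
        state.check(config.thrb2_total)
    if record_times is not None:
        while rec_i < len(record_times):
            record.append((state.thrb2_active, state.s_opsin, state.m_opsin))
            rec_i += 1
    return state


# ---------------------------------------------------------------------------
# numba batch kernel

# parameter packing order for the kernel
PARAM_NAMES = (
    "k_on", "k_off", "k_fateS_max", "K_fate", "h_fate", "k_fateC",
    "beta_S_high", "beta_M", "K_M", "h_M", "beta_S_cec", "K_Srep", "h_Srep",
    "phi", "thrb2_total",
)


def pack_params(config: SimConfig) -> np.ndarray:
    return np.array([float(getattr(config, n)) for n in PARAM_NAMES], dtype=np.float64)


@njit(cache=True, inline="always")
def _splitmix64(s):
    s = (s + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = s
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return s, z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _uniform(s):
    s, z = _splitmix64(s)
    return s, (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def advance_cells(fate, t3, rin, ract, sop, mop, duration, params, seed, step_index):
    """Advance every cell's SSA by ``duration`` (in place).

    One counter-based stream per (seed, cell, step): deterministic and
    independent of cell processing order.
    """
    (k_on, k_off, k_fs, K_f, h_f, k_fc, b_sh, b_m, K_m, h_m, b_sc, K_s, h_s,
     phi, r_tot) = (params[0], params[1], params[2], params[3], params[4],
                    params[5], params[6], params[7], params[8], params[9],
                    params[10], params[11], params[12], params[13], params[14])
    Kf_h = K_f ** h_f
    Km_h = K_m ** h_m
    Ks_h = K_s ** h_s
    n = fate.size
    for i in range(n):
        s = (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
             ^ np.uint64(i) * np.uint64(0xD1B54A32D192ED03)
             ^ np.uint64(step_index) * np.uint64(0x8CB92BA72F3D8DD7))
        s, _ = _splitmix64(s)  # decorrelate the seed words
        t = 0.0
        f = fate[i]
        x_t3 = t3[i]
        x_ri = rin[i]
        x_ra = ract[i]
        x_s = sop[i]
        x_m = mop[i]
        while True:
            A = float(x_ra)
            a0c = k_on * x_t3 * x_ri
            a1 = k_off * A
            a2 = 0.0
            a3 = 0.0
            a4 = 0.0
            a5 = 0.0
            a6 = 0.0
            if f == 0:
                if A > 0.0:
                    a2 = k_fs * Kf_h / (Kf_h + A ** h_f)
                else:
                    a2 = k_fs
                a3 = k_fc
            elif f == 1:
                a4 = b_sh
            else:
                if A > 0.0:
                    a5 = b_m * A ** h_m / (Km_h + A ** h_m)
                    a6 = b_sc * (x_ri / r_tot) * Ks_h / (Ks_h + A ** h_s)
                else:
                    a6 = b_sc * (x_ri / r_tot)
            a7 = phi * x_s
            a8 = phi * x_m
            a0 = a0c + a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8
            if a0 <= 0.0:
                break
            s, u1 = _uniform(s)
            if u1 <= 0.0:
                u1 = 1e-16
            t += -np.log(u1) / a0
            if t > duration:
                break
            s, u2 = _uniform(s)
            r = u2 * a0
            if r < a0c:
                x_t3 -= 1
                x_ri -= 1
                x_ra += 1
            elif r < a0c + a1:
                x_ra -= 1
                x_ri += 1
                x_t3 += 1
            elif r < a0c + a1 + a2:
                f = 1
            elif r < a0c + a1 + a2 + a3:
                f = 2
            elif r < a0c + a1 + a2 + a3 + a4:
                x_s += 1
            elif r < a0c + a1 + a2 + a3 + a4 + a5:
                x_m += 1
            elif r < a0c + a1 + a2 + a3 + a4 + a5 + a6:
                x_s += 1
            elif r < a0c + a1 + a2 + a3 + a4 + a5 + a6 + a7:
                x_s -= 1
            else:
                x_m -= 1
        fate[i] = f
        t3[i] = x_t3
        rin[i] = x_ri
        ract[i] = x_ra
        sop[i] = x_s
        mop[i] = x_m
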