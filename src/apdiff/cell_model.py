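"""Human endocardial ventricular myocyte model (ten Tusscher–Panfilov 2006).

The cell is described by 19 coupled ODEs: membrane potential, 12
Hodgkin–Huxley gating variables, the ryanodine-receptor availability
variable, and 5 ionic concentrations (cytosolic/subspace/SR Ca2+,
Na+, K+).  Each gated membrane current has the form

    I = G * (gate product) * (V - E)

with ``G`` a maximal conductance; the ten reference conductances are the
quantities the scan module perturbs.  Integration uses a fixed-step
Rush–Larsen scheme (exponential update for the gates, forward Euler for
potential and concentrations), the standard approach for this stiff
model; an adaptive LSODA route is provided as an integration cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "ModelParameters",
    "CellState",
    "CurrentSet",
    "StimulusProtocol",
    "APTrace",
    "CONDUCTANCE_NAMES",
    "compute_currents",
    "derivatives",
    "load_config",
    "run_paced",
    "run_unstimulated",
    "resting_state",
]

# Scalable maximal conductances, in the row order of the reference table.
# This order also defines the 0-9 class labels used throughout the package.
CONDUCTANCE_NAMES: tuple[str, ...] = (
    "GKs", "GKr", "GK1", "GNa", "GbNa", "GCaL", "GbCa", "Gto", "GpCa", "GpK",
)

N_STATE = 19
# state vector layout
_IV, _IM, _IH, _IJ, _ID, _IF, _IF2, _IFCASS, _IR, _IS = range(10)
_IXR1, _IXR2, _IXS, _IRBAR, _ICAI, _ICASR, _ICASS, _INAI, _IKI = range(10, 19)

STATE_NAMES: tuple[str, ...] = (
    "V", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s",
    "xr1", "xr2", "xs", "R_bar", "Ca_i", "Ca_SR", "Ca_ss", "Na_i", "K_i",
)

CURRENT_NAMES: tuple[str, ...] = (
    "I_Na", "I_K1", "I_to", "I_Kr", "I_Ks", "I_CaL", "I_NaCa", "I_NaK",
    "I_pCa", "I_pK", "I_bCa", "I_bNa", "I_leak", "I_rel", "I_up", "I_xfer",
)

# Published resting state of the endocardial variant (1 Hz steady pacing
# limit), used as the initial condition for every simulation.
_RESTING_STATE = np.array([
    -86.709,      # V (mV)
    0.00165,      # m
    0.749,        # h
    0.6788,       # j
    3.288e-5,     # d
    0.7026,       # f
    0.9526,       # f2
    0.9942,       # fCass
    2.347e-8,     # r
    0.999998,     # s
    0.0165,       # xr1
    0.473,        # xr2
    0.0174,       # xs
    0.9068,       # R_bar
    0.00013,      # Ca_i (mM)
    3.715,        # Ca_SR (mM)
    0.00036,      # Ca_ss (mM)
    10.355,       # Na_i (mM)
    138.4,        # K_i (mM)
])


@dataclass(frozen=True)
class ModelParameters:
    """Fixed constants plus the ten scalable maximal conductances.

    Conductances are in nS/pF except ``GCaL`` which is in the model's
    native units (litre/(farad*s) scaling of the GHK-like flux).
    Defaults are the endocardial reference values.
    """

    # scalable conductances (reference-table order)
    GKs: float = 0.392
    GKr: float = 0.153
    GK1: float = 5.405
    GNa: float = 14.838
    GbNa: float = 0.00029
    GCaL: float = 0.0000398
    GbCa: float = 0.000592
    Gto: float = 0.073
    GpCa: float = 0.1238
    GpK: float = 0.0146

    # membrane / geometry
    Cm: float = 0.185          # uF
    V_c: float = 0.016404      # cytoplasm volume (um^3 scaled)
    V_sr: float = 0.001094
    V_ss: float = 0.00005468

    # physical constants
    R: float = 8314.472        # J/(kmol K)
    T: float = 310.0           # K
    F: float = 96485.3415      # C/mmol

    # extracellular concentrations (mM)
    Ko: float = 5.4
    Nao: float = 140.0
    Cao: float = 2.0
    pKNa: float = 0.03

    # Na/K pump, Na/Ca exchanger
    PNaK: float = 2.724
    KmK: float = 1.0
    KmNa: float = 40.0
    kNaCa: float = 1000.0
    gamma: float = 0.35
    KmCa: float = 1.38
    KmNai: float = 87.5
    Ksat: float = 0.1
    alpha_NaCa: float = 2.5
    KpCa: float = 0.0005

    # SR calcium handling
    Vmax_up: float = 0.006375
    K_up: float = 0.00025
    V_rel: float = 0.102
    V_leak: float = 0.00036
    V_xfer: float = 0.0038
    k1_prime: float = 0.15
    k2_prime: float = 0.045
    k3: float = 0.060
    k4: float = 0.005
    EC: float = 1.5
    max_sr: float = 2.5
    min_sr: float = 1.0

    # calcium buffering
    Buf_c: float = 0.2
    K_buf_c: float = 0.001
    Buf_sr: float = 10.0
    K_buf_sr: float = 0.3
    Buf_ss: float = 0.4
    K_buf_ss: float = 0.00025

    def __post_init__(self) -> None:
        for name in CONDUCTANCE_NAMES:
            if not getattr(self, name) > 0:
                raise ValueError(f"conductance {name} must be strictly positive")

    def conductances(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CONDUCTANCE_NAMES])

    def scaled(self, channel_index: int, scale: float) -> "ModelParameters":
        """Return a copy with one conductance multiplied by ``scale``."""
        if not 0 <= channel_index < len(CONDUCTANCE_NAMES):
            raise IndexError(f"channel_index {channel_index} out of range 0-9")
        if scale <= 0:
            raise ValueError("scale must be strictly positive")
        name = CONDUCTANCE_NAMES[channel_index]
        return replace(self, **{name: getattr(self, name) * scale})

    def _vector(self) -> np.ndarray:
        return np.array([
            self.GKs, self.GKr, self.GK1, self.GNa, self.GbNa, self.GCaL,
            self.GbCa, self.Gto, self.GpCa, self.GpK,
            self.Cm, self.V_c, self.V_sr, self.V_ss,
            self.R, self.T, self.F,
            self.Ko, self.Nao, self.Cao, self.pKNa,
            self.PNaK, self.KmK, self.KmNa,
            self.kNaCa, self.gamma, self.KmCa, self.KmNai, self.Ksat,
            self.alpha_NaCa, self.KpCa,
            self.Vmax_up, self.K_up, self.V_rel, self.V_leak, self.V_xfer,
            self.k1_prime, self.k2_prime, self.k3, self.k4,
            self.EC, self.max_sr, self.min_sr,
            self.Buf_c, self.K_buf_c, self.Buf_sr, self.K_buf_sr,
            self.Buf_ss, self.K_buf_ss,
        ])


@dataclass
class CellState:
    """Instantaneous state: potential, gates, concentrations."""

    V: float
    m: float
    h: float
    j: float
    d: float
    f: float
    f2: float
    fCass: float
    r: float
    s: float
    xr1: float
    xr2: float
    xs: float
    R_bar: float
    Ca_i: float
    Ca_SR: float
    Ca_ss: float
    Na_i: float
    K_i: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES])

    @classmethod
    def from_vector(cls, y: Sequence[float]) -> "CellState":
        return cls(*[float(v) for v in y])

    def validate(self) -> None:
        y = self.as_vector()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite state component")
        gates = y[1:14]
        if np.any(gates < 0) or np.any(gates > 1):
            raise ValueError("gating variable outside [0, 1]")
        if np.any(y[14:] <= 0):
            raise ValueError("non-positive ionic concentration")


def load_config(path: str | "Path") -> tuple[ModelParameters, "StimulusProtocol"]:
    """Read parameters and protocol from a YAML or JSON config file.

    Conductances are keyed by their standard abbreviations (GKs, GKr,
    GK1, GNa, GbNa, GCaL, GbCa, Gto, GpCa, GpK) under ``conductances``;
    the optional ``protocol`` section takes the StimulusProtocol fields.
    Unknown keys are rejected.
    """
    import json
    from pathlib import Path

    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    cond = data.get("conductances", {})
    unknown = set(cond) - set(CONDUCTANCE_NAMES)
    if unknown:
        raise ValueError(f"unknown conductance keys: {sorted(unknown)}")
    params = ModelParameters(**cond)
    protocol = StimulusProtocol(**data.get("protocol", {}))
    return params, protocol


def resting_state() -> CellState:
    """Published 1 Hz resting state of the endocardial variant."""
    return CellState.from_vector(_RESTING_STATE)


@dataclass(frozen=True)
class CurrentSet:
    """All membrane and SR currents at one instant (A/F)."""

    I_Na: float
    I_K1: float
    I_to: float
    I_Kr: float
    I_Ks: float
    I_CaL: float
    I_NaCa: float
    I_NaK: float
    I_pCa: float
    I_pK: float
    I_bCa: float
    I_bNa: float
    I_leak: float
    I_rel: float
    I_up: float
    I_xfer: float

    @property
    def I_ion(self) -> float:
        """Total transmembrane current: sum of the 12 membrane currents."""
        return (self.I_Na + self.I_K1 + self.I_to + self.I_Kr + self.I_Ks
                + self.I_CaL + self.I_NaCa + self.I_NaK + self.I_pCa
                + self.I_pK + self.I_bCa + self.I_bNa)


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic rectangular stimulus train.

    amplitude is in A/F (negative = depolarizing inward convention of
    the membrane equation dV/dt = -(I_ion + I_stim)/Cm).  The default
    amplitude is calibrated so the unmodified cell reproduces the
    standard 295-ms APD90 under the 10-beat, 1-Hz protocol.
    """

    amplitude: float = -80.0
    duration: float = 1.0      # ms
    cycle_length: float = 1000.0
    n_beats: int = 10
    onset: float = 50.0        # ms into each cycle

    def __post_init__(self) -> None:
        if not self.cycle_length > self.duration > 0:
            raise ValueError("require cycle_length > pulse duration > 0")
        if self.n_beats < 1:
            raise ValueError("number of beats must be >= 1")
        if not 0 <= self.onset < self.cycle_length:
            raise ValueError("onset must lie within the cycle")

    @property
    def total_time(self) -> float:
        return self.n_beats * self.cycle_length


@dataclass
class APTrace:
    """Uniformly sampled membrane-potential time series for one condition."""

    time: np.ndarray           # ms
    vm: np.ndarray             # mV
    protocol: StimulusProtocol
    sample_interval: float
    channel_index: int | None = None   # None for the standard trace
    scale: float = 1.0
    final_state: CellState | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.time.shape != self.vm.shape:
            raise ValueError("time and vm must have equal length")

    @property
    def samples_per_beat(self) -> int:
        return int(round(self.protocol.cycle_length / self.sample_interval))

    def beat(self, beat_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (time, vm) of one beat window [i*CL, (i+1)*CL)."""
        n = self.samples_per_beat
        if beat_index < 0:
            beat_index += self.protocol.n_beats
        if not 0 <= beat_index < self.protocol.n_beats:
            raise IndexError("beat_index out of range")
        sl = slice(beat_index * n, (beat_index + 1) * n)
        return self.time[sl], self.vm[sl]

    def last_beat(self) -> tuple[np.ndarray, np.ndarray]:
        return self.beat(self.protocol.n_beats - 1)


# ---------------------------------------------------------------------------
# jitted model core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _eval(y, p, i_stim, currents, xinf, xtau, dy):
    """Evaluate currents, gate targets/time-constants, and state derivatives.

    currents: 16 entries in CURRENT_NAMES order.
    xinf/xtau: 13 entries for state indices 1..13 (gates + R_bar).
    dy: full 19-entry derivative (gates via (xinf-x)/xtau).
    """
    (gKs, gKr, gK1, gNa, gbNa, gCaL, gbCa, gto, gpCa, gpK,
     Cm, V_c, V_sr, V_ss, Rgas, T, F,
     Ko, Nao, Cao, pKNa, PNaK, KmK, KmNa,
     kNaCa, gam, KmCa, KmNai, Ksat, alpha_nc, KpCa,
     Vmax_up, K_up, V_rel, V_leak, V_xfer,
     k1p, k2p, k3, k4, EC, max_sr, min_sr,
     Buf_c, K_buf_c, Buf_sr, K_buf_sr, Buf_ss, K_buf_ss) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9],
        p[10], p[11], p[12], p[13], p[14], p[15], p[16],
        p[17], p[18], p[19], p[20], p[21], p[22], p[23],
        p[24], p[25], p[26], p[27], p[28], p[29], p[30],
        p[31], p[32], p[33], p[34], p[35],
        p[36], p[37], p[38], p[39], p[40], p[41], p[42],
        p[43], p[44], p[45], p[46], p[47], p[48])

    V = y[0]
    m = y[1]; h = y[2]; j = y[3]
    d = y[4]; f = y[5]; f2 = y[6]; fcass = y[7]
    r = y[8]; s = y[9]
    xr1 = y[10]; xr2 = y[11]; xs = y[12]
    rbar = y[13]
    Cai = y[14]; CaSR = y[15]; Cass = y[16]
    Nai = y[17]; Ki = y[18]

    rtf = Rgas * T / F
    E_Na = rtf * math.log(Nao / Nai)
    E_K = rtf * math.log(Ko / Ki)
    E_Ks = rtf * math.log((Ko + pKNa * Nao) / (Ki + pKNa * Nai))
    E_Ca = 0.5 * rtf * math.log(Cao / Cai)

    # fast Na+
    I_Na = gNa * m * m * m * h * j * (V - E_Na)

    # L-type Ca2+ (GHK-like driving term on subspace Ca)
    vshift = V - 15.0
    if abs(vshift) < 1e-6:
        vshift = 1e-6
    expv = math.exp(2.0 * vshift * F / (Rgas * T))
    I_CaL = (gCaL * d * f * f2 * fcass * 4.0 * vshift * F * F / (Rgas * T)
             * (0.25 * Cass * expv - Cao) / (expv - 1.0))

    # transient outward
    I_to = gto * r * s * (V - E_K)

    # delayed rectifiers
    I_Kr = gKr * math.sqrt(Ko / 5.4) * xr1 * xr2 * (V - E_K)
    I_Ks = gKs * xs * xs * (V - E_Ks)

    # inward rectifier (instantaneous gate)
    a_K1 = 0.1 / (1.0 + math.exp(0.06 * (V - E_K - 200.0)))
    b_K1 = ((3.0 * math.exp(0.0002 * (V - E_K + 100.0))
             + math.exp(0.1 * (V - E_K - 10.0)))
            / (1.0 + math.exp(-0.5 * (V - E_K))))
    I_K1 = gK1 * (a_K1 / (a_K1 + b_K1)) * math.sqrt(Ko / 5.4) * (V - E_K)

    # exchanger / pumps / background
    vfrt = V * F / (Rgas * T)
    I_NaCa = (kNaCa
              * (math.exp(gam * vfrt) * Nai ** 3 * Cao
                 - math.exp((gam - 1.0) * vfrt) * Nao ** 3 * Cai * alpha_nc)
              / ((KmNai ** 3 + Nao ** 3) * (KmCa + Cao)
                 * (1.0 + Ksat * math.exp((gam - 1.0) * vfrt))))
    I_NaK = (PNaK * Ko * Nai
             / ((Ko + KmK) * (Nai + KmNa)
                * (1.0 + 0.1245 * math.exp(-0.1 * vfrt)
                   + 0.0353 * math.exp(-vfrt))))
    I_pCa = gpCa * Cai / (KpCa + Cai)
    I_pK = gpK * (V - E_K) / (1.0 + math.exp((25.0 - V) / 5.98))
    I_bNa = gbNa * (V - E_Na)
    I_bCa = gbCa * (V - E_Ca)

    # SR calcium fluxes
    kcasr = max_sr - (max_sr - min_sr) / (1.0 + (EC / CaSR) ** 2)
    k1 = k1p / kcasr
    k2 = k2p * kcasr
    O = k1 * Cass * Cass * rbar / (k3 + k1 * Cass * Cass)
    I_rel = V_rel * O * (CaSR - Cass)
    I_up = Vmax_up / (1.0 + (K_up / Cai) ** 2)
    I_leak = V_leak * (CaSR - Cai)
    I_xfer = V_xfer * (Cass - Cai)

    currents[0] = I_Na; currents[1] = I_K1; currents[2] = I_to
    currents[3] = I_Kr; currents[4] = I_Ks; currents[5] = I_CaL
    currents[6] = I_NaCa; currents[7] = I_NaK; currents[8] = I_pCa
    currents[9] = I_pK; currents[10] = I_bCa; currents[11] = I_bNa
    currents[12] = I_leak; currents[13] = I_rel; currents[14] = I_up
    currents[15] = I_xfer

    # --- gate kinetics ---
    # m
    xinf[0] = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    a = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    b = (0.1 / (1.0 + math.exp((V + 35.0) / 5.0))
         + 0.10 / (1.0 + math.exp((V - 50.0) / 200.0)))
    xtau[0] = a * b
    # h
    xinf[1] = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    xtau[1] = 1.0 / (ah + bh)
    # j
    xinf[2] = xinf[1]
    if V < -40.0:
        aj = ((-2.5428e4 * math.exp(0.2444 * V)
               - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = (0.02424 * math.exp(-0.01052 * V)
              / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    else:
        aj = 0.0
        bj = (0.6 * math.exp(0.057 * V)
              / (1.0 + math.exp(-0.1 * (V + 32.0))))
    xtau[2] = 1.0 / (aj + bj)
    # d
    xinf[3] = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    xtau[3] = ad * bd + gd
    # f
    xinf[4] = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    xtau[4] = (1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
               + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
               + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0)
    # f2
    xinf[5] = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    xtau[5] = (562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
               + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
               + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0)))
    # fCass (depends on subspace Ca, not V)
    ca_ratio = (Cass / 0.05) ** 2
    xinf[6] = 0.6 / (1.0 + ca_ratio) + 0.4
    xtau[6] = 80.0 / (1.0 + ca_ratio) + 2.0
    # r
    xinf[7] = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    xtau[7] = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    # s (endocardial kinetics)
    xinf[8] = 1.0 / (1.0 + math.exp((V + 28.0) / 5.0))
    xtau[8] = 1000.0 * math.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    # xr1
    xinf[9] = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    xtau[9] = axr1 * bxr1
    # xr2
    xinf[10] = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    xtau[10] = axr2 * bxr2
    # xs
    xinf[11] = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    xtau[11] = axs * bxs + 80.0
    # R_bar (RyR availability): dR/dt = k4(1-R) - k2*Cass*R
    rate = k4 + k2 * Cass
    xinf[12] = k4 / rate
    xtau[12] = 1.0 / rate

    # --- derivatives ---
    I_ion = (I_Na + I_K1 + I_to + I_Kr + I_Ks + I_CaL + I_NaCa + I_NaK
             + I_pCa + I_pK + I_bCa + I_bNa)
    dy[0] = -(I_ion + i_stim)
    for k in range(13):
        dy[1 + k] = (xinf[k] - y[1 + k]) / xtau[k]

    buf_c = 1.0 / (1.0 + Buf_c * K_buf_c / (Cai + K_buf_c) ** 2)
    buf_sr = 1.0 / (1.0 + Buf_sr * K_buf_sr / (CaSR + K_buf_sr) ** 2)
    buf_ss = 1.0 / (1.0 + Buf_ss * K_buf_ss / (Cass + K_buf_ss) ** 2)
    dy[14] = buf_c * ((I_leak - I_up) * V_sr / V_c + I_xfer
                      - (I_bCa + I_pCa - 2.0 * I_NaCa) * Cm / (2.0 * V_c * F))
    dy[15] = buf_sr * (I_up - I_rel - I_leak)
    dy[16] = buf_ss * (-I_CaL * Cm / (2.0 * V_ss * F)
                       + I_rel * V_sr / V_ss - I_xfer * V_c / V_ss)
    dy[17] = -(I_Na + I_bNa + 3.0 * I_NaK + 3.0 * I_NaCa) * Cm / (V_c * F)
    dy[18] = -(I_K1 + I_to + I_Kr + I_Ks - 2.0 * I_NaK + I_pK
               + i_stim) * Cm / (V_c * F)


@njit(cache=True)
def _integrate_rl(y0, p, amplitude, duration, cl, n_beats, onset, dt,
                  sample_interval):
    """Fixed-step Rush–Larsen integration of the paced protocol.

    Gates (state 1..13) use the exponential update
    x <- xinf - (xinf - x) exp(-dt/tau); V and concentrations use forward
    Euler.  Returns (vm samples, final state, error time: <0 if none).
    """
    steps_per_sample = int(round(sample_interval / dt))
    steps_per_cl = int(round(cl / dt))
    k_on = int(round(onset / dt))
    k_off = int(round((onset + duration) / dt))
    n_steps = steps_per_cl * n_beats
    n_out = n_steps // steps_per_sample
    out = np.empty(n_out)
    y = y0.copy()
    currents = np.empty(16)
    xinf = np.empty(13)
    xtau = np.empty(13)
    dy = np.empty(N_STATE)
    i_out = 0
    for k in range(n_steps):
        if k % steps_per_sample == 0:
            out[i_out] = y[0]
            i_out += 1
        kc = k % steps_per_cl
        i_stim = amplitude if (k_on <= kc < k_off) else 0.0
        _eval(y, p, i_stim, currents, xinf, xtau, dy)
        if not np.isfinite(dy[0]):
            return out, y, k * dt
        y[0] += dt * dy[0]
        for g in range(13):
            xi = xinf[g]
            y[1 + g] = xi - (xi - y[1 + g]) * math.exp(-dt / xtau[g])
        for c in range(14, N_STATE):
            y[c] += dt * dy[c]
    return out, y, -1.0


class IntegrationError(RuntimeError):
    """Solver failure (NaN/step underflow) at a reported model time."""

    def __init__(self, t: float):
        super().__init__(f"integration failed at t = {t:.3f} ms")
        self.t = t


def compute_currents(state: CellState, params: ModelParameters) -> CurrentSet:
    """All ionic, pump, exchanger and SR currents at the given state."""
    state.validate()
    y = state.as_vector()
    currents = np.empty(16)
    xinf = np.empty(13)
    xtau = np.empty(13)
    dy = np.empty(N_STATE)
    _eval(y, params._vector(), 0.0, currents, xinf, xtau, dy)
    return CurrentSet(*currents)


def derivatives(state: CellState, params: ModelParameters,
                i_stim: float = 0.0) -> np.ndarray:
    """Full state derivative.

    The membrane equation dV/dt = -(I_ion + i_stim)/C_m is evaluated
    with currents in A/F (already normalized per unit capacitance), so
    numerically dV/dt = -(I_ion + i_stim) in mV/ms; the whole-cell C_m
    enters only the concentration balance equations.
    """
    state.validate()
    y = state.as_vector()
    currents = np.empty(16)
    xinf = np.empty(13)
    xtau = np.empty(13)
    dy = np.empty(N_STATE)
    _eval(y, params._vector(), i_stim, currents, xinf, xtau, dy)
    return dy


def _rhs_vector(y: np.ndarray, params_vec: np.ndarray,
                i_stim: float) -> np.ndarray:
    currents = np.empty(16)
    xinf = np.empty(13)
    xtau = np.empty(13)
    dy = np.empty(N_STATE)
    _eval(y, params_vec, i_stim, currents, xinf, xtau, dy)
    return dy


def run_paced(params: ModelParameters | None = None,
              protocol: StimulusProtocol | None = None,
              sample_interval: float = 2.0,
              dt: float = 0.02,
              method: str = "rush_larsen",
              initial_state: CellState | None = None,
              channel_index: int | None = None,
              scale: float = 1.0,
              rtol: float = 1e-8,
              atol: float = 1e-8) -> APTrace:
    """Pace the cell and return the sampled membrane potential.

    The membrane equation dV/dt = -(I_ion + I_stim)/Cm is integrated over
    ``protocol.n_beats`` cycles.  Note the integrator works on the
    Cm-normalized equation (currents in A/F), so dV/dt = -(I_ion + I_stim)
    numerically.  ``method`` is ``"rush_larsen"`` (fixed step ``dt``) or
    ``"lsoda"`` (adaptive, for cross-checks).  Output is sampled every
    ``sample_interval`` ms starting at t = 0; the sample count is
    n_beats * cycle_length / sample_interval.
    """
    params = params or ModelParameters()
    protocol = protocol or StimulusProtocol()
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    n_per_cl = protocol.cycle_length / sample_interval
    if abs(n_per_cl - round(n_per_cl)) > 1e-9:
        raise ValueError("sample_interval must divide the cycle length")
    y0 = (initial_state or resting_state()).as_vector()
    p = params._vector()

    if method == "rush_larsen":
        vm, y_end, t_err = _integrate_rl(
            y0, p, protocol.amplitude, protocol.duration,
            protocol.cycle_length, protocol.n_beats, protocol.onset,
            dt, sample_interval)
        if t_err >= 0:
            raise IntegrationError(t_err)
    elif method == "lsoda":
        vm, y_end = _run_lsoda(y0, p, protocol,
                               sample_interval, rtol, atol)
    else:
        raise ValueError(f"unknown method {method!r}")

    n_out = vm.size
    time = np.arange(n_out) * sample_interval
    return APTrace(time=time, vm=vm, protocol=protocol,
                   sample_interval=sample_interval,
                   channel_index=channel_index, scale=scale,
                   final_state=CellState.from_vector(y_end))


def _run_lsoda(y0, p, protocol, sample_interval, rtol, atol):
    """Piecewise adaptive integration (stimulus edges are breakpoints)."""
    from scipy.integrate import solve_ivp

    cl = protocol.cycle_length
    n_samples = int(round(protocol.total_time / sample_interval))
    t_grid = np.arange(n_samples) * sample_interval
    vm = np.empty(n_samples)
    y = y0.copy()
    filled = 0
    for beat in range(protocol.n_beats):
        t0 = beat * cl
        edges = [t0, t0 + protocol.onset,
                 t0 + protocol.onset + protocol.duration, t0 + cl]
        for a_t, b_t in zip(edges[:-1], edges[1:]):
            if b_t <= a_t:
                continue
            mid = 0.5 * (a_t + b_t)
            tc = mid - math.floor(mid / cl) * cl
            stim = (protocol.amplitude
                    if protocol.onset <= tc < protocol.onset + protocol.duration
                    else 0.0)
            t_eval = t_grid[(t_grid >= a_t - 1e-9) & (t_grid < b_t - 1e-9)]
            sol = solve_ivp(
                lambda t, yy: _rhs_vector(yy, p, stim),
                (a_t, b_t), y, method="LSODA", rtol=rtol, atol=atol,
                t_eval=t_eval if t_eval.size else None, max_step=b_t - a_t)
            if not sol.success:
                raise IntegrationError(sol.t[-1] if sol.t.size else a_t)
            if t_eval.size:
                vm[filled:filled + t_eval.size] = sol.y[0]
                filled += t_eval.size
            y = sol.y[:, -1].copy() if t_eval.size else sol.y[:, -1].copy()
            # advance to exact segment end
            if sol.t[-1] < b_t - 1e-9:
                sol2 = solve_ivp(lambda t, yy: _rhs_vector(yy, p, stim),
                                 (sol.t[-1], b_t), y, method="LSODA",
                                 rtol=rtol, atol=atol)
                if not sol2.success:
                    raise IntegrationError(sol2.t[-1])
                y = sol2.y[:, -1].copy()
    return vm, y


def run_unstimulated(params: ModelParameters | None = None,
                     duration: float = 10_000.0,
                     dt: float = 0.02,
                     initial_state: CellState | None = None) -> CellState:
    """Integrate without stimulus and return the final state."""
    params = params or ModelParameters()
    protocol = StimulusProtocol(amplitude=0.0, duration=1.0,
                                cycle_length=duration, n_beats=1, onset=0.0)
    trace = run_paced(params, protocol, sample_interval=duration / 2,
                      dt=dt, initial_state=initial_state)
    assert trace.final_state is not None
    return trace.final_state
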