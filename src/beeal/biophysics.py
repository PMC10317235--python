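"""Single-neuron and synaptic dynamics.

Each neuron is a two-compartment (soma + axon) Hodgkin–Huxley cell.  The
soma carries a calcium current, a transient potassium current, the GABAergic
synaptic current, noise and the sensory input; the axon carries the
spike-generating sodium, delayed-rectifier potassium and calcium-dependent
potassium currents.  Units throughout: mV, ms, nF, uS, nA (a consistent
set: nF*mV/ms = uS*mV = nA); intracellular calcium in the model's native
concentration units (reported as uM).

All functions here are pure and operate on scalars or numpy arrays; the
network integrator in :mod:`beeal.simulator` re-implements the same forms
in a compiled kernel and is tested against these reference functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IonChannel",
    "CellParams",
    "GatingState",
    "SynapseState",
    "StimulusSpec",
    "ILN_PARAMS",
    "PN_PARAMS",
    "sigmoid",
    "f_ca",
    "ionic_current",
    "gating_derivatives",
    "calcium_derivative",
    "gabaA_gate_derivative",
    "gabaB_gate_derivatives",
    "gabaA_current",
    "gabaB_current",
    "stimulus_current",
]

IONS = ("Ca", "A", "Na", "Kd", "KCa")


@dataclass(frozen=True)
class IonChannel:
    """Maximal conductance (uS), gate powers and reversal potential (mV)."""
    gmax: float
    M: int
    H: int
    Vr: float


# Maximal conductances are not tabulated in the source parameter set; the
# defaults below were calibrated once so that a PN rests quietly at zero
# input yet fires repetitively under a sustained 7 nA somatic input, spike
# rate and calcium grow monotonically with input over 0-100 nA, and activity
# ceases after stimulus offset.  They are first-class configuration values.
# The delayed rectifier uses the classical fourth-power activation: with a
# first-power gate its resting activation (~8% just below threshold) shunts
# the input, while the m/h overlap of the Na kinetics near -30 mV then
# locks the cell in a depolarized plateau.
_PN_CHANNELS = {
    "Ca": IonChannel(gmax=30.0, M=3, H=0, Vr=0.0),
    "A": IonChannel(gmax=50.0, M=1, H=0, Vr=-60.0),
    "Na": IonChannel(gmax=1100.0, M=2, H=1, Vr=50.0),
    "Kd": IonChannel(gmax=450.0, M=4, H=0, Vr=-60.0),
    "KCa": IonChannel(gmax=8.0, M=1, H=0, Vr=-60.0),
}
# iLN axons are only loosely coupled to their soma (gAS = 10 uS), so they
# need a higher Na density to overshoot the +30 mV transmitter-release
# threshold and a stronger rectifier to stay silent without drive.
_ILN_CHANNELS = {
    "Ca": IonChannel(gmax=30.0, M=3, H=0, Vr=0.0),
    "A": IonChannel(gmax=50.0, M=1, H=0, Vr=-60.0),
    "Na": IonChannel(gmax=1800.0, M=2, H=1, Vr=50.0),
    "Kd": IonChannel(gmax=1000.0, M=4, H=0, Vr=-60.0),
    "KCa": IonChannel(gmax=8.0, M=1, H=0, Vr=-60.0),
}
_DEFAULT_CHANNELS = _PN_CHANNELS


@dataclass(frozen=True)
class CellParams:
    """Biophysical constants of one cell class (iLN or PN)."""

    Cs: float = 10.0           # soma capacitance, nF
    Cax: float = 10.0          # axon capacitance, nF
    VL: float = -45.0          # resting/leak potential, mV
    gl: float = 0.16           # leak conductance, uS
    gAS: float = 10.0          # axon-soma coupling, uS
    Vt: float = -51.7          # threshold potential, mV
    MU: float = 1.5            # calcium dissipation, dimensionless
    sc: float = 0.5            # input connection strength, dimensionless
    rate: float = 0.05         # sensory adaptation, 1/s
    channels: dict = field(default_factory=lambda: dict(_DEFAULT_CHANNELS))
    VGABA: float = -90.0       # GABA reversal, mV
    KfGABA_A: float = 10.0     # 1/ms
    KrGABA_A: float = 0.1      # 1/ms
    KdGABA_B: float = 100.0    # dimensionless
    K1: float = 0.6            # 1/(mM ms)
    K2: float = 0.001
    K3: float = 0.3
    K4: float = 0.0025
    gabaB_hill: int = 1        # exponent of the GABA-B transfer m^n/(m^n+Kd)
    f_ca_mode: str = "offset"  # "offset": 1/(1+exp((2+Vs)/24.4)); "scaled": 1/(1+exp(2 Vs/24.4))
    mca_half: float = -39.1    # half-activation (mV) of the Ca gate

    def with_gmax(self, **gmax: float) -> "CellParams":
        ch = dict(self.channels)
        for ion, g in gmax.items():
            ch[ion] = replace(ch[ion], gmax=g)
        return replace(self, channels=ch)


ILN_PARAMS = CellParams(gAS=10.0, Vt=-51.7, MU=1.5, sc=0.5,
                        channels=dict(_ILN_CHANNELS))
PN_PARAMS = CellParams(gAS=65.0, Vt=-52.1, MU=1.6, sc=0.7,
                       channels=dict(_PN_CHANNELS))


@dataclass
class GatingState:
    """Dynamic variables of one neuron."""
    Vs: float = -45.0
    Va: float = -45.0
    mCa: float = 0.0
    mA: float = 0.0
    mNa: float = 0.0
    hNa: float = 1.0
    mKd: float = 0.0
    mKCa: float = 0.0
    Ca: float = 0.0


@dataclass
class SynapseState:
    """Synaptic gates of one presynaptic iLN, shared by all its targets."""
    mGABA_A: float = 0.0
    hGABA_B: float = 0.0
    mGABA_B: float = 0.0


@dataclass(frozen=True)
class StimulusSpec:
    """Odor input: a depolarizing current pulse with sensory adaptation.

    The pulse is injected identically into every neuron of each recruited
    glomerulus.  ``recruited_glomeruli`` may be given explicitly; otherwise
    a random fraction ``recruit_fraction`` of glomeruli is drawn with
    ``seed``.
    """

    I0: float = 0.0            # nA
    t0: float = 2000.0         # onset, ms
    duration: float = 4000.0   # ms
    recruited_glomeruli: frozenset[int] | None = None
    recruit_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I0 < 0:
            raise ValueError("I0 must be >= 0")

    def resolve_recruited(self, n_glomeruli: int) -> frozenset[int]:
        if self.recruited_glomeruli is not None:
            bad = {g for g in self.recruited_glomeruli if not 0 <= g < n_glomeruli}
            if bad:
                raise ValueError(f"unknown glomeruli: {sorted(bad)}")
            return frozenset(self.recruited_glomeruli)
        if self.recruit_fraction is None:
            return frozenset(range(n_glomeruli))
        rng = np.random.default_rng(self.seed)
        k = int(round(self.recruit_fraction * n_glomeruli))
        return frozenset(int(g) for g in
                         rng.choice(n_glomeruli, size=k, replace=False))


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def f_ca(Vs, mode: str = "offset"):
    """Voltage factor of the calcium current."""
    if mode == "offset":
        return 1.0 / (1.0 + np.exp((2.0 + Vs) / 24.4))
    if mode == "scaled":
        return 1.0 / (1.0 + np.exp(2.0 * Vs / 24.4))
    raise ValueError(f"unknown f_Ca mode: {mode!r}")


def ionic_current(ion: str, p: CellParams, s: GatingState) -> float:
    """I = gmax * m^M * h^H * (V - Vr) * f_ion, in nA.

    Soma-resident currents (Ca, A) read Vs; axon-resident ones
    (Na, Kd, KCa) read Va.
    """
    if ion not in IONS:
        raise ValueError(f"unknown ion: {ion!r}")
    ch = p.channels[ion]
    gates = {
        "Ca": (s.mCa, 1.0),
        "A": (s.mA, 1.0),
        "Na": (s.mNa, s.hNa),
        "Kd": (s.mKd, 1.0),
        "KCa": (s.mKCa, 1.0),
    }
    m, h = gates[ion]
    V = s.Vs if ion in ("Ca", "A") else s.Va
    f = f_ca(V, p.f_ca_mode) if ion == "Ca" else 1.0
    return ch.gmax * m**ch.M * h**ch.H * (V - ch.Vr) * f


def _vtrap(x, y):
    """x / (exp(x / y) - 1) with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, y * (1.0 - x / (2.0 * y)), safe / np.expm1(safe / y))
    return out if out.ndim else float(out)


def gating_derivatives(p: CellParams, s: GatingState) -> dict[str, float]:
    """Time derivatives (1/ms) of the six voltage/calcium gates."""
    Vs, Va, Vt = s.Vs, s.Va, p.Vt

    dmCa = 0.1 * (sigmoid((Vs - p.mca_half) / 2.0) - s.mCa)

    mA_inf = sigmoid((Vs - 10.8) / 8.0)
    tauA = 350.0 - 349.0 / (1.0 + math.exp((Vs + 46.0) / 4.0))
    dmA = (mA_inf - s.mA) / tauA

    a_m = 0.32 * _vtrap(Vt - Va + 18.0, 4.0)
    b_m = 0.28 * _vtrap(Va - Vt - 40.0, 5.0)
    dmNa = a_m * (1.0 - s.mNa) - b_m * s.mNa

    a_h = 0.128 * math.exp((17.0 + Vt - Va) / 18.0)
    b_h = 4.0 / (1.0 + math.exp((40.0 + Vt - Va) / 5.0))
    dhNa = a_h * (1.0 - s.hNa) - b_h * s.hNa

    a_k = 0.16 * _vtrap(Vt - Va + 20.0, 5.0)
    b_k = 0.25 * math.exp((20.0 + Vt - Va) / 40.0)
    dmKd = a_k * (1.0 - s.mKd) - b_k * s.mKd

    a_kca = 3.0 / (1.0 + math.exp((0.08 - s.Ca) / 0.8))
    dmKCa = a_kca * (1.0 - s.mKCa) - 20.0 * s.mKCa

    return {"mCa": dmCa, "mA": dmA, "mNa": dmNa,
            "hNa": dhNa, "mKd": dmKd, "mKCa": dmKCa}


def calcium_derivative(ICa: float, Ca: float, p: CellParams) -> float:
    """First-order intracellular calcium model, d[Ca]/dt in 1/ms."""
    return 0.001 * (-0.35 * ICa - p.MU * Ca + 0.04 * p.MU**2)


def gabaA_gate_derivative(m: float, Va_pre: float, p: CellParams) -> float:
    """Fast ionotropic gate: opens when the presynaptic axon depolarizes
    past ~30 mV, closes with time constant 1/Kr."""
    return (p.KfGABA_A * (1.0 - m) * sigmoid((Va_pre - 30.0) / 2.0)
            - p.KrGABA_A * m)


def gabaB_gate_derivatives(h: float, m: float, Va_pre: float,
                           p: CellParams) -> tuple[float, float]:
    """Slow metabotropic cascade: receptor activation h drives the
    second-messenger concentration m."""
    dh = p.K1 * (1.0 - h) * sigmoid(Va_pre / 2.0) - p.K2 * h
    dm = p.K3 * h - p.K4 * m
    return dh, dm


def gabaA_current(i: int, gates: dict[int, SynapseState], connectome,
                  gA, Vs_i: float, p: CellParams) -> float:
    """Summed GABA-A current onto neuron ``i`` (nA).

    ``gA`` is the conductance (uS) applied per incoming edge; it may be a
    scalar or a callable of the target role.
    """
    g = gA(p) if callable(gA) else gA
    total = 0.0
    for pre, post in connectome.edges:
        if post == i:
            total += g * gates[pre].mGABA_A * (Vs_i - p.VGABA)
    return total


def gabaB_current(i: int, gates: dict[int, SynapseState], connectome,
                  gB, Vs_i: float, p: CellParams) -> float:
    """Summed GABA-B current onto neuron ``i`` (nA), with a Hill-type
    transfer of the second messenger: m^n / (m^n + Kd)."""
    g = gB(p) if callable(gB) else gB
    n = p.gabaB_hill
    total = 0.0
    for pre, post in connectome.edges:
        if post == i:
            m = gates[pre].mGABA_B
            total += g * (Vs_i - p.VGABA) * m**n / (m**n + p.KdGABA_B)
    return total


def stimulus_current(spec: StimulusSpec, neuron: int, connectome,
                     p: CellParams, t: float) -> float:
    """Odor input current to one neuron at time ``t`` (ms):
    I0 * sc * exp(-rate * (t - t0) / 1000) inside the stimulus window of a
    recruited glomerulus, 0 elsewhere."""
    recruited = spec.resolve_recruited(connectome.spec.n_glomeruli)
    if int(connectome.home_glomerulus[neuron]) not in recruited:
        return 0.0
    if not (spec.t0 <= t <= spec.t0 + spec.duration):
        return 0.0
    return spec.I0 * p.sc * math.exp(-p.rate * (t - spec.t0) / 1000.0)
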