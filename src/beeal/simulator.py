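"""Fixed-step integration of the full antennal-lobe network.

The network state couples, per neuron, two membrane potentials (soma and
axon), six Hodgkin–Huxley gates and the intracellular calcium
concentration, and per presynaptic iLN one fast GABA-A gate and the
two-variable GABA-B second-messenger cascade.  Integration is classical
4th-order Runge–Kutta at a fixed step (default 0.02 ms) in a compiled
numba kernel; optional membrane noise is added as a seeded
Euler–Maruyama increment to the soma potential after each deterministic
step.  A settling period precedes t = 0 and is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .biophysics import (
    CellParams,
    ILN_PARAMS,
    PN_PARAMS,
    StimulusSpec,
    IONS,
)
from .topology import Connectome, ILN, PN

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "run_simulation",
    "glomerular_calcium_traces",
    "bin_to_imaging_rate",
    "detect_spikes",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Numerical blow-up or invalid simulation setup."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and synaptic-strength settings.

    The four conductance scalars are the per-edge synaptic strengths (uS)
    by receptor type and target role; they are the axes of the
    conductance searches.  Defaults are the calibrated working point used
    throughout (see docs/methods.md).
    """

    dt: float = 0.02               # ms
    total_duration: float = 10000.0  # ms, post-settling
    settle: float = 500.0          # ms discarded before t = 0
    seed: int = 0
    noise_sd: float = 0.0          # nA * sqrt(ms)
    gA_PN: float = 1.0
    gA_LN: float = 1.0
    gB_PN: float = 0.1
    gB_LN: float = 0.1
    record_stride: int = 50        # steps between stored samples

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if min(self.gA_PN, self.gA_LN, self.gB_PN, self.gB_LN) < 0:
            raise ValueError("conductances must be >= 0")


@dataclass
class SimulationResult:
    """Recorded traces of one network simulation."""

    time: np.ndarray        # (T,) ms, from 0
    Vs: np.ndarray          # (n_neurons, T) mV
    Va: np.ndarray          # (n_neurons, T) mV
    Ca: np.ndarray          # (n_neurons, T)
    mean_isyn: np.ndarray   # (n_neurons,) nA, time-average over the stimulus window
    config: SimulationConfig
    stimulus: StimulusSpec
    connectome: Connectome
    recruited: frozenset[int] = field(default_factory=frozenset)

    def spike_times(self, threshold: float = 0.0,
                    refractory: float = 2.0) -> list[np.ndarray]:
        """Per-neuron spike times from the recorded axon potential."""
        return [detect_spikes(self.Va[i], self.time, threshold, refractory)
                for i in range(self.Va.shape[0])]


_GATE_OFFSETS = 6  # mCa, mA, mNa, hNa, mKd, mKCa


@njit(cache=True, fastmath=True)
def _rhs(t, y, dy, N, L,
         Cs, Cax, VL, gl, gAS, Vt, MU,
         gmax, Mpow, Hpow, Vrev, fca_offset, mca_half,
         WA, WB, iln_idx,
         amp, t0, t1, stim_rate,
         hill, KdB, VGABA, KfA, KrA, K1, K2, K3, K4):
    # layout: Vs[0:N], Va[N:2N], gates[2N:8N], Ca[8N:9N], sA, hB, mB
    oCa = 8 * N
    oA = 9 * N
    oHB = oA + L
    oMB = oHB + L

    # synaptic gate drives (per presynaptic iLN)
    sA = y[oA:oA + L]
    hillB = np.empty(L)
    for k in range(L):
        m = y[oMB + k]
        if m < 0.0:
            m = 0.0
        mn = m ** hill
        hillB[k] = mn / (mn + KdB)
    driveA = np.dot(WA, sA)        # (N,) uS
    driveB = np.dot(WB, hillB)

    stim_on = t0 <= t <= t1
    decay = np.exp(-stim_rate * (t - t0) / 1000.0) if stim_on else 0.0

    for i in range(N):
        Vs = y[i]
        Va = y[N + i]
        mCa = y[2 * N + i]
        mA = y[3 * N + i]
        mNa = y[4 * N + i]
        hNa = y[5 * N + i]
        mKd = y[6 * N + i]
        mKCa = y[7 * N + i]
        Ca = y[oCa + i]

        # ionic currents: soma (Ca, A), axon (Na, Kd, KCa)
        if fca_offset:
            fca = 1.0 / (1.0 + np.exp((2.0 + Vs) / 24.4))
        else:
            fca = 1.0 / (1.0 + np.exp(2.0 * Vs / 24.4))
        ICa = gmax[i, 0] * mCa ** Mpow[i, 0] * (Vs - Vrev[i, 0]) * fca
        IA = gmax[i, 1] * mA ** Mpow[i, 1] * (Vs - Vrev[i, 1])
        INa = gmax[i, 2] * mNa ** Mpow[i, 2] * hNa ** Hpow[i, 2] * (Va - Vrev[i, 2])
        IKd = gmax[i, 3] * mKd ** Mpow[i, 3] * (Va - Vrev[i, 3])
        IKCa = gmax[i, 4] * mKCa ** Mpow[i, 4] * (Va - Vrev[i, 4])

        Isyn = (driveA[i] + driveB[i]) * (Vs - VGABA)
        Iin = amp[i] * decay if stim_on else 0.0

        dy[i] = (-gl[i] * (Vs - VL[i]) - gAS[i] * (Vs - Va)
                 - ICa - IA - Isyn + Iin) / Cs[i]
        dy[N + i] = (-gl[i] * (Va - VL[i]) - gAS[i] * (Va - Vs)
                     - INa - IKd - IKCa) / Cax[i]

        # gating kinetics
        dy[2 * N + i] = 0.1 * (1.0 / (1.0 + np.exp(-(Vs - mca_half) / 2.0)) - mCa)

        mA_inf = 1.0 / (1.0 + np.exp(-(Vs - 10.8) / 8.0))
        tauA = 350.0 - 349.0 / (1.0 + np.exp((Vs + 46.0) / 4.0))
        dy[3 * N + i] = (mA_inf - mA) / tauA

        x = Vt[i] - Va + 18.0
        if abs(x) < 1e-7:
            a_m = 0.32 * 4.0
        else:
            a_m = 0.32 * x / (np.exp(x / 4.0) - 1.0)
        x = Va - Vt[i] - 40.0
        if abs(x) < 1e-7:
            b_m = 0.28 * 5.0
        else:
            b_m = 0.28 * x / (np.exp(x / 5.0) - 1.0)
        dy[4 * N + i] = a_m * (1.0 - mNa) - b_m * mNa

        a_h = 0.128 * np.exp((17.0 + Vt[i] - Va) / 18.0)
        b_h = 4.0 / (1.0 + np.exp((40.0 + Vt[i] - Va) / 5.0))
        dy[5 * N + i] = a_h * (1.0 - hNa) - b_h * hNa

        x = Vt[i] - Va + 20.0
        if abs(x) < 1e-7:
            a_k = 0.16 * 5.0
        else:
            a_k = 0.16 * x / (np.exp(x / 5.0) - 1.0)
        b_k = 0.25 * np.exp((20.0 + Vt[i] - Va) / 40.0)
        dy[6 * N + i] = a_k * (1.0 - mKd) - b_k * mKd

        a_kca = 3.0 / (1.0 + np.exp((0.08 - Ca) / 0.8))
        dy[7 * N + i] = a_kca * (1.0 - mKCa) - 20.0 * mKCa

        dy[oCa + i] = 0.001 * (-0.35 * ICa - MU[i] * Ca + 0.04 * MU[i] * MU[i])

    # synaptic gates, driven by the presynaptic axon potential
    for k in range(L):
        Va_pre = y[N + iln_idx[k]]
        m = y[oA + k]
        dy[oA + k] = (KfA * (1.0 - m) / (1.0 + np.exp(-(Va_pre - 30.0) / 2.0))
                      - KrA * m)
        h = y[oHB + k]
        dy[oHB + k] = K1 * (1.0 - h) / (1.0 + np.exp(-Va_pre / 2.0)) - K2 * h
        dy[oMB + k] = K3 * h - K4 * y[oMB + k]
    return dy


@njit(cache=True, fastmath=True)
def _integrate(y, N, L, dt, n_settle, n_steps, stride,
               Cs, Cax, VL, gl, gAS, Vt, MU,
               gmax, Mpow, Hpow, Vrev, fca_offset, mca_half,
               WA, WB, iln_idx,
               amp, t0, t1, stim_rate,
               hill, KdB, VGABA, KfA, KrA, K1, K2, K3, K4,
               noise_sd, seed,
               rec_vs, rec_va, rec_ca, isyn_sum):
    np.random.seed(seed)
    n_state = y.size
    k1 = np.empty(n_state)
    k2 = np.empty(n_state)
    k3 = np.empty(n_state)
    k4 = np.empty(n_state)
    ytmp = np.empty(n_state)
    oA = 9 * N
    oMB = oA + 2 * L
    noise_scale = noise_sd * np.sqrt(dt)
    rec_i = 0
    isyn_n = 0
    for step in range(n_settle + n_steps):
        t = (step - n_settle) * dt
        if step >= n_settle and (step - n_settle) % stride == 0:
            for i in range(N):
                rec_vs[i, rec_i] = y[i]
                rec_va[i, rec_i] = y[N + i]
                rec_ca[i, rec_i] = y[8 * N + i]
            rec_i += 1
        if t0 <= t <= t1:
            # accumulate the instantaneous synaptic current for averaging
            sA = y[oA:oA + L]
            hb = np.empty(L)
            for k in range(L):
                m = y[oMB + k]
                if m < 0.0:
                    m = 0.0
                mn = m ** hill
                hb[k] = mn / (mn + KdB)
            dA = np.dot(WA, sA)
            dB = np.dot(WB, hb)
            for i in range(N):
                isyn_sum[i] += (dA[i] + dB[i]) * (y[i] - VGABA)
            isyn_n += 1

        _rhs(t, y, k1, N, L, Cs, Cax, VL, gl, gAS, Vt, MU,
             gmax, Mpow, Hpow, Vrev, fca_offset, mca_half, WA, WB, iln_idx,
             amp, t0, t1, stim_rate, hill, KdB, VGABA, KfA, KrA, K1, K2, K3, K4)
        for j in range(n_state):
            ytmp[j] = y[j] + 0.5 * dt * k1[j]
        _rhs(t + 0.5 * dt, ytmp, k2, N, L, Cs, Cax, VL, gl, gAS, Vt, MU,
             gmax, Mpow, Hpow, Vrev, fca_offset, mca_half, WA, WB, iln_idx,
             amp, t0, t1, stim_rate, hill, KdB, VGABA, KfA, KrA, K1, K2, K3, K4)
        for j in range(n_state):
            ytmp[j] = y[j] + 0.5 * dt * k2[j]
        _rhs(t + 0.5 * dt, ytmp, k3, N, L, Cs, Cax, VL, gl, gAS, Vt, MU,
             gmax, Mpow, Hpow, Vrev, fca_offset, mca_half, WA, WB, iln_idx,
             amp, t0, t1, stim_rate, hill, KdB, VGABA, KfA, KrA, K1, K2, K3, K4)
        for j in range(n_state):
            ytmp[j] = y[j] + dt * k3[j]
        _rhs(t + dt, ytmp, k4, N, L, Cs, Cax, VL, gl, gAS, Vt, MU,
             gmax, Mpow, Hpow, Vrev, fca_offset, mca_half, WA, WB, iln_idx,
             amp, t0, t1, stim_rate, hill, KdB, VGABA, KfA, KrA, K1, K2, K3, K4)
        for j in range(n_state):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        # clamp HH gates to [0, 1]; keep Ca and GABA-B messenger >= 0
        for i in range(2 * N, 8 * N):
            if y[i] < 0.0:
                y[i] = 0.0
            elif y[i] > 1.0:
                y[i] = 1.0
        for i in range(8 * N, 9 * N):
            if y[i] < 0.0:
                y[i] = 0.0
        for k in range(L):
            if y[oA + k] < 0.0:
                y[oA + k] = 0.0
            elif y[oA + k] > 1.0:
                y[oA + k] = 1.0
            if y[oA + L + k] < 0.0:
                y[oA + L + k] = 0.0
            elif y[oA + L + k] > 1.0:
                y[oA + L + k] = 1.0
            if y[oMB + k] < 0.0:
                y[oMB + k] = 0.0

        if noise_scale > 0.0:
            for i in range(N):
                y[i] += noise_scale * np.random.normal() / Cs[i]

        if step % 500 == 0:
            for i in range(2 * N):
                if not np.isfinite(y[i]) or abs(y[i]) > 200.0:
                    return -1, isyn_n
    return 0, isyn_n


def _role_param(params: dict[str, CellParams], role: int) -> CellParams:
    return params["PN"] if role == PN else params["ILN"]


def run_simulation(connectome: Connectome,
                   stim: StimulusSpec,
                   cfg: SimulationConfig | None = None,
                   params: dict[str, CellParams] | None = None) -> SimulationResult:
    """Integrate the network over the full protocol.

    Deterministic for fixed (connectome, stimulus, config) including the
    noise seed.  Raises :class:`SimulationError` on numerical blow-up
    (|V| > 200 mV).
    """
    cfg = cfg or SimulationConfig()
    params = params or {"PN": PN_PARAMS, "ILN": ILN_PARAMS}
    pn, iln = params["PN"], params["ILN"]
    N = connectome.neuron_count
    role = connectome.role
    iln_idx = connectome.iln_indices().astype(np.int64)
    L = iln_idx.size

    def per_neuron(attr):
        return np.array([getattr(_role_param(params, r), attr) for r in role],
                        dtype=float)

    Cs, Cax, VL = per_neuron("Cs"), per_neuron("Cax"), per_neuron("VL")
    gl, gAS, Vt, MU = (per_neuron("gl"), per_neuron("gAS"),
                       per_neuron("Vt"), per_neuron("MU"))

    gmax = np.empty((N, 5))
    Mpow = np.empty((N, 5), dtype=np.int64)
    Hpow = np.empty((N, 5), dtype=np.int64)
    Vrev = np.empty((N, 5))
    for i, r in enumerate(role):
        p = _role_param(params, r)
        for j, ion in enumerate(IONS):
            ch = p.channels[ion]
            gmax[i, j], Mpow[i, j], Hpow[i, j], Vrev[i, j] = (
                ch.gmax, ch.M, ch.H, ch.Vr)

    # synaptic weight matrices scaled by target-role conductance
    iln_col = {int(k): j for j, k in enumerate(iln_idx)}
    WA = np.zeros((N, L))
    WB = np.zeros((N, L))
    for pre, post in connectome.edges:
        j = iln_col[pre]
        if role[post] == PN:
            WA[post, j] = cfg.gA_PN
            WB[post, j] = cfg.gB_PN
        else:
            WA[post, j] = cfg.gA_LN
            WB[post, j] = cfg.gB_LN

    recruited = stim.resolve_recruited(connectome.spec.n_glomeruli)
    rec_mask = np.array([connectome.home_glomerulus[i] in recruited
                         for i in range(N)])
    amp = np.where(rec_mask, stim.I0 * per_neuron("sc"), 0.0)

    # initial conditions: rest, gates at their V = VL steady state
    from .biophysics import GatingState, gating_derivatives
    y = np.zeros(9 * N + 3 * L)
    y[0:N] = VL
    y[N:2 * N] = VL
    for i, r in enumerate(role):
        p = _role_param(params, r)
        s = GatingState(Vs=VL[i], Va=VL[i], Ca=0.04 * p.MU)
        ss = _gate_steady_state(p, s)
        for j, g in enumerate(("mCa", "mA", "mNa", "hNa", "mKd", "mKCa")):
            y[(2 + j) * N + i] = ss[g]
        y[8 * N + i] = 0.04 * p.MU

    n_settle = int(round(cfg.settle / cfg.dt))
    n_steps = int(round(cfg.total_duration / cfg.dt))
    n_rec = (n_steps + cfg.record_stride - 1) // cfg.record_stride
    rec_vs = np.empty((N, n_rec))
    rec_va = np.empty((N, n_rec))
    rec_ca = np.empty((N, n_rec))
    isyn_sum = np.zeros(N)

    status, isyn_n = _integrate(
        y, N, L, cfg.dt, n_settle, n_steps, cfg.record_stride,
        Cs, Cax, VL, gl, gAS, Vt, MU,
        gmax, Mpow, Hpow, Vrev, pn.f_ca_mode == "offset", pn.mca_half,
        WA, WB, iln_idx,
        amp, stim.t0, stim.t0 + stim.duration, pn.rate,
        pn.gabaB_hill, pn.KdGABA_B, pn.VGABA,
        pn.KfGABA_A, pn.KrGABA_A, pn.K1, pn.K2, pn.K3, pn.K4,
        cfg.noise_sd, cfg.seed % (2**31),
        rec_vs, rec_va, rec_ca, isyn_sum)
    if status != 0:
        raise SimulationError(
            "membrane potential diverged (|V| > 200 mV); "
            "reduce dt or conductances")

    time = np.arange(n_rec) * cfg.record_stride * cfg.dt
    mean_isyn = isyn_sum / max(isyn_n, 1)
    return SimulationResult(time=time, Vs=rec_vs, Va=rec_va, Ca=rec_ca,
                            mean_isyn=mean_isyn, config=cfg, stimulus=stim,
                            connectome=connectome, recruited=recruited)


def _gate_steady_state(p: CellParams, s) -> dict[str, float]:
    """Steady state of each gate at the clamped voltage/calcium of ``s``."""
    from .biophysics import gating_derivatives, GatingState
    import dataclasses
    out = {}
    # solve dx/dt = a(1-x) - b x = 0 via two derivative evaluations
    for gate in ("mCa", "mA", "mNa", "hNa", "mKd", "mKCa"):
        s0 = dataclasses.replace(s, **{gate: 0.0})
        s1 = dataclasses.replace(s, **{gate: 1.0})
        d0 = gating_derivatives(p, s0)[gate]   # = a
        d1 = gating_derivatives(p, s1)[gate]   # = -b
        out[gate] = d0 / (d0 - d1) if d0 != d1 else 0.0
    return out


def glomerular_calcium_traces(result: SimulationResult,
                              connectome: Connectome | None = None) -> np.ndarray:
    """Per-glomerulus calcium trace: mean over the glomerulus's PNs."""
    c = connectome or result.connectome
    G = c.spec.n_glomeruli
    out = np.empty((G, result.Ca.shape[1]))
    for g in range(G):
        pns = [i for i in c.glomerulus_members(g) if c.role[i] == PN]
        out[g] = result.Ca[pns].mean(axis=0)
    return out


def bin_to_imaging_rate(trace: np.ndarray, sample_dt: float,
                        target_rate: float = 8.0) -> np.ndarray:
    """Bin a trace (last axis = time, uniform ``sample_dt`` ms) to the
    imaging frame rate by averaging within consecutive windows.

    A 10-s trace yields exactly 80 frames at 8 Hz.
    """
    window_ms = 1000.0 / target_rate
    per_bin = int(round(window_ms / sample_dt))
    if per_bin < 1:
        raise ValueError("trace sampling must be finer than the target rate")
    T = trace.shape[-1]
    n_frames = T // per_bin
    if n_frames == 0:
        raise ValueError("trace shorter than one imaging frame")
    trimmed = trace[..., :n_frames * per_bin]
    shape = trimmed.shape[:-1] + (n_frames, per_bin)
    return trimmed.reshape(shape).mean(axis=-1)


def detect_spikes(va: np.ndarray, time: np.ndarray,
                  threshold: float = 0.0, refractory: float = 2.0) -> np.ndarray:
    """Upward threshold crossings separated by at least ``refractory`` ms."""
    above = va >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    spikes = []
    last = -np.inf
    for idx in crossings:
        t = time[idx]
        if t - last >= refractory:
            spikes.append(t)
            last = t
    return np.asarray(spikes)
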