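"""Figure-level computational experiments on the network model.

Three orchestrations: the conductance grid search scored by similarity
to a reference calcium pattern (with one receptor family blocked to
mimic PTX or CGP perfusion), the input-strength gain curves under
scaled inhibition, and the input x recruited-fraction response surface.
All of them run the simulator on a common protocol and read out
glomerular calcium at the analysis frames (375 ms and 1375 ms after
odor onset).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biophysics import StimulusSpec
from .imaging import FRAME_MS, similarity_index
from .simulator import (SimulationConfig, SimulationResult, run_simulation,
                        glomerular_calcium_traces, bin_to_imaging_rate,
                        SimulationError)
from .topology import Connectome, LayoutSpec, build_topology, PN, ILN

__all__ = [
    "SweepGrid", "SweepResult",
    "reduced_protocol", "full_protocol",
    "sweep_gaba", "mean_inhibitory_current",
    "gain_curve", "recruitment_sweep",
    "window_frame", "windowed_response",
]


def full_protocol() -> tuple[SimulationConfig, StimulusSpec]:
    """The complete acquisition protocol: 10 s, odor from 2 to 6 s."""
    return (SimulationConfig(),
            StimulusSpec(I0=40.0, t0=2000.0, duration=4000.0))


def reduced_protocol(I0: float = 40.0,
                     recruit_fraction: float | None = 0.55,
                     seed: int = 0) -> tuple[SimulationConfig, StimulusSpec]:
    """Desk-scale protocol: 2.5 s total, 1.5 s odor from t = 0.5 s.

    Long enough to contain both analysis windows (375 and 1375 ms after
    onset) while keeping a simulation to a few seconds of wall time.
    """
    return (SimulationConfig(total_duration=2500.0),
            StimulusSpec(I0=I0, t0=500.0, duration=1500.0,
                         recruit_fraction=recruit_fraction, seed=seed))


def window_frame(stim: StimulusSpec, window_ms: float) -> int:
    """Imaging-frame index of an analysis window after odor onset."""
    return int(round((stim.t0 + window_ms) / FRAME_MS))


def windowed_response(result: SimulationResult, window_ms: float,
                      average_pm1: bool = False) -> float:
    """Mean recruited-glomerulus calcium at a post-onset analysis frame."""
    frames = bin_to_imaging_rate(glomerular_calcium_traces(result),
                                 result.time[1] - result.time[0])
    f = window_frame(result.stimulus, window_ms)
    rec = sorted(result.recruited)
    if not rec:
        rec = list(range(frames.shape[0]))
    if average_pm1:
        lo, hi = max(f - 1, 0), min(f + 2, frames.shape[1])
        return float(frames[rec, lo:hi].mean())
    return float(frames[rec, f].mean())


def _scaled_config(cfg: SimulationConfig, gA_PN, gA_LN, gB_PN, gB_LN,
                   blocked: str) -> SimulationConfig:
    if blocked == "GABA_A":
        gA_PN = gA_LN = 0.0
    elif blocked == "GABA_B":
        gB_PN = gB_LN = 0.0
    elif blocked != "none":
        raise ValueError(f"unknown receptor family: {blocked!r}")
    return replace(cfg, gA_PN=gA_PN, gA_LN=gA_LN, gB_PN=gB_PN, gB_LN=gB_LN)


def mean_inhibitory_current(result: SimulationResult, role: str) -> float:
    """Time-averaged total synaptic current (nA) received by one neuron
    of the given role over the stimulus window."""
    c = result.connectome
    want = PN if role == "PN" else ILN
    idx = np.flatnonzero(c.role == want)
    return float(result.mean_isyn[idx].mean())


@dataclass(frozen=True)
class SweepGrid:
    """Axes of a conductance search.

    ``receptor`` selects which family's conductances are varied
    (``values_pn`` on PN targets, ``values_ln`` on iLN targets); the
    other family is either blocked or held at ``fixed``.
    """

    receptor: str                       # "GABA_A" | "GABA_B"
    values_pn: tuple[float, ...]
    values_ln: tuple[float, ...]
    fixed: SimulationConfig = field(default_factory=SimulationConfig)
    stimulus: StimulusSpec = field(default_factory=lambda: StimulusSpec(I0=40.0))
    layout: LayoutSpec = field(default_factory=LayoutSpec)

    def __post_init__(self) -> None:
        if self.receptor not in ("GABA_A", "GABA_B"):
            raise ValueError("receptor must be GABA_A or GABA_B")
        for vals in (self.values_pn, self.values_ln):
            if not vals or list(vals) != sorted(vals):
                raise ValueError("axis values must be non-empty and sorted")


@dataclass
class SweepResult:
    grid: SweepGrid
    similarity: np.ndarray       # (len(values_ln), len(values_pn))
    isyn_pn: np.ndarray          # realized mean inhibitory current, nA
    isyn_ln: np.ndarray
    errors: np.ndarray           # object array of per-cell failures
    best: tuple[int, int]        # (row, col) of the similarity argmax

    @property
    def best_conductances(self) -> dict[str, float]:
        i, j = self.best
        key = "gA" if self.grid.receptor == "GABA_A" else "gB"
        return {f"{key}_LN": self.grid.values_ln[i],
                f"{key}_PN": self.grid.values_pn[j]}


def sweep_gaba(grid: SweepGrid, blocked: str,
               standard: np.ndarray) -> SweepResult:
    """Grid-search one receptor family's conductances against a
    reference pattern.

    For every (LN-target, PN-target) conductance pair the network is
    simulated with ``blocked`` receptor currents set to zero, glomerular
    calcium is binned to the imaging rate and scored with the greedy
    similarity index against ``standard``.  Per-cell simulator failures
    are recorded without aborting the sweep.
    """
    connectome = build_topology(grid.layout)
    n_ln, n_pn = len(grid.values_ln), len(grid.values_pn)
    sim = np.full((n_ln, n_pn), np.nan)
    ipn = np.full((n_ln, n_pn), np.nan)
    iln = np.full((n_ln, n_pn), np.nan)
    errors = np.empty((n_ln, n_pn), dtype=object)
    for (i, v_ln), (j, v_pn) in itertools.product(
            enumerate(grid.values_ln), enumerate(grid.values_pn)):
        cfg = grid.fixed
        if grid.receptor == "GABA_A":
            cfg = replace(cfg, gA_LN=v_ln, gA_PN=v_pn)
        else:
            cfg = replace(cfg, gB_LN=v_ln, gB_PN=v_pn)
        cfg = _scaled_config(cfg, cfg.gA_PN, cfg.gA_LN, cfg.gB_PN, cfg.gB_LN,
                             blocked)
        try:
            r = run_simulation(connectome, grid.stimulus, cfg)
        except SimulationError as exc:
            errors[i, j] = str(exc)
            continue
        frames = bin_to_imaging_rate(glomerular_calcium_traces(r),
                                     r.time[1] - r.time[0])
        sim[i, j] = similarity_index(frames, standard)
        ipn[i, j] = mean_inhibitory_current(r, "PN")
        iln[i, j] = mean_inhibitory_current(r, "ILN")
    best = np.unravel_index(np.nanargmax(sim), sim.shape)
    return SweepResult(grid=grid, similarity=sim, isyn_pn=ipn, isyn_ln=iln,
                       errors=errors, best=(int(best[0]), int(best[1])))


def gain_curve(i0_grid=(0.0, 20.0, 40.0, 60.0, 80.0, 100.0),
               recruit_fraction: float = 0.55,
               scales=(1.0, 0.5, 0.0),
               receptor: str = "both",
               window_ms: float = 375.0,
               topology_seeds=(0, 1, 2),
               noise_seeds=(0,),
               base: tuple[SimulationConfig, StimulusSpec] | None = None
               ) -> pd.DataFrame:
    """Response-vs-input curves under scaled inhibition.

    Scale 1 is the calibrated ("saline") working point, scale 0 the
    fully blocked condition; ``receptor`` restricts the scaling to one
    family.  Returns a tidy table of mean recruited-glomerulus calcium
    at the analysis window with mean and SEM over repetitions.
    """
    cfg0, stim0 = base if base is not None else reduced_protocol()
    rows = []
    for scale in scales:
        gA = cfg0.gA_PN * scale if receptor in ("both", "GABA_A") else cfg0.gA_PN
        gAl = cfg0.gA_LN * scale if receptor in ("both", "GABA_A") else cfg0.gA_LN
        gB = cfg0.gB_PN * scale if receptor in ("both", "GABA_B") else cfg0.gB_PN
        gBl = cfg0.gB_LN * scale if receptor in ("both", "GABA_B") else cfg0.gB_LN
        for I0 in i0_grid:
            vals = []
            for ts, ns in itertools.product(topology_seeds, noise_seeds):
                c = build_topology(LayoutSpec(seed=ts))
                stim = replace(stim0, I0=float(I0),
                               recruit_fraction=recruit_fraction, seed=ts + 101)
                cfg = replace(cfg0, gA_PN=gA, gA_LN=gAl, gB_PN=gB, gB_LN=gBl,
                              seed=ns)
                r = run_simulation(c, stim, cfg)
                vals.append(windowed_response(r, window_ms))
            vals = np.asarray(vals)
            rows.append({"scale": scale, "I0": I0,
                         "response": vals.mean(),
                         "sem": vals.std(ddof=1) / np.sqrt(vals.size)
                         if vals.size > 1 else 0.0,
                         "n": vals.size})
    return pd.DataFrame(rows)


def response_slope(curve: pd.DataFrame, scale: float) -> float:
    """Least-squares slope of response vs I0 over the upper half of the
    input grid — the operational measure of gain."""
    sub = curve[curve["scale"] == scale].sort_values("I0")
    half = len(sub) // 2
    x = sub["I0"].to_numpy()[half:]
    y = sub["response"].to_numpy()[half:]
    return float(np.polyfit(x, y, 1)[0])


def recruitment_sweep(i0_grid=(20.0, 60.0, 100.0),
                      fractions=(0.1, 0.3, 0.55, 0.8, 1.0),
                      windows=(375.0, 1375.0),
                      topology_seeds=(0, 1, 2),
                      base: tuple[SimulationConfig, StimulusSpec] | None = None
                      ) -> pd.DataFrame:
    """Mean recruited-glomerulus calcium over an input x recruited-
    fraction grid, at both analysis windows."""
    cfg0, stim0 = base if base is not None else reduced_protocol()
    rows = []
    for I0, frac in itertools.product(i0_grid, fractions):
        vals = {w: [] for w in windows}
        for ts in topology_seeds:
            c = build_topology(LayoutSpec(seed=ts))
            stim = replace(stim0, I0=float(I0), recruit_fraction=frac,
                           seed=ts + 101)
            r = run_simulation(c, stim, cfg0)
            for w in windows:
                vals[w].append(windowed_response(r, w))
        for w in windows:
            v = np.asarray(vals[w])
            rows.append({"I0": I0, "fraction": frac, "window_ms": w,
                         "response": v.mean(),
                         "sem": v.std(ddof=1) / np.sqrt(v.size)
                         if v.size > 1 else 0.0})
    return pd.DataFrame(rows)
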