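"""Synthetic ratiometric-imaging datasets with known ground truth.

The generator emulates the structure of the glomerular Delta(340/380)
recordings the analysis pipeline expects: per bee, two series of
10 measurements (9-step dilution ladder plus a mineral-oil blank), 11
glomeruli, 80 frames at 8 Hz with the odor on from 2 to 6 s.  Each
glomerulus has sigmoid concentration tuning; the temporal response is a
rise-and-adapt kernel shaped by two GABAergic suppression components —
a fast one peaking ~375 ms after onset and a slow tonic one peaking
~1375 ms — plus subtractive lateral inhibition proportional to the mean
network drive, which silences weakly tuned glomeruli and stabilises the
pattern across concentrations.  Blocker conditions remove the
corresponding components: PTX the fast, CGP the slow, the cocktail
everything.

Everything is parameterised by :class:`GeneratorSpec` and reproducible
from its seed; the ground truth travels with the dataset so tests are
self-validating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import (CONCENTRATION_LADDER, FRAMES, FRAME_MS, ONSET_FRAME,
                      OFFSET_FRAME)

__all__ = [
    "GeneratorSpec",
    "ImagingDataset",
    "generate_imaging_dataset",
    "generate_standard_pattern",
    "write_dataset",
    "read_dataset",
]

CONDITIONS = ("saline", "PTX", "CGP", "cocktail")


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth parameters of a synthetic imaging experiment."""

    n_bees: int = 8
    n_glomeruli: int = 11
    concentrations: tuple[float, ...] = CONCENTRATION_LADDER
    include_blank: bool = True
    condition: str = "cocktail"      # condition of each bee's second series
    # per-glomerulus tuning; None -> default core/late layout (see tuning())
    amplitudes: tuple[float, ...] | None = None
    ec50s: tuple[float, ...] | None = None
    slopes: tuple[float, ...] | None = None
    rise_ms: float = 150.0           # kernel rise time constant
    adapt_ms: float = 6000.0         # kernel adaptation time constant
    decay_ms: float = 500.0          # post-offset decay
    fast_peak_ms: float = 375.0      # fast (GABA-A-like) suppression peak
    slow_peak_ms: float = 1375.0     # slow (GABA-B-like) suppression peak
    fast_weight: float = 0.45
    slow_weight: float = 0.45
    fast_inhibition: float = 0.3     # subtractive lateral inhibition, as a
    slow_inhibition: float = 0.3     # fraction of the mean network drive
    bee_amplitude_cv: float = 0.10   # across-bee amplitude variability
    bee_ec50_jitter: float = 0.15    # across-bee EC50 jitter (log10 units)
    noise_sd: float = 0.012
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.fast_weight + self.slow_weight >= 1.0:
            raise ValueError("suppression weights must sum below 1")

    def tuning(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(amplitudes, ec50s, slopes) with defaults filled in."""
        G = self.n_glomeruli
        # default layout, three groups: a sensitive "core" saturating by
        # mid-ladder; a strong low-affinity "late" group that only rises
        # at high concentration and rotates the disinhibited pattern;
        # and two weakly responsive glomeruli that never clear the
        # subtractive threshold under intact inhibition.  The saline
        # pattern is thus concentration-stable and incomplete, while the
        # blocked pattern is complete but rotates with concentration.
        if G >= 6:
            n_weak = 2
            n_late = max((G - n_weak) // 3, 1)
            n_core = G - n_late - n_weak
        else:
            n_weak, n_late, n_core = 0, 0, G
        if self.amplitudes is not None:
            a = np.asarray(self.amplitudes, dtype=float)
        else:
            a = np.concatenate([np.linspace(0.85, 1.2, n_core),
                                np.linspace(0.9, 1.3, n_late),
                                np.full(n_weak, 0.18)])
        if self.ec50s is not None:
            c = np.asarray(self.ec50s, dtype=float)
        else:
            c = np.concatenate([np.linspace(-4.6, -2.4, n_core),
                                np.linspace(-1.5, -0.6, n_late),
                                np.full(n_weak, -2.0)])
        b = (np.asarray(self.slopes, dtype=float) if self.slopes is not None
             else np.full(G, 2.5))
        if not (a.size == c.size == b.size == G):
            raise ValueError("tuning arrays must match n_glomeruli")
        return a, c, b


@dataclass
class ImagingDataset:
    """Tidy trace table plus the generating ground truth.

    ``table`` columns: bee, series, condition, concentration (label),
    log10_conc (nan for the blank), glomerulus, frame, value.
    """

    table: pd.DataFrame
    spec: GeneratorSpec

    def traces(self, bee: int, series: int, conc_label: str) -> np.ndarray:
        """(n_glomeruli, n_frames) array for one measurement."""
        sub = self.table[(self.table.bee == bee)
                         & (self.table.series == series)
                         & (self.table.concentration == conc_label)]
        if sub.empty:
            raise KeyError((bee, series, conc_label))
        return (sub.pivot(index="glomerulus", columns="frame", values="value")
                .sort_index().to_numpy())

    @property
    def concentration_labels(self) -> list[str]:
        return [_conc_label(x) for x in self.spec.concentrations]


def _conc_label(log10_conc: float) -> str:
    return f"{10 ** log10_conc:.2e}"


def _kernel(t_ms: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    """Unit-scale odor-response kernel on the frame grid."""
    on = ONSET_FRAME * FRAME_MS
    off = OFFSET_FRAME * FRAME_MS
    t = t_ms - on
    k = np.where(
        (t_ms >= on) & (t_ms < off),
        (1.0 - np.exp(-np.maximum(t, 0) / spec.rise_ms))
        * np.exp(-np.maximum(t, 0) / spec.adapt_ms),
        0.0,
    )
    # post-offset exponential decay from the value at offset
    k_off = ((1.0 - np.exp(-(off - on) / spec.rise_ms))
             * np.exp(-(off - on) / spec.adapt_ms))
    post = t_ms >= off
    k[post] = k_off * np.exp(-(t_ms[post] - off) / spec.decay_ms)
    return k


def _alpha_bump(t_ms: np.ndarray, peak_ms: float) -> np.ndarray:
    """Unit-peak alpha function starting at odor onset."""
    t = t_ms - ONSET_FRAME * FRAME_MS
    s = np.where(t > 0, (t / peak_ms) * np.exp(1.0 - t / peak_ms), 0.0)
    return np.clip(s, 0.0, None)


def _condition_flags(condition: str) -> tuple[bool, bool]:
    """(fast GABA-A active, slow GABA-B active) under a perfusion."""
    return condition not in ("PTX", "cocktail"), condition not in ("CGP", "cocktail")


def _measurement(spec: GeneratorSpec, a_g, c_g, b_g, log10_conc: float,
                 condition: str) -> np.ndarray:
    """Noise-free (n_glomeruli, FRAMES) response of one measurement.

    With inhibition intact the pattern is separable — a fixed,
    subtractively thresholded weight template times a common gain curve
    — so its direction is concentration-invariant.  Removing inhibition
    exposes each glomerulus's own tuning curve: amplitudes grow and the
    pattern rotates as low-affinity glomeruli are recruited at high
    concentration.
    """
    t = (np.arange(FRAMES) + 0.5) * FRAME_MS
    k = _kernel(t, spec)
    fast_on, slow_on = _condition_flags(condition)
    shape = 1.0
    if fast_on:
        shape = shape - spec.fast_weight * _alpha_bump(t, spec.fast_peak_ms)
    if slow_on:
        shape = shape - spec.slow_weight * _alpha_bump(t, spec.slow_peak_ms)
    raw = a_g / (1.0 + np.exp(c_g - b_g * log10_conc))    # (G,) own tuning
    inh_total = spec.fast_inhibition + spec.slow_inhibition
    # stabilized pattern: weights are the responses at a mid-ladder
    # reference concentration, subtractively thresholded by the network
    # drive there — glomeruli that inhibition silences at the reference
    # stay silent at every concentration
    x_ref = -2.0
    ref = a_g / (1.0 + np.exp(c_g - b_g * x_ref))
    weights = np.clip(ref - inh_total * ref.mean(), 0.0, None)
    ec50 = c_g / b_g
    core = ec50 <= np.median(ec50)
    b_ref = float(b_g[core].mean())
    c_ref = b_ref * float(ec50[core].mean())
    common = 1.0 / (1.0 + np.exp(c_ref - b_ref * log10_conc))
    common = common / (1.0 / (1.0 + np.exp(c_ref - b_ref * x_ref)))
    lam = ((spec.fast_inhibition * fast_on + spec.slow_inhibition * slow_on)
           / inh_total) if inh_total > 0 else 0.0
    stabilized = np.minimum(weights * common, raw)
    amp = lam * stabilized + (1.0 - lam) * raw
    return amp[:, None] * (k * shape)[None, :]


def generate_imaging_dataset(spec: GeneratorSpec) -> ImagingDataset:
    """Simulate a full two-series imaging experiment.

    Series 1 of every bee runs under saline; series 2 under
    ``spec.condition``.  Gaussian noise of SD ``noise_sd`` is added to
    every frame; all randomness derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    a0, c0, b0 = spec.tuning()
    rows = []
    for bee in range(spec.n_bees):
        a = a0 * (1.0 + spec.bee_amplitude_cv * rng.standard_normal(a0.size))
        a = np.clip(a, 0.02, None)
        c = c0 + spec.bee_ec50_jitter * rng.standard_normal(c0.size)
        for series, condition in ((1, "saline"), (2, spec.condition)):
            ladder = [(lbl, x) for lbl, x in
                      zip([_conc_label(v) for v in spec.concentrations],
                          spec.concentrations)]
            if spec.include_blank:
                ladder.append(("MO", np.nan))
            for lbl, x in ladder:
                if np.isnan(x):
                    clean = np.zeros((spec.n_glomeruli, FRAMES))
                else:
                    # logistic offset parameter is c_g = b_g * EC50_g
                    clean = _measurement(spec, a, c * b0, b0, x, condition)
                noisy = clean + spec.noise_sd * rng.standard_normal(clean.shape)
                for g in range(spec.n_glomeruli):
                    rows.append(pd.DataFrame({
                        "bee": bee, "series": series, "condition": condition,
                        "concentration": lbl, "log10_conc": x,
                        "glomerulus": g, "frame": np.arange(FRAMES),
                        "value": noisy[g],
                    }))
    table = pd.concat(rows, ignore_index=True)
    return ImagingDataset(table=table, spec=spec)


def generate_standard_pattern(spec: GeneratorSpec, condition: str = "saline",
                              log10_conc: float = -2.0) -> np.ndarray:
    """Noise-free mean response pattern (G x 80) at a fixed mid
    concentration — the reference against which model output is scored."""
    a, c, b = spec.tuning()
    return _measurement(spec, a, c * b, b, log10_conc, condition)


# --------------------------------------------------------------------
# on-disk format: one CSV + one JSON sidecar

def write_dataset(ds: ImagingDataset, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ds.table.to_csv(path / "traces.csv", index=False)
    (path / "meta.json").write_text(json.dumps(asdict(ds.spec), indent=1))


def read_dataset(path: str | Path) -> ImagingDataset:
    path = Path(path)
    meta = path / "meta.json"
    csv = path / "traces.csv"
    if not meta.exists():
        raise FileNotFoundError(f"missing metadata: {meta}")
    if not csv.exists():
        raise FileNotFoundError(f"missing trace table: {csv}")
    doc = json.loads(meta.read_text())
    for key in ("concentrations", "amplitudes", "ec50s", "slopes"):
        if doc.get(key) is not None:
            doc[key] = tuple(doc[key])
    spec = GeneratorSpec(**doc)
    table = pd.read_csv(csv)
    expected = (spec.n_bees * 2 * (len(spec.concentrations) + spec.include_blank)
                * spec.n_glomeruli * FRAMES)
    if len(table) != expected:
        raise ValueError(
            f"truncated table: {len(table)} rows, expected {expected}")
    return ImagingDataset(table=table, spec=spec)
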