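"""Ratiometric calcium-imaging analysis.

Implements the processing chain applied to glomerular Delta(340/380)
traces: ratio computation and baseline subtraction, saline-referenced
normalisation, blocker-minus-saline difference traces with time-to-peak
extraction, logistic concentration-response fits with dynamic range and
sensibility, recruitment counting against the baseline noise, pairwise
and frame-wise pattern correlations with Fisher-z transforms, and the
greedy similarity index between model and imaging trace sets.

Conventions: acquisitions are 80 frames at 8 Hz (10 s); the odor is on
from frame 16 to frame 48 (seconds 2-6); baseline statistics use the
second before onset (frames 8-15); times-to-peak are quantised to the
125 ms frame grid and referenced to odor onset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

FRAME_MS = 125.0
FRAMES = 80
ONSET_FRAME = 16
OFFSET_FRAME = 48
BASELINE_FRAMES = range(8, 16)

#: log10 of the liquid-phase dilution ladder (3x / 10x half-decade steps)
CONCENTRATION_LADDER = (-4.0, -3.52, -3.0, -2.52, -2.0, -1.52, -1.0, -0.52, 0.0)

#: nominal dilution-ratio bins used when pooling concentration pairs
RATIO_BINS = (3, 10, 30, 100, 300, 1000, 3000, 10000, 30000)

__all__ = [
    "FRAME_MS", "FRAMES", "ONSET_FRAME", "OFFSET_FRAME",
    "CONCENTRATION_LADDER", "RATIO_BINS",
    "GainFit", "CorrelationSet",
    "delta_ratio", "normalize", "blocker_difference", "peak_time",
    "fit_gain_curve", "count_recruited",
    "pattern_correlation", "pool_by_ratio", "framewise_correlation",
    "fisher_z", "similarity_index", "ratio_bin",
]


# --------------------------------------------------------------------
# preprocessing

def delta_ratio(f340: np.ndarray, f380: np.ndarray,
                baseline_frames=BASELINE_FRAMES) -> np.ndarray:
    """Delta(340/380): ratio trace minus its pre-onset baseline.

    R_i = (F340_i / F380_i) * 100; Delta_i = R_i - mean(R over the
    baseline window).  Raises on non-positive F380.
    """
    f340 = np.asarray(f340, dtype=float)
    f380 = np.asarray(f380, dtype=float)
    if f340.shape != f380.shape:
        raise ValueError("channel stacks must have equal shape")
    if np.any(f380 <= 0):
        raise ValueError("F380 must be strictly positive")
    r = f340 / f380 * 100.0
    idx = np.asarray(list(baseline_frames))
    return r - r[..., idx].mean(axis=-1, keepdims=True)


def normalize(df: pd.DataFrame, mode: str = "per_glomerulus_saline_max") -> pd.DataFrame:
    """Normalise a tidy trace table against its saline maxima.

    ``df`` columns: bee, series, condition, concentration, glomerulus,
    frame, value.  ``per_glomerulus_saline_max`` sets the saline maximum
    of each (bee, glomerulus) to 1; ``per_bee_saline_max`` the saline
    maximum of each bee.  Blocker-series values may exceed 1.
    """
    if mode == "per_glomerulus_saline_max":
        keys = ["bee", "glomerulus"]
    elif mode == "per_bee_saline_max":
        keys = ["bee"]
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    saline = df[df["condition"] == "saline"]
    if saline.empty:
        raise ValueError("no saline series present")
    mx = saline.groupby(keys)["value"].max().rename("_max")
    if (mx == 0).any():
        raise ValueError("zero saline maximum")
    out = df.merge(mx, on=keys, how="left")
    out["value"] = out["value"] / out["_max"]
    return out.drop(columns="_max")


def blocker_difference(saline: np.ndarray, blocker: np.ndarray) -> np.ndarray:
    """Frame-by-frame blocker minus saline trace."""
    saline = np.asarray(saline, dtype=float)
    blocker = np.asarray(blocker, dtype=float)
    if saline.shape != blocker.shape:
        raise ValueError("trace length mismatch")
    return blocker - saline


def peak_time(difference: np.ndarray, min_peak: float = 0.2,
              onset_frame: int = ONSET_FRAME) -> float | None:
    """Time (ms after odor onset) of the post-onset maximum of a
    blocker-difference trace, or None when the peak stays below
    ``min_peak`` (trace normalised to the saline maximum)."""
    post = np.asarray(difference, dtype=float)[onset_frame:]
    if post.size == 0:
        return None
    k = int(np.argmax(post))
    if post[k] < min_peak:
        return None
    return k * FRAME_MS


# --------------------------------------------------------------------
# concentration-response fits

@dataclass
class GainFit:
    """Logistic concentration-response fit Delta = a / (1 + exp(c - b x)).

    ``x`` is the log10 dilution.  DR (dynamic range) is EC90 - EC10 =
    2 ln(9) / b in log10-concentration units; Sens = 0.8 a / DR.
    """

    a: float | None
    b: float | None
    c: float | None
    converged: bool
    residual_norm: float = math.nan

    @property
    def DR(self) -> float | None:
        if not self.converged or not self.b:
            return None
        return 2.0 * math.log(9.0) / self.b

    @property
    def Sens(self) -> float | None:
        dr = self.DR
        if dr is None or self.a is None:
            return None
        return 0.8 * self.a / dr

    def predict(self, x) -> np.ndarray:
        if not self.converged:
            raise ValueError("fit did not converge")
        return _logistic(np.asarray(x, dtype=float), self.a, self.b, self.c)

    def summary(self) -> str:
        if not self.converged:
            return "GainFit: not converged"
        return (f"GainFit: a={self.a:.4g}  b={self.b:.4g}  c={self.c:.4g}  "
                f"DR={self.DR:.4g}  Sens={self.Sens:.4g}  "
                f"resid={self.residual_norm:.3g}")


def _logistic(x, a, b, c):
    return a / (1.0 + np.exp(c - b * x))


def fit_gain_curve(log10_conc: np.ndarray, response: np.ndarray) -> GainFit:
    """Nonlinear least-squares logistic fit of responses at a fixed
    post-onset frame against log10 concentration."""
    x = np.asarray(log10_conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 matched points")
    a0 = max(y.max(), 1e-6)
    b0 = 2.0
    c0 = b0 * x[np.argmin(np.abs(y - a0 / 2))]
    try:
        popt, _ = curve_fit(_logistic, x, y, p0=(a0, b0, c0), maxfev=20000)
    except RuntimeError:
        return GainFit(a=None, b=None, c=None, converged=False)
    resid = float(np.linalg.norm(y - _logistic(x, *popt)))
    return GainFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                   converged=True, residual_norm=resid)


# --------------------------------------------------------------------
# recruitment

def count_recruited(traces: np.ndarray, baseline: slice = slice(8, 16),
                    response: slice = slice(ONSET_FRAME, OFFSET_FRAME),
                    threshold_sd: float = 2.0) -> float:
    """Fraction of glomeruli whose mean response over the odor window
    exceeds ``threshold_sd`` times the SD of their pre-onset baseline.

    ``traces`` is (n_glomeruli, n_frames).  A glomerulus with zero
    baseline variance is degenerate and raises.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    base = traces[:, baseline]
    sd = base.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance baseline")
    resp = traces[:, response].mean(axis=1) - base.mean(axis=1)
    return float(np.mean(resp > threshold_sd * sd))


# --------------------------------------------------------------------
# pattern correlations

def fisher_z(r) -> np.ndarray:
    """Fisher z = atanh(r), with |r| clipped below 1 for finiteness."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-7, 1 - 1e-7)
    return np.arctanh(r)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return math.nan
    return float(np.corrcoef(u, v)[0, 1])


@dataclass
class CorrelationSet:
    """Pairwise correlations between activity patterns across
    concentrations, with Fisher-z values."""

    concentrations: tuple[float, ...]
    r: np.ndarray                     # (C, C) symmetric, nan diagonal
    pairs: list[tuple[float, float]] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        return fisher_z(self.r)

    def pair_values(self) -> pd.DataFrame:
        rows = []
        for i, j in itertools.combinations(range(len(self.concentrations)), 2):
            rows.append({
                "conc_low": self.concentrations[i],
                "conc_high": self.concentrations[j],
                "r": self.r[i, j],
                "z": fisher_z(self.r[i, j]),
            })
        return pd.DataFrame(rows)


def pattern_correlation(patterns: np.ndarray,
                        concentrations=CONCENTRATION_LADDER) -> CorrelationSet:
    """Pearson correlations between the glomerular activity vectors of
    every unordered pair of concentrations (9 concentrations -> 36 pairs).

    ``patterns`` is (n_concentrations, n_glomeruli), each row the pattern
    at a fixed post-onset frame.  A constant pattern yields nan.
    """
    patterns = np.asarray(patterns, dtype=float)
    C = patterns.shape[0]
    if C < 2:
        raise ValueError("need >= 2 concentrations")
    if C != len(concentrations):
        raise ValueError("pattern/concentration count mismatch")
    r = np.full((C, C), np.nan)
    for i, j in itertools.combinations(range(C), 2):
        r[i, j] = r[j, i] = _pearson(patterns[i], patterns[j])
    return CorrelationSet(concentrations=tuple(concentrations), r=r)


def ratio_bin(conc_a: float, conc_b: float) -> int:
    """Nominal dilution-ratio bin for a pair of log10 concentrations.

    The half-decade ladder's actual ratios (10^0.48, 10^0.52, ...) are
    snapped to the nominal 3-10-30-... series.
    """
    d = abs(conc_a - conc_b)
    nominal = min(RATIO_BINS, key=lambda b: abs(math.log10(b) - d))
    if abs(math.log10(nominal) - d) > 0.15:
        raise ValueError(f"pair ({conc_a}, {conc_b}) not on the ladder")
    return nominal


def pool_by_ratio(cs: CorrelationSet) -> pd.DataFrame:
    """Mean and SEM of pairwise r per nominal dilution-ratio bin.

    Every one of the 36 pairs lands in exactly one bin.
    """
    df = cs.pair_values()
    df["ratio"] = [ratio_bin(a, b) for a, b in zip(df.conc_low, df.conc_high)]
    g = df.groupby("ratio")["r"]
    out = g.agg(mean_r="mean", sem_r="sem", n_pairs="count").reset_index()
    return out.sort_values("ratio").reset_index(drop=True)


def framewise_correlation(traces_a: np.ndarray, traces_b: np.ndarray,
                          frames: slice = slice(ONSET_FRAME - 8,
                                                OFFSET_FRAME + 8)) -> np.ndarray:
    """Pearson r between two glomerular patterns at every frame.

    ``traces_*`` are (n_glomeruli, n_frames); the default window spans
    1 s before odor onset to 1 s after offset.  Returns one r per frame
    (nan where a pattern is constant).
    """
    a = np.asarray(traces_a, dtype=float)
    b = np.asarray(traces_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trace sets must have equal shape")
    idx = range(*frames.indices(a.shape[1]))
    return np.array([_pearson(a[:, f], b[:, f]) for f in idx])


# --------------------------------------------------------------------
# model-vs-imaging similarity

def similarity_index(model_traces: np.ndarray,
                     standard_traces: np.ndarray,
                     return_matching: bool = False):
    """Greedy-matching similarity between model and reference trace sets.

    Repeatedly take the globally best-correlated (standard, model) pair,
    record its Pearson r, and remove both traces, until every standard
    trace is matched; the index is the mean of the matched correlations.
    Requires at least as many model traces as standard traces.
    """
    model = np.asarray(model_traces, dtype=float)
    standard = np.asarray(standard_traces, dtype=float)
    if model.shape[0] < standard.shape[0]:
        raise ValueError("fewer model traces than standard traces")
    if model.shape[1] != standard.shape[1]:
        raise ValueError("frame-count mismatch")
    corr = np.array([[_pearson(s, m) for m in model] for s in standard])
    work = np.nan_to_num(corr, nan=-np.inf)
    matched = []
    pairs = []
    free_s = list(range(standard.shape[0]))
    free_m = list(range(model.shape[0]))
    for _ in range(standard.shape[0]):
        i, j = map(int, np.unravel_index(np.argmax(work), work.shape))
        if not np.isfinite(work[i, j]):
            # only degenerate (constant-trace) pairings remain; match
            # them arbitrarily with an undefined correlation
            i, j = free_s[0], free_m[0]
        matched.append(corr[i, j])
        pairs.append((i, j))
        free_s.remove(i)
        free_m.remove(j)
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    index = float(np.nanmean(matched)) if not np.all(np.isnan(matched)) \
        else math.nan
    if return_matching:
        return index, pairs
    return index
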