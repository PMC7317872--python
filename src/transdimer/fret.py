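"""Single-molecule FRET: per-trace efficiencies, population mode, distances.

Traces are donor/acceptor intensity time series from surface-immobilized
dimers.  The acceptor photobleaches in a single step; frames before the
bleach give the raw efficiency E = I_A / (I_A + gamma I_D) after background
subtraction.  The population's most probable efficiency (the peak of a
Gaussian fitted to the per-trace histogram) converts to a donor-acceptor
distance through E = 1 / (1 + (R/R0)^6).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .exceptions import (
    DegenerateInputError,
    InvalidParameterError,
    OutOfDomainError,
)
from .smfs import scott_bin_width


@dataclass(frozen=True)
class FRETPairConfig:
    """Forster radius ``R0`` (nm) and detection-correction factor ``gamma``."""

    R0: float
    gamma: float = 1.0

    def __post_init__(self):
        if self.R0 <= 0 or self.gamma <= 0:
            raise InvalidParameterError("R0 and gamma must be positive")


@dataclass
class FRETTrace:
    """Donor/acceptor intensity trace with per-channel backgrounds."""

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    bg_donor: float = 0.0
    bg_acceptor: float = 0.0
    trace_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise InvalidParameterError("channel lengths must match")
        if self.bg_donor < 0 or self.bg_acceptor < 0:
            raise InvalidParameterError("backgrounds must be >= 0")


@dataclass
class EfficiencyDistribution:
    """Population of per-trace efficiencies and the fitted mode EFRETmp."""

    efficiencies: np.ndarray
    EFRETmp: float
    sd: float
    n: int
    unimodal: bool = True

    def summary(self) -> str:
        flag = "" if self.unimodal else "  [warning: distribution not unimodal]"
        return (f"smFRET population (n={self.n})\n"
                f"  EFRETmp = {self.EFRETmp:.4f}\n"
                f"  sd      = {self.sd:.4f}{flag}\n")


def _median3(x):
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = np.median(np.vstack([x[:-2], x[1:-1], x[2:]]), axis=0)
    return out


def detect_bleach(trace: FRETTrace) -> int | None:
    """Frame index of the single-step acceptor photobleach.

    Change-point by the largest single-frame drop of the 3-frame
    median-filtered acceptor trace, validated against the post-bleach noise
    level.  Returns ``None`` when no credible acceptor signal exists.
    """
    a = _median3(trace.acceptor) - trace.bg_acceptor
    if a.size < 12:
        return None
    drops = a[:-1] - a[1:]
    k = int(np.argmax(drops))
    bleach = k + 1
    post = a[bleach:]
    pre = a[:bleach]
    if post.size < 3 or pre.size < 1:
        return None
    post_sd = float(np.std(post)) + 1e-9
    # acceptor must sit clearly above the post-bleach background before the step
    if np.mean(pre) < np.mean(post) + 3 * post_sd:
        return None
    if drops[k] < 3 * post_sd:
        return None
    return bleach


def trace_efficiency(trace: FRETTrace, cfg: FRETPairConfig | None = None,
                     gamma: float | None = None,
                     min_frames: int = 10) -> float | None:
    """Mean gamma-corrected efficiency over pre-bleach frames.

    E = (I_A - bg_A) / [(I_A - bg_A) + gamma (I_D - bg_D)], averaged over
    frames before the detected acceptor bleach.  Traces without a detectable
    acceptor signal, or with fewer than ``min_frames`` pre-bleach frames,
    return ``None`` (excluded, not an error).
    """
    g = gamma if gamma is not None else (cfg.gamma if cfg else 1.0)
    bleach = detect_bleach(trace)
    if bleach is None or bleach < min_frames:
        return None
    a = trace.acceptor[:bleach] - trace.bg_acceptor
    d = trace.donor[:bleach] - trace.bg_donor
    denom = a + g * d
    ok = denom > 0
    if not np.any(ok):
        return None
    return float(np.mean(a[ok] / denom[ok]))


def most_probable_efficiency(efficiencies, min_n: int = 10) -> EfficiencyDistribution:
    """Gaussian fit (Scott's-rule histogram) of per-trace efficiencies.

    EFRETmp is the fitted mean.  A histogram with more than one local
    maximum above 20% of the peak sets the ``unimodal`` flag to False and
    the dominant mode is reported.  Degenerate populations (all values in
    one bin) fall back to the sample mean.
    """
    es = np.asarray([e for e in efficiencies if e is not None and np.isfinite(e)],
                    dtype=float)
    n = es.size
    if n < min_n:
        raise InvalidParameterError(f"need at least {min_n} efficiencies")
    sample_sd = float(np.std(es, ddof=1))
    if sample_sd == 0:
        return EfficiencyDistribution(es, float(es[0]), 0.0, n)
    h = scott_bin_width(es)
    edges = np.arange(es.min() - h / 2, es.max() + h, h)
    counts, edges = np.histogram(es, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    maxima = [i for i in range(len(counts))
              if counts[i] >= 0.2 * counts.max()
              and (i == 0 or counts[i] >= counts[i - 1])
              and (i == len(counts) - 1 or counts[i] > counts[i + 1])]
    unimodal = len(maxima) <= 1
    if not unimodal:
        warnings.warn("efficiency histogram is not unimodal; reporting the "
                      "dominant mode", stacklevel=2)
    if len(centers) < 4:
        return EfficiencyDistribution(es, float(np.mean(es)), sample_sd, n,
                                      unimodal)

    def gauss(x, amp, mu, sd):
        return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    if unimodal:
        x_fit, y_fit = centers, counts
        mu0 = float(np.mean(es))
    else:
        # dominant mode only: fit the contiguous region around the peak
        k = int(np.argmax(counts))
        lo, hi = k, k
        while lo > 0 and counts[lo - 1] >= 0.3 * counts[k]:
            lo -= 1
        while hi < len(counts) - 1 and counts[hi + 1] >= 0.3 * counts[k]:
            hi += 1
        x_fit, y_fit = centers[lo:hi + 1], counts[lo:hi + 1]
        mu0 = float(centers[k])
        if x_fit.size < 4:
            return EfficiencyDistribution(es, mu0, sample_sd, n, unimodal)
    try:
        popt, _ = optimize.curve_fit(
            gauss, x_fit, y_fit,
            p0=[counts.max(), mu0, max(sample_sd if unimodal else h, h)],
            maxfev=20000)
        mp, fit_sd = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        mp, fit_sd = mu0, sample_sd
    return EfficiencyDistribution(es, mp, fit_sd, n, unimodal)


def distance_from_efficiency(E: float, cfg: FRETPairConfig) -> float:
    """Donor-acceptor distance R = R0 (1/E - 1)^(1/6), for 0 < E < 1."""
    if not 0.0 < E < 1.0:
        raise OutOfDomainError("efficiency must lie strictly in (0, 1)")
    return cfg.R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)


def efficiency_from_distance(R: float, cfg: FRETPairConfig) -> float:
    """Forward relation E = 1 / (1 + (R/R0)^6)."""
    if R <= 0:
        raise OutOfDomainError("distance must be positive")
    return 1.0 / (1.0 + (R / cfg.R0) ** 6)


class FRETExperiment:
    """Model: a set of traces -> efficiency distribution and distances."""

    def __init__(self, traces, cfg: FRETPairConfig | None = None,
                 gamma: float = 1.0):
        self.traces = list(traces)
        self.cfg = cfg
        self.gamma = cfg.gamma if cfg else gamma

    def fit(self) -> EfficiencyDistribution:
        es = [trace_efficiency(t, self.cfg, gamma=self.gamma)
              for t in self.traces]
        return most_probable_efficiency([e for e in es if e is not None])

    def distance(self, result: EfficiencyDistribution) -> float:
        if self.cfg is None:
            raise InvalidParameterError("distance conversion requires a "
                                        "FRETPairConfig with R0")
        return distance_from_efficiency(result.EFRETmp, self.cfg)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trace_csv(path, bg_donor: float = 0.0,
                   bg_acceptor: float = 0.0) -> FRETTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return FRETTrace(time=data[:, 0], donor=data[:, 1], acceptor=data[:, 2],
                     bg_donor=bg_donor, bg_acceptor=bg_acceptor,
                     trace_id=Path(path).name)


def write_trace_csv(trace: FRETTrace, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "donor", "acceptor"])
        for row in zip(trace.time, trace.donor, trace.acceptor):
            w.writerow([f"{v:.6g}" for v in row])
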