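"""Dynamic force spectroscopy of receptor-ligand unbinding.

The processing chain mirrors a standard AFM single-molecule experiment with a
polymer (PEG) tether: retract curves are screened for single rupture events by
a freely-jointed-chain (FJC) fit, rupture forces are histogrammed per pulling
speed (Scott's rule, Gaussian / bi-Gaussian fits), the force-dependent loading
rate is corrected for the tether compliance in series with the cantilever, and
the most-probable-force vs log(loading-rate) relation is fitted to the
Bell-Evans model to extract the intrinsic bond lifetime ``tau0`` and the
distance to the transition state ``x_beta``.

Units throughout: force pN, length nm, time s, energy pN.nm, loading rate
pN/s, spring constant pN/nm.
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
    FitFailureError,
    InvalidParameterError,
)

#: thermal energy at 298 K in pN.nm; the default wherever kBT is not supplied
KBT_ROOM = 4.11


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FJCParams:
    """Freely-jointed-chain tether: contour length ``Lc`` and Kuhn length
    ``kuhn`` (both nm)."""

    Lc: float
    kuhn: float

    def __post_init__(self):
        if self.Lc <= 0 or self.kuhn <= 0:
            raise InvalidParameterError("Lc and kuhn must be positive")
        if self.kuhn >= self.Lc:
            raise InvalidParameterError("Kuhn length must be << contour length")


@dataclass(frozen=True)
class BellEvansParams:
    """Bell-Evans bond: intrinsic lifetime ``tau0`` (s) at zero force and
    transition-state distance ``x_beta`` (nm)."""

    tau0: float
    x_beta: float
    kBT: float = KBT_ROOM

    def __post_init__(self):
        if self.tau0 <= 0 or self.x_beta <= 0 or self.kBT <= 0:
            raise InvalidParameterError("tau0, x_beta and kBT must be positive")

    @property
    def koff(self) -> float:
        """Zero-force off-rate 1/tau0 (1/s)."""
        return 1.0 / self.tau0


@dataclass(frozen=True)
class PullingConfig:
    """Cantilever and ramp settings for one pulling speed."""

    kc: float                      # cantilever spring constant, pN/nm
    v: float                       # pulling velocity, nm/s
    sampling_rate: float = 6000.0  # samples per second
    noise_sd: float = 6.0          # Gaussian force noise, pN

    def __post_init__(self):
        if self.kc <= 0 or self.v <= 0 or self.sampling_rate <= 0:
            raise InvalidParameterError("kc, v and sampling_rate must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class ForceCurve:
    """One retract trace: tip-sample separation vs force plus pull metadata."""

    extension: np.ndarray  # nm
    force: np.ndarray      # pN
    v: float               # pulling speed, nm/s
    kc: float              # spring constant, pN/nm
    id: str = ""
    sampling_rate: float = 6000.0

    def __post_init__(self):
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape:
            raise InvalidParameterError("extension and force must match in length")
        if self.extension.size < 50:
            raise InvalidParameterError("curve must hold at least 50 samples")


@dataclass
class RuptureEvent:
    """A selected single-molecule unbinding event."""

    F_rupture: float       # pN
    Lc_fit: float          # nm
    kuhn_fit: float        # nm
    fit_residual: float    # pN RMS over the stretching segment
    pulling_speed: float   # nm/s
    spring_constant: float  # pN/nm
    curve_id: str = ""
    r_squared: float = np.nan
    loading_rate: float = np.nan  # pN/s, filled once Fmp of the state is known


@dataclass
class GaussianComponent:
    """One Gaussian component of a rupture-force distribution."""

    Fmp: float     # component mean = most probable force, pN
    sd: float      # pN
    weight: float  # mixture fraction
    Fmp_se: float = np.nan


@dataclass
class DFSPoint:
    """One (loading rate, most probable force) point of the dynamic force
    spectrum of a single bound state."""

    pulling_speed: float  # nm/s
    vF: float             # pN/s
    Fmp: float            # pN
    Fmp_se: float = np.nan

    def __post_init__(self):
        if self.vF <= 0:
            raise InvalidParameterError("loading rate must be positive")


@dataclass
class BellEvansFit:
    """Bell-Evans parameters of one state with linear-fit uncertainties."""

    tau0: float
    x_beta: float
    tau0_se: float
    x_beta_se: float
    kBT: float
    state: str = ""
    slope: float = np.nan      # kBT/x_beta, pN
    intercept: float = np.nan  # pN
    n_points: int = 0

    def summary(self) -> str:
        return (
            f"Bell-Evans fit ({self.state or 'state'}, kBT={self.kBT} pN.nm, "
            f"n={self.n_points})\n"
            f"  tau0   = {self.tau0:.4g} +/- {self.tau0_se:.2g} s\n"
            f"  x_beta = {self.x_beta:.4g} +/- {self.x_beta_se:.2g} nm\n"
            f"  koff   = {1.0 / self.tau0:.4g} 1/s\n"
        )


# ---------------------------------------------------------------------------
# freely jointed chain
# ---------------------------------------------------------------------------

def _langevin(x):
    """coth(x) - 1/x, series-protected near zero."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    out = 1.0 / np.tanh(safe) - 1.0 / safe
    return np.where(small, x / 3.0 - x**3 / 45.0, out)


def _dlangevin(x):
    """d/dx of coth(x) - 1/x  =  1/x^2 - csch^2(x)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    csch2 = 1.0 / np.sinh(np.clip(safe, -350, 350)) ** 2
    out = 1.0 / safe**2 - csch2
    return np.where(small, 1.0 / 3.0 - x**2 / 15.0, out)


def fjc_extension(F, p: FJCParams, kBT: float = KBT_ROOM):
    """FJC extension l(F) = Lc [coth(Fa/kBT) - kBT/(Fa)] at force F (pN).

    Vectorized in ``F``; the continuous limit l(0)=0 is honoured.
    Negative forces raise :class:`InvalidParameterError`.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise InvalidParameterError("force must be >= 0")
    return p.Lc * _langevin(F * p.kuhn / kBT)


def fjc_compliance(F, p: FJCParams, kBT: float = KBT_ROOM):
    """Tether compliance dl/dF (nm/pN) of the FJC at force F."""
    F = np.asarray(F, dtype=float)
    x = F * p.kuhn / kBT
    return p.Lc * p.kuhn / kBT * _dlangevin(x)


def fjc_force(extension, p: FJCParams, kBT: float = KBT_ROOM):
    """Numerically invert the FJC: force (pN) producing a given extension.

    Uses Cohen's Pade approximant of the inverse Langevin function as the
    starting point, refined by Newton iterations to machine precision.
    Extensions must satisfy 0 <= l < Lc.
    """
    ext = np.asarray(extension, dtype=float)
    y = ext / p.Lc
    if np.any(y < 0) or np.any(y >= 1.0):
        raise InvalidParameterError("extension must lie in [0, Lc)")
    # inverse Langevin, Cohen (1991): x ~ y (3 - y^2) / (1 - y^2)
    with np.errstate(divide="ignore"):
        x = y * (3.0 - y**2) / (1.0 - y**2)
    for _ in range(50):
        fx = _langevin(x) - y
        dfx = _dlangevin(x)
        step = np.where(dfx > 0, fx / np.where(dfx > 0, dfx, 1.0), 0.0)
        x = np.maximum(x - step, 0.0)
        if np.all(np.abs(fx) < 1e-14):
            break
    return x * kBT / p.kuhn


# ---------------------------------------------------------------------------
# curve processing
# ---------------------------------------------------------------------------

def _robust_noise_sd(force):
    """Noise sd from the median absolute successive difference."""
    d = np.diff(force)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def _median3(x):
    if len(x) < 3:
        return np.asarray(x, dtype=float)
    out = np.asarray(x, dtype=float).copy()
    stacked = np.vstack([out[:-2], out[1:-1], out[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


@dataclass
class FJCFitResult:
    params: FJCParams
    residual_rms: float
    r_squared: float
    segment: slice


def fit_fjc(curve: ForceCurve, kBT: float = KBT_ROOM,
            kuhn_init: float = 0.7,
            end_index: int | None = None) -> FJCFitResult | None:
    """Least-squares FJC fit of the stretching segment of a retract curve.

    The segment runs from liftoff (force persistently above the noise floor)
    to the force peak, searched up to ``end_index`` when given (used by the
    event selector to stop at the detected rupture).  The trace is boxcar
    -smoothed (window 5) before fitting, as is standard for high-bandwidth
    AFM retract data; the noise floor scales down accordingly.  Returns
    ``None`` when the curve shows no rising segment (a no-event curve) --
    this is a signal, not an error.
    """
    fraw = curve.force if end_index is None else curve.force[:end_index]
    w = min(5, fraw.size)
    kernel = np.ones(w)
    f = np.convolve(fraw, kernel, mode="same") \
        / np.convolve(np.ones_like(fraw), kernel, mode="same")
    sd = _robust_noise_sd(curve.force) / np.sqrt(w)
    floor = max(3.0 * sd, 1e-9)
    peak = int(np.argmax(f))
    if f[peak] <= 2 * floor or peak < 5:
        return None
    below = np.nonzero(f[:peak] < floor)[0]
    liftoff = int(below[-1]) + 1 if below.size else 0
    seg = slice(liftoff, peak + 1)
    x_seg, f_seg = curve.extension[seg], f[seg]
    if x_seg.size < 8:
        return None
    x_max = float(np.max(x_seg))

    def residuals(theta):
        lc, a = theta
        p = FJCParams(lc, a)
        ratio = np.clip(x_seg / lc, 0.0, 0.999)
        return fjc_force(ratio * lc, p, kBT) - f_seg

    lc0 = max(x_max / 0.9, x_max + 1.0)
    try:
        sol = optimize.least_squares(
            residuals, x0=[lc0, kuhn_init],
            bounds=([x_max * 1.001, 0.05], [10 * x_max + 100.0, 5.0]),
            xtol=1e-10, ftol=1e-10)
    except Exception:
        return None
    res = sol.fun
    rms = float(np.sqrt(np.mean(res**2)))
    ss_tot = float(np.sum((f_seg - f_seg.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res**2)) / ss_tot if ss_tot > 0 else 0.0
    return FJCFitResult(FJCParams(*sol.x), rms, r2, seg)


@dataclass(frozen=True)
class SelectionCriteria:
    """Acceptance thresholds for single-molecule events."""

    min_r_squared: float = 0.9
    lc_range: tuple = (20.0, 120.0)   # nm, two 5-kDa PEGs in series
    max_residual: float | None = None  # pN RMS; None disables
    drop_threshold_factor: float = 5.0
    drop_window: int = 3

    def __post_init__(self):
        if self.min_r_squared <= 0 or self.drop_threshold_factor <= 0:
            raise InvalidParameterError("criteria thresholds must be positive")


def _find_drops(force, sd, factor=5.0, window=3):
    """Indices where the (median-filtered) force falls by > factor*sd within
    <= ``window`` samples; adjacent detections are merged into one drop."""
    sm = _median3(force)
    n = len(sm)
    thr = factor * max(sd, 1e-9)
    hit = np.zeros(n, dtype=bool)
    for k in range(1, window + 1):
        d = sm[:-k] - sm[k:]
        hit[:-k] |= d > thr
    idx = np.nonzero(hit)[0]
    drops = []
    for i in idx:
        if drops and i - drops[-1][-1] <= window + 2:
            drops[-1].append(i)
        else:
            drops.append([i])
    return [d[0] for d in drops], drops


def select_single_events(curves, criteria: SelectionCriteria | None = None,
                         kBT: float = KBT_ROOM):
    """Screen retract curves for single-rupture events passing the FJC fit.

    A curve qualifies when its trace shows exactly one sharp drop to the
    baseline and the FJC fit of the stretching segment meets the criteria.
    The rupture force is the force maximum immediately preceding the drop.
    """
    criteria = criteria or SelectionCriteria()
    events = []
    for curve in curves:
        f = curve.force
        sd = _robust_noise_sd(f)
        starts, groups = _find_drops(
            f, sd, criteria.drop_threshold_factor, criteria.drop_window)
        if len(starts) != 1:
            continue
        drop_at = starts[0]
        # peak maximum immediately preceding the drop
        lo = max(0, drop_at - 10)
        F_rup = float(np.max(f[lo:drop_at + 1]))
        end = groups[0][-1] + criteria.drop_window + 1
        if end < len(f) - 5 and np.median(f[end:]) > 3 * max(sd, 1e-9) + 1e-9:
            continue  # does not return to baseline: not a final rupture
        fit = fit_fjc(curve, kBT, end_index=drop_at + 1)
        if fit is None:
            continue
        lc = fit.params.Lc
        if fit.r_squared < criteria.min_r_squared:
            continue
        if not (criteria.lc_range[0] <= lc <= criteria.lc_range[1]):
            continue
        if criteria.max_residual is not None and fit.residual_rms > criteria.max_residual:
            continue
        events.append(RuptureEvent(
            F_rupture=F_rup, Lc_fit=lc, kuhn_fit=fit.params.kuhn,
            fit_residual=fit.residual_rms, pulling_speed=curve.v,
            spring_constant=curve.kc, curve_id=curve.id,
            r_squared=fit.r_squared))
    return events


# ---------------------------------------------------------------------------
# force distributions
# ---------------------------------------------------------------------------

def scott_bin_width(values) -> float:
    """Scott's-rule histogram bin width h = 3.49 sd n^(-1/3)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise DegenerateInputError("need at least two values")
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise DegenerateInputError("constant input: bin width undefined")
    return 3.49 * sd * n ** (-1.0 / 3.0)


def _two_means_split(values, max_iter=100):
    """1-D two-means clustering; returns the two clusters (each size >= 2)."""
    v = np.sort(np.asarray(values, dtype=float))
    m1, m2 = v[len(v) // 4], v[3 * len(v) // 4]
    for _ in range(max_iter):
        cut = 0.5 * (m1 + m2)
        left, right = v[v <= cut], v[v > cut]
        if left.size < 2 or right.size < 2:
            return v, v
        n1, n2 = float(np.mean(left)), float(np.mean(right))
        if n1 == m1 and n2 == m2:
            break
        m1, m2 = n1, n2
    return left, right


def _gauss(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _bigauss(x, a1, m1, s1, a2, m2, s2):
    return _gauss(x, a1, m1, s1) + _gauss(x, a2, m2, s2)


def fit_force_distribution(forces, n_components: int = 1,
                           refine_mode: bool = True):
    """Histogram (Scott's rule) + least-squares Gaussian / bi-Gaussian fit.

    Returns a list of :class:`GaussianComponent` ordered by ascending mean.
    When the two components of a 2-component fit overlap (means closer than
    one combined sd) the fit falls back to a single component with a warning.

    ``refine_mode`` (default) refits each component's center on the bins
    inside its fitted full-width-half-maximum window, after subtracting the
    other component.  Rupture-force distributions are left-skewed, so a
    single symmetric Gaussian over the full histogram centers systematically
    below the peak; the windowed refit tracks the peak maximum itself.
    """
    forces = np.asarray(forces, dtype=float)
    n = forces.size
    if n_components not in (1, 2):
        raise InvalidParameterError("n_components must be 1 or 2")
    if (n_components == 1 and n < 30) or (n_components == 2 and n < 60):
        raise InvalidParameterError("too few forces for requested components")
    if n_components == 1:
        h = scott_bin_width(forces)
    else:
        # Scott's rule is derived for a single Gaussian; for a two-state
        # histogram apply it per cluster (1-D two-means split) and keep the
        # finer width so the narrower component stays resolved
        try:
            h = min(scott_bin_width(c) for c in _two_means_split(forces))
        except DegenerateInputError:
            h = scott_bin_width(forces)
    edges = np.arange(forces.min() - h / 2, forces.max() + h, h)
    counts, edges = np.histogram(forces, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def _refine(amp, mu, sd, other=None):
        """Refit the component center inside its FWHM window."""
        resid = counts if other is None else counts - other(centers)
        keep = np.abs(centers - mu) <= 1.177 * sd  # half-maximum half-width
        if np.count_nonzero(keep) < 4:
            return None
        try:
            popt, pcov = optimize.curve_fit(
                _gauss, centers[keep], resid[keep], p0=[amp, mu, sd],
                maxfev=20000)
        except RuntimeError:
            return None
        return (float(popt[1]), abs(float(popt[2])),
                float(np.sqrt(np.abs(pcov[1, 1]))))

    def _fit_single():
        mu0, sd0 = float(np.mean(forces)), float(np.std(forces))
        try:
            popt, pcov = optimize.curve_fit(
                _gauss, centers, counts,
                p0=[counts.max(), mu0, max(sd0, h)], maxfev=20000)
        except RuntimeError as exc:
            raise FitFailureError("Gaussian fit did not converge",
                                  diagnostics={"n": n, "bins": len(centers)}) from exc
        amp, mu, sd = popt[0], popt[1], abs(popt[2])
        se = float(np.sqrt(np.abs(pcov[1, 1])))
        if refine_mode:
            ref = _refine(amp, mu, sd)
            if ref is not None:
                mu, _, se = ref
        return [GaussianComponent(float(mu), float(sd), 1.0, se)]

    if n_components == 1:
        return _fit_single()

    # init the two means from the two best-separated histogram peaks
    order = np.argsort(counts)[::-1]
    m1_0 = centers[order[0]]
    m2_0 = None
    for i in order[1:]:
        if abs(centers[i] - m1_0) > 3 * h:
            m2_0 = centers[i]
            break
    if m2_0 is None:
        m1_0, m2_0 = np.percentile(forces, [25, 75])
    sd0 = max(float(np.std(forces)) / 2, h)
    p0 = [counts.max(), min(m1_0, m2_0), sd0, counts.max() / 2, max(m1_0, m2_0), sd0]
    try:
        popt, pcov = optimize.curve_fit(_bigauss, centers, counts, p0=p0,
                                        maxfev=40000)
    except RuntimeError as exc:
        raise FitFailureError("bi-Gaussian fit did not converge",
                              diagnostics={"n": n, "bins": len(centers)}) from exc
    a1, m1, s1, a2, m2, s2 = popt
    s1, s2 = abs(s1), abs(s2)
    if abs(m2 - m1) < (s1 + s2):
        warnings.warn("bi-Gaussian components overlap; falling back to a "
                      "single component", stacklevel=2)
        return _fit_single()
    comps = [(m1, s1, a1, float(np.sqrt(np.abs(pcov[1, 1])))),
             (m2, s2, a2, float(np.sqrt(np.abs(pcov[4, 4]))))]
    comps.sort(key=lambda c: c[0])
    if refine_mode:
        refined = []
        for k, (m, s, a, se) in enumerate(comps):
            mo, so, ao, _ = comps[1 - k]
            ref = _refine(a, m, s, other=lambda x: _gauss(x, ao, mo, so))
            refined.append((ref[0], s, a, ref[2]) if ref is not None
                           else (m, s, a, se))
        comps = sorted(refined, key=lambda c: c[0])
    total = sum(abs(a) * s for m, s, a, _ in comps)
    return [GaussianComponent(float(m), float(s), float(abs(a) * s / total), se)
            for m, s, a, se in comps]


def assign_states(forces, components):
    """Assign each force to a Gaussian component by posterior weight.

    Ties go to the low-force state.  Returns an integer array of component
    indices (ascending component order assumed)."""
    forces = np.asarray(forces, dtype=float)
    post = np.stack([
        c.weight / max(c.sd, 1e-12)
        * np.exp(-0.5 * ((forces - c.Fmp) / max(c.sd, 1e-12)) ** 2)
        for c in components])
    # argmax takes the first (low-force) component on exact ties
    return np.argmax(post, axis=0)


# ---------------------------------------------------------------------------
# loading rate and Bell-Evans
# ---------------------------------------------------------------------------

def effective_loading_rate(F, pull: PullingConfig, tether: FJCParams,
                           kBT: float = KBT_ROOM):
    """Loading rate at force F for a tether and cantilever in series:

    vF = kc v / (1 + kc (Lc a / kBT) [ (kBT/(F a))^2 - csch^2(F a / kBT) ])

    Monotone increasing in F and bounded above by kc*v.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise InvalidParameterError("force must be positive")
    return pull.kc * pull.v / (1.0 + pull.kc * fjc_compliance(F, tether, kBT))


def bell_evans_force(vF, params: BellEvansParams):
    """Most probable rupture force F = (kBT/x_beta) ln(vF x_beta tau0 / kBT).

    Returns 0 where the logarithm argument is <= 1 (ruptures pile up at
    vanishing force)."""
    vF = np.asarray(vF, dtype=float)
    arg = vF * params.x_beta * params.tau0 / params.kBT
    out = np.where(arg > 1.0, params.kBT / params.x_beta
                   * np.log(np.where(arg > 1.0, arg, 1.0)), 0.0)
    return out if out.shape else float(out)


def fit_bell_evans(points, kBT: float = KBT_ROOM, state: str = "") -> BellEvansFit:
    """Weighted linear fit of Fmp against ln(vF).

    The Bell-Evans relation is exactly linear in ln(vF): slope = kBT/x_beta
    and intercept = slope * ln(x_beta tau0 / kBT), so tau0 and x_beta follow
    from the line, with standard errors propagated from the linear-fit
    covariance (delta method).
    """
    points = list(points)
    if len(points) < 3:
        raise InvalidParameterError("need at least 3 dynamic-force-spectrum points")
    vF = np.array([p.vF for p in points], dtype=float)
    if np.log10(vF.max() / vF.min()) < 1.0:
        raise InvalidParameterError("loading rates must span at least a decade")
    F = np.array([p.Fmp for p in points], dtype=float)
    se = np.array([p.Fmp_se for p in points], dtype=float)
    x = np.log(vF)
    weighted = bool(np.all(np.isfinite(se)) and np.all(se > 0))
    w = 1.0 / se if weighted else np.ones_like(F)
    (m, b), cov = np.polyfit(x, F, 1, w=w,
                             cov="unscaled" if weighted else True)
    if m <= 0:
        raise FitFailureError("nonpositive slope: unphysical x_beta",
                              diagnostics={"slope": float(m)})
    x_beta = kBT / m
    # numerically (vF in pN/s, m in pN): x_beta*tau0/kBT = exp(b/m)
    tau0 = m * np.exp(b / m)
    # delta-method errors
    g = np.array([np.exp(b / m) * (1.0 - b / m), np.exp(b / m)])
    var_tau0 = float(g @ cov @ g)
    tau0_se = float(np.sqrt(max(var_tau0, 0.0)))
    x_beta_se = float(kBT * np.sqrt(np.abs(cov[0, 0])) / m**2)
    return BellEvansFit(float(tau0), float(x_beta), tau0_se, x_beta_se, kBT,
                        state=state, slope=float(m), intercept=float(b),
                        n_points=len(points))


# ---------------------------------------------------------------------------
# model object: curves -> Bell-Evans kinetics
# ---------------------------------------------------------------------------

@dataclass
class DFSResults:
    """Results of a dynamic-force-spectroscopy analysis.

    Holds the per-state Bell-Evans fits, the per-speed Gaussian components,
    and the dynamic-force-spectrum points that entered each fit.
    """

    fits: list            # list[BellEvansFit], low-force state first
    points: dict          # state index -> list[DFSPoint]
    components: dict      # pulling speed -> list[GaussianComponent]
    n_events: int = 0

    def summary(self) -> str:
        lines = [f"Dynamic force spectroscopy: {self.n_events} events, "
                 f"{len(self.components)} pulling speeds, "
                 f"{len(self.fits)} bound state(s)\n"]
        for fit in self.fits:
            lines.append(fit.summary())
        return "\n".join(lines)


class DynamicForceSpectroscopy:
    """Model: rupture events grouped by pulling speed -> Bell-Evans kinetics.

    Parameters
    ----------
    events : list of RuptureEvent
        Selected single-molecule events (see :func:`select_single_events`).
    tether : FJCParams
        Tether used for the series-compliance loading-rate correction.
    kBT : float
        Thermal energy in pN.nm.
    """

    def __init__(self, events, tether: FJCParams, kBT: float = KBT_ROOM):
        self.events = list(events)
        if not self.events:
            raise InvalidParameterError("no events supplied")
        self.tether = tether
        self.kBT = kBT

    @classmethod
    def from_curves(cls, curves, tether: FJCParams,
                    criteria: SelectionCriteria | None = None,
                    kBT: float = KBT_ROOM):
        return cls(select_single_events(curves, criteria, kBT), tether, kBT)

    def fit(self, n_components: int = 2) -> DFSResults:
        """Per speed: histogram + (bi-)Gaussian fit; per state: Eq.-5 loading
        rate at the fitted Fmp, then the Bell-Evans line."""
        by_speed = {}
        for ev in self.events:
            by_speed.setdefault((ev.pulling_speed, ev.spring_constant), []).append(ev)
        components = {}
        points: dict[int, list] = {}
        for (v, kc), evs in sorted(by_speed.items()):
            forces = np.array([e.F_rupture for e in evs])
            ncomp = n_components if forces.size >= 60 else 1
            comps = fit_force_distribution(forces, ncomp)
            components[v] = comps
            pull = PullingConfig(kc=kc, v=v)
            for idx, comp in enumerate(comps):
                vF = float(effective_loading_rate(comp.Fmp, pull, self.tether,
                                                  self.kBT))
                points.setdefault(idx, []).append(
                    DFSPoint(v, vF, comp.Fmp, comp.Fmp_se))
        labels = {0: "low-force", 1: "high-force"}
        fits = []
        for idx in sorted(points):
            pts = points[idx]
            if len(pts) >= 3:
                fits.append(fit_bell_evans(pts, self.kBT,
                                           state=labels.get(idx, str(idx))))
        return DFSResults(fits=fits, points=points, components=components,
                          n_events=len(self.events))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_force_curves(directory) -> list:
    """Read a directory of two-column TSV curves plus ``manifest.csv``."""
    directory = Path(directory)
    curves = []
    with open(directory / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            data = np.loadtxt(directory / row["filename"])
            curves.append(ForceCurve(
                extension=data[:, 0], force=data[:, 1],
                v=float(row["pulling_speed_nm_s"]),
                kc=float(row["spring_constant_pN_nm"]),
                id=row["filename"],
                sampling_rate=float(row["sampling_rate_hz"])))
    return curves


def write_events_csv(events, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["curve_id", "F_rupture_pN", "Lc_nm", "kuhn_nm",
                    "residual_pN", "speed_nm_s", "kc_pN_nm", "vF_pN_s"])
        for e in events:
            w.writerow([e.curve_id, e.F_rupture, e.Lc_fit, e.kuhn_fit,
                        e.fit_residual, e.pulling_speed, e.spring_constant,
                        e.loading_rate])


def read_events_csv(path) -> list:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(RuptureEvent(
                F_rupture=float(row["F_rupture_pN"]),
                Lc_fit=float(row["Lc_nm"]), kuhn_fit=float(row["kuhn_nm"]),
                fit_residual=float(row["residual_pN"]),
                pulling_speed=float(row["speed_nm_s"]),
                spring_constant=float(row["kc_pN_nm"]),
                curve_id=row["curve_id"],
                loading_rate=float(row["vF_pN_s"])))
    return events
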