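"""Small-angle X-ray scattering shape analysis.

Implements the standard desk-scale SAXS toolchain for 1-D profiles:
Guinier analysis (auto-iterated low-q window), normalized Kratky curves,
a regularized indirect Fourier transform to the pair-distance distribution
P(r) with non-negativity and endpoint-zero constraints, a Dmax scan, the
volume-of-correlation molecular weight (Rambo-Tainer calibration), and
z-score consistency tests of structural models against SAXS/FRET-derived
parameters.

q is handled in nm^-1 internally; Angstrom^-1 input is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    AggregationError,
    FitFailureError,
    InvalidParameterError,
)


@dataclass
class SAXSProfile:
    """1-D scattering profile: q (nm^-1), intensity, uncertainty."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise InvalidParameterError("q must be positive and strictly "
                                        "increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise InvalidParameterError("sigma must be positive where given")

    @property
    def weights(self):
        if self.sigma is None:
            return np.ones_like(self.I)
        return 1.0 / self.sigma


@dataclass
class GuinierResult:
    Rg: float          # nm
    I0: float
    q_window: tuple    # (qmin, qmax) used, nm^-1
    r_squared: float
    qmax_rg: float
    n_points: int

    def summary(self) -> str:
        return (f"Guinier fit: Rg = {self.Rg:.4g} nm, I0 = {self.I0:.4g}, "
                f"qmax*Rg = {self.qmax_rg:.3f}, R^2 = {self.r_squared:.4f}, "
                f"n = {self.n_points}\n")


@dataclass
class KratkyCurve:
    x: np.ndarray        # q Rg
    y: np.ndarray        # (q Rg)^2 I / I0
    peak_x: float
    peak_y: float


@dataclass
class PrDistribution:
    r: np.ndarray        # nm
    p: np.ndarray
    Dmax: float          # nm
    Rg_real: float       # from the second moment of p(r)
    I0_real: float
    alpha: float
    chi2: float          # reduced chi^2 of the forward model

    def effective_dmax(self, frac: float = 0.01) -> float:
        """Smallest r beyond which p stays below ``frac`` of its peak."""
        thresh = frac * float(np.max(self.p))
        above = np.nonzero(self.p > thresh)[0]
        if above.size == 0:
            return 0.0
        return float(self.r[min(above[-1] + 1, self.r.size - 1)])


@dataclass
class VcResult:
    Vc: float            # nm^2
    QR: float            # nm^3
    mw_kda: float
    mw_sensitivity: float  # relative MW shift when qmax is cut by 20%
    converged: bool = True


@dataclass
class DmaxScan:
    Dmax: float
    candidates: np.ndarray
    chi2: np.ndarray
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# Guinier
# ---------------------------------------------------------------------------

def guinier_fit(profile: SAXSProfile, qRg_max: float = 1.3,
                min_points: int = 8, max_iter: int = 50) -> GuinierResult:
    """Weighted linear fit of ln I vs q^2 over an auto-iterated low-q window.

    The window shrinks (or grows) until qmax*Rg <= ``qRg_max``.  A
    non-negative slope (low-q upturn) raises :class:`AggregationError`.
    """
    q, I = profile.q, profile.I
    pos = I > 0
    if np.count_nonzero(pos) < min_points:
        raise InvalidParameterError("too few positive intensities")
    w_all = profile.weights

    def _fit(n):
        idx = np.nonzero(pos)[0][:n]
        x, y = q[idx] ** 2, np.log(I[idx])
        # ln-transform: sd(ln I) = sigma/I
        w = (I[idx] * w_all[idx]) if profile.sigma is not None \
            else np.ones(idx.size)
        (slope, inter), cov = np.polyfit(x, y, 1, w=w, cov=True)
        yhat = slope * x + inter
        ss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum((y - yhat) ** 2) / ss if ss > 0 else 1.0
        return slope, inter, r2, idx

    n = max(min_points, min(20, np.count_nonzero(pos)))
    last = None
    for _ in range(max_iter):
        slope, inter, r2, idx = _fit(n)
        if slope >= 0:
            raise AggregationError(
                "non-negative Guinier slope: low-q upturn / aggregation")
        Rg = float(np.sqrt(-3.0 * slope))
        qmax = q[idx][-1]
        target = int(np.searchsorted(q, qRg_max / Rg, side="right"))
        target = max(min_points, min(target, np.count_nonzero(pos)))
        if target == n or (last is not None and target == last):
            n = min(n, target)
            break
        last, n = n, target
    slope, inter, r2, idx = _fit(n)
    if slope >= 0:
        raise AggregationError("non-negative Guinier slope after iteration")
    Rg = float(np.sqrt(-3.0 * slope))
    return GuinierResult(Rg=Rg, I0=float(np.exp(inter)),
                         q_window=(float(q[idx][0]), float(q[idx][-1])),
                         r_squared=float(r2), qmax_rg=float(q[idx][-1] * Rg),
                         n_points=int(idx.size))


# ---------------------------------------------------------------------------
# Kratky
# ---------------------------------------------------------------------------

def normalized_kratky(profile: SAXSProfile, g: GuinierResult) -> KratkyCurve:
    """Dimensionless Kratky curve (qRg)^2 I/I0 vs qRg with its peak.

    A globular (Gaussian-like) profile peaks at qRg = sqrt(3) ~ 1.732 with
    height 3/e; elongated shapes shift the peak to larger qRg."""
    x = profile.q * g.Rg
    y = x**2 * profile.I / g.I0
    k = int(np.argmax(y))
    if 0 < k < x.size - 1:
        # parabolic refinement through the three points around the maximum
        x3, y3 = x[k - 1:k + 2], y[k - 1:k + 2]
        denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
        a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2])
             + x3[0] * (y3[2] - y3[1])) / denom
        b = (x3[2]**2 * (y3[0] - y3[1]) + x3[1]**2 * (y3[2] - y3[0])
             + x3[0]**2 * (y3[1] - y3[2])) / denom
        if a < 0:
            px = -b / (2 * a)
            c = y3[0] - a * x3[0]**2 - b * x3[0]
            py = a * px**2 + b * px + c
        else:
            px, py = float(x[k]), float(y[k])
    else:
        px, py = float(x[k]), float(y[k])
    return KratkyCurve(x=x, y=y, peak_x=float(px), peak_y=float(py))


# ---------------------------------------------------------------------------
# indirect Fourier transform
# ---------------------------------------------------------------------------

def _ift_kernel(q, r):
    """K[i, j] = 4 pi sinc(q_i r_j) dr with trapezoid end-weights."""
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    K = 4.0 * np.pi * np.sinc(qr / np.pi) * dr
    K[:, 0] *= 0.5
    K[:, -1] *= 0.5
    return K


def _second_difference(n):
    """Second-difference operator acting on the full p vector."""
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i:i + 3] = (1.0, -2.0, 1.0)
    return L


def _solve_ift(profile, Dmax, alpha, n_r):
    q, I = profile.q, profile.I
    sig = profile.sigma if profile.sigma is not None \
        else np.full_like(I, max(1e-3 * float(np.max(np.abs(I))), 1e-30))
    r = np.linspace(0.0, Dmax, n_r)
    K = _ift_kernel(q, r)
    # endpoint-zero constraints: solve only for interior nodes
    Ki = K[:, 1:-1] / sig[:, None]
    L = _second_difference(n_r)[:, 1:-1]
    scale = float(np.linalg.norm(Ki)) / max(float(np.linalg.norm(L)), 1e-30)
    A = np.vstack([Ki, np.sqrt(alpha) * scale * L])
    b = np.concatenate([I / sig, np.zeros(L.shape[0])])
    p_int, _ = optimize.nnls(A, b)
    p = np.zeros(n_r)
    p[1:-1] = p_int
    resid = (K @ p - I) / sig
    chi2 = float(np.sum(resid**2) / max(I.size - 1, 1))
    return r, p, chi2


def ift_pr(profile: SAXSProfile, Dmax: float, alpha: float | None = None,
           n_r: int = 101) -> PrDistribution:
    """Regularized indirect Fourier transform to the P(r) distribution.

    Solves I(q) = 4 pi int_0^Dmax p(r) sinc(qr) dr on an ``n_r``-point grid
    by non-negative least squares with second-difference smoothing of weight
    ``alpha`` and p(0) = p(Dmax) = 0.  ``alpha=None`` selects the largest
    weight whose chi^2 stays within 5% of the best over an L-curve scan.
    Real-space invariants: Rg^2 = int r^2 p dr / (2 int p dr) and
    I(0) = 4 pi int p dr.
    """
    if Dmax <= 0:
        raise InvalidParameterError("Dmax must be positive")
    if profile.q[-1] * Dmax < 6.0:
        warnings.warn("q-range barely resolves Dmax (q_max*Dmax < 6); "
                      "P(r) may be ill-conditioned", stacklevel=2)
    if alpha is None:
        alphas = np.geomspace(1e-6, 1e2, 17)
        sols = [(a, *_solve_ift(profile, Dmax, a, n_r)[1:]) for a in alphas]
        chi2s = np.array([s[2] for s in sols])
        best = float(np.min(chi2s))
        ok = chi2s <= 1.05 * best + 1e-30
        alpha = float(alphas[np.nonzero(ok)[0][-1]])
    r, p, chi2 = _solve_ift(profile, Dmax, alpha, n_r)
    norm = np.trapezoid(p, r)
    if norm <= 0:
        raise FitFailureError("P(r) vanished; alpha too large or Dmax too "
                              "small", diagnostics={"alpha": alpha})
    rg_real = float(np.sqrt(np.trapezoid(r**2 * p, r) / (2.0 * norm)))
    return PrDistribution(r=r, p=p, Dmax=float(Dmax), Rg_real=rg_real,
                          I0_real=float(4.0 * np.pi * norm),
                          alpha=float(alpha), chi2=chi2)


def scan_dmax(profile: SAXSProfile, candidates, alpha: float | None = None,
              n_r: int = 101, plateau_tol: float = 0.05) -> DmaxScan:
    """Pick Dmax as the smallest candidate whose IFT chi^2 is within
    ``plateau_tol`` of the plateau of the chi^2-vs-Dmax curve."""
    candidates = np.asarray(sorted(candidates), dtype=float)
    if candidates.size < 2:
        raise InvalidParameterError("need at least two Dmax candidates")
    chi2 = np.array([ift_pr(profile, d, alpha=alpha, n_r=n_r).chi2
                     for d in candidates])
    plateau = float(np.min(chi2))
    ok = chi2 <= (1.0 + plateau_tol) * plateau
    chosen = float(candidates[np.nonzero(ok)[0][0]])
    # no plateau: the curve is still falling steeply at the last candidate
    ambiguous = bool(np.argmin(chi2) == chi2.size - 1
                     and chi2[-2] > (1.0 + plateau_tol) * chi2[-1])
    if ambiguous:
        warnings.warn("chi^2(Dmax) shows no plateau inside the candidate "
                      "range; Dmax is ambiguous", stacklevel=2)
    return DmaxScan(Dmax=chosen, candidates=candidates, chi2=chi2,
                    ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# volume of correlation
# ---------------------------------------------------------------------------

def vc_molecular_weight(profile: SAXSProfile, g: GuinierResult,
                        qmax: float | None = None,
                        rt_const: float = 0.1231,
                        rt_exponent: float = 1.0) -> VcResult:
    """Volume of correlation Vc = I0 / int q I dq and Rambo-Tainer MW.

    The published protein calibration (constants ``rt_const``/``rt_exponent``
    on Angstrom-based QR = Vc^2/Rg) gives MW in Da.  A tail carrying more
    than 5% of the integral flags non-convergence; the 20%-truncation
    sensitivity of the MW is always reported.
    """
    q, I = profile.q, profile.I
    if qmax is not None:
        keep = q <= qmax
        q, I = q[keep], I[keep]
    integrand = q * I

    def _vc(qv, iv):
        total = np.trapezoid(qv * iv, qv)
        return g.I0 / total, total

    vc_nm, total = _vc(q, I)
    # convergence: fraction of the integral in the last 10% of the q-range
    cut = q >= q[0] + 0.9 * (q[-1] - q[0])
    tail_frac = float(np.trapezoid(integrand[cut], q[cut]) / total)
    converged = tail_frac < 0.05
    if not converged:
        warnings.warn(f"int q I dq not converged (tail fraction "
                      f"{tail_frac:.1%}); Vc/MW are lower-bound estimates",
                      stacklevel=2)
    # Angstrom units for the calibration: q_A = q_nm / 10
    vc_A = vc_nm * 100.0
    qr_A = vc_A**2 / (g.Rg * 10.0)
    mw_da = (qr_A / rt_const) ** rt_exponent
    # sensitivity: recompute with the top 20% of the q-range removed
    keep = q <= q[0] + 0.8 * (q[-1] - q[0])
    vc_cut, _ = _vc(q[keep], I[keep])
    mw_cut = ((vc_cut * 100.0) ** 2 / (g.Rg * 10.0) / rt_const) ** rt_exponent
    sens = abs(mw_cut - mw_da) / mw_da
    return VcResult(Vc=float(vc_nm), QR=float(vc_nm**2 / g.Rg),
                    mw_kda=float(mw_da / 1000.0),
                    mw_sensitivity=float(sens), converged=converged)


# ---------------------------------------------------------------------------
# model-vs-experiment consistency
# ---------------------------------------------------------------------------

@dataclass
class ZTestResult:
    z: dict              # parameter -> z-score
    p: dict              # parameter -> two-sided p
    worst_parameter: str
    min_p: float
    combined_p: float    # Fisher combination
    consistent: bool     # min_p above the threshold


def model_consistency_z(model: dict, experimental: dict,
                        threshold: float = 0.05) -> ZTestResult:
    """Per-parameter z-test of model values against experimental (value, sd).

    ``experimental`` maps parameter name -> (value, sd).  Each z is
    (model - experimental)/sd with a two-sided normal p-value; the minimum-p
    parameter decides the consistency flag, and Fisher's method gives a
    combined p across parameters.
    """
    zs, ps = {}, {}
    for name, (val, sd) in experimental.items():
        if sd <= 0:
            raise InvalidParameterError(f"sd for {name!r} must be positive")
        z = (model[name] - val) / sd
        zs[name] = float(z)
        ps[name] = float(2.0 * stats.norm.sf(abs(z)))
    worst = min(ps, key=ps.get)
    chi2_stat = -2.0 * sum(np.log(max(p, 1e-300)) for p in ps.values())
    combined = float(stats.chi2.sf(chi2_stat, 2 * len(ps)))
    return ZTestResult(z=zs, p=ps, worst_parameter=worst, min_p=ps[worst],
                       combined_p=combined, consistent=ps[worst] > threshold)


def mw_from_standard(profile_I0: float, standard_I0: float,
                     standard_mw_da: float, conc_ratio: float = 1.0) -> float:
    """Forward-scattering ratio MW estimate against a user-supplied standard
    measured at known concentration (I0 proportional to c * MW)."""
    if standard_I0 <= 0 or standard_mw_da <= 0 or conc_ratio <= 0:
        raise InvalidParameterError("standard I0, MW and conc ratio must be "
                                    "positive")
    return standard_mw_da * (profile_I0 / standard_I0) / conc_ratio


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dat(path, q_unit: str = "nm") -> SAXSProfile:
    """Read a whitespace 3-column .dat (q, I, sigma; '#' comments).

    ``q_unit='A'`` converts Angstrom^-1 input to nm^-1."""
    data = np.loadtxt(path, comments="#")
    if data.ndim == 1:
        data = data[None, :]
    q = data[:, 0]
    if q_unit == "A":
        q = q * 10.0
    elif q_unit != "nm":
        raise InvalidParameterError("q_unit must be 'nm' or 'A'")
    sigma = data[:, 2] if data.shape[1] > 2 else None
    return SAXSProfile(q=q, I=data[:, 1], sigma=sigma,
                       metadata={"source": str(path), "q_unit_in": q_unit})


def write_dat(profile: SAXSProfile, path, header: str = ""):
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q_nm^-1  I  sigma\n")
        sig = profile.sigma if profile.sigma is not None \
            else np.zeros_like(profile.I)
        for qq, ii, ss in zip(profile.q, profile.I, sig):
            fh.write(f"{qq:.8g} {ii:.8g} {ss:.8g}\n")


def write_pr(pr: PrDistribution, path):
    """Two-column p(r) text plus a GNOM-like summary block."""
    with open(path, "w") as fh:
        fh.write("# real-space summary\n")
        fh.write(f"# Rg = {pr.Rg_real:.4f} nm   I0 = {pr.I0_real:.6g}   "
                 f"Dmax = {pr.Dmax:.3f} nm   alpha = {pr.alpha:.3g}\n")
        fh.write("# r_nm  p\n")
        for rr, pp in zip(pr.r, pr.p):
            fh.write(f"{rr:.6f} {pp:.8g}\n")
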