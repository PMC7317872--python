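"""Time-resolved fluorescence anisotropy.

Polarized decays I_par(t), I_perp(t) are combined into the anisotropy
r(t) = (I_par - G I_perp) / (I_par + 2 G I_perp) and fitted to the
biexponential rotational model

    r(t) = r0 [ A1 exp(-t/phi1) + A2 exp(-t/phi2) ],   A1 + A2 = 1,

where the fast correlation time phi1 reports local fluorophore motion and
the slow phi2 whole-molecule tumbling.  Times are in ns.

A convention switch reproduces the perpendicular-minus-parallel variant of
the anisotropy ratio; the standard parallel-minus-perpendicular form is the
default because only it yields positive anisotropy for polarized emission.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import DegenerateInputError, InvalidParameterError

#: fundamental anisotropy upper bound for one-photon excitation
R0_LIMIT = 0.4


@dataclass
class PolarizedDecay:
    """Parallel/perpendicular emission decays with G correction factor."""

    t: np.ndarray        # ns
    I_par: np.ndarray
    I_perp: np.ndarray
    G: float = 1.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.I_par = np.asarray(self.I_par, dtype=float)
        self.I_perp = np.asarray(self.I_perp, dtype=float)
        if not (len(self.t) == len(self.I_par) == len(self.I_perp)):
            raise InvalidParameterError("array lengths must match")
        if np.any(np.diff(self.t) <= 0):
            raise InvalidParameterError("time axis must be strictly increasing")
        if self.G <= 0:
            raise InvalidParameterError("G factor must be positive")


@dataclass
class AnisotropyFit:
    """Biexponential anisotropy parameters, phi1 < phi2 (ns)."""

    r0: float
    A1: float
    A2: float
    phi1: float
    phi2: float
    residual_rms: float
    mono_fallback: bool = False
    r0_exceeds_limit: bool = False

    def r_model(self, t):
        t = np.asarray(t, dtype=float)
        return self.r0 * (self.A1 * np.exp(-t / self.phi1)
                          + self.A2 * np.exp(-t / self.phi2))

    def summary(self) -> str:
        lines = ["Time-resolved anisotropy fit"]
        if self.mono_fallback:
            lines.append("  (ill-conditioned biexponential; "
                         "monoexponential fallback)")
        lines += [f"  r0   = {self.r0:.4f}"
                  + ("  [exceeds fundamental limit 0.4]" if self.r0_exceeds_limit else ""),
                  f"  A1   = {self.A1:.3f}  phi1 = {self.phi1:.4g} ns (fast, local)",
                  f"  A2   = {self.A2:.3f}  phi2 = {self.phi2:.4g} ns (slow, global)",
                  f"  rms residual = {self.residual_rms:.2e}"]
        return "\n".join(lines) + "\n"


def anisotropy_curve(decay: PolarizedDecay, convention: str = "standard",
                     intensity_threshold: float | None = None):
    """Anisotropy r(t) from polarized decays; low-intensity points masked.

    ``convention='standard'`` computes (I_par - G I_perp)/(I_par + 2 G I_perp);
    ``'perpendicular'`` computes the transposed ratio
    (I_perp - G I_par)/(I_perp + 2 G I_par).  Points whose total intensity
    falls below ``intensity_threshold`` (default: 1% of the maximum) are
    dropped.  Returns ``(t, r)`` over the retained points.
    """
    if convention == "standard":
        num = decay.I_par - decay.G * decay.I_perp
        den = decay.I_par + 2.0 * decay.G * decay.I_perp
    elif convention == "perpendicular":
        num = decay.I_perp - decay.G * decay.I_par
        den = decay.I_perp + 2.0 * decay.G * decay.I_par
    else:
        raise InvalidParameterError(f"unknown convention {convention!r}")
    total = decay.I_par + 2.0 * decay.G * decay.I_perp
    if intensity_threshold is None:
        intensity_threshold = 0.01 * float(np.max(total))
    keep = (total > intensity_threshold) & (den > 0)
    if not np.any(keep):
        raise DegenerateInputError("all points fall below the intensity "
                                   "threshold")
    return decay.t[keep], num[keep] / den[keep]


def _biexp(t, r0, a1, phi1, phi2):
    return r0 * (a1 * np.exp(-t / phi1) + (1.0 - a1) * np.exp(-t / phi2))


def fit_biexponential(r_t, t, fix_r0: float | None = None,
                      min_ratio: float = 3.0) -> AnisotropyFit:
    """Nonlinear least squares of the biexponential anisotropy model.

    A1 + A2 = 1 is enforced by parameterization.  When the two correlation
    times are not separable (phi2/phi1 < ``min_ratio``) or the fit fails,
    a monoexponential fallback is returned with a warning.  An r(0) above
    the fundamental 0.4 bound is flagged, never clamped.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(r_t, dtype=float)
    if t.size < 20:
        raise InvalidParameterError("need at least 20 valid points")
    span = t[-1] - t[0]
    r0_guess = fix_r0 if fix_r0 is not None else max(float(r[0]), 1e-3)

    # tail slope for the slow time, decade split for the fast one
    phi2_0 = max(span / 3.0, 1e-3)
    tail = slice(max(t.size // 2, t.size - 200), None)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = r[tail] > 0
        if np.count_nonzero(pos) > 5:
            sl = np.polyfit(t[tail][pos], np.log(r[tail][pos]), 1)[0]
            if sl < 0:
                phi2_0 = min(max(-1.0 / sl, 1e-3), 50 * span)
    phi1_0 = max(phi2_0 / 10.0, t[1] - t[0])

    def model(tt, *theta):
        if fix_r0 is None:
            return _biexp(tt, theta[0], theta[1], theta[2], theta[3])
        return _biexp(tt, fix_r0, theta[0], theta[1], theta[2])

    if fix_r0 is None:
        p0 = [r0_guess, 0.5, phi1_0, phi2_0]
        bounds = ([0.0, 0.0, 1e-6, 1e-6], [1.5, 1.0, 100 * span, 1000 * span])
    else:
        p0 = [0.5, phi1_0, phi2_0]
        bounds = ([0.0, 1e-6, 1e-6], [1.0, 100 * span, 1000 * span])

    def _mono():
        def mono_model(tt, r0m, phi):
            return r0m * np.exp(-tt / phi)
        if fix_r0 is None:
            popt, _ = optimize.curve_fit(mono_model, t, r,
                                         p0=[r0_guess, phi2_0], maxfev=20000)
            r0m, phi = popt
        else:
            popt, _ = optimize.curve_fit(
                lambda tt, phi: mono_model(tt, fix_r0, phi), t, r,
                p0=[phi2_0], maxfev=20000)
            r0m, phi = fix_r0, popt[0]
        rms = float(np.sqrt(np.mean((mono_model(t, r0m, phi) - r) ** 2)))
        return AnisotropyFit(float(r0m), 1.0, 0.0, float(phi), float(phi),
                             rms, mono_fallback=True,
                             r0_exceeds_limit=r0m > R0_LIMIT)

    try:
        popt, _ = optimize.curve_fit(model, t, r, p0=p0, bounds=bounds,
                                     maxfev=40000)
    except RuntimeError:
        warnings.warn("biexponential fit did not converge; monoexponential "
                      "fallback", stacklevel=2)
        return _mono()

    if fix_r0 is None:
        r0, a1, phi1, phi2 = popt
    else:
        r0 = fix_r0
        a1, phi1, phi2 = popt
    if phi1 > phi2:  # order fast < slow
        phi1, phi2 = phi2, phi1
        a1 = 1.0 - a1
    if phi2 / phi1 < min_ratio:
        warnings.warn("correlation times not separable (phi2/phi1 < "
                      f"{min_ratio}); monoexponential fallback", stacklevel=2)
        return _mono()
    rms = float(np.sqrt(np.mean((_biexp(t, r0, a1, phi1, phi2) - r) ** 2)))
    return AnisotropyFit(float(r0), float(a1), float(1.0 - a1), float(phi1),
                         float(phi2), rms,
                         r0_exceeds_limit=r0 > R0_LIMIT)


class AnisotropyDecayModel:
    """Model: polarized decay -> anisotropy curve -> rotational times."""

    def __init__(self, decay: PolarizedDecay, convention: str = "standard"):
        self.decay = decay
        self.convention = convention

    def anisotropy(self, **kw):
        return anisotropy_curve(self.decay, self.convention, **kw)

    def fit(self, t_start: float = 0.0, fix_r0: float | None = None,
            **kw) -> AnisotropyFit:
        t, r = self.anisotropy(**kw)
        keep = t >= t_start
        return fit_biexponential(r[keep], t[keep], fix_r0=fix_r0)


def read_polarized_csv(path, G: float = 1.0) -> PolarizedDecay:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return PolarizedDecay(t=data[:, 0], I_par=data[:, 1], I_perp=data[:, 2],
                          G=G)


def write_polarized_csv(decay: PolarizedDecay, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ns", "I_par", "I_perp"])
        for row in zip(decay.t, decay.I_par, decay.I_perp):
            w.writerow([f"{v:.8g}" for v in row])
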