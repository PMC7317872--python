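"""Sedimentation-equilibrium analysis of a monomer-dimer association.

At equilibrium in the centrifuge each species follows a Boltzmann
exponential in r^2 with reduced buoyant molar mass

    sigma_i = M_i (1 - vbar rho) omega^2 / (R T)      [cm^-2],

and mass action couples the dimer to the monomer everywhere in the cell,
c_d(r) = c_m(r)^2 / K_D.  The absorbance model for one scan is

    A(r) = eps_l c_m,ref exp[sigma_m (r^2 - r_ref^2)/2]
         + 2 eps_l (c_m,ref^2 / K_D) exp[sigma_m (r^2 - r_ref^2)]
         + baseline,

with r_ref at the meniscus and the factor 2 because a dimer carries two
chromophores.  A global fit over several rotor speeds shares K_D while the
reference concentration and baseline float per scan; the K_D confidence
interval comes from the profile of the residual sum of squares.

Units: r in cm, omega in rad/s, concentrations molar, absorbance AU,
``eps_l`` = extinction coefficient x path length in AU per molar.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import FitFailureError, InvalidParameterError

#: gas constant in CGS units, erg / (mol K) -- consistent with r in cm
R_GAS_CGS = 8.31446261815324e7


def rpm_to_omega(rpm: float) -> float:
    """Rotor speed conversion rpm -> rad/s."""
    return rpm * 2.0 * np.pi / 60.0


@dataclass(frozen=True)
class SpeciesParams:
    """Monomer species: molar mass M (Da), partial specific volume vbar
    (mL/g), solvent density rho (g/mL), extinction x pathlength (AU/M)."""

    M: float
    vbar: float = 0.73
    rho: float = 1.0
    eps_l: float = 14400.0

    def __post_init__(self):
        if self.M <= 0:
            raise InvalidParameterError("molar mass must be positive")
        if not 0 < self.vbar * self.rho < 1:
            raise InvalidParameterError(
                "vbar*rho must lie in (0, 1); species would float otherwise")
        if self.eps_l <= 0:
            raise InvalidParameterError("eps_l must be positive")


@dataclass
class RadialScan:
    """Absorbance-vs-radius profile at one rotor speed."""

    r: np.ndarray          # cm
    A: np.ndarray          # AU
    omega: float           # rad/s
    T: float = 293.15      # K
    meniscus: float = 6.9  # cm
    bottom: float = 7.2    # cm

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.r.shape != self.A.shape:
            raise InvalidParameterError("r and A must match in length")
        if self.omega < 0:
            raise InvalidParameterError("omega must be >= 0")
        if self.meniscus >= self.bottom:
            raise InvalidParameterError("meniscus must lie below bottom")


@dataclass
class EquilibriumFit:
    """Global monomer-dimer fit: shared K_D plus per-scan nuisances."""

    KD: float                   # molar
    KD_ci: tuple                # (low, high) molar; np.inf for open bounds
    c_mono_ref: list            # per-scan reference monomer conc., molar
    baselines: list             # per-scan, AU
    rms: float                  # global residual RMS, AU
    no_association: bool = False
    n_scans: int = 0

    def summary(self) -> str:
        lo, hi = self.KD_ci
        lines = [f"Sedimentation-equilibrium global fit ({self.n_scans} scans)"]
        if self.no_association:
            lines.append("  no association detected (K_D at upper boundary)")
        lines += [f"  K_D  = {self.KD * 1e6:.3g} uM  "
                  f"[{lo * 1e6:.3g}, {hi * 1e6:.3g}] uM (95% profile CI)",
                  f"  rms  = {self.rms:.2e} AU"]
        return "\n".join(lines) + "\n"


def reduced_buoyant_term(species: SpeciesParams, omega: float,
                         T: float = 293.15) -> float:
    """sigma = M (1 - vbar rho) omega^2 / (R T), in cm^-2."""
    if omega < 0:
        raise InvalidParameterError("omega must be >= 0")
    return species.M * (1.0 - species.vbar * species.rho) * omega**2 \
        / (R_GAS_CGS * T)


def se_profile(c_mono_ref: float, KD: float, species: SpeciesParams,
               r, omega: float, T: float = 293.15, baseline: float = 0.0,
               r_ref: float | None = None):
    """Two-species Boltzmann absorbance profile A(r) (see module docstring).

    ``r_ref`` defaults to the first radius supplied (the meniscus when the
    grid starts there)."""
    if c_mono_ref <= 0 or KD <= 0:
        raise InvalidParameterError("c_mono_ref and KD must be positive")
    r = np.asarray(r, dtype=float)
    if r_ref is None:
        r_ref = float(r[0])
    sigma = reduced_buoyant_term(species, omega, T)
    expo = sigma * (r**2 - r_ref**2) / 2.0
    if np.any(expo > 700):
        raise OverflowError(
            "exponent overflow in se_profile: rescale the radial window or "
            "reduce the rotor speed")
    mono = c_mono_ref * np.exp(expo)
    dimer = (c_mono_ref**2 / KD) * np.exp(2.0 * expo)
    return species.eps_l * (mono + 2.0 * dimer) + baseline


def _pack_residuals(theta, scans, species):
    """theta = [ln KD, (ln c_ref_i, baseline_i) per scan]."""
    KD = np.exp(theta[0])
    res = []
    for i, scan in enumerate(scans):
        c_ref = np.exp(theta[1 + 2 * i])
        base = theta[2 + 2 * i]
        model = se_profile(c_ref, KD, species, scan.r, scan.omega, scan.T,
                           baseline=base, r_ref=scan.meniscus)
        res.append(model - scan.A)
    return np.concatenate(res)


def _fit_at_kd(ln_kd, scans, species, x0_nuis):
    """Optimize per-scan nuisances with K_D fixed; returns (SSR, nuisances)."""
    def resid(nuis):
        return _pack_residuals(np.concatenate([[ln_kd], nuis]), scans, species)
    sol = optimize.least_squares(resid, x0_nuis, xtol=1e-12, ftol=1e-12)
    return float(np.sum(sol.fun**2)), sol.x


def global_fit_se(scans, species: SpeciesParams, kd_init: float | None = None,
                  ci: bool = True, kd_max: float = 1.0) -> EquilibriumFit:
    """Global nonlinear least squares over scans at distinct rotor speeds.

    K_D is shared; monomer reference concentration and baseline float per
    scan (meniscus and bottom are fixed geometry).  The 95% confidence
    interval is a profile over log10 K_D at Delta-chi2 = 3.84 with the
    residual variance estimated at the optimum.  A K_D running into
    ``kd_max`` (default 1 M) is reported as a no-association outcome.
    """
    scans = list(scans)
    if len(scans) < 2:
        raise InvalidParameterError("need at least 2 scans at distinct speeds")
    if len({round(s.omega, 6) for s in scans}) < 2:
        raise InvalidParameterError("scans must be at distinct rotor speeds")

    # crude concentration scale from the mean signal
    a_mean = max(float(np.mean([np.mean(s.A) for s in scans])), 1e-6)
    c_scale = a_mean / species.eps_l
    nuis0 = []
    for _ in scans:
        nuis0 += [np.log(max(c_scale / 2, 1e-12)), 0.0]
    nuis0 = np.array(nuis0)

    # coarse K_D grid start, then full refinement
    if kd_init is None:
        grid = np.log(np.array([1e-7, 1e-6, 1e-5, 1e-4, 1e-3]))
        ssrs = [(_fit_at_kd(lk, scans, species, nuis0)[0], lk) for lk in grid]
        ln_kd0 = min(ssrs)[1]
    else:
        ln_kd0 = np.log(kd_init)

    def resid(theta):
        return _pack_residuals(theta, scans, species)

    x0 = np.concatenate([[ln_kd0], nuis0])
    sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise FitFailureError("global SE fit did not converge",
                              diagnostics={"status": sol.status})
    ln_kd = float(sol.x[0])
    KD = float(np.exp(ln_kd))
    n_tot = sum(s.r.size for s in scans)
    ssr_min = float(np.sum(sol.fun**2))
    dof = n_tot - sol.x.size
    s2 = ssr_min / max(dof, 1)
    rms = float(np.sqrt(ssr_min / n_tot))
    c_refs = [float(np.exp(sol.x[1 + 2 * i])) for i in range(len(scans))]
    bases = [float(sol.x[2 + 2 * i]) for i in range(len(scans))]

    no_assoc = KD >= kd_max
    kd_ci = (np.nan, np.nan)
    if ci:
        # profile-likelihood bounds: root of Delta-SSR(ln KD) = 3.84 s^2
        nuis_hat = sol.x[1:]
        thresh = 3.84 * s2
        max_span = 3.0 * np.log(10.0)

        def dssr(lk):
            return _fit_at_kd(lk, scans, species, nuis_hat)[0] - ssr_min

        def bound(direction):
            step = 0.05
            prev = ln_kd
            while step <= max_span:
                lk = ln_kd + direction * step
                if dssr(lk) > thresh:
                    return float(optimize.brentq(
                        lambda z: dssr(z) - thresh, min(prev, lk),
                        max(prev, lk), xtol=1e-4))
                prev = lk
                step *= 2.0
            return direction * np.inf

        lo, hi = bound(-1.0), bound(+1.0)
        kd_ci = (float(np.exp(lo)) if np.isfinite(lo) else 0.0,
                 float(np.exp(hi)) if np.isfinite(hi) else np.inf)
        if not np.isfinite(hi):
            no_assoc = True
    return EquilibriumFit(KD, kd_ci, c_refs, bases, rms,
                          no_association=no_assoc, n_scans=len(scans))


class MonomerDimerSE:
    """Model: radial scans + species -> global K_D estimate."""

    def __init__(self, scans, species: SpeciesParams):
        self.scans = list(scans)
        self.species = species

    def fit(self, **kw) -> EquilibriumFit:
        return global_fit_se(self.scans, self.species, **kw)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_radial_scan(scan: RadialScan, path, wavelength_nm: float = 280.0):
    rpm = scan.omega * 60.0 / (2.0 * np.pi)
    with open(path, "w", newline="") as fh:
        fh.write(f"# rotor_speed_rpm={rpm:.1f} wavelength_nm={wavelength_nm} "
                 f"T_K={scan.T} meniscus_cm={scan.meniscus} "
                 f"bottom_cm={scan.bottom}\n")
        w = csv.writer(fh)
        w.writerow(["radius_cm", "absorbance_AU"])
        for rr, aa in zip(scan.r, scan.A):
            w.writerow([f"{rr:.6f}", f"{aa:.6f}"])


def read_radial_scan(path) -> RadialScan:
    meta = {}
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#").split()
        for tok in header:
            if "=" in tok:
                k, v = tok.split("=")
                meta[k] = float(v)
    data = np.loadtxt(path, delimiter=",", skiprows=2)
    return RadialScan(r=data[:, 0], A=data[:, 1],
                      omega=rpm_to_omega(meta.get("rotor_speed_rpm", 0.0)),
                      T=meta.get("T_K", 293.15),
                      meniscus=meta.get("meniscus_cm", float(data[0, 0])),
                      bottom=meta.get("bottom_cm", float(data[-1, 0])))
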