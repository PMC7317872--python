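"""Synthetic data generators for every analysis stage.

Each generator reproduces the statistical structure the corresponding
analysis assumes -- Bell-Evans rupture statistics on FJC (PEG) tethers,
two-species Boltzmann sedimentation-equilibrium gradients, smFRET traces
with single-step acceptor photobleaching, biexponential anisotropy decays,
and analytic sphere/rod scattering profiles -- so that every stage of the
pipeline can be validated by parameter recovery against planted ground
truth.  All generators are deterministic for a fixed seed.

Noise is Gaussian throughout (a shot-noise approximation consistent with
the least-squares estimators downstream).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aucse import RadialScan, SpeciesParams, reduced_buoyant_term, se_profile
from .anisotropy import PolarizedDecay
from .exceptions import InvalidParameterError
from .fret import FRETTrace
from .saxs import SAXSProfile
from .smfs import (
    KBT_ROOM,
    BellEvansParams,
    FJCParams,
    ForceCurve,
    PullingConfig,
    effective_loading_rate,
    fjc_compliance,
    fjc_extension,
)

#: the seven pulling speeds of the reference experiment, nm/s
DEFAULT_PULL_SPEEDS = (500.0, 750.0, 2000.0, 5000.0, 7500.0, 10000.0, 15000.0)

#: PEG tether default: two 5-kDa PEGs in series (contour length from the
#: reference experiment; 0.7 nm is a literature-typical PEG Kuhn length)
DEFAULT_TETHER = FJCParams(Lc=58.7, kuhn=0.7)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Bell-Evans rupture statistics
# ---------------------------------------------------------------------------

def rupture_force_pdf(F, params: BellEvansParams, loading_rate: float):
    """First-passage density of rupture forces under a constant loading rate:

    p(F) = (koff/r) e^(F x_beta/kBT) exp[-(koff kBT/(r x_beta))
           (e^(F x_beta/kBT) - 1)]
    """
    if loading_rate <= 0:
        raise InvalidParameterError("loading rate must be positive")
    F = np.asarray(F, dtype=float)
    beta = params.x_beta / params.kBT
    a = params.koff / (loading_rate * beta)
    e = np.exp(np.clip(beta * F, None, 700))
    return params.koff / loading_rate * e * np.exp(-a * (e - 1.0))


def rupture_force_cdf(F, params: BellEvansParams, loading_rate: float):
    """Closed-form CDF 1 - exp[-(koff kBT/(r x_beta)) (e^(F x_beta/kBT)-1)]."""
    if loading_rate <= 0:
        raise InvalidParameterError("loading rate must be positive")
    F = np.asarray(F, dtype=float)
    beta = params.x_beta / params.kBT
    a = params.koff / (loading_rate * beta)
    e = np.exp(np.clip(beta * F, None, 700))
    return 1.0 - np.exp(-a * (e - 1.0))


def most_probable_rupture_force(params: BellEvansParams,
                                loading_rate: float) -> float:
    """Analytic mode (kBT/x_beta) ln(r x_beta tau0 / kBT), floored at 0."""
    arg = loading_rate * params.x_beta * params.tau0 / params.kBT
    if arg <= 1.0:
        return 0.0
    return params.kBT / params.x_beta * float(np.log(arg))


def sample_rupture_forces(params: BellEvansParams, loading_rate: float,
                          n: int, seed=0):
    """Inverse-CDF sampling of i.i.d. rupture forces (pN).

    F = (kBT/x_beta) ln[1 - ln(1-u) r x_beta/(koff kBT)] for u ~ U(0,1).
    """
    if loading_rate <= 0:
        raise InvalidParameterError("loading rate must be positive")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = _rng(seed)
    u = rng.random(n)
    beta = params.x_beta / params.kBT
    a = params.koff / (loading_rate * beta)
    return np.log1p(-np.log1p(-u) / a) / beta


def state_loading_rate(params: BellEvansParams, tether: FJCParams,
                       pull: PullingConfig, kBT: float = KBT_ROOM,
                       tol: float = 1e-10, max_iter: int = 200):
    """Self-consistent loading rate of one bound state.

    Iterates r <- vF(F*(r)) where F* is the analytic most-probable rupture
    force and vF the tether-corrected loading rate, starting from the bare
    cantilever rate kc*v.  Returns ``(r, F_mode)``.
    """
    r = pull.kc * pull.v
    F = max(most_probable_rupture_force(params, r), 1.0)
    for _ in range(max_iter):
        r_new = float(effective_loading_rate(F, pull, tether, kBT))
        F_new = max(most_probable_rupture_force(params, r_new), 1.0)
        if abs(r_new - r) <= tol * r:
            return r_new, F_new
        r, F = r_new, F_new
    return r, F


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

def _force_vs_displacement(d, tether: FJCParams, kc: float, kBT: float,
                           F_hint_max: float):
    """Solve l(F) + F/kc = d for F, vectorized (grid + Newton refinement)."""
    grid = np.geomspace(1e-4, max(2.0 * F_hint_max, 10.0), 3000)
    d_of_F = fjc_extension(grid, tether, kBT) + grid / kc
    F = np.interp(d, d_of_F, grid)
    for _ in range(5):
        g = fjc_extension(F, tether, kBT) + F / kc - d
        dg = fjc_compliance(F, tether, kBT) + 1.0 / kc
        F = np.maximum(F - g / dg, 0.0)
    return F


def make_force_curve(tether: FJCParams, pull: PullingConfig,
                     rupture_force: float, kBT: float = KBT_ROOM, seed=0,
                     total_distance: float = 200.0, curve_id: str = "") -> ForceCurve:
    """One retract trace: FJC stretch up to the planted rupture force, a
    sharp drop to baseline, Gaussian force noise.

    The tip displacement v*t is shared between tether extension l(F) and
    cantilever deflection F/kc; the recorded extension axis is the
    tip-sample separation l(F).  A sample is placed exactly at the rupture
    point so the last above-baseline force equals ``rupture_force`` up to
    noise."""
    if rupture_force <= 0:
        raise InvalidParameterError("rupture force must be positive")
    rng = _rng(seed)
    d_rup = float(fjc_extension(rupture_force, tether, kBT)
                  + rupture_force / pull.kc)
    if not np.isfinite(d_rup) or d_rup >= total_distance:
        raise InvalidParameterError(
            "rupture force beyond the numeric FJC range of the ramp")
    step = pull.v / pull.sampling_rate
    d = np.arange(0.0, total_distance, step)
    if d.size < 50:
        d = np.linspace(0.0, total_distance, 50)
    cut = int(np.searchsorted(d, d_rup))
    d = np.insert(d, cut, d_rup)
    force = np.zeros_like(d)
    pre = slice(0, cut + 1)
    force[pre] = _force_vs_displacement(d[pre], tether, pull.kc, kBT,
                                        rupture_force)
    force[cut] = rupture_force  # exact at the inserted rupture sample
    extension = d - force / pull.kc
    if pull.noise_sd > 0:
        force = force + rng.normal(0.0, pull.noise_sd, size=force.size)
    return ForceCurve(extension=extension, force=force, v=pull.v, kc=pull.kc,
                      id=curve_id, sampling_rate=pull.sampling_rate)


def make_baseline_curve(pull: PullingConfig, seed=0,
                        total_distance: float = 200.0,
                        curve_id: str = "") -> ForceCurve:
    """A no-event retract trace: pure force noise around zero."""
    rng = _rng(seed)
    step = pull.v / pull.sampling_rate
    d = np.arange(0.0, total_distance, step)
    if d.size < 50:
        d = np.linspace(0.0, total_distance, 50)
    force = rng.normal(0.0, max(pull.noise_sd, 1e-12), size=d.size)
    return ForceCurve(extension=d, force=force, v=pull.v, kc=pull.kc,
                      id=curve_id, sampling_rate=pull.sampling_rate)


@dataclass(frozen=True)
class MixtureSpec:
    """One or two Bell-Evans bound states with mixture weights."""

    states: tuple  # ((BellEvansParams, weight), ...)

    def __post_init__(self):
        if not 1 <= len(self.states) <= 2:
            raise InvalidParameterError("1 or 2 states supported")
        wsum = sum(w for _, w in self.states)
        if any(not 0 < w <= 1 for _, w in self.states) or abs(wsum - 1) > 1e-6:
            raise InvalidParameterError("weights must lie in (0,1] and sum to 1")


def make_dfs_dataset(mix: MixtureSpec, tether: FJCParams, pulls,
                     n_per_speed: int, event_fraction: float = 0.08,
                     seed=0, kBT: float = KBT_ROOM):
    """A dynamic-force-spectroscopy campaign across pulling speeds.

    Per pulling configuration, ``n_per_speed`` retract curves of which a
    binomial fraction ``event_fraction`` contain a rupture event; the bound
    state of each event is drawn from the mixture weights and the rupture
    force from the Bell-Evans first-passage law at the state's
    self-consistent loading rate.  The rest are no-event baselines.
    """
    pulls = list(pulls)
    if not pulls:
        raise InvalidParameterError("empty pulls list")
    if not 0 < event_fraction <= 1:
        raise InvalidParameterError("event_fraction must lie in (0, 1]")
    rng = _rng(seed)
    weights = np.array([w for _, w in mix.states])
    curves = []
    for pull in pulls:
        rates = [state_loading_rate(p, tether, pull, kBT)[0]
                 for p, _ in mix.states]
        n_events = rng.binomial(n_per_speed, event_fraction)
        for i in range(n_per_speed):
            cid = f"v{pull.v:g}_{i:05d}"
            if i < n_events:
                k = rng.choice(len(mix.states), p=weights)
                F = float(sample_rupture_forces(mix.states[k][0], rates[k],
                                                1, rng)[0])
                try:
                    curves.append(make_force_curve(tether, pull, F, kBT, rng,
                                                   curve_id=cid))
                    continue
                except InvalidParameterError:
                    pass  # unresolvably small/large force: emit a baseline
            curves.append(make_baseline_curve(pull, rng, curve_id=cid))
    return curves


def write_force_curves(curves, directory):
    """Write curves as two-column TSVs plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "pulling_speed_nm_s", "spring_constant_pN_nm",
                    "sampling_rate_hz"])
        for i, c in enumerate(curves):
            name = f"curve_{i:06d}.tsv"
            np.savetxt(directory / name,
                       np.column_stack([c.extension, c.force]),
                       fmt="%.6f", delimiter="\t",
                       header="extension_nm\tforce_pN")
            w.writerow([name, c.v, c.kc, c.sampling_rate])


# ---------------------------------------------------------------------------
# sedimentation equilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SEGroundTruth:
    """Planted monomer-dimer equilibrium for synthetic radial scans."""

    KD: float                   # molar
    M_monomer: float            # Da
    vbar: float = 0.73          # mL/g
    rho: float = 1.0            # g/mL
    c_load: float = 36e-6       # molar (monomer equivalents)
    speeds: tuple = ()          # rad/s
    r_range: tuple = (6.9, 7.2)  # (meniscus, bottom), cm
    eps_l: float = 14400.0      # AU per molar
    T: float = 293.15
    baseline: float = 0.0

    def __post_init__(self):
        if self.KD <= 0 or self.M_monomer <= 0 or self.c_load <= 0:
            raise InvalidParameterError("KD, M_monomer, c_load must be positive")
        if not 0 < self.vbar * self.rho < 1:
            raise InvalidParameterError("vbar*rho must lie in (0,1)")
        if self.r_range[0] >= self.r_range[1]:
            raise InvalidParameterError("meniscus must lie below bottom")

    @property
    def species(self) -> SpeciesParams:
        return SpeciesParams(M=self.M_monomer, vbar=self.vbar, rho=self.rho,
                             eps_l=self.eps_l)


def _conserved_c_ref(truth: SEGroundTruth, omega: float) -> float:
    """Meniscus monomer concentration honouring mass conservation.

    The radially averaged monomer-equivalent concentration over the
    sector-shaped cell, (int (c_m + 2 c_d) r dr)/(int r dr), equals the
    loading concentration."""
    from scipy.optimize import brentq

    men, bot = truth.r_range
    r = np.linspace(men, bot, 400)
    sigma = reduced_buoyant_term(truth.species, omega, truth.T)
    e1 = np.exp(sigma * (r**2 - men**2) / 2.0)
    denom = np.trapezoid(r, r)

    def avg_minus_load(c_ref):
        c = c_ref * e1 + 2.0 * c_ref**2 / truth.KD * e1**2
        return np.trapezoid(c * r, r) / denom - truth.c_load

    hi = truth.c_load
    while avg_minus_load(hi) < 0:
        hi *= 2.0
    return brentq(avg_minus_load, truth.c_load * 1e-12, hi, xtol=1e-18,
                  rtol=1e-13)


def make_se_scans(truth: SEGroundTruth, n_points: int = 80,
                  noise_sd_AU: float = 0.005, seed=0):
    """Synthetic radial scans, one per rotor speed, following the two-species
    Boltzmann model exactly plus Gaussian absorbance noise."""
    if n_points < 20:
        raise InvalidParameterError("need at least 20 points per scan")
    rng = _rng(seed)
    men, bot = truth.r_range
    scans = []
    for omega in truth.speeds:
        r = np.linspace(men, bot, n_points)
        c_ref = _conserved_c_ref(truth, omega)
        A = se_profile(c_ref, truth.KD, truth.species, r, omega, truth.T,
                       baseline=truth.baseline, r_ref=men)
        if noise_sd_AU > 0:
            A = A + rng.normal(0.0, noise_sd_AU, size=A.size)
        scans.append(RadialScan(r=r, A=A, omega=omega, T=truth.T,
                                meniscus=men, bottom=bot))
    return scans


# ---------------------------------------------------------------------------
# smFRET traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FRETGroundTruth:
    """Planted efficiency and photophysics for synthetic trace pairs."""

    E_true: float
    I_total: float = 500.0      # mean total photons per frame
    n_frames: float = 150.0     # mean pre-bleach length (frames)
    noise_sd: float | None = None  # per-channel sd; None = sqrt(mean signal)
    background: float = 30.0
    n_total: int = 400          # frames recorded
    dt: float = 1.0             # s per frame

    def __post_init__(self):
        if not 0.0 <= self.E_true <= 1.0:
            raise InvalidParameterError("E_true must lie in [0, 1]")
        if self.I_total <= 0 or self.n_frames <= 1:
            raise InvalidParameterError("I_total and n_frames must be positive")


def make_fret_traces(truth: FRETGroundTruth, n_traces: int, seed=0):
    """Donor/acceptor trace pairs with single-step acceptor photobleaching.

    Pre-bleach means: acceptor E*I_total, donor (1-E)*I_total (total
    conserved); the bleach frame is geometric with the requested mean, after
    which the acceptor falls to background and the donor rises to I_total
    (anticorrelated step).  Gaussian noise approximates shot noise."""
    rng = _rng(seed)
    traces = []
    t = np.arange(truth.n_total) * truth.dt
    for i in range(n_traces):
        bleach = int(np.clip(rng.geometric(1.0 / truth.n_frames), 12,
                             truth.n_total - 5))
        a_mean = np.where(np.arange(truth.n_total) < bleach,
                          truth.E_true * truth.I_total, 0.0) + truth.background
        d_mean = np.where(np.arange(truth.n_total) < bleach,
                          (1.0 - truth.E_true) * truth.I_total,
                          truth.I_total) + truth.background
        sd_a = truth.noise_sd if truth.noise_sd is not None \
            else np.sqrt(np.maximum(a_mean, 1.0))
        sd_d = truth.noise_sd if truth.noise_sd is not None \
            else np.sqrt(np.maximum(d_mean, 1.0))
        traces.append(FRETTrace(
            time=t,
            donor=d_mean + rng.normal(0.0, 1.0, truth.n_total) * sd_d,
            acceptor=a_mean + rng.normal(0.0, 1.0, truth.n_total) * sd_a,
            bg_donor=truth.background, bg_acceptor=truth.background,
            trace_id=f"trace_{i:04d}"))
    return traces


# ---------------------------------------------------------------------------
# anisotropy decays
# ---------------------------------------------------------------------------

def make_anisotropy_decay(r0: float, A1: float, phi1: float, A2: float,
                          phi2: float, t_grid, noise_sd: float = 0.0, seed=0,
                          I0: float = 1e4, tau_fl: float = 3.0) -> PolarizedDecay:
    """Polarized decay pair consistent with the biexponential anisotropy
    r(t) = r0 [A1 e^(-t/phi1) + A2 e^(-t/phi2)] and a monoexponential total
    intensity I(t) = I0 e^(-t/tau_fl):

        I_par = I (1 + 2 r)/3,    I_perp = I (1 - r)/3.

    Channel noise is Gaussian with sd ``noise_sd * I(t)``, which keeps the
    anisotropy noise roughly constant in time."""
    t = np.asarray(t_grid, dtype=float)
    rng = _rng(seed)
    r = r0 * (A1 * np.exp(-t / phi1) + A2 * np.exp(-t / phi2))
    I_tot = I0 * np.exp(-t / tau_fl)
    par = I_tot * (1.0 + 2.0 * r) / 3.0
    perp = I_tot * (1.0 - r) / 3.0
    if noise_sd > 0:
        par = par + rng.normal(0.0, noise_sd, t.size) * I_tot
        perp = perp + rng.normal(0.0, noise_sd, t.size) * I_tot
    return PolarizedDecay(t=t, I_par=par, I_perp=perp, G=1.0)


# ---------------------------------------------------------------------------
# SAXS profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereModel:
    """Homogeneous sphere: analytic oracle for the SAXS stage."""

    R: float                    # nm
    I0: float = 1.0
    q_grid: tuple | np.ndarray = ()
    noise_frac: float = 0.0

    def __post_init__(self):
        if self.R <= 0 or self.I0 <= 0 or self.noise_frac < 0:
            raise InvalidParameterError("R and I0 must be positive, "
                                        "noise_frac >= 0")
        q = np.asarray(self.q_grid, dtype=float)
        if q.size and (np.any(q <= 0) or np.any(np.diff(q) <= 0)):
            raise InvalidParameterError("q grid must be positive, increasing")


def sphere_form_factor(q, R):
    """Amplitude 3 (sin qR - qR cos qR)/(qR)^3, -> 1 as q -> 0."""
    q = np.asarray(q, dtype=float)
    x = q * R
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    ff = 3.0 * (np.sin(safe) - safe * np.cos(safe)) / safe**3
    return np.where(small, 1.0 - x**2 / 10.0, ff)


def sphere_intensity(q, R, I0=1.0):
    return I0 * sphere_form_factor(q, R) ** 2


def sphere_pr(r, R):
    """Analytic pair-distance distribution of a sphere (unit integral)."""
    r = np.asarray(r, dtype=float)
    x = r / R
    p = np.where(r <= 2 * R,
                 r**2 * (1.0 - 0.75 * x + x**3 / 16.0), 0.0)
    p = np.clip(p, 0.0, None)
    norm = np.trapezoid(p, r)
    return p / norm if norm > 0 else p


def dumbbell_intensity(q, R, separation, I0=1.0):
    """Two identical spheres with centers ``separation`` apart."""
    q = np.asarray(q, dtype=float)
    ff2 = sphere_form_factor(q, R) ** 2
    x = q * separation
    sinc = np.sinc(x / np.pi)
    return I0 * ff2 * (1.0 + sinc) / 2.0


def gaussian_profile(q, Rg, I0=1.0):
    """Idealized globular profile I0 exp(-q^2 Rg^2 / 3)."""
    q = np.asarray(q, dtype=float)
    return I0 * np.exp(-(q * Rg) ** 2 / 3.0)


def make_saxs_profile(model: SphereModel, seed=0) -> SAXSProfile:
    """Sphere scattering profile with relative Gaussian noise.

    The sigma column records the noise sd (with a small positive floor so
    downstream weights stay defined at the form-factor zeros)."""
    rng = _rng(seed)
    q = np.asarray(model.q_grid, dtype=float)
    if q.size == 0:
        q = np.linspace(0.05, 5.0, 400)
    I = sphere_intensity(q, model.R, model.I0)
    sigma = model.noise_frac * I + 1e-6 * model.I0
    if model.noise_frac > 0:
        I = I + rng.normal(0.0, 1.0, q.size) * sigma
    return SAXSProfile(q=q, I=I, sigma=sigma,
                       metadata={"model": "sphere", "R": model.R,
                                 "I0": model.I0})
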