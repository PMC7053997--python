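"""Ligand-binding and signaling assay analysis.

Covers the quantitative pharmacology used to test the conformational
hypotheses: radioligand saturation binding, competition binding with
Cheng-Prusoff conversion to Ki, pK <-> K interconversion and mutant/WT
affinity fold-changes, time-resolved FRET plate preprocessing, and BRET
concentration-response Emax normalization.

Models
------
Saturation (globally fitted to total and nonspecific binding):

    Y_total([A]) = Bmax * [A] / ([A] + K_A) + NS * [A]
    Y_nonspec([A]) = NS * [A]

with Bmax the receptor density, K_A the radioligand's equilibrium
dissociation constant and NS the (linear) nonspecific-binding fraction.

Competition (four-parameter logistic on X = log10 [competitor]):

    Y(X) = Bottom + (Top - Bottom) / (1 + 10^((X - logIC50) * nH))

Cheng-Prusoff:  Ki = IC50 / (1 + [L]/Kd)  for tracer concentration [L] and
tracer dissociation constant Kd.

Concentrations are handled in nM on the user-facing surface; fits run on
log-scaled concentration internally where appropriate. Nonlinear fits use
trust-region least squares with data-driven initialization; confidence
intervals are computed by profile likelihood (an F-test threshold on the
profiled sum of squares).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DataError, FitError

__all__ = [
    "SaturationDataset",
    "CompetitionDataset",
    "BindingFit",
    "fit_saturation",
    "fit_competition",
    "cheng_prusoff",
    "pk_convert",
    "k_to_pk",
    "fold_change",
    "tr_fret_ratio",
    "normalize_emax",
]


@dataclass
class SaturationDataset:
    """Total and nonspecific radioligand binding vs free concentration (nM)."""

    conc_nM: np.ndarray
    total: np.ndarray
    nonspecific: np.ndarray

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        self.nonspecific = np.asarray(self.nonspecific, dtype=float)
        if np.any(self.conc_nM <= 0):
            raise DataError("concentrations must be positive")
        if len(np.unique(self.conc_nM)) < 5:
            raise DataError("saturation fitting needs >= 5 concentration levels")
        if not (len(self.conc_nM) == len(self.total) == len(self.nonspecific)):
            raise DataError("concentration/response arrays must align")


@dataclass
class CompetitionDataset:
    """Percent specific binding vs competitor concentration, plus tracer info."""

    conc_nM: np.ndarray
    response: np.ndarray
    tracer_conc_nM: float
    tracer_kd_nM: float

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(self.conc_nM <= 0):
            raise DataError("competitor concentrations must be positive")
        if len(np.unique(self.conc_nM)) < 6:
            raise DataError("competition fitting needs >= 6 concentration levels")
        if len(self.conc_nM) != len(self.response):
            raise DataError("concentration/response arrays must align")
        if self.tracer_conc_nM <= 0 or self.tracer_kd_nM <= 0:
            raise DataError("tracer concentration and Kd must be positive")


@dataclass
class BindingFit:
    """Fitted binding-model parameters with derived quantities."""

    model: str
    params: dict[str, float]
    ki_nM: float | None = None
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_ss: float = 0.0
    n_obs: int = 0

    @property
    def kd_nM(self) -> float | None:
        return self.params.get("KA")

    @property
    def ic50_nM(self) -> float | None:
        if "logIC50" in self.params:
            return 10.0 ** self.params["logIC50"]
        return None


def _saturation_model(conc, bmax, ka, ns):
    return bmax * conc / (conc + ka) + ns * conc


def fit_saturation(data: SaturationDataset, compute_ci: bool = False) -> BindingFit:
    """Global least-squares fit of the saturation model to total and
    nonspecific binding. Returns Bmax, KA (= radioligand Kd, nM) and NS."""
    conc, tot, nsb = data.conc_nM, data.total, data.nonspecific

    def residuals(theta):
        bmax, log_ka, ns = theta
        ka = 10.0 ** log_ka
        return np.concatenate([
            tot - _saturation_model(conc, bmax, ka, ns),
            nsb - ns * conc,
        ])

    # initialize: NS from the nonspecific slope, KA from half-max interpolation
    ns0 = max(float(np.sum(nsb * conc) / np.sum(conc**2)), 0.0)
    spec = tot - ns0 * conc
    bmax0 = max(float(spec.max()), 1e-6)
    half = bmax0 / 2.0
    ka0 = float(np.interp(half, np.sort(spec), conc[np.argsort(spec)]))
    ka0 = ka0 if np.isfinite(ka0) and ka0 > 0 else float(np.median(conc))
    sol = optimize.least_squares(residuals, x0=[bmax0, np.log10(ka0), ns0], method="trf")
    if not sol.success:
        raise FitError(f"saturation fit did not converge: {sol.message}")
    bmax, log_ka, ns = sol.x
    params = {"Bmax": float(bmax), "KA": float(10.0 ** log_ka), "NS": float(ns)}
    fit = BindingFit("saturation", params, residual_ss=float(np.sum(sol.fun**2)),
                     n_obs=2 * len(conc))
    if compute_ci:
        fit.ci95["pKd"] = _profile_ci(
            lambda lka: _refit_fixed(residuals_factory=_sat_fixed(conc, tot, nsb),
                                     fixed=lka, x0=[bmax, ns]),
            center=log_ka, ssr_min=fit.residual_ss, n=fit.n_obs, p=3, as_pk=True)
    return fit


def _sat_fixed(conc, tot, nsb):
    def factory(log_ka):
        ka = 10.0 ** log_ka
        def residuals(theta):
            bmax, ns = theta
            return np.concatenate([
                tot - _saturation_model(conc, bmax, ka, ns), nsb - ns * conc])
        return residuals
    return factory


def _competition_model(x, top, bottom, logic50, nh):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((x - logic50) * nh))


def fit_competition(data: CompetitionDataset, compute_ci: bool = False) -> BindingFit:
    """Four-parameter logistic fit of a competition curve.

    Returns Top, Bottom, logIC50 (X is log10 nM) and the Hill slope nH, plus
    the Cheng-Prusoff Ki derived from the dataset's tracer conditions.
    """
    x = np.log10(data.conc_nM)
    y = data.response

    def residuals(theta):
        return y - _competition_model(x, *theta)

    x0 = [float(y.max()), float(y.min()), float(np.median(x)), 1.0]
    sol = optimize.least_squares(residuals, x0=x0, method="trf")
    if not sol.success:
        raise FitError(f"competition fit did not converge: {sol.message}")
    top, bottom, logic50, nh = sol.x
    if bottom >= top:
        raise FitError("fit degenerate: Bottom >= Top")
    params = {"Top": float(top), "Bottom": float(bottom),
              "logIC50": float(logic50), "nH": float(nh)}
    ic50 = 10.0 ** logic50
    ki = cheng_prusoff(ic50, data.tracer_conc_nM, data.tracer_kd_nM)
    fit = BindingFit("competition", params, ki_nM=ki,
                     residual_ss=float(np.sum(sol.fun**2)), n_obs=len(x))
    if compute_ci:
        def refit(fix_logic50):
            def res(theta):
                return y - _competition_model(x, theta[0], theta[1], fix_logic50, theta[2])
            s = optimize.least_squares(res, x0=[top, bottom, nh], method="trf")
            return float(np.sum(s.fun**2))
        fit.ci95["logIC50"] = _profile_ci(refit, center=logic50,
                                          ssr_min=fit.residual_ss,
                                          n=fit.n_obs, p=4, as_pk=False)
    return fit


def _refit_fixed(residuals_factory, fixed, x0):
    sol = optimize.least_squares(residuals_factory(fixed), x0=x0, method="trf")
    return float(np.sum(sol.fun**2))


def _profile_ci(profile_ssr, center, ssr_min, n, p, as_pk=False,
                span=2.0, alpha=0.05):
    """Profile-likelihood interval on one (log-scaled) parameter.

    The bound is where the profiled SSR crosses
    ``ssr_min * (1 + F(1, n-p; alpha) / (n-p))``. With an essentially
    perfect fit (ssr_min ~ 0) the interval collapses to the point estimate.
    """
    dof = n - p
    if dof <= 0 or ssr_min <= 1e-12:
        lo = hi = center
    else:
        threshold = ssr_min * (1.0 + stats.f.ppf(1 - alpha, 1, dof) / dof)
        def g(v):
            return profile_ssr(v) - threshold
        lo, hi = center, center
        for sign in (-1, 1):
            a, b = center, center + sign * 1e-3
            while abs(b - center) <= span and g(b) < 0:
                b = center + (b - center) * 2.0
            if g(b) >= 0:
                root = optimize.brentq(g, min(a, b), max(a, b), xtol=1e-6)
            else:
                root = b  # bound not reached within the scan span
            if sign < 0:
                lo = root
            else:
                hi = root
    if as_pk:  # parameter is log10 K(nM); report as pK interval
        return (float(9 - hi), float(9 - lo))
    return (float(lo), float(hi))


def cheng_prusoff(ic50_nM: float, tracer_conc_nM: float, tracer_kd_nM: float) -> float:
    """Convert a competition IC50 to Ki: Ki = IC50 / (1 + [L]/Kd)."""
    if ic50_nM <= 0 or tracer_conc_nM < 0 or tracer_kd_nM <= 0:
        raise DataError("IC50 and Kd must be positive; tracer concentration non-negative")
    return float(ic50_nM / (1.0 + tracer_conc_nM / tracer_kd_nM))


def pk_convert(pk: float) -> float:
    """pK (−log10 of molar K) to K in nM: K_nM = 10^(9 − pK)."""
    if not np.isfinite(pk):
        raise DataError("pK must be finite")
    return float(10.0 ** (9.0 - pk))


def k_to_pk(k_nM: float) -> float:
    """K in nM to pK; inverse of :func:`pk_convert`."""
    if k_nM <= 0:
        raise DataError("K must be positive")
    return float(9.0 - np.log10(k_nM))


def fold_change(k_mut_nM: float, k_wt_nM: float) -> float:
    """Mutant/WT affinity fold-change (>1: the mutant binds more weakly)."""
    if k_wt_nM <= 0 or k_mut_nM <= 0:
        raise DataError("dissociation constants must be positive")
    return float(k_mut_nM / k_wt_nM)


def tr_fret_ratio(acceptor_665, donor_620, nonspecific=0.0):
    """Specific TR-FRET signal: (acceptor/donor) x 10,000 minus nonspecific.

    Vectorized over plate wells; the donor channel must be strictly positive.
    """
    acceptor = np.asarray(acceptor_665, dtype=float)
    donor = np.asarray(donor_620, dtype=float)
    if np.any(donor <= 0):
        raise DataError("donor channel must be positive")
    out = acceptor / donor * 10000.0 - np.asarray(nonspecific, dtype=float)
    return float(out) if out.ndim == 0 else out


def normalize_emax(drug_induced_max, reference_max: float):
    """Maximal drug response as a percentage of a reference full agonist.

    Inverse agonists yield negative percentages (a value below -30% of the
    reference agonist's maximum marks strong inverse agonism in the BRET
    readout).
    """
    if reference_max == 0:
        raise DataError("reference maximum must be nonzero")
    out = 100.0 * np.asarray(drug_induced_max, dtype=float) / reference_max
    return float(out) if out.ndim == 0 else out
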