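"""In-vitro pharmacology equations: Cheng-Prusoff Ki, 4PL fits, dose ratio, Ke.

Competition-binding IC50 values convert to inhibition constants via the
Cheng-Prusoff equation Ki = IC50 / (1 + [L]/Kd), with the radioligand
concentration [L] and its dissociation constant Kd.  The assay this package
models uses [3H]DAMGO at [L] = 1 nM with Kd = 1.59 nM.

Functional concentration-response data are fitted with a four-parameter
logistic (4PL) in log10 concentration; the rightward shift of an agonist
EC50 caused by a fixed antagonist concentration gives the dose ratio
DR = EC50_with / EC50_without, and the antagonist equilibrium constant
follows as Ke = [a] / (DR - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitConvergenceError


@dataclass(frozen=True)
class BindingAssayConfig:
    """Radioligand concentration and Kd (nM) for the Cheng-Prusoff conversion."""

    radioligand_conc_nM: float = 1.0
    radioligand_Kd_nM: float = 1.59

    def __post_init__(self):
        if self.radioligand_conc_nM <= 0 or self.radioligand_Kd_nM <= 0:
            raise DomainError("assay concentrations must be positive")


def cheng_prusoff(IC50_nM: float, config: BindingAssayConfig | None = None) -> float:
    """Ki = IC50 / (1 + [L]/Kd)."""
    config = config or BindingAssayConfig()
    if IC50_nM <= 0:
        raise DomainError("IC50 must be positive")
    return IC50_nM / (1.0 + config.radioligand_conc_nM / config.radioligand_Kd_nM)


def dose_ratio(EC50_with_antagonist: float, EC50_without: float) -> float:
    """DR = EC50(agonist + antagonist) / EC50(agonist alone)."""
    if EC50_with_antagonist <= 0 or EC50_without <= 0:
        raise DomainError("EC50 values must be positive")
    return EC50_with_antagonist / EC50_without


def antagonist_ke(antagonist_conc: float, DR: float) -> float:
    """Ke = [a] / (DR - 1), in the units of the antagonist concentration."""
    if antagonist_conc <= 0:
        raise DomainError("antagonist concentration must be positive")
    if DR <= 1.0:
        raise DomainError("Ke is undefined without a measurable rightward shift (DR <= 1)")
    return antagonist_conc / (DR - 1.0)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters; Emax is expressed relative to a reference maximum."""

    EC50: float
    Emax: float
    hill: float
    bottom: float
    top: float
    residual: float  # root-mean-square residual of the fit

    def __post_init__(self):
        if self.EC50 <= 0:
            raise DomainError("EC50 must be positive")
        if self.bottom > self.top:
            raise DomainError("bottom must not exceed top")


def _logistic4(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


def fit_dose_response(
    concentrations,
    responses,
    reference_max: float | None = None,
    fixed_hill: float | None = None,
    basal: float | None = None,
    normalize_before_subtract: bool = False,
) -> DoseResponseFit:
    """Least-squares 4PL fit of a concentration-response curve.

    Fitting happens in log10 concentration with quartile-heuristic
    initialisation and deterministic optimizer settings.  Requires at least
    five points spanning the transition.  ``reference_max`` rescales the
    efficacy to percent of a reference agonist's maximum.  A supplied
    ``basal`` response is subtracted before normalisation by default; set
    ``normalize_before_subtract`` to reverse that order.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise DomainError("concentrations and responses must be parallel 1-D arrays")
    if len(conc) < 5:
        raise DomainError("at least five concentration points are required")
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive")
    if basal is not None:
        if normalize_before_subtract and reference_max is not None:
            resp = resp * (100.0 / reference_max) - basal * (100.0 / reference_max)
        else:
            resp = resp - basal
    span = resp.max() - resp.min()
    scale = max(abs(resp.max()), abs(resp.min()), 1.0)
    if span < 1e-9 * scale or span == 0.0:
        raise FitConvergenceError(
            f"flat response (range {span:g}); no transition to fit"
        )
    logc = np.log10(conc)
    p0_bottom = float(resp.min())
    p0_top = float(resp.max())
    p0_logec50 = float(np.median(logc))
    if fixed_hill is None:
        def model(x, bottom, top, log_ec50, hill):
            return _logistic4(x, bottom, top, log_ec50, hill)
        p0 = [p0_bottom, p0_top, p0_logec50, 1.0]
    else:
        def model(x, bottom, top, log_ec50):
            return _logistic4(x, bottom, top, log_ec50, fixed_hill)
        p0 = [p0_bottom, p0_top, p0_logec50]
    try:
        popt, _ = curve_fit(model, logc, resp, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(
            f"4PL fit did not converge: {exc}; response range {span:g}, "
            f"log10 concentration range [{logc.min():.3g}, {logc.max():.3g}]"
        ) from exc
    if fixed_hill is None:
        bottom, top, log_ec50, hill = popt
    else:
        bottom, top, log_ec50 = popt
        hill = fixed_hill
    if hill < 0:  # decreasing parametrization: flip to canonical form
        bottom, top, hill = top, bottom, -hill
        # note: _logistic4 with negated hill and swapped asymptotes is identical
    if bottom > top:
        bottom, top = top, bottom
    ec50 = float(10.0 ** log_ec50)
    if not (conc.min() * 1e-4 <= ec50 <= conc.max() * 1e4):
        raise FitConvergenceError(
            f"fitted EC50 {ec50:g} nM lies far outside the tested range "
            f"[{conc.min():g}, {conc.max():g}] nM; data do not constrain the transition"
        )
    fitted = _logistic4(logc, *popt) if fixed_hill is None else model(logc, *popt)
    rmse = float(np.sqrt(np.mean((fitted - resp) ** 2)))
    emax = float(top) if reference_max is None else float(100.0 * top / reference_max)
    return DoseResponseFit(
        EC50=ec50, Emax=emax, hill=float(abs(hill)),
        bottom=float(bottom), top=float(top), residual=rmse,
    )


def simulate_dose_response(
    EC50: float,
    concentrations,
    Emax: float = 100.0,
    bottom: float = 0.0,
    hill: float = 1.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic 4PL responses with optional proportional Gaussian noise."""
    conc = np.asarray(concentrations, dtype=float)
    resp = _logistic4(np.log10(conc), bottom, Emax, np.log10(EC50), hill)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_frac * Emax, size=resp.shape)
    return resp
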