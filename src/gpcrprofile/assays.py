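"""Pharmacological curve fitting: luminescence normalisation, 3-parameter
concentration-response curves and one-site saturation binding.

Concentration-response data (e.g. NanoBiT G-protein dissociation or
GloSensor cAMP luminescence) are modelled with the 3-parameter logistic

    y(c) = bottom + (top - bottom) / (1 + 10**(log10 EC50 - log10 c))

i.e. a Hill slope fixed at 1 — fixing the slope is what makes the fit
"3-parametric".  The span top - bottom is reported as Emax and -log10 EC50
as pEC50.

Saturation binding of a radioligand is modelled as the one-site equation
with a linear nonspecific component, fitted jointly:

    total(L) = Bmax * L / (Kd + L) + ns_slope * L

Zero-concentration (vehicle) points cannot enter a log-concentration model
directly; they are assigned a pseudo-concentration three log units below the
lowest nonzero dose, anchoring the fitted bottom at the vehicle response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseData",
    "DoseResponseFit",
    "SaturationFit",
    "normalize_luminescence",
    "fit_dose_response",
    "fit_saturation_binding",
    "logistic3",
    "one_site_total",
]


def normalize_luminescence(
    raw: np.ndarray, baseline: np.ndarray, vehicle_raw: np.ndarray, vehicle_baseline: np.ndarray
) -> np.ndarray:
    """Fold-change over vehicle: (raw/baseline) / mean(vehicle_raw/vehicle_baseline).

    Counts are first normalised to each well's initial (pre-stimulus) count,
    then expressed relative to the mean vehicle-treated ratio, so an
    untreated well reads 1.0.
    """
    raw = np.asarray(raw, float)
    baseline = np.asarray(baseline, float)
    vr = np.asarray(vehicle_raw, float)
    vb = np.asarray(vehicle_baseline, float)
    if np.any(baseline <= 0) or np.any(vb <= 0):
        raise ValueError("baseline counts must be positive")
    if vr.size == 0:
        raise ValueError("vehicle series must be non-empty")
    return (raw / baseline) / np.mean(vr / vb)


@dataclass
class DoseResponseData:
    """Concentration (molar, may include 0 = vehicle) vs normalised response."""

    concentration: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, float)
        self.response = np.asarray(self.response, float)
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must have equal length")
        if np.any(self.concentration < 0) or not np.all(np.isfinite(self.response)):
            raise ValueError("concentrations must be >= 0 and responses finite")
        if len(np.unique(self.concentration)) < 4:
            raise ValueError("need at least 4 distinct concentrations to fit")


@dataclass
class DoseResponseFit:
    pEC50: float
    top: float
    bottom: float
    sse: float
    converged: bool
    extrapolated: bool = False
    message: str = ""

    @property
    def span(self) -> float:
        """Emax: top - bottom."""
        return self.top - self.bottom

    @property
    def ec50(self) -> float:
        return 10.0 ** (-self.pEC50)


@dataclass
class SaturationFit:
    Kd: float
    Bmax: float
    ns_slope: float
    sse: float
    converged: bool
    message: str = ""


def logistic3(logc: np.ndarray, pec50: float, top: float, bottom: float) -> np.ndarray:
    """3-parameter logistic in log10-concentration, Hill slope 1."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (-pec50 - logc))


def _log_concentrations(conc: np.ndarray) -> np.ndarray:
    """log10 concentrations with vehicle (0) mapped 3 log units below the
    lowest nonzero dose."""
    conc = np.asarray(conc, float)
    nonzero = conc[conc > 0]
    if nonzero.size == 0:
        raise ValueError("all concentrations are zero")
    floor = np.log10(nonzero.min()) - 3.0
    out = np.where(conc > 0, np.log10(np.where(conc > 0, conc, 1.0)), floor)
    return out


def fit_dose_response(
    data: DoseResponseData, hill_slope: float = 1.0, n_starts: int = 5, seed: int = 0
) -> DoseResponseFit:
    """Least-squares fit of the 3-parameter concentration-response curve.

    Bounded least squares with a deterministic multi-start over the sampled
    concentration span.  Non-convergence and degenerate (flat) data are
    flagged on the result instead of raising.
    """
    logc = _log_concentrations(data.concentration)
    y = data.response
    lo, hi = logc.min(), logc.max()
    y_lo, y_hi = float(y.min()), float(y.max())
    spread = max(y_hi - y_lo, 1e-12)

    def resid(p: np.ndarray) -> np.ndarray:
        pec50, top, bottom = p
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((-pec50 - logc) * hill_slope)) - y

    rng = np.random.default_rng(seed)
    starts = [np.array([-(lo + hi) / 2.0, y_hi, y_lo])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    -rng.uniform(lo, hi),
                    y_hi + rng.uniform(0, spread),
                    y_lo - rng.uniform(0, spread),
                ]
            )
        )
    margin = 10 * spread + 0.01 * max(1.0, abs(y_hi))  # stays open for flat data
    bounds = (
        np.array([-hi - 6.0, y_lo - margin, y_lo - margin]),
        np.array([-lo + 6.0, y_hi + margin, y_hi + margin]),
    )
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0] + 1e-9, bounds[1] - 1e-9)
        sol = least_squares(resid, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    sse = float(2 * best.cost)
    pec50, top, bottom = (float(v) for v in best.x)
    degenerate = abs(top - bottom) < 1e-6 * max(1.0, abs(y_hi))
    ec50_log = -pec50
    extrapolated = not (lo <= ec50_log <= hi)
    msg = "degenerate: span ~ 0" if degenerate else best.message
    return DoseResponseFit(
        pEC50=pec50,
        top=top,
        bottom=bottom,
        sse=sse,
        converged=bool(best.success) and not degenerate,
        extrapolated=extrapolated,
        message=msg,
    )


def one_site_total(L: np.ndarray, bmax: float, kd: float, ns: float) -> np.ndarray:
    """One-site binding with linear nonspecific term: Bmax*L/(Kd+L) + ns*L."""
    L = np.asarray(L, float)
    return bmax * L / (kd + L) + ns * L


def fit_saturation_binding(
    L: np.ndarray, total_bound: np.ndarray, n_starts: int = 5, seed: int = 0
) -> SaturationFit:
    """Joint least-squares fit of Kd, Bmax and the nonspecific slope.

    ``L`` is the free radioligand concentration (molar), ``total_bound`` the
    measured total binding (counts).
    """
    L = np.asarray(L, float)
    y = np.asarray(total_bound, float)
    if L.shape != y.shape or len(np.unique(L)) < 5:
        raise ValueError("need matched arrays with at least 5 distinct concentrations")
    if np.any(L <= 0):
        raise ValueError("ligand concentrations must be positive")

    def resid(p: np.ndarray) -> np.ndarray:
        log_kd, bmax, ns = p
        return one_site_total(L, bmax, 10.0**log_kd, ns) - y

    y_max = max(float(y.max()), 1e-12)
    log_lo, log_hi = np.log10(L.min()) - 3, np.log10(L.max()) + 3
    rng = np.random.default_rng(seed)
    starts = [np.array([np.log10(np.median(L)), y_max, 0.0])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    rng.uniform(np.log10(L.min()), np.log10(L.max())),
                    y_max * rng.uniform(0.5, 2.0),
                    rng.uniform(0, y_max / L.max()),
                ]
            )
        )
    bounds = (
        np.array([log_lo, 0.0, 0.0]),
        np.array([log_hi, 10 * y_max, 10 * y_max / L.min()]),
    )
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        sol = least_squares(resid, x0, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    log_kd, bmax, ns = (float(v) for v in best.x)
    return SaturationFit(
        Kd=10.0**log_kd,
        Bmax=bmax,
        ns_slope=ns,
        sse=float(2 * best.cost),
        converged=bool(best.success),
        message=best.message,
    )
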