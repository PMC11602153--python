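"""Dus enzyme kinetics: initial rates, Michaelis–Menten fits, time courses.

NAD(P)H oxidation is followed spectrophotometrically by the absorbance
decrease at 343 nm (eps343 = 6.21 mM^-1 cm^-1); the initial rate is the
(negative) least-squares slope over the earliest part of the trace converted
through Beer–Lambert to uM/s.  Initial rates versus substrate concentration
are fitted to v = Vmax S / (Km + S) by multi-start nonlinear least squares;
kcat = Vmax / [E] and the catalytic efficiency kcat/Km are derived, with
standard errors from the local curvature.  Dihydrouridylation time courses
are fitted to the saturating form D(t) = plateau (1 - e^-kt).

An enzyme whose fitted Vmax confidence interval includes zero is reported as
having no detectable activity rather than a numeric turnover number;
:func:`rank_enzymes` places such fits last, which reproduces the activity
hierarchy DusA > DusB > DusC on the packaged presets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import EPSILON_343_MM


@dataclass
class MMFit:
    """Michaelis–Menten parameters for one enzyme."""

    vmax: float  # uM/s
    km: float  # uM
    kcat: float  # 1/s (= vmax / enzyme_conc)
    efficiency: float  # 1/(uM s) (= kcat / km)
    se_vmax: float
    se_km: float
    enzyme_conc: float
    converged: bool
    detectable: bool = True
    message: str = ""

    def predict(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.vmax * S / (self.km + S)


@dataclass
class TimecourseFit:
    k: float  # 1/min
    plateau: float
    t_half: float  # min (= ln 2 / k)
    converged: bool
    message: str = ""


@dataclass
class InitialRate:
    rate_uM_per_s: float
    slope_AU_per_s: float
    n_points: int
    clamped: bool = False


def initial_rate_from_trace(
    trace: pd.DataFrame,
    epsilon_mM: float = EPSILON_343_MM,
    path_cm: float = 1.0,
    window_frac: float = 0.1,
) -> InitialRate:
    """Initial rate (uM/s) from an absorbance trace (columns t_s, A343).

    Uses the least-squares slope over the earliest ``window_frac`` of points
    (at least 5); rate = -slope / (eps x path) x 1000.  A positive slope
    (rising absorbance, i.e. no consumption) yields a rate clamped to 0.
    """
    t = np.asarray(trace["t_s"], dtype=float)
    a = np.asarray(trace["A343"], dtype=float)
    n = max(5, int(math.ceil(window_frac * len(t))))
    if len(t) < 5:
        raise ValueError("need at least 5 points in the initial window")
    n = min(n, len(t))
    fit = stats.linregress(t[:n], a[:n])
    rate = -float(fit.slope) / (epsilon_mM * path_cm) * 1000.0
    clamped = rate < 0
    return InitialRate(
        rate_uM_per_s=0.0 if clamped else rate,
        slope_AU_per_s=float(fit.slope),
        n_points=n,
        clamped=clamped,
    )


def _mm_model(S, vmax, km):
    return vmax * S / (km + S)


def fit_michaelis_menten(S, v, enzyme_conc: float) -> MMFit:
    """Multi-start nonlinear least squares of v = Vmax S / (Km + S).

    Km starts on a log-spaced grid spanning the substrate range, Vmax at the
    maximal observed rate; the start with the lowest residual sum of squares
    wins.  ``enzyme_conc`` (uM) is required to derive kcat.  A fit whose
    Vmax 95% interval includes zero is flagged ``detectable=False`` (no
    detectable activity).
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")
    if np.unique(S).size < 4:
        warnings.warn("fewer than 4 distinct substrate concentrations", stacklevel=2)
    vmax0 = float(max(v.max(), 1e-12))
    km_grid = np.geomspace(max(S[S > 0].min(), 1e-6) / 10.0, S.max() * 10.0, 9)
    best = None
    for km0 in km_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    _mm_model,
                    S,
                    v,
                    p0=[vmax0, km0],
                    bounds=([0.0, 1e-12], [np.inf, np.inf]),
                    maxfev=10000,
                )
            ssr = float(np.sum((v - _mm_model(S, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        return MMFit(
            vmax=float("nan"), km=float("nan"), kcat=float("nan"),
            efficiency=float("nan"), se_vmax=float("nan"), se_km=float("nan"),
            enzyme_conc=enzyme_conc, converged=False, detectable=False,
            message="no start converged",
        )
    _, (vmax, km), pcov = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    kcat = vmax / enzyme_conc
    detectable = bool(vmax - 1.96 * se[0] > 0)
    return MMFit(
        vmax=float(vmax),
        km=float(km),
        kcat=float(kcat),
        efficiency=float(kcat / km),
        se_vmax=float(se[0]),
        se_km=float(se[1]),
        enzyme_conc=enzyme_conc,
        converged=True,
        detectable=detectable,
        message="" if detectable else "Vmax interval includes 0: no detectable activity",
    )


def _timecourse_model(t, plateau, k):
    return plateau * (1.0 - np.exp(-k * t))


def fit_saturating_timecourse(t, D) -> TimecourseFit:
    """Least squares of D(t) = plateau (1 - e^-kt) with multi-start over k.

    Requires >= 4 time points including t = 0.  An all-zero signal returns
    k = 0, plateau = 0, flagged unconverged (nothing to fit).
    """
    t = np.asarray(t, dtype=float)
    D = np.asarray(D, dtype=float)
    if t.size < 4 or 0.0 not in t:
        raise ValueError("need at least 4 time points including t = 0")
    if np.allclose(D, 0.0):
        return TimecourseFit(k=0.0, plateau=0.0, t_half=float("inf"),
                             converged=False, message="all-zero signal")
    plateau0 = float(max(D.max(), 1e-12))
    best = None
    for k0 in np.geomspace(1e-3, 10.0, 9):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _timecourse_model, t, D,
                    p0=[plateau0, k0],
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    maxfev=10000,
                )
            ssr = float(np.sum((D - _timecourse_model(t, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        return TimecourseFit(k=float("nan"), plateau=float("nan"), t_half=float("nan"),
                             converged=False, message="no start converged")
    _, (plateau, k) = best
    t_half = math.log(2.0) / k if k > 0 else float("inf")
    return TimecourseFit(k=float(k), plateau=float(plateau), t_half=float(t_half), converged=True)


def rank_enzymes(
    fits: dict[str, MMFit | TimecourseFit], criterion: str = "efficiency"
) -> list[tuple[str, float, str]]:
    """Order enzymes by descending criterion ('efficiency' for MM fits, 'k'
    for time-course fits).

    Fits that did not converge, or whose activity is not detectable, rank
    last (flag ``not_detectable``/``not_converged``); exact ties keep a
    stable alphabetical order and are flagged ``tie``.
    """
    if criterion not in ("efficiency", "k"):
        raise ValueError(f"unknown criterion {criterion!r}")

    def value_of(fit) -> float | None:
        if not fit.converged:
            return None
        if isinstance(fit, MMFit) and not fit.detectable:
            return None
        return fit.efficiency if criterion == "efficiency" else fit.k

    scored = []
    for name in sorted(fits):
        val = value_of(fits[name])
        scored.append((name, val))
    usable = [(n, v) for n, v in scored if v is not None]
    unusable = [(n, v) for n, v in scored if v is None]
    usable.sort(key=lambda item: (-item[1], item[0]))
    values = [v for _, v in usable]
    ranked: list[tuple[str, float, str]] = []
    for name, val in usable:
        flag = "tie" if values.count(val) > 1 else ""
        ranked.append((name, val, flag))
    for name, _ in unusable:
        fit = fits[name]
        flag = "not_converged" if not fit.converged else "not_detectable"
        ranked.append((name, float("nan"), flag))
    return ranked


def mm_fit_table(fits: dict[str, MMFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "enzyme": name,
                "Vmax_uM_per_s": f.vmax,
                "Km_uM": f.km,
                "kcat_per_s": f.kcat,
                "efficiency_per_uM_s": f.efficiency,
                "se_Vmax": f.se_vmax,
                "se_Km": f.se_km,
                "converged": f.converged,
                "detectable": f.detectable,
            }
            for name, f in sorted(fits.items())
        ],
        columns=[
            "enzyme", "Vmax_uM_per_s", "Km_uM", "kcat_per_s", "efficiency_per_uM_s",
            "se_Vmax", "se_Km", "converged", "detectable",
        ],
    )
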