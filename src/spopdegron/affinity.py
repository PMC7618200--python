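"""Binding models for degron affinity measurements.

Three assay families quantify peptide binding to the SPOP MATH domain:

* fluorescence-polarization (FP) saturation: a constant trace of labeled
  peptide titrated with protein; fit with a one-site total binding
  equation, ``y = Bmax*x/(Kd + x) + NS*x + baseline``;
* FP competition: unlabeled peptide displaces a labeled probe from a fixed
  protein-probe mix; fit with the four-parameter variable-slope logistic
  ("4PL"), IC50 being the competitor concentration halfway between the top
  and bottom plateaus;
* isothermal titration calorimetry (ITC): per-injection heats fit with the
  one-set-of-sites total-heat model with cumulative-dilution correction;
  Kd is reported as the reciprocal of the fitted association constant Ka.

Replicate aggregation follows the convention of reporting the arithmetic
mean +/- sample standard deviation (n-1 denominator) across independent
experiments.  Fits are deterministic: initial guesses are simple,
documented functions of the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BindingCurve",
    "CompetitionCurve",
    "ITCExperiment",
    "FitResult",
    "normalize_percent_fp",
    "subtract_dilution_control",
    "one_site_total",
    "four_param_logistic",
    "itc_injection_heats",
    "fit_one_site_total",
    "fit_ic50_4pl",
    "fit_itc_one_site",
    "aggregate_fits",
    "read_curves",
    "write_fit_report",
]


def _as_sorted_xy(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    order = np.argsort(x, kind="stable")
    return x[order], y[order]


@dataclass
class BindingCurve:
    """An FP saturation series: titrant concentration (uM) vs signal.

    Signal may be raw millipolarization (mP) or normalized percent FP;
    ``normalized`` records which.
    """

    x: np.ndarray
    y: np.ndarray
    replicate_id: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.x, self.y = _as_sorted_xy(self.x, self.y)
        if len(self.x) < 5:
            raise ValueError("a binding curve needs at least 5 points")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("concentrations must be distinct")


@dataclass
class CompetitionCurve:
    """An FP competition series: unlabeled competitor (uM) vs signal (mP),
    measured against a fixed probe/receptor mix."""

    x: np.ndarray
    y: np.ndarray
    probe_conc: float = 0.05
    receptor_conc: float = 5.0
    replicate_id: str = ""

    def __post_init__(self):
        self.x, self.y = _as_sorted_xy(self.x, self.y)
        if len(self.x) < 5:
            raise ValueError("a competition curve needs at least 5 points")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("concentrations must be distinct")
        if self.probe_conc <= 0 or self.receptor_conc <= 0:
            raise ValueError("probe and receptor concentrations must be positive")


@dataclass
class ITCExperiment:
    """One ITC titration: syringe species injected into the cell species.

    Concentrations in uM, volumes in ul, heats in ucal (already corrected
    against the heat-of-dilution control), temperature in Celsius.  Note the
    role inversion relative to common practice: here the *protein* is
    titrated into the *peptide*, so the cell species is treated as the
    "macromolecule" of the one-set-of-sites model.
    """

    cell_species_conc: float
    syringe_species_conc: float
    injection_volumes: np.ndarray
    heats: np.ndarray
    cell_volume: float = 200.0
    temperature: float = 25.0

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_species_conc <= 0 or self.syringe_species_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")
        if len(self.injection_volumes) != len(self.heats):
            raise ValueError("one heat per injection required")


@dataclass
class FitResult:
    """Fitted model parameters plus diagnostics."""

    model_name: str
    parameters: dict
    residual_sum_squares: float
    converged: bool
    n_points: int = 0
    message: str = ""

    def __getitem__(self, key):
        return self.parameters[key]


def normalize_percent_fp(y, zero_ref: float, full_ref: float) -> np.ndarray:
    """Map mP signals to percent FP: the no-protein control is 0 % and the
    highest-protein reference 100 %.  Values outside [0, 100] are permitted
    (noise)."""
    if full_ref == zero_ref:
        raise ValueError("zero and full references must differ")
    return 100.0 * (np.asarray(y, dtype=float) - zero_ref) / (full_ref - zero_ref)


def subtract_dilution_control(heats, control_heats) -> np.ndarray:
    """Utility: subtract a heat-of-dilution control titration, injection by
    injection.  The ITC fitter itself expects pre-corrected heats."""
    heats = np.asarray(heats, dtype=float)
    control = np.asarray(control_heats, dtype=float)
    if heats.shape != control.shape:
        raise ValueError("control must have one heat per injection")
    return heats - control


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def one_site_total(x, kd: float, bmax: float, ns: float = 0.0, baseline: float = 0.0):
    """One-site total binding: specific hyperbola plus nonspecific line."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x) + ns * x + baseline


def four_param_logistic(x, ic50: float, hill: float, top: float, bottom: float):
    """Inhibitor-vs-response variable-slope logistic in log10 dose.

    ``y = bottom + (top-bottom) / (1 + 10**((log10(ic50) - log10(x)) * hill))``
    with hill < 0 for inhibition; at ``x == ic50`` the response is halfway
    between top and bottom.  Defined for x > 0.
    """
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(ic50) - np.log10(x)) * hill))


def _itc_totals(exp: ITCExperiment) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell ("macromolecule") and syringe ("titrant") totals after each
    injection, with the standard cumulative-displacement correction."""
    v0 = exp.cell_volume * 1e-6  # liters
    dv = exp.injection_volumes * 1e-6
    cum = np.cumsum(dv)
    m0 = exp.cell_species_conc * 1e-6  # molar
    x0 = exp.syringe_species_conc * 1e-6
    mt = m0 * (1.0 - cum / (2.0 * v0)) / (1.0 + cum / (2.0 * v0))
    xt = x0 * (cum / v0) / (1.0 + cum / (2.0 * v0))
    if np.any(mt <= 0):
        raise ValueError("cell species depleted: injected volume too large for the cell")
    return mt, xt, dv


def itc_injection_heats(
    exp: ITCExperiment, n: float, ka: float, dh: float
) -> np.ndarray:
    """Per-injection heats (ucal) from the one-set-of-sites total-heat model.

    ``n`` is the stoichiometry, ``ka`` the association constant (1/M) and
    ``dh`` the molar enthalpy (cal/mol).  The cumulative heat content of the
    cell after injection i is

        Q_i = n*Mt_i*dH*V0/2 * [1 + Xt/(n*Mt) + 1/(n*Ka*Mt)
                                - sqrt((1 + Xt/(n*Mt) + 1/(n*Ka*Mt))**2
                                       - 4*Xt/(n*Mt))]

    and the measured heat of injection i corrects for the liquid displaced
    into the overflow: ``dQ_i = Q_i - Q_{i-1} + (dV_i/V0)*(Q_i+Q_{i-1})/2``.
    """
    mt, xt, dv = _itc_totals(exp)
    v0 = exp.cell_volume * 1e-6
    r = xt / (n * mt)
    s = 1.0 + r + 1.0 / (n * ka * mt)
    q = n * mt * dh * v0 / 2.0 * (s - np.sqrt(s * s - 4.0 * r))
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    return dq * 1e6  # cal -> ucal


# ---------------------------------------------------------------------------
# Fitters (deterministic, data-driven initial guesses)
# ---------------------------------------------------------------------------

def _run_least_squares(residual, p0, bounds):
    try:
        res = least_squares(residual, p0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
        return res, res.success
    except Exception as exc:  # pragma: no cover - defensive
        class _Failed:
            x = np.asarray(p0, dtype=float)
            fun = np.asarray([np.inf])
            message = str(exc)
        return _Failed(), False


def fit_one_site_total(curve: BindingCurve, include_ns: bool = False) -> FitResult:
    """Fit the one-site total binding equation to a saturation curve.

    Initial guesses: baseline = signal at the lowest concentration; Bmax =
    signal range; Kd = concentration nearest the half-maximal signal;
    NS = 0.  When ``include_ns`` is false the nonspecific slope is fixed at
    zero.  A fit whose Kd runs far beyond the sampled range (>100x the top
    concentration) is flagged unconverged rather than reported as a number
    the data cannot support.
    """
    x, y = curve.x, curve.y
    n_params = 4 if include_ns else 3
    if len(x) < n_params + 1:
        raise ValueError(f"need more points than parameters ({n_params})")
    baseline0 = float(y[0])
    bmax0 = float(y[-1] - y[0]) or 1.0
    half = baseline0 + bmax0 / 2.0
    kd0 = float(x[np.argmin(np.abs(y - half))]) or float(np.median(x[x > 0]) if np.any(x > 0) else 1.0)
    xmax = float(x[-1])

    if include_ns:
        p0 = [kd0, bmax0, 0.0, baseline0]
        lower = [1e-12, -np.inf, -np.inf, -np.inf]
        upper = [np.inf] * 4

        def residual(p):
            return one_site_total(x, p[0], p[1], p[2], p[3]) - y
    else:
        p0 = [kd0, bmax0, baseline0]
        lower = [1e-12, -np.inf, -np.inf]
        upper = [np.inf] * 3

        def residual(p):
            return one_site_total(x, p[0], p[1], 0.0, p[2]) - y

    res, success = _run_least_squares(residual, p0, (lower, upper))
    p = res.x
    kd = float(p[0])
    params = {
        "Kd": kd,
        "Bmax": float(p[1]),
        "NS": float(p[2]) if include_ns else 0.0,
        "baseline": float(p[-1]),
    }
    rss = float(np.sum(np.square(res.fun)))
    # Kd is unidentifiable when it runs far beyond the sampled range or when
    # there is no specific-binding amplitude to constrain it.
    identifiable = 0 < kd <= 100.0 * xmax and abs(params["Bmax"]) > 1e-6 * max(1.0, float(np.ptp(y)))
    converged = bool(success) and np.isfinite(rss) and identifiable
    msg = "" if converged else "Kd unbounded: no binding signal in the sampled range"
    return FitResult("one_site_total", params, rss, converged, len(x), msg)


def fit_ic50_4pl(curve: CompetitionCurve) -> FitResult:
    """Fit the variable-slope four-parameter logistic to a competition curve.

    Zero-concentration points are excluded from the log-domain fit but are
    used (together with the lowest doses) to seed the top plateau.  Initial
    guesses: top/bottom from the curve ends, hill = -1, IC50 = the dose
    nearest the mid-response.  A curve with no inhibition signal (response
    rising with dose) is returned with ``converged=False`` and the IC50
    marked not determined.
    """
    x_all, y_all = curve.x, curve.y
    pos = x_all > 0
    x, y = x_all[pos], y_all[pos]
    if len(np.unique(x)) < 6:
        raise ValueError("need at least 6 distinct nonzero concentrations")
    if np.log10(x[-1] / x[0]) < 2.0:
        raise ValueError("concentrations must span at least 2 log units")
    top0 = float(np.mean(y_all[x_all <= x[0]]))  # includes any x == 0 point
    bottom0 = float(y[-1])
    mid = (top0 + bottom0) / 2.0
    ic50_0 = float(x[np.argmin(np.abs(y - mid))])
    p0 = [math.log10(ic50_0), -1.0, top0, bottom0]
    lower = [math.log10(x[0]) - 6.0, -50.0, -np.inf, -np.inf]
    upper = [math.log10(x[-1]) + 6.0, 50.0, np.inf, np.inf]

    def residual(p):
        log_ic50, hill, top, bottom = p
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - np.log10(x)) * hill)) - y

    res, success = _run_least_squares(residual, p0, (lower, upper))
    log_ic50, hill, top, bottom = (float(v) for v in res.x)
    ic50 = 10.0 ** log_ic50
    rss = float(np.sum(np.square(res.fun)))
    # Inhibition means the response falls from top to bottom as dose grows.
    trend = float(np.polyfit(np.log10(x), y, 1)[0])
    determined = (
        bool(success)
        and np.isfinite(rss)
        and top > bottom
        and hill < 0
        and trend < 0
        and x[0] / 100.0 <= ic50 <= x[-1] * 100.0
    )
    params = {
        "IC50": ic50,
        "hill": hill,
        "top": top,
        "bottom": bottom,
        "determined": determined,
    }
    msg = "" if determined else "IC50 not determined (no inhibition signal)"
    return FitResult("ic50_4pl", params, rss, determined, len(x), msg)


def fit_itc_one_site(
    exp: ITCExperiment,
    exclude_first: bool = True,
    fix_n: float = None,
) -> FitResult:
    """Fit (n, Ka, dH) to per-injection ITC heats; Kd reported as 1/Ka.

    The first injection (conventionally a small pre-injection) is excluded
    from the residuals by default.  Initial guesses: n = 1; dH = heat of the
    first usable injection divided by the moles injected; Ka = 10 / cell
    concentration (a mid-range sigmoid).  ``fix_n`` pins the stoichiometry.
    """
    if len(exp.heats) < 10:
        raise ValueError("need at least 10 injections")
    mask = np.ones(len(exp.heats), dtype=bool)
    if exclude_first:
        mask[0] = False
    y = exp.heats
    first_usable = int(np.argmax(mask))
    moles_first = exp.injection_volumes[first_usable] * 1e-6 * exp.syringe_species_conc * 1e-6
    dh0 = float(y[first_usable] * 1e-6 / moles_first) if moles_first > 0 else -1e4
    if dh0 == 0.0:
        dh0 = -1e4
    ka0 = 10.0 / (exp.cell_species_conc * 1e-6)
    n0 = 1.0

    def heats_for(p):
        if fix_n is None:
            n, log_ka, dh = p
        else:
            n = fix_n
            log_ka, dh = p
        return itc_injection_heats(exp, n, 10.0 ** log_ka, dh)

    def residual(p):
        return heats_for(p)[mask] - y[mask]

    if fix_n is None:
        p0 = [n0, math.log10(ka0), dh0]
        lower = [0.05, 0.0, -np.inf]
        upper = [20.0, 15.0, np.inf]
    else:
        p0 = [math.log10(ka0), dh0]
        lower = [0.0, -np.inf]
        upper = [15.0, np.inf]

    res, success = _run_least_squares(residual, p0, (lower, upper))
    if fix_n is None:
        n_fit, log_ka, dh = (float(v) for v in res.x)
    else:
        n_fit = float(fix_n)
        log_ka, dh = (float(v) for v in res.x)
    ka = 10.0 ** log_ka
    rss = float(np.sum(np.square(res.fun)))
    # All-zero (or information-free) heats cannot determine the parameters.
    signal = float(np.max(np.abs(y[mask]))) if np.any(mask) else 0.0
    converged = bool(success) and np.isfinite(rss) and signal > 0.0
    params = {
        "n": n_fit,
        "Ka": ka,  # 1/M
        "dH": dh,  # cal/mol
        "Kd": 1.0 / ka * 1e6,  # uM, the reciprocal of Ka
    }
    msg = "" if converged else "no heat signal to fit"
    return FitResult("itc_one_site", params, rss, converged, int(mask.sum()), msg)


def aggregate_fits(results: Sequence[FitResult], parameter: str) -> Tuple[float, float]:
    """Mean +/- sample SD (n-1) of one parameter over converged replicates.

    Mirrors the convention of averaging e.g. Kd over three independent
    experiments and reporting the standard deviation.
    """
    values = [r.parameters[parameter] for r in results if r.converged]
    models = {r.model_name for r in results if r.converged}
    if len(values) < 2:
        raise ValueError("need at least 2 converged results to aggregate")
    if len(models) > 1:
        raise ValueError(f"mixed models in aggregation: {sorted(models)}")
    arr = np.asarray(values, dtype=float)
    return float(np.mean(arr)), float(np.std(arr, ddof=1))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_curves(path, kind: str = "saturation", **kwargs) -> List:
    """Read delimited text (CSV/TSV by extension) with columns
    ``concentration``, ``signal`` and optional ``replicate`` into one curve
    per replicate."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"concentration", "signal"}
    if not required <= set(df.columns):
        raise IOError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if "replicate" not in df.columns:
        df["replicate"] = ""
    cls = {"saturation": BindingCurve, "competition": CompetitionCurve}[kind]
    curves = []
    for rep, grp in df.groupby("replicate", sort=False):
        curves.append(cls(grp["concentration"].values, grp["signal"].values, replicate_id=str(rep), **kwargs)
                      if kind == "saturation"
                      else cls(grp["concentration"].values, grp["signal"].values, replicate_id=str(rep), **kwargs))
    return curves


def write_fit_report(result: FitResult, path, format: str = None) -> None:
    """Write a fit report as JSON or TSV (chosen by extension or ``format``)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    payload = {
        "model": result.model_name,
        "converged": result.converged,
        "residual_sum_squares": result.residual_sum_squares,
        "n_points": result.n_points,
        "message": result.message,
        **{k: v for k, v in result.parameters.items()},
    }
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    elif fmt == "tsv":
        pd.DataFrame([payload]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
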