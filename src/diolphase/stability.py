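"""Thermal stability, octanol/water partitioning, and cross-assay correlation.

Fits two-state van't Hoff melting curves (MRE at 222 nm versus temperature)
for Tm and ΔTm, quantifies concentrations from NMR integrals to obtain logP,
and assembles the per-compound potency ledger joining Csat, CSP slope, logP
and ΔTm with Pearson correlations, including explicit named-outlier
re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .synthetic import two_state_signal

__all__ = [
    "MeltFit",
    "CorrelationResult",
    "PotencyLedger",
    "fit_melting_curve",
    "tm_midpoint",
    "delta_tm",
    "concentration_from_integral",
    "log_p",
    "logp_from_measurement",
    "pearson_with_exclusion",
    "assemble_potency_ledger",
]


@dataclass
class MeltFit:
    tm_celsius: float
    tm_err: float
    dh_kj_mol: float
    dh_err: float
    folded_baseline: tuple[float, float]
    unfolded_baseline: tuple[float, float]
    converged: bool
    tm_midpoint_celsius: float  # model-free cross-check
    methods_disagree: bool  # |fit - midpoint| > 1 degC


def tm_midpoint(temperature_c: np.ndarray, signal: np.ndarray) -> float:
    """Model-free Tm: temperature where the min-max-normalized signal crosses 0.5.

    Used as a cross-check on the van't Hoff fit; returns NaN for a flat curve.
    """
    t = np.asarray(temperature_c, dtype=float)
    y = np.asarray(signal, dtype=float)
    if np.ptp(y) == 0:
        return float("nan")
    norm = (y - y[:5].mean()) / (y[-5:].mean() - y[:5].mean())
    crossing = np.nonzero(np.diff(np.signbit(norm - 0.5)))[0]
    if crossing.size == 0:
        return float("nan")
    k = crossing[0]
    f = (0.5 - norm[k]) / (norm[k + 1] - norm[k])
    return float(t[k] + f * (t[k + 1] - t[k]))


def fit_melting_curve(
    temperature_c: np.ndarray, signal: np.ndarray
) -> MeltFit:
    """Two-state van't Hoff fit with linear folded/unfolded baselines.

    The model matches the generator's: theta(T) = [theta_N + theta_U K]/[1+K]
    with K = exp[-(dH/R)(1/T - 1/Tm)].  Initialisation takes baselines from
    the curve ends and Tm from the steepest-slope temperature; a fit that does
    not converge or places Tm outside the data range is flagged rather than
    reported.
    """
    t = np.asarray(temperature_c, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 points spanning the transition")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")

    mid = tm_midpoint(t, y)
    n_edge = max(3, len(t) // 10)
    f_slope, f_int = np.polyfit(t[:n_edge], y[:n_edge], 1)
    u_slope, u_int = np.polyfit(t[-n_edge:], y[-n_edge:], 1)

    dy = np.gradient(y, t)
    tm0_c = t[np.argmax(np.abs(dy))] if np.isnan(mid) else mid
    p0 = (tm0_c + 273.15, 400.0, f_int, f_slope, u_int, u_slope)

    def model(tc, tm_k, dh, fi, fs, ui, us):
        return two_state_signal(tc, tm_k, dh, (fi, fs), (ui, us))

    try:
        popt, pcov = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=(
                [t[0] + 273.15 - 20.0, 1.0, -np.inf, -np.inf, -np.inf, -np.inf],
                [t[-1] + 273.15 + 20.0, 5000.0, np.inf, np.inf, np.inf, np.inf],
            ),
            maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
        tm_c = float(popt[0] - 273.15)
        in_range = t[0] <= tm_c <= t[-1]
        # a genuine transition separates the baselines at Tm by more than the
        # residual scatter; flat curves fail this and are flagged
        amp = abs(
            (popt[2] + popt[3] * tm_c) - (popt[4] + popt[5] * tm_c)
        )
        resid_sd = float(np.std(y - model(t, *popt)))
        significant = amp > 5.0 * max(resid_sd, 1e-12)
        converged = bool(np.all(np.isfinite(perr)) and in_range and significant)
    except RuntimeError:
        popt = np.array(p0)
        perr = np.full(6, np.nan)
        tm_c = float("nan")
        converged = False

    disagree = bool(
        converged and not np.isnan(mid) and abs(tm_c - mid) > 1.0
    )
    return MeltFit(
        tm_celsius=tm_c,
        tm_err=float(perr[0]),
        dh_kj_mol=float(popt[1]),
        dh_err=float(perr[1]),
        folded_baseline=(float(popt[2]), float(popt[3])),
        unfolded_baseline=(float(popt[4]), float(popt[5])),
        converged=converged,
        tm_midpoint_celsius=mid,
        methods_disagree=disagree,
    )


def delta_tm(reference: MeltFit, condition: MeltFit) -> tuple[float, float]:
    """Tm(condition) - Tm(reference) in degC with quadrature uncertainty."""
    if not (reference.converged and condition.converged):
        raise ValueError("both melting fits must have converged")
    d = condition.tm_celsius - reference.tm_celsius
    err = float(np.hypot(reference.tm_err, condition.tm_err))
    return float(d), err


# ---------------------------------------------------------------------------
# partition coefficient
# ---------------------------------------------------------------------------

def concentration_from_integral(
    integral: float,
    protons: int,
    ref_integral: float,
    ref_protons: int,
    ref_concentration: float,
) -> float:
    """Concentration from an NMR integral against a reference standard.

    c = c_ref * (I / protons) / (I_ref / protons_ref); integrals scale with
    concentration times the number of contributing protons.
    """
    if ref_integral <= 0:
        raise ValueError("reference integral must be > 0")
    if protons <= 0 or ref_protons <= 0:
        raise ValueError("proton counts must be > 0")
    if ref_concentration <= 0:
        raise ValueError("reference concentration must be > 0")
    if integral < 0:
        raise ValueError("integral must be >= 0")
    return ref_concentration * (integral / protons) / (ref_integral / ref_protons)


def log_p(c_octanol: float, c_water: float) -> float:
    """log10 of the octanol/water concentration ratio."""
    if c_octanol <= 0 or c_water <= 0:
        raise ValueError("concentrations must be > 0")
    return float(np.log10(c_octanol / c_water))


def logp_from_measurement(measurement) -> float:
    """logP from a PartitionMeasurement's integrals via the reference standard."""
    c_o = concentration_from_integral(
        measurement.integral_octanol,
        measurement.protons_per_molecule,
        measurement.integral_reference,
        measurement.reference_protons,
        measurement.reference_concentration,
    )
    c_w = concentration_from_integral(
        measurement.integral_water,
        measurement.protons_per_molecule,
        measurement.integral_reference,
        measurement.reference_protons,
        measurement.reference_concentration,
    )
    return log_p(c_o, c_w)


# ---------------------------------------------------------------------------
# correlations and the potency ledger
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    pcc: float
    n: int
    pcc_excluded: float | None  # None when < 3 pairs remain after exclusion
    n_excluded: int
    excluded_labels: tuple[str, ...]


def pearson_with_exclusion(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
    exclude: Iterable[str] = (),
) -> CorrelationResult:
    """Pearson correlation over label-matched pairs, with and without outliers.

    Pairs are formed over labels present (non-NaN) in both inputs; the
    excluded correlation drops the named labels and is reported as unavailable
    (None) if fewer than 3 pairs remain.
    """
    xs = pd.Series(dict(x), dtype=float)
    ys = pd.Series(dict(y), dtype=float)
    common = xs.index.intersection(ys.index)
    paired = pd.DataFrame({"x": xs[common], "y": ys[common]}).dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 matched pairs")
    pcc = float(pearsonr(paired["x"], paired["y"]).statistic)
    excl = tuple(exclude)
    kept = paired.drop(index=[e for e in excl if e in paired.index])
    if len(kept) >= 3:
        pcc_excl = float(pearsonr(kept["x"], kept["y"]).statistic)
    else:
        pcc_excl = None
    return CorrelationResult(
        pcc=pcc,
        n=len(paired),
        pcc_excluded=pcc_excl,
        n_excluded=len(kept),
        excluded_labels=excl,
    )


@dataclass
class PotencyLedger:
    table: pd.DataFrame  # outer join over compounds; NaN where missing
    correlations: dict[tuple[str, str], CorrelationResult]


def _as_series(table, value_name: str) -> pd.Series:
    if isinstance(table, pd.Series):
        s = table.astype(float)
    elif isinstance(table, Mapping):
        s = pd.Series(dict(table), dtype=float)
    else:
        df = pd.DataFrame(table)
        s = df.set_index("compound")[value_name].astype(float)
    if s.index.has_duplicates:
        dupes = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate compound keys: {dupes}")
    return s


def assemble_potency_ledger(
    csat=None,
    csp_slope=None,
    logp=None,
    delta_tm_c=None,
    exclude: Iterable[str] = (),
) -> PotencyLedger:
    """Outer-join per-compound measures and compute pairwise correlations.

    Inputs are compound-keyed Series/dicts (or DataFrames with ``compound``
    and the value column).  Every pairwise Pearson correlation is computed
    over the intersection of non-missing compounds; pairs with fewer than 3
    common compounds are reported as unavailable (NaN PCC, n recorded).
    """
    columns = {
        "csat": csat,
        "csp_slope": csp_slope,
        "logp": logp,
        "delta_tm": delta_tm_c,
    }
    series = {
        name: _as_series(val, name) for name, val in columns.items() if val is not None
    }
    if not series:
        raise ValueError("provide at least one measure")
    table = pd.DataFrame(series)
    table.index.name = "compound"

    correlations: dict[tuple[str, str], CorrelationResult] = {}
    for a, b in combinations(series, 2):
        paired = table[[a, b]].dropna()
        if len(paired) >= 3:
            correlations[(a, b)] = pearson_with_exclusion(
                paired[a], paired[b], exclude=exclude
            )
        else:
            correlations[(a, b)] = CorrelationResult(
                pcc=float("nan"),
                n=len(paired),
                pcc_excluded=None,
                n_excluded=0,
                excluded_labels=tuple(exclude),
            )
    return PotencyLedger(table=table, correlations=correlations)
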