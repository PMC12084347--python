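"""NMR analysis: referencing, chemical-shift perturbations, relaxation.

Covers indirect chemical-shift referencing from the 1H carrier, per-residue
chemical shift perturbations (CSPs) between a reference and a cosolvent
condition, residue-type binning, cross-condition slope/correlation analysis
(the shared-pattern potency readout), monoexponential relaxation-rate fitting
(R1/R2), and heteronuclear NOE ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

__all__ = [
    "REFERENCING_RATIOS",
    "R2_DELAYS_S",
    "R1_DELAYS_S",
    "indirect_reference_frequency",
    "compute_csp",
    "combined_csp",
    "bin_csp_by_residue_type",
    "cross_condition_slope",
    "SlopeFit",
    "fit_relaxation_rate",
    "RateFit",
    "het_noe",
    "read_peaklist",
    "read_sparky_list",
]

#: Indirect referencing ratios Xi (percent of the 1H carrier frequency) for
#: DSS-referenced spectra.
REFERENCING_RATIOS = {"15N": 10.132912, "13C": 25.144953}

#: CPMG loop lengths (s) of a standard 15N R2 experiment series.
R2_DELAYS_S = (0.0165, 0.0331, 0.0826, 0.1157, 0.1653, 0.1818, 0.2644)
#: Inversion-recovery delays (s) of a standard 15N R1 experiment series.
R1_DELAYS_S = (0.1, 0.2, 0.3, 0.4, 0.6, 0.8, 1.0)


def indirect_reference_frequency(v_1h: float, nucleus: str) -> float:
    """Zero-point frequency of a heteronucleus from the 1H carrier (MHz).

    V_X = V_1H * Xi / 100 with the DSS gyromagnetic-ratio-derived constants
    Xi(15N) = 10.132912 and Xi(13C) = 25.144953.
    """
    if v_1h <= 0:
        raise ValueError("v_1h must be positive")
    try:
        ratio = REFERENCING_RATIOS[nucleus]
    except KeyError:
        raise ValueError(
            f"unknown nucleus {nucleus!r}; expected one of {sorted(REFERENCING_RATIOS)}"
        ) from None
    return v_1h * ratio / 100.0


# ---------------------------------------------------------------------------
# chemical shift perturbations
# ---------------------------------------------------------------------------

def compute_csp(
    reference: pd.DataFrame, condition: pd.DataFrame, nucleus: str = "15N"
) -> pd.DataFrame:
    """Signed per-residue CSP table between two peak lists.

    delta_ppm = shift(condition) - shift(reference); intensity_ratio =
    I(condition)/I(reference).  Residues present in only one list appear with
    NaN (missing, never imputed to zero).  Raises if the residue sets are
    disjoint.
    """
    ref = reference[reference["nucleus"] == nucleus]
    cond = condition[condition["nucleus"] == nucleus]
    merged = ref.merge(
        cond,
        on="residue_index",
        how="outer",
        suffixes=("_ref", "_cond"),
    ).sort_values("residue_index")
    both = merged["shift_ppm_ref"].notna() & merged["shift_ppm_cond"].notna()
    if not both.any():
        raise ValueError("peak lists share no residues for this nucleus")
    rtype = merged["residue_type_ref"].where(
        merged["residue_type_ref"].notna(), merged["residue_type_cond"]
    )
    return pd.DataFrame(
        {
            "residue_index": merged["residue_index"].to_numpy(),
            "residue_type": rtype.to_numpy(),
            "nucleus": nucleus,
            "delta_ppm": (
                merged["shift_ppm_cond"] - merged["shift_ppm_ref"]
            ).to_numpy(),
            "intensity_ratio": (
                merged["intensity_cond"] / merged["intensity_ref"]
            ).to_numpy(),
        }
    )


def combined_csp(
    csp_1h: pd.DataFrame, csp_15n: pd.DataFrame, n_scale: float = 0.2
) -> pd.DataFrame:
    """Optional Euclidean combined CSP sqrt(d_H^2 + (a d_N)^2), a = 0.2.

    Per-nucleus tables remain the primary representation; this combination is
    provided for comparison with the common single-number convention.
    """
    merged = csp_1h.merge(
        csp_15n, on="residue_index", suffixes=("_1h", "_15n")
    )
    d = np.sqrt(
        merged["delta_ppm_1h"] ** 2 + (n_scale * merged["delta_ppm_15n"]) ** 2
    )
    return pd.DataFrame(
        {
            "residue_index": merged["residue_index"],
            "residue_type": merged["residue_type_1h"],
            "delta_ppm": d,
        }
    )


def bin_csp_by_residue_type(
    table: pd.DataFrame,
    sequence: str | None = None,
    signed: bool = False,
) -> pd.DataFrame:
    """Group CSPs by residue type: mean, sd, n, and the individual values.

    Uses |delta| by default (magnitude binning); ``signed=True`` keeps signs.
    If ``sequence`` is given it must agree with the table's residue types at
    every populated position.
    """
    tab = table.dropna(subset=["delta_ppm"]).copy()
    if sequence is not None:
        for _, row in tab.iterrows():
            idx = int(row["residue_index"])
            if idx < 1 or idx > len(sequence):
                raise ValueError(f"residue {idx} outside the provided sequence")
            if sequence[idx - 1] != row["residue_type"]:
                raise ValueError(
                    f"residue {idx}: table says {row['residue_type']!r}, "
                    f"sequence says {sequence[idx - 1]!r}"
                )
    values = tab["delta_ppm"] if signed else tab["delta_ppm"].abs()
    tab = tab.assign(value=values)
    out = (
        tab.groupby("residue_type")["value"]
        .agg(mean="mean", sd="std", n="count", values=list)
        .reset_index()
    )
    return out


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    pcc: float
    n: int
    fit: str  # "intercept" | "origin"


def cross_condition_slope(
    table_x: pd.DataFrame,
    table_ref: pd.DataFrame,
    fit: str = "intercept",
) -> SlopeFit:
    """Least-squares slope of one condition's CSPs against a reference's.

    Fits delta_x = m * delta_ref (+ b) over residues present in both tables
    and reports the Pearson correlation alongside.  ``fit`` selects ordinary
    least squares with intercept (default) or through-origin.
    """
    merged = table_x.merge(
        table_ref, on="residue_index", suffixes=("_x", "_ref")
    ).dropna(subset=["delta_ppm_x", "delta_ppm_ref"])
    if len(merged) < 3:
        raise ValueError("need at least 3 common residues")
    x = merged["delta_ppm_ref"].to_numpy()
    y = merged["delta_ppm_x"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("reference CSPs have zero variance")
    if fit == "intercept":
        slope, intercept = np.polyfit(x, y, 1)
    elif fit == "origin":
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        raise ValueError("fit must be 'intercept' or 'origin'")
    pcc = float(pearsonr(x, y).statistic) if np.ptp(y) > 0 else float("nan")
    return SlopeFit(
        slope=float(slope),
        intercept=float(intercept),
        pcc=pcc,
        n=len(merged),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------

@dataclass
class RateFit:
    rate: float  # s^-1
    rate_err: float
    i0: float
    non_decaying: bool  # fit warning: data do not decay


def fit_relaxation_rate(
    delays_s: np.ndarray, intensities: np.ndarray
) -> RateFit:
    """Monoexponential I(t) = I0 exp(-R t) fit for R1/R2 series.

    Requires >= 3 distinct delays with positive intensities.  Initial values
    come from the log-linear regression; uncertainties from the fit
    covariance.  Non-decaying data (fitted R <= 0) are returned with a warning
    flag rather than clamped.
    """
    t = np.asarray(delays_s, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct relaxation delays")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")
    slope, logi0 = np.polyfit(t, np.log(y), 1)
    p0 = (float(np.exp(logi0)), float(-slope))
    popt, pcov = curve_fit(
        lambda tt, i0, r: i0 * np.exp(-r * tt),
        t,
        y,
        p0=p0,
        maxfev=10000,
        xtol=1e-12,
        ftol=1e-12,
    )
    i0, rate = popt
    rate_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return RateFit(
        rate=float(rate),
        rate_err=rate_err,
        i0=float(i0),
        non_decaying=bool(rate <= 1e-9),
    )


def het_noe(i_saturated: float, i_reference: float) -> float:
    """Heteronuclear NOE ratio I_sat / I_ref (values < 0.5 indicate disorder)."""
    if i_reference == 0:
        raise ValueError("reference intensity must be nonzero")
    return i_saturated / i_reference


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_peaklist(path) -> pd.DataFrame:
    """Read a CSV peak list (residue_index,residue_type,nucleus,shift_ppm,...)."""
    df = pd.read_csv(path)
    required = {"residue_index", "residue_type", "nucleus", "shift_ppm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns: {sorted(missing)}")
    return df


def read_sparky_list(path, nucleus: str = "15N", condition: str = "") -> pd.DataFrame:
    """Read a simple Sparky-style peak list: 'G12N-H  118.23  8.45  [height]'.

    The w1 (heteronucleus) shift and optional height column are kept; the
    residue type and index are parsed from the assignment label.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].lower().startswith(("assignment", "w1")):
                continue
            label = parts[0]
            rtype = label[0]
            digits = "".join(ch for ch in label[1:] if ch.isdigit())
            if not digits:
                continue
            rows.append(
                {
                    "residue_index": int(digits),
                    "residue_type": rtype,
                    "nucleus": nucleus,
                    "shift_ppm": float(parts[1]),
                    "intensity": float(parts[3]) if len(parts) > 3 else 1.0,
                    "condition": condition,
                }
            )
    if not rows:
        raise ValueError(f"no peaks parsed from {path}")
    return pd.DataFrame(rows)
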