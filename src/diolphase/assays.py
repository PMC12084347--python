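"""Phase-separation assay quantification.

Supernatant saturation-concentration (Csat) readout by Beer-Lambert,
two-wavelength (260/280 nm) deconvolution of protein and RNA contributions,
background-corrected turbidity, droplet segmentation (area fraction and
counts) from fluorescence images, and linear Csat-versus-cosolvent trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as _label, regionprops

__all__ = [
    "AbsorbanceRecord",
    "ExtinctionMatrix",
    "DropletQuant",
    "TrendFit",
    "concentration_from_a280",
    "deconvolve_protein_rna",
    "forward_absorbance",
    "turbidity_corrected",
    "droplet_area_fraction",
    "count_droplets",
    "fit_concentration_trend",
]


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One absorbance reading set (any subset of A260/A280/A600 present)."""

    a260: float | None = None
    a280: float | None = None
    a600: float | None = None
    pathlength_cm: float = 1.0
    dilution: float = 1.0
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for name, v in (("a260", self.a260), ("a280", self.a280), ("a600", self.a600)):
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength_cm must be > 0")


@dataclass(frozen=True)
class ExtinctionMatrix:
    """Extinction coefficients (per-concentration per-cm) at 260 and 280 nm."""

    protein_260: float
    protein_280: float
    rna_260: float
    rna_280: float

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.protein_260, self.rna_260], [self.protein_280, self.rna_280]]
        )

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.as_matrix())) < 1e-300:
            raise ValueError("extinction matrix is singular; cannot deconvolve")


@dataclass
class DropletQuant:
    area_fraction_pct: float
    count: int
    threshold: float
    min_area_px: int
    image_id: str = ""


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    n_points: int
    points: pd.DataFrame  # per-concentration mean, sd, n


def concentration_from_a280(rec: AbsorbanceRecord, epsilon_m_cm: float) -> float:
    """Protein concentration in uM from A280 by Beer-Lambert.

    c = A280 * dilution / (epsilon * pathlength), with epsilon in M^-1 cm^-1.
    """
    if epsilon_m_cm <= 0:
        raise ValueError("extinction coefficient must be > 0")
    if rec.a280 is None:
        raise ValueError("record has no A280 reading")
    molar = rec.a280 * rec.dilution / (epsilon_m_cm * rec.pathlength_cm)
    return molar * 1e6


def forward_absorbance(
    c_protein: float, c_rna: float, em: ExtinctionMatrix, pathlength_cm: float = 1.0
) -> tuple[float, float]:
    """(A260, A280) predicted from concentrations by the two-species model."""
    a = em.as_matrix() @ np.array([c_protein, c_rna]) * pathlength_cm
    return float(a[0]), float(a[1])


def deconvolve_protein_rna(
    rec: AbsorbanceRecord, em: ExtinctionMatrix
) -> tuple[float, float, bool]:
    """Split A260/A280 into (protein, RNA) concentrations via the 2x2 system.

    Returns (c_protein, c_rna, negative_flag); negative solutions are reported
    with the flag raised (typically a blank mismatch), never clipped.
    Concentration units follow the extinction-coefficient units.
    """
    if rec.a260 is None or rec.a280 is None:
        raise ValueError("record needs both A260 and A280")
    rhs = (
        np.array([rec.a260, rec.a280]) * rec.dilution / rec.pathlength_cm
    )
    c = np.linalg.solve(em.as_matrix(), rhs)
    return float(c[0]), float(c[1]), bool(np.any(c < 0))


def turbidity_corrected(
    sample: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Background-corrected turbidity with replicate aggregation.

    Both tables need columns ``condition`` and ``a600`` (and optionally
    ``replicate``).  The control mean for each condition is subtracted from
    every matching sample reading; negative corrected values are preserved.
    Output columns: condition, mean, sd, n.
    """
    missing = set(sample["condition"]) - set(control["condition"])
    if missing:
        raise ValueError(f"control lacks conditions: {sorted(missing)}")
    ctrl_mean = control.groupby("condition")["a600"].mean()
    corrected = sample.assign(
        corrected=sample["a600"] - sample["condition"].map(ctrl_mean)
    )
    out = (
        corrected.groupby("condition")["corrected"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def _threshold(image: np.ndarray, method: str, threshold: float | None) -> float:
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold value")
        return float(threshold)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError(
                "constant image: Otsu threshold undefined; use method='fixed'"
            )
        return float(threshold_otsu(image))
    raise ValueError("method must be 'otsu' or 'fixed'")


def droplet_area_fraction(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_area_px: int = 5,
    image_id: str = "",
) -> DropletQuant:
    """Percentage of above-threshold ('fluorescently illuminated') pixels.

    The area fraction counts every above-threshold pixel; the droplet count
    applies the min-area filter to 8-connected components.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    thr = _threshold(image, method, threshold)
    mask = image > thr
    fraction = 100.0 * float(mask.mean())
    count = _count_components(mask, min_area_px)
    return DropletQuant(
        area_fraction_pct=fraction,
        count=count,
        threshold=thr,
        min_area_px=min_area_px,
        image_id=image_id,
    )


def _count_components(mask: np.ndarray, min_area_px: int) -> int:
    if not mask.any():
        return 0
    labels = _label(mask, connectivity=2)
    return sum(1 for p in regionprops(labels) if p.area >= min_area_px)


def count_droplets(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_area_px: int = 5,
) -> int:
    """Number of 8-connected above-threshold regions with area >= min_area_px."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    thr = _threshold(image, method, threshold)
    return _count_components(image > thr, min_area_px)


def fit_concentration_trend(
    points: pd.DataFrame, weighted: bool = False
) -> TrendFit:
    """OLS line through (cosolvent %, Csat) replicate means.

    ``points`` needs columns ``concentration`` and ``value`` (one row per
    replicate).  ``weighted=True`` weights each mean by 1/sd^2 where replicate
    scatter is available.
    """
    agg = (
        points.groupby("concentration")["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    if len(agg) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    x = agg["concentration"].to_numpy(dtype=float)
    y = agg["mean"].to_numpy(dtype=float)
    if weighted and agg["sd"].notna().all() and (agg["sd"] > 0).all():
        w = 1.0 / agg["sd"].to_numpy() ** 2
        wls = np.polyfit(x, y, 1, w=np.sqrt(w))
        slope, intercept = float(wls[0]), float(wls[1])
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(w * resid**2))
        ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        stderr = float("nan")
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
        stderr = float(res.stderr)
    return TrendFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_stderr=stderr,
        n_points=len(agg),
        points=agg,
    )
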