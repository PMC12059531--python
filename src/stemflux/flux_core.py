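"""Closed-chamber stem CO2 efflux (EA) computation and quality control.

A chamber clamped to a stem collar accumulates CO2 while closed; the efflux
per unit stem surface is recovered from the initial linear rise of the
(water-corrected) CO2 mole fraction:

    EA = 10 * V * P0 * (1 - W0/1000) / (R * S * (T0 + 273.15)) * dC'/dt

with V the system volume (cm^3), P0 the initial pressure (kPa), W0 the
initial water vapour mole fraction (mmol mol^-1), S the collar area (cm^2),
T0 the initial air temperature (degC), R = 8.314 J mol^-1 K^-1, and dC'/dt
the fitted slope (umol mol^-1 s^-1).  The leading factor 10 collects the
unit conversions so that EA comes out in umol m^-2 s^-1.

The first seconds after closure (the *dead band*) are excluded from the
slope fit while the headspace mixes.  Fluxes are quality-controlled by a
minimum-r2 gate and a per-tree 1.5*IQR outlier rule, optionally standardized
to a reference temperature with a Q10 factor, and reported in
mg C m^-2 h^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GAS_CONSTANT = 8.314
"""Universal gas constant, J mol^-1 K^-1."""

CARBON_MOLAR_MASS = 12.011
"""Molar mass of carbon, g mol^-1; one umol CO2 carries 12.011 ug C."""

UMOL_S_TO_MGC_H = CARBON_MOLAR_MASS * 3600.0 / 1000.0
"""Conversion factor from umol CO2 m^-2 s^-1 to mg C m^-2 h^-1 (43.2396)."""

FluxMode = Literal["closed_system", "ideal_gas"]


class DegenerateSeriesError(ValueError):
    """Raised when a concentration series has too few usable points."""


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and timing of one chamber system.

    Parameters
    ----------
    system_volume_cm3 : total enclosed volume, chamber plus tubing (V).
    collar_area_cm2 : stem surface enclosed by the collar (S).
    dead_band_s : initial seconds excluded from the slope fit.
    closure_duration_s : total closure length.
    """

    system_volume_cm3: float
    collar_area_cm2: float
    dead_band_s: float = 90.0
    closure_duration_s: float = 180.0

    def __post_init__(self) -> None:
        for name in ("system_volume_cm3", "collar_area_cm2",
                     "dead_band_s", "closure_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dead_band_s >= self.closure_duration_s:
            raise ValueError("dead_band_s must be shorter than closure_duration_s")


@dataclass
class ConcentrationSeries:
    """One chamber closure's gas concentrations over time.

    ``h2o``, ``pressure`` and ``temperature`` may be scalars (held constant)
    or arrays aligned with ``time_s``; only the first post-dead-band sample
    (the "initial" conditions P0, W0, T0) enters the flux equation.
    """

    time_s: np.ndarray
    co2_umol_mol: np.ndarray
    h2o_mmol_mol: np.ndarray | float = 0.0
    pressure_kpa: np.ndarray | float = 101.325
    temp_c: np.ndarray | float = 25.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.co2_umol_mol = np.asarray(self.co2_umol_mol, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.co2_umol_mol.shape:
            raise ValueError("time_s and co2_umol_mol must be 1-d and aligned")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any(self.co2_umol_mol < 0):
            raise ValueError("co2_umol_mol must be non-negative")
        for name in ("h2o_mmol_mol", "pressure_kpa", "temp_c"):
            val = np.asarray(getattr(self, name), dtype=float)
            if val.ndim == 0:
                val = np.full_like(self.time_s, float(val))
            elif val.shape != self.time_s.shape:
                raise ValueError(f"{name} must be scalar or aligned with time_s")
            setattr(self, name, val)

    def after_dead_band(self, dead_band_s: float) -> "ConcentrationSeries":
        """Return the sub-series with ``time_s >= dead_band_s``."""
        mask = self.time_s >= dead_band_s
        if int(mask.sum()) < 3:
            raise DegenerateSeriesError(
                f"only {int(mask.sum())} samples after the {dead_band_s}-s dead band; "
                "need at least 3"
            )
        return ConcentrationSeries(
            self.time_s[mask], self.co2_umol_mol[mask],
            self.h2o_mmol_mol[mask], self.pressure_kpa[mask], self.temp_c[mask],
        )


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of CO2 mole fraction against time."""

    slope: float          # umol mol^-1 s^-1
    intercept: float      # umol mol^-1
    r2: float             # coefficient of determination in [0, 1]
    n: int                # points used (post dead band)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must lie in [0, 1]")


@dataclass
class FluxObservation:
    """One EA value with its metadata and QC state."""

    tree_tag: str
    datetime: object
    ea: float                  # mg C m^-2 h^-1
    ea_raw: float              # umol m^-2 s^-1
    temperature: float         # degC
    height: float = 1.1        # m above ground
    position: str = "stem"     # buttress | stem | above_branch
    fit_r2: float = float("nan")
    qc_flag: str = "ok"        # ok | outlier | leak | error


def fit_concentration_slope(series: ConcentrationSeries,
                            chamber: ChamberSpec) -> SlopeFit:
    """Fit the post-dead-band CO2 rise by ordinary least squares.

    A zero-variance series (flat CO2) yields slope 0 with r2 reported as 0
    by convention, so downstream QC thresholds remain applicable.
    """
    sub = series.after_dead_band(chamber.dead_band_s)
    if np.ptp(sub.co2_umol_mol) == 0.0:
        return SlopeFit(slope=0.0, intercept=float(sub.co2_umol_mol[0]),
                        r2=0.0, n=len(sub.time_s))
    res = stats.linregress(sub.time_s, sub.co2_umol_mol)
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    r2=float(res.rvalue ** 2), n=len(sub.time_s))


def chamber_flux(fit: SlopeFit, series: ConcentrationSeries,
                 chamber: ChamberSpec, mode: FluxMode = "closed_system") -> float:
    """Convert a fitted concentration slope into a flux (umol m^-2 s^-1).

    ``closed_system`` applies the full equation including the water-vapour
    dilution term (1 - W0/1000); ``ideal_gas`` omits the water correction
    (W0 forced to 0), the form used by EGM-style analysers.  P0, W0 and T0
    are taken from the first post-dead-band sample.
    """
    if mode not in ("closed_system", "ideal_gas"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = series.after_dead_band(chamber.dead_band_s)
    p0 = float(sub.pressure_kpa[0])
    t0 = float(sub.temp_c[0])
    w0 = 0.0 if mode == "ideal_gas" else float(sub.h2o_mmol_mol[0])
    v = chamber.system_volume_cm3
    s = chamber.collar_area_cm2
    return (10.0 * v * p0 * (1.0 - w0 / 1000.0)
            / (GAS_CONSTANT * s * (t0 + 273.15)) * fit.slope)


def convert_flux_units(flux_umol_m2_s: float | np.ndarray) -> float | np.ndarray:
    """umol CO2 m^-2 s^-1 -> mg C m^-2 h^-1 (factor 12.011 * 3600 / 1000)."""
    return flux_umol_m2_s * UMOL_S_TO_MGC_H


def hourly_to_daily(ea_mgc_m2_h: float | np.ndarray) -> float | np.ndarray:
    """mg C m^-2 h^-1 -> g C m^-2 d^-1 (x 24 / 1000)."""
    return ea_mgc_m2_h * 24.0 / 1000.0


def q10_standardize(ea: float | np.ndarray, measured_t: float | np.ndarray,
                    reference_t: float = 25.0, q10: float = 2.0):
    """Standardize a flux to a reference temperature with a Q10 factor.

    ``ea * q10 ** ((reference_t - measured_t) / 10)``; Q10 = 2 halves the
    flux for a measurement 10 degC above the reference.
    """
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return ea * q10 ** ((np.asarray(reference_t) - np.asarray(measured_t)) / 10.0)


@dataclass
class IQRFilterResult:
    kept: np.ndarray
    kept_indices: np.ndarray
    removed_indices: np.ndarray
    warned: bool = False      # group too small for quartiles; passed through


def iqr_outlier_filter(values: Sequence[float], k: float = 1.5) -> IQRFilterResult:
    """Remove values beyond ``k`` interquartile ranges from the quartiles.

    Quartiles use linear interpolation between order statistics.  Groups of
    fewer than 4 values pass through unchanged with ``warned=True``.
    """
    arr = np.asarray(values, dtype=float)
    idx = np.arange(arr.size)
    if arr.size < 4:
        warnings.warn("group smaller than 4; IQR filter passed through", stacklevel=2)
        return IQRFilterResult(arr, idx, np.empty(0, dtype=int), warned=True)
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    keep = (arr >= q1 - k * iqr) & (arr <= q3 + k * iqr)
    return IQRFilterResult(arr[keep], idx[keep], idx[~keep])


def filter_flux_table(table: pd.DataFrame, value_col: str = "ea",
                      group_col: str = "tree_tag", k: float = 1.5) -> pd.DataFrame:
    """Apply the per-tree IQR rule to a flux table, setting ``qc_flag``.

    Rows already flagged (qc_flag != 'ok') are excluded from quartile
    computation and left untouched.
    """
    out = table.copy()
    if "qc_flag" not in out.columns:
        out["qc_flag"] = "ok"
    for _, grp in out[out["qc_flag"] == "ok"].groupby(group_col):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = iqr_outlier_filter(grp[value_col].to_numpy(), k=k)
        out.loc[grp.index[res.removed_indices], "qc_flag"] = "outlier"
    return out


def process_closures(series_table: pd.DataFrame, chamber: ChamberSpec,
                     mode: FluxMode = "closed_system",
                     min_r2: float = 0.9,
                     q10: float | None = None,
                     reference_t: float = 25.0,
                     iqr_filter: bool = True) -> pd.DataFrame:
    """End-to-end: long-format closure table -> QC'd flux table.

    ``series_table`` columns: closure_id, tree_tag, time_s, co2_umol_mol,
    h2o_mmol_mol, pressure_kpa, temp_c, and optionally datetime.  Returns one
    row per closure with ea (mg C m^-2 h^-1), ea_raw (umol m^-2 s^-1),
    fit_r2 and qc_flag.  Slope fits with r2 below ``min_r2`` are flagged
    'leak' (leaks and mechanical faults degrade linearity); negative fluxes
    are flagged 'error'.  ``q10=None`` leaves fluxes at measurement
    temperature (diel data); pass e.g. ``q10=2.0`` to standardize to
    ``reference_t`` (vertical-profile data).
    """
    rows = []
    for closure_id, grp in series_table.groupby("closure_id", sort=False):
        grp = grp.sort_values("time_s")
        series = ConcentrationSeries(
            grp["time_s"].to_numpy(), grp["co2_umol_mol"].to_numpy(),
            grp["h2o_mmol_mol"].to_numpy() if "h2o_mmol_mol" in grp else 0.0,
            grp["pressure_kpa"].to_numpy() if "pressure_kpa" in grp else 101.325,
            grp["temp_c"].to_numpy() if "temp_c" in grp else 25.0,
        )
        fit = fit_concentration_slope(series, chamber)
        raw = chamber_flux(fit, series, chamber, mode=mode)
        t_meas = float(series.after_dead_band(chamber.dead_band_s).temp_c[0])
        ea = convert_flux_units(raw)
        if q10 is not None:
            ea = q10_standardize(ea, t_meas, reference_t, q10)
        flag = "ok"
        if fit.r2 < min_r2:
            flag = "leak"
        elif raw < 0:
            flag = "error"
        rows.append({
            "closure_id": closure_id,
            "tree_tag": grp["tree_tag"].iloc[0],
            "datetime": grp["datetime"].iloc[0] if "datetime" in grp else pd.NaT,
            "ea": float(ea), "ea_raw": float(raw),
            "temperature": t_meas, "fit_r2": fit.r2, "qc_flag": flag,
        })
    out = pd.DataFrame(rows)
    if iqr_filter and len(out):
        out = filter_flux_table(out)
    return out
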