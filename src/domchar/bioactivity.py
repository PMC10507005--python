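"""Bioassay quantification: percent inhibition, IC50, TEAC and
descriptor-activity regressions.

IC50 values come either from log-linear interpolation of the dilution
series around the 50% crossing (the default, matching screening practice)
or from a four-parameter logistic fit. Samples never reaching 50%
inhibition at the top concentration are censored as ">Cmax" and excluded
from regressions. Antioxidant readouts can be converted to
Trolox-equivalent antioxidant capacity (TEAC) per gram dry weight via a
Trolox calibration line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "percent_inhibition",
    "DoseResponse",
    "Ic50Result",
    "ic50",
    "ic50_table",
    "TeacResult",
    "fit_trolox_calibration",
    "teac",
    "FitResult",
    "regress",
]


def percent_inhibition(signal: float, negative_control: float) -> float:
    """100 x (1 - signal / negative control)."""
    if negative_control <= 0:
        raise ValueError("negative control must be positive")
    return 100.0 * (1.0 - signal / negative_control)


@dataclass
class DoseResponse:
    """One sample's concentration / inhibition series for one assay."""

    sample_id: str
    assay: str
    concentration: np.ndarray   # ug/mL, > 0
    inhibition: np.ndarray      # percent; may stray outside [0, 100] with noise

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.concentration.shape != self.inhibition.shape:
            raise ValueError("concentration and inhibition must align")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be positive")
        order = np.argsort(self.concentration)
        self.concentration = self.concentration[order]
        self.inhibition = self.inhibition[order]


@dataclass
class Ic50Result:
    sample_id: str
    assay: str
    ic50: float | None          # ug/mL; None when censored
    censored: bool
    cmax: float
    method: str

    @property
    def label(self) -> str:
        return f">{self.cmax:g}" if self.censored else f"{self.ic50:.4g}"


def _four_pl(conc, bottom, top, ic50_, hill):
    return bottom + (top - bottom) / (1.0 + (ic50_ / conc) ** hill)


def ic50(curve: DoseResponse, method: str = "interpolation") -> Ic50Result:
    """Half-maximal inhibitory concentration of one dose-response curve.

    ``interpolation``: if the maximum inhibition stays below 50% the result
    is censored at the top concentration; otherwise the 50% crossing is
    linearly interpolated in log10(concentration) between the bracketing
    points (the lowest crossing wins, with a warning, if the curve is
    non-monotone). ``logistic``: four-parameter logistic fit, midpoint
    reported.
    """
    if curve.concentration.size < 2:
        raise ValueError("need at least two concentrations")
    cmax = float(curve.concentration.max())
    if curve.inhibition.max() < 50.0:
        return Ic50Result(curve.sample_id, curve.assay, None, True, cmax, method)

    if method == "interpolation":
        above = curve.inhibition >= 50.0
        crossings = np.nonzero(above[1:] & ~above[:-1])[0]
        if above[0]:
            # already above 50% at the lowest concentration
            return Ic50Result(
                curve.sample_id, curve.assay, float(curve.concentration[0]),
                False, cmax, method,
            )
        if crossings.size > 1:
            warnings.warn(
                f"non-monotone curve for {curve.sample_id}; "
                "using the lowest 50% crossing",
                stacklevel=2,
            )
        i = int(crossings[0])
        x0, x1 = np.log10(curve.concentration[i : i + 2])
        y0, y1 = curve.inhibition[i : i + 2]
        logc = x0 + (50.0 - y0) / (y1 - y0) * (x1 - x0)
        return Ic50Result(
            curve.sample_id, curve.assay, float(10.0**logc), False, cmax, method
        )

    if method == "logistic":
        c = curve.concentration
        y = curve.inhibition
        mid0 = float(np.exp(np.interp(50.0, np.sort(y), np.log(c[np.argsort(y)]))))
        p0 = [0.0, 100.0, np.clip(mid0, c.min(), c.max()), 1.0]
        try:
            popt, _ = optimize.curve_fit(
                _four_pl, c, y, p0=p0,
                bounds=([-20.0, 50.0, c.min() / 100.0, 0.2],
                        [20.0, 150.0, c.max() * 100.0, 5.0]),
                maxfev=10_000,
            )
        except RuntimeError as exc:
            raise ValueError(f"logistic fit failed for {curve.sample_id}") from exc
        return Ic50Result(
            curve.sample_id, curve.assay, float(popt[2]), False, cmax, method
        )

    raise ValueError(f"unknown method {method!r}")


def ic50_table(
    plate: pd.DataFrame, method: str = "interpolation"
) -> pd.DataFrame:
    """Per-sample, per-assay IC50 mean +- sd over replicate curves.

    ``plate`` columns: sample_id, assay, concentration_ug_ml, replicate,
    percent_inhibition. Wells at concentration 0 (negative controls) are
    ignored. Replicate curves are fitted independently; a sample is
    censored when every replicate is censored.
    """
    rows = []
    wells = plate[plate["concentration_ug_ml"] > 0]
    for (sample, assay), sub in wells.groupby(["sample_id", "assay"], sort=True):
        reps = []
        for _, rsub in sub.groupby("replicate"):
            curve = DoseResponse(
                sample_id=sample,
                assay=assay,
                concentration=rsub["concentration_ug_ml"].to_numpy(),
                inhibition=rsub["percent_inhibition"].to_numpy(),
            )
            reps.append(ic50(curve, method=method))
        values = [r.ic50 for r in reps if not r.censored]
        cmax = reps[0].cmax
        if not values:
            rows.append(
                {"sample_id": sample, "assay": assay, "ic50_mean": np.nan,
                 "ic50_sd": np.nan, "censored": True, "label": f">{cmax:g}",
                 "n_replicates": len(reps)}
            )
            continue
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else np.nan
        rows.append(
            {"sample_id": sample, "assay": assay, "ic50_mean": mean,
             "ic50_sd": sd, "censored": False,
             "label": f"{mean:.1f} (± {sd:.1f})" if np.isfinite(sd) else f"{mean:.1f}",
             "n_replicates": len(reps)}
        )
    return pd.DataFrame(rows).set_index(["sample_id", "assay"])


@dataclass
class TeacResult:
    slope: float
    intercept: float
    r2: float
    teac_umol_per_g: float | None = None


def fit_trolox_calibration(
    trolox_umol: np.ndarray, scavenging_pct: np.ndarray
) -> TeacResult:
    """Linear Trolox standard curve: % scavenging vs µmol Trolox."""
    x = np.asarray(trolox_umol, dtype=float)
    y = np.asarray(scavenging_pct, dtype=float)
    if x.size < 3:
        raise ValueError("Trolox calibration needs at least 3 points")
    fit = stats.linregress(x, y)
    return TeacResult(slope=float(fit.slope), intercept=float(fit.intercept),
                      r2=float(fit.rvalue**2))


def teac(
    activity_pct: float, calibration: TeacResult, dw_mass_g: float
) -> float:
    """Convert % radical scavenging to µmol Trolox equivalents per g DW."""
    if abs(calibration.slope) < 1e-12:
        raise ValueError("degenerate Trolox calibration (zero slope)")
    if dw_mass_g <= 0:
        raise ValueError("dry weight must be positive")
    umol = (activity_pct - calibration.intercept) / calibration.slope
    return umol / dw_mass_g


@dataclass
class FitResult:
    """Simple linear regression between a descriptor and a bioactivity."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    n_censored: int = 0

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def regress(
    descriptor: pd.Series | np.ndarray,
    response: pd.Series | np.ndarray,
    n_censored: int = 0,
) -> FitResult:
    """OLS of bioactivity on a molecular descriptor, with slope p-value.

    Pairs with non-finite values (e.g. censored IC50s already set to NaN)
    are dropped and counted; at least 3 finite pairs and a non-constant
    descriptor are required.
    """
    if isinstance(descriptor, pd.Series) and isinstance(response, pd.Series):
        df = pd.concat([descriptor, response], axis=1, join="inner")
        x = df.iloc[:, 0].to_numpy(float)
        y = df.iloc[:, 1].to_numpy(float)
    else:
        x = np.asarray(descriptor, dtype=float)
        y = np.asarray(response, dtype=float)
        if x.shape != y.shape:
            raise ValueError("descriptor and response must align")
    finite = np.isfinite(x) & np.isfinite(y)
    n_censored += int((~finite).sum())
    x, y = x[finite], y[finite]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0:
        raise ValueError("constant descriptor: slope inference undefined")
    fit = stats.linregress(x, y)
    return FitResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue**2), p_value=float(fit.pvalue),
        n=int(x.size), n_censored=n_censored,
    )
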