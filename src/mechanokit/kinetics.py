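"""Esterase kinetics: initial rates, Michaelis–Menten fits, relative activity.

Progress curves are absorbance-vs-time series (the chromogenic readouts:
p-nitrophenol at 400 nm, nitrocefin at 496 nm, thionitrobenzoate at 420 nm
for the DTNB thiol assay).  Initial rates come from an ordinary
least-squares line over the early window; (S, v) tables are fit to
v = Vmax·S/(Km + S) by nonlinear least squares with asymptotic standard
errors from the Jacobian.  When every assayed concentration saturates the
enzyme (v ≈ Vmax at all S) the Km is not identified, only bounded above by
the smallest S; the fit flags this regime instead of reporting a precise Km
— this is how a sub-nM Km manifests when the practical concentration range
sits far above it.

Wavelengths are metadata: rates stay in AU/s unless an extinction
coefficient is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ProgressCurve",
    "RateEstimate",
    "MMFit",
    "initial_rate",
    "mm_fit",
    "relative_activity",
    "dtnb_endpoint",
]

MIN_WINDOW = 5


@dataclass
class ProgressCurve:
    times: np.ndarray  # s
    absorbance: np.ndarray  # AU
    wavelength: float | None = None  # nm, metadata only
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape or self.times.ndim != 1:
            raise ValueError("times and absorbance must be 1D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RateEstimate:
    slope: float  # AU/s
    intercept: float  # AU
    r2: float
    window: tuple[int, int]  # [start, stop) indices
    stderr: float


@dataclass
class MMFit:
    Km: float
    Vmax: float
    Km_se: float
    Vmax_se: float
    rss: float
    n_points: int
    converged: bool
    km_upper_bound_regime: bool = False
    km_upper_bound: float | None = None  # smallest assayed S when flagged

    def predict(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.Vmax * S / (self.Km + S)


def initial_rate(
    c: ProgressCurve,
    window: tuple[int, int] | None = None,
    blank: ProgressCurve | None = None,
) -> RateEstimate:
    """OLS slope of the early linear part of a progress curve.

    Default window: the first 20% of points, never fewer than 5.  A blank
    (control) curve on the same time grid is subtracted when supplied.
    """
    n = len(c.times)
    if n < MIN_WINDOW:
        raise ValueError(f"need at least {MIN_WINDOW} points, got {n}")
    y = c.absorbance
    if blank is not None:
        if not np.array_equal(blank.times, c.times):
            raise ValueError("blank curve must share the sample's time grid")
        y = y - blank.absorbance
    if window is None:
        stop = max(MIN_WINDOW, int(np.ceil(0.2 * n)))
        window = (0, stop)
    lo, hi = window
    if hi - lo < MIN_WINDOW:
        raise ValueError(f"window must span at least {MIN_WINDOW} points")
    t_w, y_w = c.times[lo:hi], y[lo:hi]
    res = stats.linregress(t_w, y_w)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return RateEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        window=(lo, hi),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
    )


def _mm(S: np.ndarray, Vmax: float, Km: float) -> np.ndarray:
    return Vmax * S / (Km + S)


def mm_fit(points: list[tuple[float, float]] | np.ndarray) -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit of an (S, v) table.

    Initialization: Vmax₀ = max v; Km₀ = the S at the first v ≥ Vmax₀/2.
    Standard errors are asymptotic (from the Jacobian at the optimum).  The
    ``km_upper_bound_regime`` flag is set when the fitted Km falls below the
    smallest assayed concentration — the data then only bound Km above by
    min(S) and the point estimate should not be read as a measurement.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (S, v) rows")
    S, v = arr[:, 0], arr[:, 1]
    if np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive")
    if np.any(v < 0):
        raise ValueError("rates must be non-negative")
    if len(np.unique(S)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all rates are zero; nothing to fit")
    order = np.argsort(S)
    above = v[order] >= vmax0 / 2
    km0 = float(S[order][above][0]) if above.any() else float(np.median(S))
    try:
        popt, pcov = optimize.curve_fit(
            _mm,
            S,
            v,
            p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax_hat, km_hat = float(popt[0]), float(popt[1])
    resid = v - _mm(S, *popt)
    rss = float(resid @ resid)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.inf, np.inf])
    s_min = float(S.min())
    upper = km_hat < s_min
    return MMFit(
        Km=km_hat,
        Vmax=vmax_hat,
        Km_se=float(se[1]),
        Vmax_se=float(se[0]),
        rss=rss,
        n_points=len(S),
        converged=True,
        km_upper_bound_regime=upper,
        km_upper_bound=s_min if upper else None,
    )


def relative_activity(
    groups: dict[str, list[float] | np.ndarray], reference: str
) -> pd.DataFrame:
    """Percent activity of each group relative to the reference group mean.

    The reference row is exactly 100%; group standard deviations are scaled
    by the same normalization factor.  Replicate counts are reported.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not in groups")
    ref = np.asarray(groups[reference], dtype=float)
    if len(ref) == 0:
        raise ValueError("reference group is empty")
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise ValueError("reference group mean is zero")
    rows = []
    for label, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(
            {
                "label": label,
                "n": len(vals),
                "mean_pct": 100.0 * vals.mean() / ref_mean,
                "sd_pct": 100.0 * sd / ref_mean,
            }
        )
    return pd.DataFrame(rows)


def dtnb_endpoint(
    points: ProgressCurve, control: ProgressCurve
) -> tuple[ProgressCurve, RateEstimate]:
    """Control-subtracted thioesterase (DTNB) endpoint series and its rate.

    The DTNB assay quenches the reaction at intervals and reads
    thionitrobenzoate at 420 nm; subtracting the paired no-enzyme control
    leaves the product-formation signal, whose slope is the rate.
    """
    if not np.array_equal(points.times, control.times):
        raise ValueError("sample and control time grids differ")
    corrected = ProgressCurve(
        times=points.times,
        absorbance=points.absorbance - control.absorbance,
        wavelength=points.wavelength,
        label=(points.label + " - control").strip(),
    )
    full = (0, len(corrected.times))
    return corrected, initial_rate(corrected, window=full)
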