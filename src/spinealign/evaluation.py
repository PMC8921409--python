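"""Rater-agreement statistics for paired angle measurements.

Implements the validation machinery used to compare an automated measurement
series against manual reference series: Pearson correlation and its square,
mean absolute error (MAE), the sample standard deviation of absolute errors
(STD of AE), Bland-Altman limits of agreement (mean difference +/- 1.96 SD
of the signed differences), detection-rate curves (fraction of cases whose
absolute error is strictly smaller than a threshold), two-expert comparison
tables and the min-over-experts error summary.

Statistics never depend on plotting; the figure helpers at the bottom are
optional conveniences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements", "AgreementStats", "BlandAltman", "DetectionRateCurve",
    "agreement", "detection_rate", "expert_table", "min_expert_error",
    "bland_altman_plot", "detection_rate_plot", "correlation_plot",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Two aligned measurement series (degrees) for one parameter."""

    case_ids: tuple[str, ...]
    method_a: np.ndarray
    method_b: np.ndarray
    parameter: str = ""

    def __post_init__(self) -> None:
        a, b = np.asarray(self.method_a, float), np.asarray(self.method_b, float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("method_a/method_b must be equal-length 1-D series")
        if len(a) < 2:
            raise ValueError("need at least 2 paired measurements")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("missing values must be dropped before pairing")
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)

    @staticmethod
    def from_arrays(a, b, parameter: str = "") -> "PairedMeasurements":
        a = np.asarray(a, float)
        ids = tuple(f"case_{i}" for i in range(len(a)))
        return PairedMeasurements(ids, a, np.asarray(b, float), parameter)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class AgreementStats:
    corr: float            # Pearson r (NaN when undefined, see flag)
    r2: float              # r squared
    mae: float             # mean |a - b|, degrees
    std_ae: float          # sample SD (n-1) of |a - b|, degrees
    bland_altman: BlandAltman
    n: int
    undefined_correlation: bool = False


def agreement(p: PairedMeasurements, *, ddof: int = 1) -> AgreementStats:
    """Agreement summary of two paired series.

    Pearson r is computed on the raw pairs and R^2 as its square; MAE and
    STD of AE summarize absolute differences (sample SD, configurable via
    ``ddof``); Bland-Altman summarizes the signed differences a - b with
    limits of agreement at mean +/- 1.96 SD.  Zero variance in either series
    leaves the correlation undefined: it is flagged, not silently NaN.
    """
    a, b = p.method_a, p.method_b
    d = a - b
    ae = np.abs(d)
    sd = float(np.std(d, ddof=ddof))
    ba = BlandAltman(mean_diff=float(d.mean()), sd_diff=sd,
                     loa_low=float(d.mean() - 1.96 * sd),
                     loa_high=float(d.mean() + 1.96 * sd))
    undefined = bool(np.isclose(a.std(), 0.0) or np.isclose(b.std(), 0.0))
    if undefined:
        r = float("nan")
    elif len(a) < 3:
        undefined = True
        r = float("nan")
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return AgreementStats(corr=r, r2=r * r, mae=float(ae.mean()),
                          std_ae=float(np.std(ae, ddof=ddof)),
                          bland_altman=ba, n=len(a),
                          undefined_correlation=undefined)


@dataclass(frozen=True)
class DetectionRateCurve:
    thresholds: np.ndarray  # degrees
    rates: np.ndarray       # fractions in [0, 1]


def detection_rate(abs_errors, thresholds) -> DetectionRateCurve:
    """Fraction of cases with absolute error strictly below each threshold."""
    errs = np.asarray(abs_errors, float)
    if errs.size == 0:
        raise ValueError("empty error list")
    if (errs < 0).any():
        raise ValueError("absolute errors must be non-negative")
    taus = np.atleast_1d(np.asarray(thresholds, float))
    rates = (errs[None, :] < taus[:, None]).mean(axis=1)
    return DetectionRateCurve(thresholds=taus, rates=rates)


def _flatten_grids(*grids: np.ndarray) -> list[np.ndarray]:
    shapes = {np.asarray(g, float).shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"misaligned measurement grids: {sorted(shapes)}")
    return [np.asarray(g, float).reshape(-1) for g in grids]


def _row(name_a: str, name_b: str, a: np.ndarray, b: np.ndarray,
         ddof: int) -> dict:
    st = agreement(PairedMeasurements.from_arrays(a, b), ddof=ddof)
    return {"measurement_1": name_a, "measurement_2": name_b,
            "corr": st.corr, "mae": st.mae, "std": st.std_ae, "n": st.n}


def expert_table(auto, expert1, expert2, *, ddof: int = 1) -> pd.DataFrame:
    """Four-row comparison across all parameters and cases, flattened.

    Rows: expert1 vs expert2, method vs expert1, method vs expert2, and
    method vs the expert average (the standard reference).  Inputs are
    aligned case x parameter grids (e.g. 30 cases x 12 parameters = 360
    angles).
    """
    a, e1, e2 = _flatten_grids(auto, expert1, expert2)
    rows = [
        _row("1st expert", "2nd expert", e1, e2, ddof),
        _row("method", "1st expert", a, e1, ddof),
        _row("method", "2nd expert", a, e2, ddof),
        _row("method", "expert average", a, 0.5 * (e1 + e2), ddof),
    ]
    return pd.DataFrame(rows)


def min_expert_error(auto, expert1, expert2, *, ddof: int = 1) -> dict[str, float]:
    """Per-angle error taken as min(|auto-e1|, |auto-e2|); returns its mean
    and sample standard deviation."""
    a, e1, e2 = _flatten_grids(auto, expert1, expert2)
    e = np.minimum(np.abs(a - e1), np.abs(a - e2))
    return {"mae": float(e.mean()), "std": float(np.std(e, ddof=ddof))}


# --- optional figure helpers -------------------------------------------------

def bland_altman_plot(p: PairedMeasurements, ax=None):
    """Difference-vs-mean plot with mean and +/- 1.96 SD limit lines."""
    import matplotlib.pyplot as plt

    st = agreement(p)
    ba = st.bland_altman
    if ax is None:
        _, ax = plt.subplots()
    mean = 0.5 * (p.method_a + p.method_b)
    ax.scatter(mean, p.method_a - p.method_b, s=14)
    ax.axhline(ba.mean_diff, color="red")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="blue", linestyle="--")
    ax.set_xlabel("mean of methods (deg)")
    ax.set_ylabel("difference (deg)")
    ax.set_title(p.parameter or "Bland-Altman")
    return ax


def detection_rate_plot(curves: dict[str, DetectionRateCurve], ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, curve in curves.items():
        ax.plot(curve.thresholds, curve.rates, label=name)
    ax.set_xlabel("error threshold (deg)")
    ax.set_ylabel("detection rate")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7, ncol=2)
    return ax


def correlation_plot(p: PairedMeasurements, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(p.method_b, p.method_a, s=14)
    lo = min(p.method_a.min(), p.method_b.min())
    hi = max(p.method_a.max(), p.method_b.max())
    ax.plot([lo, hi], [lo, hi], color="grey", linewidth=0.8)
    ax.set_xlabel("reference (deg)")
    ax.set_ylabel("method (deg)")
    ax.set_title(p.parameter)
    return ax
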