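"""Exponential proliferation model and spherical-growth compactness scoring.

Cells in a biosphere proliferate as n(t) = n0 * exp((t-t0)/tau), where tau
is the e-folding time (doubling time = tau * ln 2).  If each cell occupies a
characteristic volume v_c and the multicellular structure stays a compact
sphere, its total volume is V(t) = v_c * n(t) = V0 * exp((t-t0)/tau) and
hence

    d(t) = d0 * exp((t-t0)/(3*tau)),    A(t) = A0 * exp(2*(t-t0)/(3*tau)).

Confronting measured spheroid size distributions with these predictions,
anchored at the earliest imaging time and driven by the count-derived tau,
scores how compactly a culture grows: structures that track the prediction
are "compact"; cultures whose area falls progressively short are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

LN2 = math.log(2.0)


@dataclass
class CountSeries:
    """Cell counts per biosphere over time (days)."""

    times: np.ndarray
    counts: np.ndarray
    culture_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape or self.times.ndim != 1:
            raise ValueError("times and counts must be equal-length 1-D")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 1):
            raise ValueError("counts must be >= 1")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class GrowthFit:
    """Fitted exponential growth: n(t) = n0 * exp((t - t_start)/tau)."""

    n0: float
    tau: float
    doubling_time: float
    fit_window: tuple[float, float]
    r_squared: float
    n_points: int
    culture_id: str = ""

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not math.isclose(self.doubling_time, self.tau * LN2,
                            rel_tol=1e-12):
            raise ValueError("doubling_time must equal tau * ln 2")


@dataclass
class SphericalPrediction:
    """Parameters of the spherical-growth law, anchored at t0.

    ``v_c`` (characteristic single-cell volume, um^3) is informational:
    once d0/A0 are anchored to measured sizes the predictions depend only
    on d0, A0 and tau.
    """

    d0: float
    a0: float
    tau: float
    t0: float = 0.0
    v_c: float | None = None

    def __post_init__(self) -> None:
        if min(self.d0, self.a0, self.tau) <= 0:
            raise ValueError("d0, a0 and tau must be positive")

    @classmethod
    def from_initial_diameter(cls, d0: float, tau: float, t0: float = 0.0,
                              v_c: float | None = None):
        return cls(d0=d0, a0=math.pi * d0 ** 2 / 4.0, tau=tau, t0=t0,
                   v_c=v_c)


def cell_number(n0: float, tau: float, t, t0: float = 0.0):
    """n(t) = n0 * exp((t - t0)/tau)."""
    return n0 * np.exp((np.asarray(t, dtype=float) - t0) / tau)


def total_volume(v_c: float, n0: float, tau: float, t, t0: float = 0.0):
    """Spheroid volume as cell volume times cell number, v_c * n(t)."""
    return v_c * cell_number(n0, tau, t, t0)


def predict_diameter(pred: SphericalPrediction, t) -> np.ndarray | float:
    """d(t) = d0 * exp((t - t0)/(3*tau)); t may not precede t0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < pred.t0):
        raise ValueError(f"t must be >= t0 = {pred.t0}")
    out = pred.d0 * np.exp((t - pred.t0) / (3.0 * pred.tau))
    return float(out) if out.ndim == 0 else out


def predict_area(pred: SphericalPrediction, t) -> np.ndarray | float:
    """A(t) = A0 * exp(2*(t - t0)/(3*tau)); t may not precede t0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < pred.t0):
        raise ValueError(f"t must be >= t0 = {pred.t0}")
    out = pred.a0 * np.exp(2.0 * (t - pred.t0) / (3.0 * pred.tau))
    return float(out) if out.ndim == 0 else out


def fit_exponential(
    series: CountSeries, window: tuple[float, float] | None = None
) -> GrowthFit:
    """Fit tau and n0 by ordinary least squares of ln(count) on time.

    Log-scale OLS matches the constant-coefficient-of-variation noise of
    cell counting (multiplicative error), unlike nonlinear least squares on
    raw counts which the largest counts would dominate.  ``n0`` is the
    fitted count at the window start; r_squared is on the log scale.
    """
    t, n = series.times, series.counts
    if window is not None:
        lo, hi = window
        keep = (t >= lo) & (t <= hi)
        t, n = t[keep], n[keep]
    if t.size < 3:
        raise ValueError(
            f"need >= 3 points in the fit window, got {t.size}"
        )
    res = sps.linregress(t, np.log(n))
    if res.slope <= 0:
        raise ValueError("no exponential growth in window (slope <= 0)")
    tau = 1.0 / res.slope
    t_start = float(t[0])
    n0 = math.exp(res.intercept + res.slope * t_start)
    return GrowthFit(
        n0=n0, tau=tau, doubling_time=tau * LN2,
        fit_window=(t_start, float(t[-1])),
        r_squared=float(res.rvalue ** 2), n_points=int(t.size),
        culture_id=series.culture_id,
    )


def select_exponential_window(
    series: CountSeries, min_points: int = 4
) -> tuple[float, float]:
    """Locate the contiguous time window where growth is log-linear.

    Scans every contiguous sub-window of at least ``min_points`` points
    with positive slope and maximises the log-scale r-squared; among
    windows whose r-squared ties within 1e-9, the widest is preferred,
    then the earliest.  This makes "the period during which the cells grew
    exponentially" an explicit, reproducible procedure.
    """
    t, logn = series.times, np.log(series.counts)
    npts = t.size
    if npts < min_points:
        raise ValueError(
            f"series has {npts} points; min_points = {min_points}"
        )
    best = None  # (r2, width, -start_idx, window)
    for i in range(npts - min_points + 1):
        for j in range(i + min_points, npts + 1):
            ts, ys = t[i:j], logn[i:j]
            res = sps.linregress(ts, ys)
            if res.slope <= 0:
                continue
            r2 = res.rvalue ** 2
            key = (round(r2 / 1e-9), j - i, -i)
            if best is None or key > best[0]:
                best = (key, (float(ts[0]), float(ts[-1])))
    if best is None:
        raise ValueError("no growing window found (all slopes <= 0)")
    return best[1]


@dataclass
class CompactnessReport:
    """Observed-vs-predicted spheroid areas and the compactness verdict.

    ``table`` has one row per time point: time_d, n_obs, area_median,
    area_q1, area_q3, area_pred, kappa, plus the diameter analogues.
    kappa(t) is observed median area over predicted area; the culture is
    "compact" iff kappa stays within [1/kappa_star, kappa_star] at every
    time after the anchor.
    """

    table: "object"  # pandas DataFrame
    kappa_star: float
    verdict: str
    prediction: SphericalPrediction
    culture_id: str = ""

    @property
    def kappas(self) -> np.ndarray:
        return self.table["kappa"].to_numpy()


def compactness_report(
    measures,
    fit: GrowthFit,
    kappa_star: float = 1.5,
    min_objects: int = 10,
) -> CompactnessReport:
    """Score how compactly a culture grew against its spherical prediction.

    ``measures`` is a DataFrame with columns time_d, area_um2 (and
    optionally eq_diameter_um), covering >= 2 time points with at least
    ``min_objects`` objects each.  d0/A0 are anchored to the *median* of
    the earliest time point (robust to segmentation outliers) and tau comes
    from the cell-count fit; kappa(t) = observed median area / A(t).
    """
    import pandas as pd

    if kappa_star <= 1:
        raise ValueError("kappa_star must be > 1")
    df = pd.DataFrame(measures)
    if "time_d" not in df or "area_um2" not in df:
        raise ValueError("measures needs columns time_d and area_um2")
    df = df.dropna(subset=["time_d", "area_um2"])
    times = np.sort(df["time_d"].unique())
    if times.size < 2:
        raise ValueError("need measurements at >= 2 time points")
    sizes = df.groupby("time_d").size()
    if (sizes < min_objects).any():
        bad = sizes[sizes < min_objects].index.tolist()
        raise ValueError(
            f"time points {bad} have fewer than {min_objects} objects"
        )

    t0 = float(times[0])
    first = df[df["time_d"] == t0]
    a0 = float(first["area_um2"].median())
    d0 = 2.0 * math.sqrt(a0 / math.pi)
    pred = SphericalPrediction(d0=d0, a0=a0, tau=fit.tau, t0=t0)

    rows = []
    for t in times:
        sub = df[df["time_d"] == t]
        a_med = float(sub["area_um2"].median())
        a_pred = float(predict_area(pred, t))
        rows.append(
            {
                "time_d": float(t),
                "n_obs": int(len(sub)),
                "area_median": a_med,
                "area_q1": float(sub["area_um2"].quantile(0.25)),
                "area_q3": float(sub["area_um2"].quantile(0.75)),
                "area_pred": a_pred,
                "kappa": a_med / a_pred,
                "diameter_median": 2.0 * math.sqrt(a_med / math.pi),
                "diameter_pred": float(predict_diameter(pred, t)),
            }
        )
    table = pd.DataFrame(rows)
    after = table[table["time_d"] > t0]
    ok = np.all(
        (after["kappa"] >= 1.0 / kappa_star)
        & (after["kappa"] <= kappa_star)
    )
    return CompactnessReport(
        table=table, kappa_star=kappa_star,
        verdict="compact" if ok else "non-compact",
        prediction=pred, culture_id=fit.culture_id,
    )
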