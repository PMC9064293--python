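"""Time-lapse morphometrics of convergence, thickening and closure.

Quantities measured from fiduciary-point tracks and traced outlines:
regional width ratios W_t/W_i (convergence), thickness ratios T_t/T_i,
area ratios A_t/A_i, convergence rates in % of initial width per hour,
rate changepoints (two-segment piecewise-linear fit), spherical-geometry
area corrections for whole-embryo views, blastopore closure (A_bp/A_we),
cell-shape metrics, and the group summaries (mean, SEM, unpaired
two-tailed t-test) used to compare conditions.

Time is in hours relative to gastrulation onset (G0); the involuting
marginal zone (IMZ) converges at roughly 10 %/hr through early
gastrulation while the non-involuting marginal zone (NIMZ) starts near
7 %/hr and slows to ~0 %/hr at about G-0.7 h — the signature this module
is built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry

__all__ = [
    "TrackTable",
    "RegionSeries",
    "SphereGeometry",
    "BlastoporeMetrics",
    "CellShapeMetrics",
    "region_widths",
    "estimate_rate",
    "detect_rate_change",
    "spherical_area_correction",
    "blastopore_closure",
    "cell_shape_metrics",
    "summarize_groups",
]

REGION_LABELS = ("dorsal", "lateral", "ventral", "IMZ", "NIMZ", "other")


@dataclass
class TrackTable:
    """Fiduciary-point tracks: rows of (point_id, region, t_hr, x, y).

    ``pairs`` maps region label -> (point_id, point_id), the boundary
    point pair whose separation defines the region's width.
    """

    data: pd.DataFrame
    pairs: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    REQUIRED = ("point_id", "region", "t_hr", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        if self.data.duplicated(["point_id", "t_hr"]).any():
            raise ValueError("duplicate (point_id, t_hr) rows in track table")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pairs: dict | None = None, **kw) -> "TrackTable":
        return cls(data=pd.read_csv(path), pairs=pairs or {}, **kw)


@dataclass
class RegionSeries:
    """A region's width (or thickness/area) against time, with ratios."""

    label: str
    t_hr: np.ndarray
    W_t: np.ndarray
    kind: str = "width"  # "width" | "thickness" | "area"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_hr = np.asarray(self.t_hr, dtype=float)
        self.W_t = np.asarray(self.W_t, dtype=float)
        if self.t_hr.shape != self.W_t.shape:
            raise ValueError("t_hr and W_t must have equal length")
        if len(self.W_t) == 0 or not (self.W_t[0] > 0):
            raise ValueError("initial width must be positive")

    @property
    def W_i(self) -> float:
        return float(self.W_t[0])

    @property
    def ratio(self) -> np.ndarray:
        """W_t/W_i, equal to 1 at the first time point by construction."""
        return self.W_t / self.W_i


@dataclass(frozen=True)
class SphereGeometry:
    """Spherical embryo of radius R viewed along an axis through center."""

    R: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise ValueError(f"R must be > 0, got {self.R}")


@dataclass(frozen=True)
class BlastoporeMetrics:
    """Projected blastopore and whole-embryo areas at one time point."""

    t_hr: float
    A_bp: float
    A_we: float

    def __post_init__(self) -> None:
        if self.A_bp < 0 or self.A_we <= 0:
            raise ValueError("areas must be non-negative (A_we > 0)")
        if self.A_bp > self.A_we:
            raise ValueError(f"A_bp={self.A_bp} exceeds A_we={self.A_we}")

    @property
    def ratio(self) -> float:
        return self.A_bp / self.A_we


@dataclass
class CellShapeMetrics:
    """Per-cell, per-time shape descriptors from traced outlines."""

    t: np.ndarray
    perimeter: np.ndarray
    area: np.ndarray
    circularity: np.ndarray
    length_width_ratio: np.ndarray
    centroid_speed: np.ndarray  # length/time unit; nan at the first frame
    perimeter_change: np.ndarray  # delta P per interval; nan at first frame


def region_widths(tracks: TrackTable, pairs: dict | None = None) -> dict[str, RegionSeries]:
    """Width-vs-time series per region from paired boundary points.

    Width is the Euclidean separation of the two declared points at each
    shared time point; times at which either point is missing are
    omitted (recorded in the series meta).  Ratios are normalized to the
    first shared time.
    """
    pairs = pairs if pairs is not None else tracks.pairs
    if not pairs:
        raise ValueError("no region point pairs declared")
    df = tracks.data
    out: dict[str, RegionSeries] = {}
    for region, (pa, pb) in pairs.items():
        a = df[df.point_id == pa].set_index("t_hr")[["x", "y"]].sort_index()
        b = df[df.point_id == pb].set_index("t_hr")[["x", "y"]].sort_index()
        shared = a.index.intersection(b.index)
        dropped = len(a.index.union(b.index)) - len(shared)
        if len(shared) == 0:
            raise ValueError(f"region {region!r}: points share no time points")
        d = a.loc[shared].to_numpy() - b.loc[shared].to_numpy()
        w = np.hypot(d[:, 0], d[:, 1])
        out[region] = RegionSeries(
            label=region,
            t_hr=shared.to_numpy(dtype=float),
            W_t=w,
            meta={"dropped_timepoints": int(dropped), "pair": (pa, pb)},
        )
    return out


def estimate_rate(
    series: RegionSeries, window: tuple[float, float] | None = None
) -> dict:
    """Convergence rate in % of initial width per hour, with CI.

    OLS slope of W_t/W_i against time over the window, times -100 so
    that positive rates mean convergence (shrinking width).  Returns
    rate, its standard error, a 95% CI and the window actually used.
    """
    t, r = series.t_hr, series.ratio
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, r = t[m], r[m]
    if len(t) < 3:
        raise ValueError(f"need >= 3 time points in window, got {len(t)}")
    res = stats.linregress(t, r)
    rate = -100.0 * res.slope
    se = 100.0 * res.stderr
    tcrit = stats.t.ppf(0.975, len(t) - 2)
    return {
        "rate_pct_per_hr": float(rate),
        "stderr": float(se),
        "ci95": (float(rate - tcrit * se), float(rate + tcrit * se)),
        "n": int(len(t)),
        "window": (float(t[0]), float(t[-1])),
    }


def detect_rate_change(series: RegionSeries, f_crit: float = 10.0, min_seg: int = 3) -> dict:
    """Two-segment continuous piecewise-linear fit of W_t/W_i vs time.

    Exhaustive search over interior sample points for the breakpoint
    minimizing total squared error of the hinge model
    ``r(t) = a + b*t + c*max(0, t - t_b)``.  If the best two-segment fit
    does not improve on a single line by the F-criterion (default
    F >= 10 with (2, n-4) df), returns ``changepoint=None``.

    Rates are reported as % of initial width per hour, positive =
    convergence.
    """
    t, r = series.t_hr, series.ratio
    n = len(t)
    if n < 2 * min_seg + 1:
        raise ValueError(f"series too short for changepoint search ({n} points)")

    # single-line reference
    X1 = np.column_stack([np.ones(n), t])
    beta1, res1, *_ = np.linalg.lstsq(X1, r, rcond=None)
    sse1 = float(res1[0]) if res1.size else float(np.sum((r - X1 @ beta1) ** 2))

    # a numerically perfect single line needs no breakpoint
    scale = float(np.sum((r - r.mean()) ** 2))
    if sse1 <= 1e-18 * max(scale, 1.0):
        return {
            "changepoint_hr": None,
            "rate_pct_per_hr": float(-100.0 * beta1[1]),
            "f_stat": 0.0,
        }

    best = None
    for k in range(min_seg - 1, n - min_seg):
        tb = t[k]
        X = np.column_stack([np.ones(n), t, np.maximum(0.0, t - tb)])
        beta, res, *_ = np.linalg.lstsq(X, r, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((r - X @ beta) ** 2))
        if best is None or sse < best[0]:
            best = (sse, tb, beta)
    sse2, tb, beta = best

    dof = n - 4
    if sse2 <= 0:
        f_stat = np.inf if sse1 > sse2 else 0.0
    else:
        f_stat = ((sse1 - sse2) / 2.0) / (sse2 / dof)
    if not (f_stat >= f_crit):
        rate = -100.0 * beta1[1]
        return {
            "changepoint_hr": None,
            "rate_pct_per_hr": float(rate),
            "f_stat": float(f_stat),
        }
    return {
        "changepoint_hr": float(tb),
        "rate_before_pct_per_hr": float(-100.0 * beta[1]),
        "rate_after_pct_per_hr": float(-100.0 * (beta[1] + beta[2])),
        "f_stat": float(f_stat),
        "sse": sse2,
    }


def spherical_area_correction(geom: SphereGeometry, r_proj: float, r_proj_inner: float = 0.0) -> dict:
    """True spherical-cap (or annulus) area for a projected circular region.

    A region bounded by a circle of projected radius ``r_proj`` about the
    viewing axis corresponds to a polar cap of half-angle
    ``theta = arcsin(r_proj/R)`` with true area ``2*pi*R^2*(1-cos theta)``;
    annuli are differences of caps (``r_proj_inner > 0``).  Returns true
    and projected areas and their ratio.
    """
    R = geom.R
    for r in (r_proj, r_proj_inner):
        if r < 0 or r > R:
            raise ValueError(f"projected radius {r} outside [0, R={R}]")
    if r_proj_inner > r_proj:
        raise ValueError("inner radius exceeds outer radius")

    def cap(rp: float) -> float:
        theta = np.arcsin(rp / R)
        return 2.0 * np.pi * R**2 * (1.0 - np.cos(theta))

    a_true = cap(r_proj) - cap(r_proj_inner)
    a_proj = np.pi * (r_proj**2 - r_proj_inner**2)
    return {
        "area_true": float(a_true),
        "area_projected": float(a_proj),
        "ratio": float(a_true / a_proj) if a_proj > 0 else float("nan"),
    }


def blastopore_closure(
    series: list[BlastoporeMetrics], closure_floor: float = 0.01
) -> pd.DataFrame:
    """Closure curve A_bp/A_we vs time; closure = ratio reaching the floor.

    Returns a DataFrame (t_hr, A_bp, A_we, ratio, closed) sorted by time.
    """
    if not series:
        raise ValueError("empty blastopore series")
    df = pd.DataFrame(
        [{"t_hr": m.t_hr, "A_bp": m.A_bp, "A_we": m.A_we, "ratio": m.ratio} for m in series]
    ).sort_values("t_hr", ignore_index=True)
    df["closed"] = df["ratio"] <= closure_floor
    return df


def cell_shape_metrics(outlines: list[np.ndarray], times=None) -> CellShapeMetrics:
    """Shape metrics for one cell's outline traced at successive times.

    Each outline is an (n, 2) closed polyline (closing edge implied).
    Self-intersecting outlines are rejected.  Speeds/changes use the
    supplied ``times`` (defaults to frame index).
    """
    if times is None:
        times = np.arange(len(outlines), dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != len(outlines):
        raise ValueError("times and outlines must have equal length")
    P, A, C, LWR, cents = [], [], [], [], []
    for i, poly in enumerate(outlines):
        poly = np.asarray(poly, dtype=float)
        if geometry.is_self_intersecting(poly, closed=True):
            raise ValueError(f"outline {i} is self-intersecting; rejected")
        P.append(geometry.polygon_perimeter(poly))
        A.append(geometry.polygon_area(poly))
        C.append(geometry.circularity(poly))
        major, minor = geometry.ellipse_axes(poly)
        LWR.append(major / minor if minor > 0 else np.inf)
        cents.append(poly.mean(axis=0))
    P, A, C, LWR = map(np.asarray, (P, A, C, LWR))
    cents = np.asarray(cents)
    dt = np.diff(times)
    speed = np.full(len(outlines), np.nan)
    dperi = np.full(len(outlines), np.nan)
    if len(outlines) > 1:
        step = np.hypot(*(np.diff(cents, axis=0).T))
        speed[1:] = step / dt
        dperi[1:] = np.diff(P) / dt
    return CellShapeMetrics(
        t=times,
        perimeter=P,
        area=A,
        circularity=np.clip(C, 0.0, 1.0),
        length_width_ratio=LWR,
        centroid_speed=speed,
        perimeter_change=dperi,
    )


def summarize_groups(
    group_a, group_b=None, welch: bool = False, labels: tuple[str, str] = ("a", "b")
) -> dict:
    """Mean and SEM per group, plus an unpaired two-tailed t-test.

    Defaults to the classic pooled-variance t-test; ``welch=True``
    switches to the unequal-variance form.  SEM is sd/sqrt(n) with the
    n-1 sample SD; groups with n < 2 are flagged and SEM is NaN.
    """

    def one(vals, label):
        v = np.asarray(vals, dtype=float)
        n = len(v)
        out = {"label": label, "n": n, "mean": float(np.mean(v)) if n else float("nan")}
        if n >= 2:
            out["sem"] = float(np.std(v, ddof=1) / np.sqrt(n))
        else:
            out["sem"] = float("nan")
            out["flag"] = "sem_undefined_n_lt_2"
        return out

    res = {"groups": [one(group_a, labels[0])]}
    if group_b is not None:
        res["groups"].append(one(group_b, labels[1]))
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if len(a) >= 2 and len(b) >= 2:
            tt = stats.ttest_ind(a, b, equal_var=not welch)
            res["t_stat"] = float(tt.statistic)
            res["p_value"] = float(tt.pvalue)
            res["test"] = "welch" if welch else "pooled"
        else:
            res["flag"] = "test_skipped_n_lt_2"
    return res
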