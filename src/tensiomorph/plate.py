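"""Parallel-plate compression tensiometry and push-back trace analysis.

Surface/interfacial tension of a compressed aggregate is computed from
its ellipsoid-cap geometry after 3 min of stress relaxation:

    ``sigma = F / (pi*R3**2*(1/R1 + 1/R2) - 2*pi*R3*sin(A))``

with ``F`` the applied force, ``R1``/``R2`` the principal profile radii,
``R3`` the plate-contact radius and ``A`` the contact angle.  Compression
strains of 18-22% are used; above ~22% aggregates respond solid-like and
the tension reading is no longer meaningful.

The push-back (thickening-force) assay holds the platen fixed after a
light preload (0.2-0.3 uN) and records the force the rounding/thickening
explant exerts back on it: stress relaxation, a plateau, then — for
tissue that thickens — a force ramp whose onset time is the quantity of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CompressionGeometry",
    "ForceTrace",
    "PushbackResult",
    "PushbackConfig",
    "compute_plate_sigma",
    "compute_strain",
    "analyze_pushback",
    "GeometryError",
]

#: protocol strain band
STRAIN_MIN = 0.18
STRAIN_MAX = 0.22

#: default reading time after the start of compression, s
RELAXATION_READING_TIME = 180.0


class GeometryError(ValueError):
    """Compressed-drop geometry inconsistent with the tension formula."""


@dataclass(frozen=True)
class CompressionGeometry:
    """Post-relaxation geometry of a plate-compressed aggregate.

    All lengths in meters, force in newtons, contact angle in radians.
    ``R1`` is the equatorial (azimuthal) radius, ``R2`` the meridional
    profile radius at the equator; the tension formula is symmetric in
    them.
    """

    F: float
    R1: float
    R2: float
    R3: float
    A: float
    h0: float | None = None
    h: float | None = None

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.A < np.pi):
            raise ValueError(f"contact angle must be in (0, pi), got {self.A}")

    @property
    def strain(self) -> float | None:
        if self.h0 is None or self.h is None:
            return None
        return compute_strain(self.h0, self.h)[0]


@dataclass
class ForceTrace:
    """A force-vs-time record from the platen.

    ``t`` in seconds (strictly increasing), ``F`` in newtons.
    """

    t: np.ndarray
    F: np.ndarray
    preload: float | None = None
    platen_fixed_from: float = 0.0
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape or self.t.ndim != 1:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "F_N": self.F})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "ForceTrace":
        df = pd.read_csv(path)
        tcol = "t_s" if "t_s" in df.columns else df.columns[0]
        fcol = "F_N" if "F_N" in df.columns else df.columns[1]
        return cls(t=df[tcol].to_numpy(), F=df[fcol].to_numpy(), **kw)


@dataclass
class PushbackResult:
    """Decomposition of a push-back trace."""

    relaxation_end: float
    plateau_force: float
    onset_time: float | None
    delta_F_30min: float | None
    delta_F_30min_from_start: float | None
    noise_sd: float
    relax_amplitude: float | None = None
    relax_tau: float | None = None
    flags: list = field(default_factory=list)


@dataclass(frozen=True)
class PushbackConfig:
    """Tunables of the onset-detection rule."""

    median_window: int = 5  # samples, moving-median smoothing
    k_sd: float = 3.0  # excursion threshold in noise SDs above plateau
    sustain_window: float = 600.0  # s the excursion must persist
    plateau_window: float = 1200.0  # s after relaxation used for the plateau level
    refine_window: float = 1200.0  # s of post-crossing ramp used to refine onset


def compute_plate_sigma(geom: CompressionGeometry) -> float:
    """Tension (N/m) from plate-compression geometry.

    With lengths in meters and force in newtons the result is in N/m.
    Raises :class:`GeometryError` when the denominator is not positive
    (contact term dominates; shape inconsistent with a compressed drop).
    """
    denom = (
        np.pi * geom.R3**2 * (1.0 / geom.R1 + 1.0 / geom.R2)
        - 2.0 * np.pi * geom.R3 * np.sin(geom.A)
    )
    if denom <= 0:
        raise GeometryError(
            f"non-positive denominator ({denom:.3g} m): geometry inconsistent "
            "with a plate-compressed drop"
        )
    return float(geom.F / denom)


def compute_strain(h0: float, h: float) -> tuple[float, str]:
    """Engineering strain (h0 - h)/h0 with a protocol-regime flag.

    Returns ``(strain, flag)`` where flag is ``"in_protocol"`` for
    18-22%, ``"below_protocol"`` under 18%, and ``"solid_like_regime"``
    above 22% (where measured tension rises suddenly and stops reflecting
    interfacial physics).
    """
    if not (h0 > 0):
        raise ValueError(f"h0 must be > 0, got {h0}")
    if h > h0:
        raise ValueError(f"compressed height h={h} exceeds initial h0={h0}")
    if h <= 0:
        raise ValueError(f"h must be > 0, got {h}")
    eps = (h0 - h) / h0
    if eps > STRAIN_MAX:
        flag = "solid_like_regime"
    elif eps < STRAIN_MIN:
        flag = "below_protocol"
    else:
        flag = "in_protocol"
    return float(eps), flag


def _moving_median(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    return (
        pd.Series(y).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def analyze_pushback(trace: ForceTrace, config: PushbackConfig | None = None) -> PushbackResult:
    """Decompose a push-back trace into relaxation, plateau and onset.

    Procedure: moving-median smoothing; exponential fit
    ``a*exp(-t/tau) + b`` to the initial decaying segment (relaxation
    ends when the fitted transient falls below half the noise SD); the
    plateau level is the median of the smoothed trace over a window after
    relaxation; the onset candidate is the first time the smoothed force
    exceeds ``plateau + k*noise_sd`` and stays above for the sustain
    window; the reported onset is then refined by intersecting a line fit
    to the post-crossing ramp with the plateau level, which removes the
    threshold-crossing lag.  ``delta_F_30min`` is the force increase over
    30 min from onset (and, separately, from the start of the trace).
    """
    cfg = config or PushbackConfig()
    t, F = trace.t, trace.F
    if len(t) < max(10, cfg.median_window * 2):
        raise ValueError(f"trace too short for analysis ({len(t)} samples)")
    span = t[-1] - t[0]
    if span < cfg.plateau_window:
        raise ValueError(
            f"trace spans {span:.0f} s, shorter than the {cfg.plateau_window:.0f} s analysis window"
        )
    Fs = _moving_median(F, cfg.median_window)
    flags: list[str] = []

    # noise level: SD of first differences of the raw trace over its flat
    # middle (differencing removes slow trends; /sqrt(2) de-inflates)
    dF = np.diff(F)
    noise_sd = float(np.median(np.abs(dF - np.median(dF))) * 1.4826 / np.sqrt(2.0))

    # relaxation segment: fit a decaying exponential to the early trace
    relax_amplitude = relax_tau = None
    n_early = max(10, int(0.25 * len(t)))
    te, Fe = t[:n_early] - t[0], Fs[:n_early]
    amp0 = Fe[0] - Fe[-1]
    if amp0 > max(noise_sd, 0.0):
        tau0 = max(te[-1] / 5.0, trace.dt)
        try:
            popt, _ = curve_fit(
                lambda tt, a, tau, b: a * np.exp(-tt / tau) + b,
                te,
                Fe,
                p0=[amp0, tau0, Fe[-1]],
                maxfev=10000,
            )
            relax_amplitude, relax_tau = float(popt[0]), float(abs(popt[1]))
            floor = max(0.5 * noise_sd, 1e-4 * abs(relax_amplitude))
            relaxation_end = t[0] + relax_tau * np.log(max(abs(relax_amplitude) / floor, 1.0))
        except RuntimeError:
            flags.append("relaxation_fit_failed")
            relaxation_end = t[0] + 0.1 * span
    else:
        flags.append("no_relaxation_detected")
        relaxation_end = t[0]
    relaxation_end = float(min(relaxation_end, t[0] + 0.5 * span))

    # plateau level
    in_plateau = (t >= relaxation_end) & (t <= relaxation_end + cfg.plateau_window)
    if in_plateau.sum() < 3:
        in_plateau = t >= relaxation_end
    plateau = float(np.median(Fs[in_plateau]))

    # sustained-excursion onset candidate
    thresh = plateau + cfg.k_sd * noise_sd
    above = (Fs > thresh) & (t >= relaxation_end)
    onset_time: float | None = None
    sustain_n = max(1, int(round(cfg.sustain_window / trace.dt)))
    idx_above = np.flatnonzero(above)
    for i in idx_above:
        j = np.searchsorted(t, t[i] + cfg.sustain_window, side="right")
        seg = above[i:j]
        if len(seg) >= min(sustain_n, len(above) - i) and seg.all():
            onset_time = float(t[i])
            break
    if onset_time is not None:
        # refine: extrapolate the early ramp back to the plateau level
        jr = (t >= onset_time) & (t <= onset_time + cfg.refine_window)
        if jr.sum() >= 3:
            b, a = np.polyfit(t[jr], Fs[jr], 1)
            if b > 0:
                t_hat = (plateau - a) / b
                if relaxation_end - cfg.sustain_window <= t_hat <= onset_time:
                    onset_time = float(max(t_hat, relaxation_end))

    delta_onset = delta_start = None
    if onset_time is not None:
        f_onset = float(np.interp(onset_time, t, Fs))
        t30 = onset_time + 1800.0
        if t30 <= t[-1]:
            delta_onset = float(np.interp(t30, t, Fs) - f_onset)
        else:
            flags.append("trace_ends_before_onset_plus_30min")
    if t[0] + 1800.0 <= t[-1]:
        delta_start = float(np.interp(t[0] + 1800.0, t, Fs) - Fs[0])

    return PushbackResult(
        relaxation_end=relaxation_end,
        plateau_force=plateau,
        onset_time=onset_time,
        delta_F_30min=delta_onset,
        delta_F_30min_from_start=delta_start,
        noise_sd=noise_sd,
        relax_amplitude=relax_amplitude,
        relax_tau=relax_tau,
        flags=flags,
    )
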