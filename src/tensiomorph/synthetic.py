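"""Synthetic inputs with known ground truth for every pipeline stage.

No raw movies or force traces accompany the measurements this package
reimplements, so each analysis stage is validated by parameter recovery
on synthetic data: gravity-flattened drop profiles (and rendered images)
of known tension, push-back force traces with a known ramp onset, and
regional track tables with known convergence-rate regimes.  Every
generated object carries its ground truth in metadata and is
deterministic per seed.

Default conditions follow the measured scales: tensions ~0.2 mN/m,
aggregate apex radii a few hundred um, preloads 0.2-0.3 uN, push-back
ramps ~0.3 uN per 30 min, IMZ convergence 10 %/hr and NIMZ 7 -> 0 %/hr
with the changepoint at G-0.7 h.  Noise magnitudes are calibration
choices of this package (none are reported for the original data); see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .contours import ObservedContour
from .extraction import ImageStack
from .laplace import FluidContext, G_STANDARD, integrate_profile
from .morpho import TrackTable
from .plate import ForceTrace

__all__ = [
    "SyntheticDropSpec",
    "SyntheticTraceSpec",
    "SyntheticTrackSpec",
    "gen_drop_profile",
    "gen_drop_image",
    "gen_pushback_trace",
    "gen_track_table",
    "OverConvergenceError",
]


class OverConvergenceError(ValueError):
    """Requested rates drive a region width to zero within the time span."""


@dataclass(frozen=True)
class SyntheticDropSpec:
    """Ground truth for a sessile-drop contour.

    gamma in N/m, delta_rho in kg/m^3, R0 (apex radius) in m;
    radial_noise_sd is a fraction of R0 applied normal to the curve;
    tilt in radians rotates the whole outline about the apex.
    """

    gamma: float = 0.22e-3
    delta_rho: float = 50.0
    R0: float = 0.5e-3
    n_points: int = 200
    radial_noise_sd: float = 0.0
    tilt: float = 0.0
    seed: int = 0
    g: float = G_STANDARD

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.delta_rho < 0:
            raise ValueError(f"delta_rho must be >= 0, got {self.delta_rho}")
        if not (self.R0 > 0):
            raise ValueError(f"R0 must be > 0, got {self.R0}")
        if self.n_points < 20:
            raise ValueError(f"n_points must be >= 20, got {self.n_points}")
        if self.radial_noise_sd < 0:
            raise ValueError("radial_noise_sd must be >= 0")

    @property
    def bond_number(self) -> float:
        return self.delta_rho * self.g * self.R0**2 / self.gamma

    @classmethod
    def for_bond(cls, bond: float, gamma: float = 0.22e-3, delta_rho: float = 50.0, **kw):
        """Spec with R0 chosen to hit a target Bond number at fixed gamma."""
        R0 = float(np.sqrt(bond * gamma / (delta_rho * G_STANDARD)))
        return cls(gamma=gamma, delta_rho=delta_rho, R0=R0, **kw)


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Ground truth for a push-back force trace.

    F(t) = preload + relax_amplitude*(exp(-t/relax_tau) - 1)
         + plateau_level + ramp_rate*max(0, t - onset_time) + noise.
    Forces in N, times in s.  ``ramp_rate = 0`` produces a trace with no
    onset (a valid null case).
    """

    preload: float = 0.25e-6
    relax_amplitude: float = 0.1e-6
    relax_tau: float = 60.0
    plateau_level: float = 0.0
    onset_time: float = 3600.0
    ramp_rate: float = 1.7e-10  # N/s: ~0.3 uN over 30 min
    noise_sd: float = 5e-9
    duration: float = 10800.0
    dt: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not (self.duration > 0):
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.relax_tau <= 0:
            raise ValueError("relax_tau must be > 0")


@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Ground truth for regional convergence tracks.

    ``regions`` is a list of (label, rate_before %/hr, rate_after %/hr,
    changepoint_time hr); rates are in percent of initial width per hour
    (positive = convergence), applied piecewise-linearly to W_t/W_i with
    continuity at the changepoint.  Lengths in um, times in hours
    relative to gastrulation onset.
    """

    regions: tuple = (("IMZ", 10.0, 10.0, -0.7), ("NIMZ", 7.0, 0.0, -0.7))
    initial_width: float = 1000.0
    time_span: float = 4.0
    dt: float = 0.05  # hr: one frame per 3 min, the movie capture rate
    positional_noise_sd: float = 5.0
    seed: int = 0
    t_start: float = -2.5

    def __post_init__(self) -> None:
        labels = [r[0] for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        for r in self.regions:
            if len(r) != 4 or not all(np.isfinite(v) for v in r[1:]):
                raise ValueError(f"bad region tuple {r!r}")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if not (self.time_span > 0):
            raise ValueError("time_span must be > 0")
        if self.positional_noise_sd < 0:
            raise ValueError("positional_noise_sd must be >= 0")


def gen_drop_profile(spec: SyntheticDropSpec) -> ObservedContour:
    """Sample a noisy contour along the exact Young-Laplace outline.

    Points are spaced uniformly in arc length over the full mirrored
    outline, perturbed along the local outward normal by
    ``N(0, radial_noise_sd * R0)``, then rotated about the apex by
    ``tilt``.  Ground truth is stored in ``source['truth']``.
    """
    ctx = FluidContext(gamma=spec.gamma, delta_rho=spec.delta_rho, g=spec.g)
    prof = integrate_profile(ctx, spec.R0, n_samples=2000)
    s, x, z, th = prof.s, prof.x, prof.z, prof.theta
    s_end = s[-1]

    # signed arc parameter over the mirrored outline: -s_end .. +s_end
    n = spec.n_points
    tpar = np.linspace(-s_end, s_end, n)
    sa = np.abs(tpar)
    sign = np.sign(tpar)
    sign[sign == 0] = 1.0
    xi = np.interp(sa, s, x)
    zi = np.interp(sa, s, z)
    ti = np.interp(sa, s, th)
    pts = np.column_stack([sign * xi, zi])
    normals = np.column_stack([sign * np.sin(ti), -np.cos(ti)])

    rng = np.random.default_rng(spec.seed)
    if spec.radial_noise_sd > 0:
        pts = pts + normals * rng.normal(0.0, spec.radial_noise_sd * spec.R0, size=(n, 1))
    if spec.tilt != 0.0:
        c, sn = np.cos(spec.tilt), np.sin(spec.tilt)
        rot = np.array([[c, -sn], [sn, c]])
        pts = pts @ rot.T

    contour = ObservedContour(
        points=pts,
        pixel_scale=1e-6,  # nominal; synthetic contours are born physical
        closed=True,  # closed by the substrate chord across the theta=pi ends
        source={
            "synthetic": True,
            "truth": asdict(spec),
            "bond_number": spec.bond_number,
            "arc_length_end": float(s_end),
        },
    )
    return contour


def gen_drop_image(
    spec: SyntheticDropSpec,
    pixel_scale: float,
    blur_sd: float = 2.0,
    image_noise_sd: float = 0.01,
    frame_shape: tuple[int, int] | None = None,
    margin_px: int = 12,
) -> ImageStack:
    """Render the drop silhouette as a blurred, noisy grayscale image.

    The noise-free outline is rasterized as a filled polygon, Gaussian
    blurred by ``blur_sd`` pixels, and perturbed with additive Gaussian
    pixel noise.  The ground-truth contour (in physical units, apex at
    the stored ``apex_px``) is kept in ``meta['truth_contour']``.

    Raises if the drop does not fit in a requested ``frame_shape``.
    """
    if not (pixel_scale > 0):
        raise ValueError(f"pixel_scale must be > 0, got {pixel_scale}")
    from scipy.ndimage import gaussian_filter
    from skimage.draw import polygon as draw_polygon

    ctx = FluidContext(gamma=spec.gamma, delta_rho=spec.delta_rho, g=spec.g)
    prof = integrate_profile(ctx, spec.R0, n_samples=2000)
    outline = prof.outline()  # (x, z), apex at origin

    w_px = (outline[:, 0].max() - outline[:, 0].min()) / pixel_scale
    h_px = (outline[:, 1].max() - outline[:, 1].min()) / pixel_scale
    pad = margin_px + int(np.ceil(4 * blur_sd))
    if frame_shape is None:
        frame_shape = (int(np.ceil(h_px)) + 2 * pad, int(np.ceil(w_px)) + 2 * pad)
    rows_n, cols_n = frame_shape
    if h_px + 2 * pad > rows_n or w_px + 2 * pad > cols_n:
        raise ValueError(
            f"drop ({h_px:.0f}x{w_px:.0f} px plus {pad} px margin) does not fit "
            f"in requested frame {frame_shape}"
        )
    apex_col = cols_n / 2.0
    apex_row = float(pad)
    cols = outline[:, 0] / pixel_scale + apex_col
    rows = outline[:, 1] / pixel_scale + apex_row

    img = np.zeros(frame_shape, dtype=float)
    rr, cc = draw_polygon(rows, cols, shape=frame_shape)
    img[rr, cc] = 1.0
    if blur_sd > 0:
        img = gaussian_filter(img, blur_sd)
    rng = np.random.default_rng(spec.seed)
    if image_noise_sd > 0:
        img = img + rng.normal(0.0, image_noise_sd, size=img.shape)

    return ImageStack(
        intensities=img,
        pixel_scale=pixel_scale,
        meta={
            "synthetic": True,
            "truth": asdict(spec),
            "bond_number": spec.bond_number,
            "apex_px": (apex_col, apex_row),
            "truth_contour": outline,
            "blur_sd": blur_sd,
            "image_noise_sd": image_noise_sd,
        },
    )


def gen_pushback_trace(spec: SyntheticTraceSpec) -> ForceTrace:
    """Synthesize a push-back trace: relaxation, plateau, optional ramp."""
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    F = (
        spec.preload
        + spec.relax_amplitude * np.exp(-t / spec.relax_tau)
        - spec.relax_amplitude
        + spec.plateau_level
        + spec.ramp_rate * np.maximum(0.0, t - spec.onset_time)
    )
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        F = F + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return ForceTrace(
        t=t,
        F=F,
        preload=spec.preload,
        platen_fixed_from=0.0,
        source={"synthetic": True, "truth": asdict(spec)},
    )


def gen_track_table(spec: SyntheticTrackSpec) -> TrackTable:
    """Synthesize paired boundary-point tracks with piecewise-linear rates.

    Each region's width ratio falls with slope ``rate_before``/100 per
    hour until the changepoint, then ``rate_after``/100, continuous at
    the break.  The two boundary points sit at +-W(t)/2 about a
    region-specific center, each coordinate perturbed by
    ``N(0, positional_noise_sd)``.  Raises
    :class:`OverConvergenceError` if any width would reach zero within
    the span.
    """
    t = spec.t_start + np.arange(0.0, spec.time_span + 0.5 * spec.dt, spec.dt)
    rng = np.random.default_rng(spec.seed)
    rows = []
    pairs = {}
    for i, (label, rate_b, rate_a, t_cp) in enumerate(spec.regions):
        rb, ra = rate_b / 100.0, rate_a / 100.0
        dt_pre = np.minimum(t, t_cp) - t[0] if t_cp > t[0] else np.zeros_like(t)
        dt_post = np.maximum(0.0, t - max(t_cp, t[0]))
        ratio = 1.0 - rb * dt_pre - ra * dt_post
        if np.any(ratio <= 0):
            raise OverConvergenceError(
                f"region {label!r}: width ratio reaches {ratio.min():.3f} <= 0 "
                f"within the time span"
            )
        W = spec.initial_width * ratio
        yc = 500.0 * i  # arbitrary stacking of regions in the field
        for side, pid in ((-0.5, f"{label}_L"), (+0.5, f"{label}_R")):
            xs = side * W + rng.normal(0.0, spec.positional_noise_sd, size=t.shape)
            ys = yc + rng.normal(0.0, spec.positional_noise_sd, size=t.shape)
            for tk, xk, yk in zip(t, xs, ys):
                rows.append(
                    {"point_id": pid, "region": label, "t_hr": tk, "x": xk, "y": yk}
                )
        pairs[label] = (f"{label}_L", f"{label}_R")

    import pandas as pd

    return TrackTable(
        data=pd.DataFrame(rows),
        pairs=pairs,
        meta={"synthetic": True, "truth": asdict(spec)},
    )
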