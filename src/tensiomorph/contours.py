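"""Observed aggregate contours and their quality-control metrics.

An :class:`ObservedContour` is an ordered 2-D outline of a tissue
aggregate profile in physical units (meters), either extracted from an
image or generated synthetically.  Irregular aggregates cannot be fit as
drop shapes, so each contour carries a :class:`ContourQC` record with the
acceptance decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry

__all__ = ["ObservedContour", "ContourQC", "qc_contour"]

#: default QC thresholds: generous enough for gravity-flattened drops,
#: strict enough to reject grossly irregular explants
CIRCULARITY_MIN = 0.6
CONVEXITY_DEFICIENCY_MAX = 0.15


@dataclass
class ContourQC:
    """Shape-regularity metrics deciding whether a contour is fittable."""

    circularity: float
    convexity_deficiency: float
    closed: bool
    irregularity_score: float
    accepted: bool

    def as_dict(self) -> dict:
        return {
            "circularity": self.circularity,
            "convexity_deficiency": self.convexity_deficiency,
            "closed": self.closed,
            "irregularity_score": self.irregularity_score,
            "accepted": self.accepted,
        }


@dataclass
class ObservedContour:
    """An ordered aggregate outline in physical coordinates.

    ``points`` is (n, 2) in meters, columns (x, z) with z increasing from
    the apex toward the substrate.  ``source`` carries provenance
    metadata (tissue label, stage time relative to gastrulation onset,
    ground-truth parameters for synthetic contours, ...).
    """

    points: np.ndarray
    pixel_scale: float
    closed: bool = True
    substrate_line: tuple[float, float, float] | None = None
    source: dict = field(default_factory=dict)
    qc: ContourQC | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {self.points.shape}")
        if len(self.points) < 20:
            raise ValueError(f"need >= 20 contour points, got {len(self.points)}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("contour contains non-finite coordinates")
        if not (self.pixel_scale > 0):
            raise ValueError(f"pixel_scale must be > 0, got {self.pixel_scale}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def apex_index(self) -> int:
        """Index of the apex-most point (minimum z)."""
        return int(np.argmin(self.points[:, 1]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["x_m", "z_m"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_scale: float = 1.0, **kw) -> "ObservedContour":
        df = pd.read_csv(path)
        cols = [c for c in ("x_m", "z_m") if c in df.columns] or list(df.columns[:2])
        return cls(points=df[cols].to_numpy(), pixel_scale=pixel_scale, **kw)


def qc_contour(
    contour: ObservedContour,
    circularity_min: float = CIRCULARITY_MIN,
    convexity_deficiency_max: float = CONVEXITY_DEFICIENCY_MAX,
) -> ContourQC:
    """Compute QC metrics and the acceptance decision for a contour.

    A contour is accepted when it is closed, not self-intersecting,
    circularity >= ``circularity_min`` and convexity deficiency <=
    ``convexity_deficiency_max``.  The irregularity score combines both
    margins into one number (0 = perfectly regular).
    """
    pts = contour.points
    closed = bool(contour.closed)
    if closed and geometry.is_self_intersecting(pts, closed=True):
        qc = ContourQC(
            circularity=float("nan"),
            convexity_deficiency=float("nan"),
            closed=False,
            irregularity_score=float("inf"),
            accepted=False,
        )
        contour.qc = qc
        return qc
    if not closed:
        qc = ContourQC(
            circularity=float("nan"),
            convexity_deficiency=float("nan"),
            closed=False,
            irregularity_score=float("inf"),
            accepted=False,
        )
        contour.qc = qc
        return qc
    circ = geometry.circularity(pts)
    cdef = geometry.convexity_deficiency(pts)
    score = max(0.0, 1.0 - circ) + cdef
    accepted = (circ >= circularity_min) and (cdef <= convexity_deficiency_max)
    qc = ContourQC(
        circularity=float(circ),
        convexity_deficiency=float(cdef),
        closed=True,
        irregularity_score=float(score),
        accepted=bool(accepted),
    )
    contour.qc = qc
    return qc
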