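"""Profile-image handling: max-intensity projection and contour extraction.

Aggregate profiles arrive either as single profile images (brightfield
via a 45-degree mirror) or as small confocal stacks of a labeled deep
tissue, which are max-projected before edge detection.  The outline is
found by Gaussian smoothing, Canny edge detection, morphological closing
of the edge ring, hole filling, and subpixel contour tracing of the
largest filled region; every contour is QC'd before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology

from .contours import CIRCULARITY_MIN, CONVEXITY_DEFICIENCY_MAX, ObservedContour, qc_contour

__all__ = ["ImageStack", "max_project", "extract_contour", "qc_contour", "ExtractionError"]


class ExtractionError(RuntimeError):
    """No usable closed contour could be extracted from the image."""


@dataclass
class ImageStack:
    """A 2-D image or small 3-D confocal stack with physical pixel scale.

    ``intensities`` is (rows, cols) or (slices, rows, cols); confocal
    slices are typically spaced 10 um apart.
    """

    intensities: np.ndarray
    pixel_scale: float  # m / pixel
    slice_spacing: float | None = None  # m, for 3-D stacks
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim not in (2, 3) or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 2-D or 3-D array")
        if not (self.pixel_scale > 0):
            raise ValueError(f"pixel_scale must be > 0, got {self.pixel_scale}")

    @property
    def is_stack(self) -> bool:
        return self.intensities.ndim == 3

    @classmethod
    def from_file(cls, path, pixel_scale: float, **kw) -> "ImageStack":
        path = str(path)
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            data = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            data = iio.imread(path)
        return cls(intensities=np.asarray(data), pixel_scale=pixel_scale, **kw)

    def to_file(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), np.asarray(self.intensities))


def max_project(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection of a confocal stack along slices.

    A 2-D input is returned unchanged (with a note in ``meta``).
    """
    if not stack.is_stack:
        out = ImageStack(
            intensities=stack.intensities,
            pixel_scale=stack.pixel_scale,
            channel=stack.channel,
            meta={**stack.meta, "note": "input was already 2-D; projection skipped"},
        )
        return out
    proj = stack.intensities.max(axis=0)
    return ImageStack(
        intensities=proj,
        pixel_scale=stack.pixel_scale,
        channel=stack.channel,
        meta={**stack.meta, "projected_slices": stack.intensities.shape[0]},
    )


def _auto_canny_thresholds(gradmag: np.ndarray, low_pct: float, high_pct: float):
    """Percentile rule over *significant* gradients.

    Percentiles are taken over pixels above 10% of the (robust) peak
    gradient, so the rule keys on the object boundary rather than on the
    sea of near-zero noise gradients.
    """
    nz = gradmag[gradmag > 0]
    if nz.size == 0:
        raise ExtractionError("image has no intensity gradients (blank image?)")
    floor = 0.1 * np.percentile(nz, 99.9)
    sig = nz[nz >= floor]
    if sig.size == 0:
        sig = nz
    return np.percentile(sig, low_pct), np.percentile(sig, high_pct)


def extract_contour(
    image: ImageStack,
    smoothing_sd: float = 1.0,
    canny_thresholds: tuple[float, float] | None = None,
    circularity_min: float = CIRCULARITY_MIN,
    convexity_deficiency_max: float = CONVEXITY_DEFICIENCY_MAX,
    min_area_px: int = 64,
) -> ObservedContour:
    """Extract the aggregate outline from a 2-D profile image.

    Pipeline: Gaussian smoothing -> Canny edges (thresholds default to
    the 50th/90th percentile of the nonzero gradient magnitude) ->
    morphological closing -> hole filling -> largest filled region ->
    subpixel iso-contour.  The returned contour is ordered counter-
    clockwise starting at the apex-most (minimum-z) point, in physical
    units, with QC metrics attached.

    Raises :class:`ExtractionError` when no closed outline is found.
    Multiple candidate regions: the largest by area is used and the
    others recorded in ``source['rejected_candidates']``.
    """
    stack = max_project(image) if image.is_stack else image
    img = np.asarray(stack.intensities, dtype=float)
    if img.ndim != 2:
        raise ValueError("extract_contour requires a 2-D image")
    rng = img.max() - img.min()
    if rng == 0:
        raise ExtractionError("blank image: constant intensity")
    img = (img - img.min()) / rng
    smoothed = filters.gaussian(img, sigma=smoothing_sd, preserve_range=True)

    if canny_thresholds is None:
        gy, gx = np.gradient(smoothed)
        low, high = _auto_canny_thresholds(np.hypot(gx, gy), 50.0, 90.0)
    else:
        low, high = canny_thresholds
    edges = feature.canny(smoothed, sigma=0.0, low_threshold=low, high_threshold=high)
    if not edges.any():
        raise ExtractionError("Canny found no edges")

    # dilate -> fill -> erode: seals small gaps in the edge ring (e.g. at
    # the bottom cusp of a drop outline) without net boundary displacement
    dilated = morphology.dilation(edges, morphology.disk(3))
    filled = ndi.binary_fill_holes(dilated)
    filled = morphology.erosion(filled, morphology.disk(3))
    filled = morphology.opening(filled, morphology.disk(2))
    labels, n = ndi.label(filled)
    if n == 0:
        raise ExtractionError("no closed region after edge closing and filling")
    sizes = ndi.sum(filled, labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    best_label = int(order[0]) + 1
    if sizes[order[0]] < min_area_px:
        raise ExtractionError(f"largest region has only {int(sizes[order[0]])} px")
    mask = labels == best_label

    # subpixel boundary: trace the smoothed intensity at the mid-level
    # between object and background (the Canny-derived mask only
    # localizes the object; its own boundary is thickened by closing)
    interior = morphology.erosion(mask, morphology.disk(3))
    exterior = ~morphology.dilation(mask, morphology.disk(3))
    if interior.sum() < 16 or exterior.sum() < 16:
        raise ExtractionError("object too small to estimate intensity levels")
    level = 0.5 * (np.median(smoothed[interior]) + np.median(smoothed[exterior]))
    contours = [
        c for c in measure.find_contours(smoothed, level) if np.allclose(c[0], c[-1])
    ]
    if not contours:
        raise ExtractionError("no closed iso-contour at the object boundary level")
    # the candidate enclosing the mask centroid; largest by length
    r0c, c0c = ndi.center_of_mass(mask)
    ring = None
    for cand in sorted(contours, key=len, reverse=True):
        if measure.points_in_poly([[r0c, c0c]], cand)[0]:
            ring = cand
            break
    if ring is None:
        raise ExtractionError("no closed contour encloses the detected object")
    ring = ring[:-1]  # drop duplicated closing vertex

    # rows/cols -> physical (x, z): x along columns, z along rows (depth
    # increases downward in the image, apex at minimum row)
    px = stack.pixel_scale
    xz = np.column_stack([ring[:, 1] * px, ring[:, 0] * px])
    # counterclockwise ordering in (x, z) with z down == clockwise on screen
    x, z = xz[:, 0], xz[:, 1]
    signed = float(np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1))) / 2.0
    if signed < 0:
        xz = xz[::-1]
    apex = int(np.argmin(xz[:, 1]))
    xz = np.roll(xz, -apex, axis=0)
    apex_px = (float(xz[0, 0] / px), float(xz[0, 1] / px))
    # apex-centered physical coordinates
    xz = xz - xz[0]

    contour = ObservedContour(
        points=xz,
        pixel_scale=px,
        closed=True,
        source={
            "pipeline": "gaussian+canny",
            "smoothing_sd": smoothing_sd,
            "canny_thresholds": (float(low), float(high)),
            "n_candidate_regions": int(n),
            "rejected_candidates": int(n - 1),
            "apex_px": apex_px,
            **stack.meta,
        },
    )
    qc_contour(contour, circularity_min, convexity_deficiency_max)
    return contour


def inspection_overlay(image: ImageStack, contour: ObservedContour, path) -> None:
    """Write a PNG overlaying the extracted contour on the source image.

    Stands in for the by-eye inspection step of every processed image.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = max_project(image).intensities if image.is_stack else image.intensities
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img, cmap="gray")
    pts = contour.points / contour.pixel_scale
    apex_px = contour.source.get("apex_px")
    if apex_px is None:
        # contour was apex-centered; re-anchor at the image apex estimate
        col0 = np.asarray(img).shape[1] / 2.0
        row0 = 0.0
    else:
        col0, row0 = apex_px
    ax.plot(pts[:, 0] + col0, pts[:, 1] + row0, "r-", lw=0.8)
    ax.set_title(f"QC accepted={contour.qc.accepted if contour.qc else 'n/a'}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
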