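"""Detection of air-filled conduits in grayscale cross-section rasters.

Air-filled (embolised) lumens image dark and water-filled lumens light,
so candidate conduits are the connected components of the below-threshold
pixel set, filtered by a minimum area and an optional circularity bound.

Coordinate convention: origin at the top-left pixel centre, x rightward,
y downward, 0-based; pixel ``(row j, col i)`` has centre ``(i*px, j*px)``
micrometres. Areas are converted to square micrometres by ``px**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree
from skimage import filters, measure

from .errors import MatchError, ValidationError

__all__ = [
    "Conduit",
    "ConduitMap",
    "SegmentationSettings",
    "equivalent_diameter",
    "segment_air_conduits",
    "match_scan_pair",
]

#: default minimum particle area: a 5-um-diameter circle (sub-5-um blobs
#: at ~2 um/px are noise-scale).
MIN_AREA_DEFAULT_UM2 = math.pi * 2.5**2


@dataclass(frozen=True)
class Conduit:
    """One detected conduit lumen."""

    id: int
    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    equivalent_diameter_um: float
    state: str  # "air" | "water"
    border: bool = False

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ValidationError(f"conduit {self.id}: nonpositive area")
        if self.state not in ("air", "water"):
            raise ValidationError(f"conduit {self.id}: state must be air|water")


@dataclass
class ConduitMap:
    """All conduits measured on one cross-section image."""

    conduits: list[Conduit]
    xylem_area_mm2: float
    pixel_size_um: float
    source_image_id: str = ""
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.xylem_area_mm2 <= 0:
            raise ValidationError("xylem_area_mm2 must be > 0")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")

    def __len__(self) -> int:
        return len(self.conduits)

    def diameters_um(self, state: str | None = None) -> np.ndarray:
        return np.array(
            [c.equivalent_diameter_um for c in self.conduits
             if state is None or c.state == state],
            dtype=float,
        )

    def ids(self, state: str | None = None) -> list[int]:
        return [c.id for c in self.conduits if state is None or c.state == state]


@dataclass(frozen=True)
class SegmentationSettings:
    """Thresholding and particle-filter settings.

    ``method="fixed"`` applies ``threshold`` as an absolute gray cutoff
    (images are in [0, 1]); ``method="otsu"`` derives the cutoff from the
    image histogram and records it in the output metadata.
    """

    method: str = "fixed"
    threshold: float = 0.30
    min_area_um2: float = MIN_AREA_DEFAULT_UM2
    min_circularity: float | None = None
    connectivity: int = 2  # 8-connected

    def __post_init__(self):
        if self.method not in ("fixed", "otsu"):
            raise ValidationError("segmentation method must be 'fixed' or 'otsu'")
        if self.method == "fixed" and not (0.0 <= self.threshold <= 1.0):
            raise ValidationError("threshold must lie in [0, 1]")
        if self.min_area_um2 < 0:
            raise ValidationError("min_area_um2 must be >= 0")
        if self.connectivity not in (1, 2):
            raise ValidationError("connectivity must be 1 (4-) or 2 (8-connected)")


def equivalent_diameter(area_um2):
    """Diameter of the circle with the given area: ``2*sqrt(A/pi)`` (um)."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area <= 0):
        raise ValidationError("area must be positive")
    out = 2.0 * np.sqrt(area / math.pi)
    return float(out) if np.isscalar(area_um2) else out


def segment_air_conduits(
    image: np.ndarray,
    pixel_size_um: float,
    settings: SegmentationSettings | None = None,
    *,
    region_mask: np.ndarray | None = None,
    xylem_area_mm2: float | None = None,
    image_id: str = "",
) -> ConduitMap:
    """Label dark (air-filled) lumens and measure their areas.

    The xylem cross-sectional area is taken from ``region_mask`` (boolean,
    same shape as the image) when given, from ``xylem_area_mm2`` when given
    directly, and from the whole frame otherwise. Components touching the
    frame border are kept but flagged.
    """
    settings = settings or SegmentationSettings()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a single-channel 2-D image")
    if img.size == 0:
        raise ValidationError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite pixels")
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be > 0")

    if settings.method == "otsu":
        thr = float(filters.threshold_otsu(img))
    else:
        thr = float(settings.threshold)

    fg = img < thr
    if region_mask is not None:
        mask = np.asarray(region_mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValidationError("region_mask shape does not match image")
        fg = fg & mask

    labels = measure.label(fg, connectivity=settings.connectivity)
    px2 = pixel_size_um**2
    h, w = img.shape

    conduits: list[Conduit] = []
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * px2
        if area_um2 < settings.min_area_um2:
            continue
        if settings.min_circularity is not None:
            perim = prop.perimeter
            circ = 4.0 * math.pi * prop.area / perim**2 if perim > 0 else 1.0
            if circ < settings.min_circularity:
                continue
        r0, c0, r1, c1 = prop.bbox
        border = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        cy, cx = prop.centroid  # (row, col)
        conduits.append(
            Conduit(
                id=len(conduits),
                centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
                area_um2=float(area_um2),
                equivalent_diameter_um=equivalent_diameter(float(area_um2)),
                state="air",
                border=bool(border),
            )
        )

    if xylem_area_mm2 is not None:
        area_mm2 = float(xylem_area_mm2)
    elif region_mask is not None:
        area_mm2 = float(np.count_nonzero(region_mask)) * px2 / 1e6
    else:
        area_mm2 = h * w * px2 / 1e6

    applied = asdict(settings)
    applied["threshold_applied"] = thr
    return ConduitMap(
        conduits=conduits,
        xylem_area_mm2=area_mm2,
        pixel_size_um=pixel_size_um,
        source_image_id=image_id,
        settings=applied,
    )


def match_scan_pair(initial: ConduitMap, final: ConduitMap,
                    tol_um: float = 5.0, psi_mpa: float = float("nan")):
    """Match each air-filled conduit of the initial scan to the final scan.

    The final (fully embolised) scan shows every conduit, so each initial
    air conduit is assigned to its nearest final-scan centroid within
    ``tol_um``. Two initial conduits claiming the same final conduit is an
    error; initial conduits with no neighbour within tolerance are flagged
    as unmatched rather than silently dropped.

    Returns a :class:`~xylemct.hydraulics.ScanPair` whose embolised set is
    the matched subset of the *final* conduit ids.
    """
    from .hydraulics import ScanPair

    if abs(initial.pixel_size_um - final.pixel_size_um) > 1e-9:
        raise ValidationError("scan pair has differing pixel sizes")
    air = [c for c in initial.conduits if c.state == "air"]
    if not air:
        return ScanPair(psi_mpa=psi_mpa, initial=initial, final=final,
                        embolised_ids=frozenset(), unmatched_initial_ids=frozenset())
    if not final.conduits:
        raise ValidationError("final scan contains no conduits")

    pts = np.array([c.centroid_um for c in final.conduits])
    tree = cKDTree(pts)
    dists, idx = tree.query(np.array([c.centroid_um for c in air]), k=1)

    matched: dict[int, int] = {}  # final id -> initial id
    unmatched: set[int] = set()
    for conduit, d, j in zip(air, dists, idx):
        if d > tol_um:
            unmatched.add(conduit.id)
            continue
        fid = final.conduits[j].id
        if fid in matched:
            raise MatchError(
                f"initial conduits {matched[fid]} and {conduit.id} both match "
                f"final conduit {fid} (tol {tol_um} um)"
            )
        matched[fid] = conduit.id

    return ScanPair(
        psi_mpa=psi_mpa,
        initial=initial,
        final=final,
        embolised_ids=frozenset(matched),
        unmatched_initial_ids=frozenset(unmatched),
    )
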