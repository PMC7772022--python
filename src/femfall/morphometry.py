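"""Proximal-femur morphometry from a segmented scan.

Works purely on the segmentation mask (never the BMD values).  The
landmark constructions are fully deterministic:

* shaft axis      -- principal axis of the distal 35% of the mask;
* head centre     -- peak of the in-mask distance transform on the
                     medial side (the largest inscribed disc);
* neck axis       -- line through the head centre and the midpoint of
                     the narrowest neck cross-section (two refinement
                     passes);
* junction        -- intersection of neck and shaft axes;
* SAL             -- distal axis entry to the junction, along the shaft
                     axis;
* NW / ITW / STW  -- connected mask chords perpendicular to the
                     relevant axis at the narrowest neck section, just
                     distal of the junction, and at 25% of SAL above the
                     distal entry (a fixed subtrochanteric offset);
* HAL             -- mask chord along the neck axis (head apex to the
                     lateral cortex);
* NSA             -- angle between the neck axis and the distal shaft
                     direction;
* FA              -- mask pixel count times pixel area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .cohort import ScanRaster

__all__ = [
    "MorphometricSet",
    "RoiPartition",
    "PadGeometry",
    "MorphometryError",
    "standardise_pose",
    "measure",
    "partition_rois",
    "place_pads",
    "analyze",
]


class MorphometryError(ValueError):
    """Raised when landmarks cannot be identified on a mask."""


@dataclass(frozen=True)
class MorphometricSet:
    nw: float       # neck width, mm
    hal: float      # hip axis length, mm
    nsa: float      # neck-shaft angle, degrees
    sal: float      # shaft axis length, mm
    itw: float      # intertrochanteric width, mm
    stw: float      # subtrochanteric width, mm
    fa: float       # projected femur area, mm^2

    def __post_init__(self) -> None:
        for name in ("nw", "hal", "sal", "itw", "stw", "fa"):
            if getattr(self, name) <= 0:
                raise MorphometryError(f"{name} must be positive")
        if not 90.0 < self.nsa < 160.0:
            raise MorphometryError("NSA outside (90, 160) degrees")

    def as_dict(self) -> dict[str, float]:
        return {"NW": self.nw, "HAL": self.hal, "NSA": self.nsa,
                "SAL": self.sal, "ITW": self.itw, "STW": self.stw,
                "FA": self.fa}


@dataclass
class Landmarks:
    """Internal geometric frame shared by the measurement consumers."""

    shaft_point: np.ndarray     # point on the shaft axis, mm
    shaft_dir: np.ndarray       # unit, pointing proximally
    lateral_dir: np.ndarray     # unit, perpendicular, pointing laterally
    s0: float                   # distal axis-entry station
    s_junction: float           # neck/shaft axis crossing station
    head_centre: np.ndarray
    head_radius: float
    neck_dir: np.ndarray        # unit, neck midpoint -> head
    neck_mid: np.ndarray        # centre of the narrowest neck chord
    morph: MorphometricSet = None

    def station_offset(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rel = pts - self.shaft_point
        return rel @ self.shaft_dir, rel @ self.lateral_dir


@dataclass
class RoiPartition:
    """Neck and trochanteric regions of interest.

    Pixel masks are provided for inspection; ``classify_points`` applies
    the same geometric rules to arbitrary mm coordinates (used to map FE
    element centroids into regions).
    """

    neck_mask: np.ndarray
    troch_mask: np.ndarray
    landmarks: Landmarks
    band_half: float
    s_sub: float

    def classify_points(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lm = self.landmarks
        along_neck = (pts - lm.neck_mid) @ lm.neck_dir
        neck = np.abs(along_neck) <= self.band_half
        s, ell = lm.station_offset(pts)
        troch = (s >= self.s_sub) & (s <= lm.s_junction) & (ell > 0.0) & ~neck
        return neck, troch


@dataclass
class PadGeometry:
    """PMMA pad polygons plus the load/constraint bookkeeping the FE stage needs."""

    troch_polygon: Polygon
    head_polygon: Polygon
    b: float                    # greater-trochanter pad length, mm
    t: float                    # subject-specific out-of-plane thickness, mm
    load_p0: np.ndarray         # endpoints of the flat lateral (loaded) face
    load_p1: np.ndarray
    load_normal: np.ndarray     # unit inward (medial) load direction
    head_centre: np.ndarray
    head_outer_radius: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.t <= 0:
            raise MorphometryError("pad length and thickness must be positive")
        if self.troch_polygon.intersects(self.head_polygon):
            raise MorphometryError("pads must not intersect each other")


# --------------------------------------------------------------------------
# low-level helpers
# --------------------------------------------------------------------------

def _sample_mask(scan: ScanRaster, pts: np.ndarray) -> np.ndarray:
    """Nearest-neighbour mask lookup at mm coordinates (False outside canvas)."""
    n_rows, n_cols = scan.mask.shape
    cols = np.rint(pts[:, 0] / scan.pixel_dx).astype(int)
    rows = np.rint(n_rows - 1 - pts[:, 1] / scan.pixel_dy).astype(int)
    ok = (rows >= 0) & (rows < n_rows) & (cols >= 0) & (cols < n_cols)
    out = np.zeros(len(pts), dtype=bool)
    out[ok] = scan.mask[rows[ok], cols[ok]]
    return out


def _chord(scan: ScanRaster, point: np.ndarray, direction: np.ndarray,
           half_span: float = 90.0, step: float = 0.25) -> tuple[float, np.ndarray]:
    """Length and centre of the connected mask run through ``point`` along ``direction``."""
    ts = np.arange(-half_span, half_span + step, step)
    pts = point[None, :] + ts[:, None] * direction[None, :]
    inside = _sample_mask(scan, pts)
    i0 = len(ts) // 2
    if not inside[i0]:
        return 0.0, point.copy()
    lo = i0
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(ts) - 1 and inside[hi + 1]:
        hi += 1
    width = ts[hi] - ts[lo] + step
    centre = point + 0.5 * (ts[hi] + ts[lo]) * direction
    return float(width), centre


def _principal_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and principal direction (largest-variance eigenvector)."""
    centre = points.mean(axis=0)
    cov = np.cov((points - centre).T)
    _, v = np.linalg.eigh(cov)
    d = v[:, 1]
    if d[1] < 0:
        d = -d
    return centre, d


def _shaft_frame(scan: ScanRaster) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distal shaft axis from row-band centroids: (anchor, proximal dir, lateral dir).

    The distal 40% of the mask is sliced into horizontal bands; the shaft
    axis is the principal line through the band centroids.  A mask whose
    extent along that line is not clearly larger than its width (e.g. a
    disc) has no identifiable shaft and is rejected.
    """
    pts = scan.mask_points_mm()
    if len(pts) < 50:
        raise MorphometryError("mask too small for shaft identification")
    y = pts[:, 1]
    span = y.max() - y.min()
    distal = pts[y < y.min() + 0.40 * span]
    band_h = 2.0 * scan.pixel_dy
    edges = np.arange(distal[:, 1].min(), distal[:, 1].max() + band_h, band_h)
    centroids, widths = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        band = distal[(distal[:, 1] >= lo) & (distal[:, 1] < hi)]
        if len(band) >= 3:
            centroids.append(band.mean(axis=0))
            widths.append(band[:, 0].max() - band[:, 0].min())
    if len(centroids) < 5:
        raise MorphometryError("no elongated distal shaft found "
                               "(aspect-ratio heuristic failed)")
    centroids = np.asarray(centroids)
    widths = np.asarray(widths)
    # discard bands clipped by the oblique distal end cut, then fit
    full = widths >= 0.9 * np.median(widths)
    if full.sum() < 5:
        raise MorphometryError("no elongated distal shaft found "
                               "(aspect-ratio heuristic failed)")
    centre, d = _principal_line(centroids[full])
    # second pass: chord centres perpendicular to the first-pass axis are
    # unbiased even where horizontal bands were clipped by the tilted shaft
    lat0 = np.array([d[1], -d[0]])
    rel_s = (distal - centre) @ d
    refined = []
    scan_local = scan
    for s in np.arange(rel_s.min() + 4.0, rel_s.max() - 1.0, 2.0):
        w, c = _chord(scan_local, centre + s * d, lat0, half_span=45.0)
        if w > 0:
            refined.append(c)
    if len(refined) >= 5:
        centre, d = _principal_line(np.asarray(refined))
    if d[1] < 0:
        d = -d
    extent = (pts - centre) @ d
    if extent.max() - extent.min() < 1.8 * float(np.median(widths)):
        raise MorphometryError("no elongated distal shaft found "
                               "(aspect-ratio heuristic failed)")
    lat = np.array([d[1], -d[0]])
    # orient 'lat' away from the femoral head: the head protrudes farthest
    # from the axis in the proximal half, on the medial side
    prox = pts[y > y.min() + 0.5 * span]
    ell = (prox - centre) @ lat
    if ell[np.argmax(np.abs(ell))] > 0:
        lat = -lat
    return centre, d, lat


def _head_centre(scan: ScanRaster, centre: np.ndarray, d: np.ndarray,
                 lat: np.ndarray) -> tuple[np.ndarray, float]:
    dist = ndimage.distance_transform_edt(
        scan.mask, sampling=(scan.pixel_dy, scan.pixel_dx))
    pts = scan.mask_points_mm()
    rows, cols = np.nonzero(scan.mask)
    ell = (pts - centre) @ lat
    s = (pts - centre) @ d
    cand = (ell < -10.0) & (s > 0.45 * s.max())
    if not np.any(cand):
        raise MorphometryError("no medial head region found")
    dvals = dist[rows[cand], cols[cand]]
    peak = dvals.max()
    sel = dvals > 0.88 * peak
    cpts = pts[cand][sel]
    # small heads can tie with the neck-strip ridge in the distance
    # transform; the head is always the most medial high-distance cluster
    cell = (cpts - centre) @ lat
    keep = cell <= cell.min() + 6.0
    hc = cpts[keep].mean(axis=0)
    return hc, float(peak)


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def standardise_pose(scan: ScanRaster, target_deg: float = 10.0) -> ScanRaster:
    """Rotate the scan so the shaft axis sits ``target_deg`` from image vertical.

    The rotation is performed in the physical mm frame (the pixel grid is
    anisotropic), resampling the BMD map bilinearly and the mask with
    nearest-neighbour lookup.
    """
    centre, d, _ = _shaft_frame(scan)
    current = math.degrees(math.atan2(d[0], d[1]))   # azimuth from vertical
    delta = math.radians(current - target_deg)
    if abs(delta) < 1e-12:
        return ScanRaster(scan.bmd_map.copy(), scan.mask.copy(),
                          scan.pixel_dx, scan.pixel_dy)
    n_rows, n_cols = scan.mask.shape
    pivot = scan.mask_points_mm().mean(axis=0)
    cols = np.arange(n_cols) * scan.pixel_dx
    rows_y = (n_rows - 1 - np.arange(n_rows)) * scan.pixel_dy
    xx, yy = np.meshgrid(cols, rows_y)
    out = np.column_stack([xx.ravel(), yy.ravel()]) - pivot
    rot = np.array([[math.cos(delta), -math.sin(delta)],
                    [math.sin(delta), math.cos(delta)]])
    src = out @ rot + pivot
    src_cols = src[:, 0] / scan.pixel_dx
    src_rows = n_rows - 1 - src[:, 1] / scan.pixel_dy
    coords = np.vstack([src_rows, src_cols])
    bmd = ndimage.map_coordinates(scan.bmd_map, coords, order=1,
                                  mode="constant", cval=0.0)
    mask = ndimage.map_coordinates(scan.mask.astype(np.uint8), coords, order=0,
                                   mode="constant", cval=0) > 0
    bmd = bmd.reshape(n_rows, n_cols)
    mask = mask.reshape(n_rows, n_cols)
    bmd[~mask] = 0.0
    return ScanRaster(bmd, mask, scan.pixel_dx, scan.pixel_dy)


def analyze(scan: ScanRaster) -> Landmarks:
    """Identify all landmarks and measurements on a pose-standardised mask."""
    centre, d, lat = _shaft_frame(scan)
    pts = scan.mask_points_mm()
    s_all, ell_all = (pts - centre) @ d, (pts - centre) @ lat
    near_axis = np.abs(ell_all) <= 8.0
    if not np.any(near_axis):
        raise MorphometryError("shaft axis does not intersect the mask")
    s0 = float(s_all[near_axis].min())
    s_exit = float(s_all[near_axis].max())

    hc, r_head = _head_centre(scan, centre, d, lat)

    # Trochanteric breadth scans must not sweep through the femoral head:
    # its projection can dip below the junction level and bridge the chord
    # medially.  Scrub the head disc from a working copy of the mask.
    rows_all, cols_all = np.nonzero(scan.mask)
    xa, ya = scan.xy_of(rows_all, cols_all)
    in_head = (xa - hc[0]) ** 2 + (ya - hc[1]) ** 2 <= max(r_head - 3.0, 1.0) ** 2
    mask_nh = scan.mask.copy()
    mask_nh[rows_all[in_head], cols_all[in_head]] = False
    scan_nh = ScanRaster(scan.bmd_map, mask_nh, scan.pixel_dx, scan.pixel_dy)

    # initial junction estimate: station of maximal mask breadth (the
    # intertrochanteric flare is the widest section perpendicular to the
    # shaft); the raw axis exit overshoots into the neck for valgus necks
    best_w, s_wide = 0.0, s_exit
    for s in np.arange(s0 + 0.55 * (s_exit - s0), s_exit, 1.0):
        w, _ = _chord(scan_nh, centre + s * d, lat)
        if w > best_w:
            best_w, s_wide = w, s
    junction = centre + s_wide * d

    # neck axis refinement: head centre <-> narrowest-chord midpoint.
    # Chords under 13 mm are corner slivers, not neck cross-sections.
    neck_mid = None
    nw = math.inf
    for _ in range(4):
        axis_vec = junction - hc
        length = np.linalg.norm(axis_vec)
        u = axis_vec / length
        ts = np.arange(0.95 * r_head, 0.92 * length, 0.5)
        if len(ts) == 0:
            # very valgus necks leave only a short gap between head and
            # trochanter; scan whatever window exists
            ts = np.linspace(min(0.8 * r_head, 0.5 * length),
                             0.95 * length, 20)
        if len(ts) == 0:
            raise MorphometryError("neck segment degenerate")
        perp = np.array([u[1], -u[0]])
        widths, centres = [], []
        for t in ts:
            w, c = _chord(scan, hc + t * u, perp, half_span=60.0)
            widths.append(w)
            centres.append(c)
        widths = np.asarray(widths)
        valid = widths >= 13.0
        if not np.any(valid):
            raise MorphometryError("no neck narrowing detectable")
        k = int(np.flatnonzero(valid)[np.argmin(widths[valid])])
        nw, neck_mid = float(widths[k]), centres[k]
        # new neck direction and junction with the shaft axis
        m = hc - neck_mid
        m = m / np.linalg.norm(m)
        mat = np.column_stack([d, -m])
        try:
            sol = np.linalg.solve(mat, neck_mid - centre)
        except np.linalg.LinAlgError as exc:
            raise MorphometryError("neck axis parallel to shaft axis") from exc
        junction = centre + sol[0] * d
    s_j = float((junction - centre) @ d)
    m = hc - neck_mid
    m = m / np.linalg.norm(m)

    sal = s_j - s0
    if sal <= 0:
        raise MorphometryError("junction distal of the shaft entry")
    stw, _ = _chord(scan, centre + (s0 + 0.25 * sal) * d, lat)
    # ITW: breadth of the intertrochanteric flare.  The breadth profile
    # rises linearly to its peak at the intertrochanteric line and drops
    # beyond it; sampling discrete stations systematically undershoots the
    # peak, so the rising flank is extrapolated to the peak station.
    ss = np.arange(s_j - 8.0, s_j + 2.0, 0.25)
    ws = np.array([_chord(scan_nh, centre + s * d, lat)[0] for s in ss])
    if not np.any(ws > 0):
        raise MorphometryError("no intertrochanteric section found "
                               "near the junction")
    k_peak = int(np.argmax(ws))
    s_peak = ss[k_peak]
    flank = (ss >= s_peak - 4.0) & (ss <= s_peak) & (ws > 0)
    if flank.sum() >= 4:
        # the last rasterised row sits on average half a row pitch below
        # the true edge; extrapolate the rising flank past the raster peak
        coef = np.polyfit(ss[flank], ws[flank], 1)
        itw = float(np.polyval(coef, s_peak + 0.5 * scan.pixel_dy))
    else:
        itw = float(ws[k_peak])
    hal, _ = _chord(scan, neck_mid, m, half_span=110.0)
    nsa = math.degrees(math.acos(float(np.clip(m @ (-d), -1.0, 1.0))))
    fa = float(scan.mask.sum()) * scan.pixel_area()

    morph = MorphometricSet(nw=nw, hal=hal, nsa=nsa, sal=sal,
                            itw=itw, stw=stw, fa=fa)
    return Landmarks(shaft_point=centre, shaft_dir=d, lateral_dir=lat,
                     s0=s0, s_junction=s_j, head_centre=hc,
                     head_radius=r_head, neck_dir=m, neck_mid=neck_mid,
                     morph=morph)


def measure(scan: ScanRaster) -> MorphometricSet:
    """Measure the seven morphometric attributes of a pose-standardised mask."""
    return analyze(scan).morph


def partition_rois(scan: ScanRaster, morph: MorphometricSet | None = None,
                   neck_band_mm: float = 15.0,
                   landmarks: Landmarks | None = None) -> RoiPartition:
    """Neck band and trochanteric region of interest.

    The neck region is a band of the configured width centred on the
    narrowest neck cross-section, perpendicular to the neck axis.  The
    trochanteric region lies between the subtrochanteric level (25% of
    SAL above the distal entry) and the junction, lateral of the shaft
    axis, excluding the neck band.
    """
    lm = landmarks if landmarks is not None else analyze(scan)
    s_sub = lm.s0 + 0.25 * lm.morph.sal
    pts = scan.mask_points_mm()
    part = RoiPartition(neck_mask=None, troch_mask=None, landmarks=lm,
                        band_half=0.5 * neck_band_mm, s_sub=s_sub)
    neck, troch = part.classify_points(pts)
    rows, cols = np.nonzero(scan.mask)
    nm = np.zeros_like(scan.mask)
    tm = np.zeros_like(scan.mask)
    nm[rows[neck], cols[neck]] = True
    tm[rows[troch], cols[troch]] = True
    part.neck_mask, part.troch_mask = nm, tm
    if not nm.any() or not tm.any():
        raise MorphometryError("empty region of interest")
    return part


def place_pads(scan: ScanRaster, morph: MorphometricSet | None = None,
               pad_thickness: float = 6.0,
               b_fraction: float = 0.8,
               t_fraction: float = 0.3837,
               landmarks: Landmarks | None = None) -> PadGeometry:
    """Place the greater-trochanter and femoral-head PMMA pads.

    The trochanteric pad hugs the lateral contour over a span of
    ``b = b_fraction * ITW`` just distal of the junction; its outer face is
    flat (so the applied pressure integrates to exactly HP*b*t).  The head
    pad is an annular cap conforming to the medial femoral-head contour.
    The out-of-plane thickness ``t = t_fraction * NW`` converts between
    pressure and force; its default is calibrated so that cohort-mean hip
    pressure lands on the published scale.
    """
    lm = landmarks if landmarks is not None else analyze(scan)
    morph = morph if morph is not None else lm.morph
    b = b_fraction * morph.itw
    t = t_fraction * morph.nw
    c, d, lat = lm.shaft_point, lm.shaft_dir, lm.lateral_dir
    stations = np.linspace(lm.s_junction - b, lm.s_junction - 0.3, 25)
    inner_pts, ells = [], []
    for s in stations:
        w, run_centre = _chord(scan, c + s * d, lat)
        if w <= 0:
            raise MorphometryError("lateral contour segment too short for pad")
        ell_edge = float((run_centre - c) @ lat + 0.5 * w)
        ells.append(ell_edge)
        inner_pts.append(c + s * d + (ell_edge - 0.4) * lat)
    ell_out = max(ells) + pad_thickness
    p0 = c + stations[0] * d + ell_out * lat
    p1 = c + stations[-1] * d + ell_out * lat
    troch_poly = Polygon(inner_pts + [p1, p0])
    b_face = float(np.linalg.norm(p1 - p0))

    # head pad: annular sector about the head centre facing the medial apex
    ang0 = math.atan2(lm.neck_dir[1], lm.neck_dir[0])
    angles = ang0 + np.linspace(-1.2, 1.2, 33)
    r_in = max(lm.head_radius - 0.6, 0.5)
    r_out = lm.head_radius + pad_thickness
    inner_arc = [lm.head_centre + r_in * np.array([math.cos(a), math.sin(a)])
                 for a in angles]
    outer_arc = [lm.head_centre + r_out * np.array([math.cos(a), math.sin(a)])
                 for a in angles[::-1]]
    head_poly = Polygon(inner_arc + outer_arc)

    return PadGeometry(troch_polygon=troch_poly, head_polygon=head_poly,
                       b=b_face, t=t, load_p0=p0, load_p1=p1,
                       load_normal=-lat, head_centre=lm.head_centre,
                       head_outer_radius=r_out)
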