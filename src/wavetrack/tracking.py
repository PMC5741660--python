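"""Soma extraction, geodesic neurite length, seeded tracking, kymographs.

The neurite length is the geodesic (minimum-cost) path between two points
restricted to above-threshold pixels of the feature map, with step weights 1
for axial moves and sqrt(2) for diagonal moves — i.e. the exact 8-connected
shortest path, converted to micrometres with the pixel calibration.

Tracking is seeded: frame-0 annotations come from a file (the simulator emits
them), later frames re-localize each point near its previous position.  When
no candidate lies within the search radius — e.g. during the fast retraction
of the growth cone toward an incoming wave — the search window expands
(doubling, up to 4x) and the frame is flagged, standing in for the manual
supervision a human operator would provide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.graph import MCP_Geometric
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk
from skimage.segmentation import flood

from .errors import DisconnectionError, GeometryError, SeedError, ValidationError
from .imageproc import CalibratedStack, FeatureMap, gaussian_denoise

__all__ = [
    "SeedAnnotation",
    "Trajectory",
    "extract_soma",
    "geodesic_length",
    "geodesic_distance_map",
    "track_trajectory",
    "build_kymograph",
]


@dataclass
class SeedAnnotation:
    """Frame-0 pixel annotations; optional per-frame manual corrections.

    ``corrections`` maps a frame index to a dict with any of the keys
    ``soma``/``hillock``/``edge``/``wave`` overriding the automatic choice.
    """

    soma_point: tuple[int, int]
    hillock_point: tuple[int, int]
    edge_point: tuple[int, int]
    wave_point: tuple[int, int] | None = None
    corrections: dict[int, dict] = field(default_factory=dict)

    def validate(self, shape: tuple[int, int]) -> None:
        for name in ("soma_point", "hillock_point", "edge_point", "wave_point"):
            pt = getattr(self, name)
            if pt is None:
                continue
            if not (0 <= pt[0] < shape[0] and 0 <= pt[1] < shape[1]):
                raise ValidationError(f"{name}: {tuple(pt)} outside image {shape}")
        if tuple(self.hillock_point) == tuple(self.edge_point):
            raise ValidationError("hillock_point and edge_point must differ")


@dataclass
class Trajectory:
    """Per-frame tracked positions and geodesic distances."""

    times_s: np.ndarray
    soma_rc: np.ndarray        # (T, 2) intensity-weighted soma centroid, px
    hillock_rc: np.ndarray     # (T, 2)
    edge_rc: np.ndarray        # (T, 2)
    length_um: np.ndarray      # (T,) soma -> tip geodesic, NaN when lost
    wave_arc_um: np.ndarray    # (T,) most distal wave candidate, NaN when absent
    wave_present: np.ndarray   # (T,) bool
    gap: np.ndarray            # (T,) bool, tracking needed an expanded search
    pixel_size_um: float
    wave_candidates: list = field(default_factory=list)  # per frame, all arc candidates

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.times_s)),
            "time_s": self.times_s,
            "length_um": self.length_um,
            "wave_arc_um": self.wave_arc_um,
            "wave_present": self.wave_present.astype(bool),
            "soma_r": self.soma_rc[:, 0], "soma_c": self.soma_rc[:, 1],
            "hillock_r": self.hillock_rc[:, 0], "hillock_c": self.hillock_rc[:, 1],
            "edge_r": self.edge_rc[:, 0], "edge_c": self.edge_rc[:, 1],
            "gap": self.gap.astype(bool),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pixel_size_um: float) -> "Trajectory":
        return cls(
            times_s=df["time_s"].to_numpy(float),
            soma_rc=df[["soma_r", "soma_c"]].to_numpy(float),
            hillock_rc=df[["hillock_r", "hillock_c"]].to_numpy(float),
            edge_rc=df[["edge_r", "edge_c"]].to_numpy(float),
            length_um=df["length_um"].to_numpy(float),
            wave_arc_um=df["wave_arc_um"].to_numpy(float),
            wave_present=df["wave_present"].to_numpy(bool),
            gap=df["gap"].to_numpy(bool),
            pixel_size_um=pixel_size_um,
        )


# ---------------------------------------------------------------------------
# soma
# ---------------------------------------------------------------------------

def extract_soma(
    image: np.ndarray,
    soma_seed: tuple[int, int],
    threshold: float | None = None,
    max_radius_px: float = 40.0,
):
    """Grow the above-threshold region from the seed; return (mask, centroid).

    ``image`` may be an intensity grid (thresholded at Otsu unless given) or a
    boolean map.  The centroid is intensity-weighted and defines the origin of
    the arc-length coordinate system.
    """
    image = np.asarray(image)
    r, c = int(soma_seed[0]), int(soma_seed[1])
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise SeedError(f"soma seed ({r}, {c}) outside image")
    if image.dtype == bool:
        fg = image
        weights = None
    else:
        thr = threshold_otsu(image) if threshold is None else threshold
        fg = image >= thr
        weights = image
    if not fg[r, c]:
        raise SeedError(f"soma seed ({r}, {c}) lies on background")
    rr, cc = np.ogrid[:image.shape[0], :image.shape[1]]
    within = (rr - r) ** 2 + (cc - c) ** 2 <= max_radius_px**2
    mask = flood(fg & within, (r, c), connectivity=2)
    if weights is None:
        w = mask.astype(float)
    else:
        w = np.where(mask, weights, 0.0)
    total = w.sum()
    centroid = np.array([(w * rr).sum() / total, (w * cc).sum() / total])
    return mask, centroid


# ---------------------------------------------------------------------------
# geodesics
# ---------------------------------------------------------------------------

def geodesic_distance_map(mask: np.ndarray, source: tuple[int, int]) -> np.ndarray:
    """Exact 8-connected geodesic distances (px) from ``source`` on ``mask``.

    Uses a minimum-cost-path search on a uniform unit cost field, which for
    8-connectivity gives step costs of exactly 1 (axial) and sqrt(2)
    (diagonal).  Off-mask and unreachable pixels are +inf.
    """
    mask = np.asarray(mask, dtype=bool)
    r, c = int(source[0]), int(source[1])
    if not mask[r, c]:
        raise SeedError(f"point ({r}, {c}) lies on background")
    costs = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    dist, _ = mcp.find_costs([(r, c)])
    return dist


def geodesic_length(
    mask: np.ndarray,
    p1: tuple[int, int],
    p2: tuple[int, int],
    pixel_size_um: float,
) -> float:
    """Shortest above-threshold path length between two points, micrometres."""
    if not pixel_size_um > 0:
        raise ValidationError("pixel_size_um: must be > 0")
    mask = np.asarray(mask, dtype=bool)
    for name, p in (("p1", p1), ("p2", p2)):
        if not mask[int(p[0]), int(p[1])]:
            raise SeedError(f"{name} ({int(p[0])}, {int(p[1])}) lies on background")
    dist = geodesic_distance_map(mask, p1)
    d = dist[int(p2[0]), int(p2[1])]
    if not np.isfinite(d):
        raise DisconnectionError(f"p1 {tuple(p1)} and p2 {tuple(p2)} are not connected")
    return float(d) * pixel_size_um


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _nearest_on_mask(mask, point, radius, max_expand=4):
    """Nearest True pixel within ``radius`` of ``point``; expands on failure.

    Returns (pixel, expanded_flag) or (None, True) if nothing found at 4x.
    """
    coords = np.argwhere(mask)
    if coords.size == 0:
        return None, True
    d = np.hypot(coords[:, 0] - point[0], coords[:, 1] - point[1])
    rad = radius
    for attempt in range(max_expand):
        sel = d <= rad
        if sel.any():
            best = coords[sel][np.argmin(d[sel])]
            return (int(best[0]), int(best[1])), attempt > 0
        rad *= 2
    return None, True


def track_trajectory(
    stack: CalibratedStack,
    maps: list[FeatureMap],
    seeds: SeedAnnotation,
    search_radius_px: float = 15.0,
    *,
    denoise_sigma_px: float = 1.0,
    soma_max_radius_px: float = 25.0,
    wave_min_factor: float = 1.5,
    wave_prominence_factor: float = 1.0,
    soma_exclude_um: float = 12.0,
    tip_exclude_um: float = 15.0,
    fill_bright: bool = True,
) -> Trajectory:
    """Track soma, hillock, edge and wave through the movie.

    Per frame: the soma region is re-grown from the previous centroid; the
    hillock snaps to the nearest feature pixel; the edge is the component
    pixel with the largest geodesic distance from the arc origin within the
    search region; the wave is the most distal local intensity maximum along
    the component whose height exceeds ``wave_min_factor`` times the frame
    background (other candidates are logged).  Frames with no qualifying wave
    candidate carry the no-wave flag so downstream statistics can drop them.

    With ``fill_bright`` (default) the phase-congruency map is unioned with an
    Otsu intensity mask of the denoised frame: phase congruency outlines blob
    structures (soma, growth cone, wave core) by their rims only, and filling
    them keeps geodesics from detouring around boundary rings — the same
    background-corrected thresholding step interactive workflows apply before
    measuring the neurite.
    """
    if len(maps) != stack.n_frames:
        raise ValidationError("maps: need one FeatureMap per frame")
    seeds.validate(stack.shape)
    px = stack.pixel_size_um
    T = stack.n_frames

    soma_rc = np.full((T, 2), np.nan)
    hillock_rc = np.full((T, 2), np.nan)
    edge_rc = np.full((T, 2), np.nan)
    length_um = np.full(T, np.nan)
    wave_arc = np.full(T, np.nan)
    wave_present = np.zeros(T, dtype=bool)
    gap = np.zeros(T, dtype=bool)
    candidates_log: list[list[float]] = []

    prev_soma = np.asarray(seeds.soma_point, dtype=float)
    prev_hillock = tuple(seeds.hillock_point)
    prev_edge = tuple(seeds.edge_point)

    for t in range(T):
        den = gaussian_denoise(stack.frames[t], denoise_sigma_px)
        binary = maps[t].binary
        if fill_bright:
            # Background-relative fill: phase congruency outlines blobs by
            # their rims and fades where the shaft exits the soma; pixels
            # clearly above background complete the structure.
            binary = binary | (den >= wave_min_factor * np.median(den))
        # Bridge sub-pixel dropouts along thin ridges so one neurite stays
        # one 8-connected component.
        binary = closing(binary, disk(2))
        corr = seeds.corrections.get(t, {})

        # --- soma ---
        seed_pt = corr.get("soma", tuple(np.round(prev_soma).astype(int)))
        try:
            _, centroid = extract_soma(den, seed_pt, max_radius_px=soma_max_radius_px)
        except SeedError:
            centroid = prev_soma.copy()
            gap[t] = True
        soma_rc[t] = centroid
        prev_soma = centroid

        # --- hillock ---
        if "hillock" in corr:
            hillock = tuple(corr["hillock"])
            expanded = False
        else:
            hillock, expanded = _nearest_on_mask(binary, prev_hillock, search_radius_px)
        gap[t] |= expanded
        if hillock is None:
            candidates_log.append([])
            continue
        hillock_rc[t] = hillock
        prev_hillock = hillock

        labels = cc_label(binary, connectivity=2)
        comp = labels == labels[hillock]

        # Arc origin: projection of the soma centroid onto the component.
        origin, _ = _nearest_on_mask(comp, centroid, radius=max(comp.shape))
        dist = geodesic_distance_map(comp, origin)

        # --- edge ---
        if "edge" in corr:
            edge = tuple(corr["edge"])
            expanded = False
        else:
            edge, expanded = None, False
            coords = np.argwhere(comp)
            d_prev = np.hypot(coords[:, 0] - prev_edge[0], coords[:, 1] - prev_edge[1])
            rad = search_radius_px
            for attempt in range(4):
                sel = d_prev <= rad
                if sel.any():
                    cand = coords[sel]
                    edge = tuple(cand[np.argmax(dist[cand[:, 0], cand[:, 1]])])
                    expanded = attempt > 0
                    break
                rad *= 2
        gap[t] |= expanded
        if edge is not None:
            edge_rc[t] = edge
            length_um[t] = dist[edge] * px
            prev_edge = edge

        # --- wave: arc-binned intensity profile of the component ---
        comp_pix = np.argwhere(comp)
        arcs = dist[comp_pix[:, 0], comp_pix[:, 1]]
        finite = np.isfinite(arcs)
        comp_pix, arcs = comp_pix[finite], arcs[finite]
        bins = np.round(arcs).astype(int)
        n_bins = bins.max() + 1 if bins.size else 0
        profile = np.zeros(n_bins)
        np.maximum.at(profile, bins, den[comp_pix[:, 0], comp_pix[:, 1]])
        background = float(np.median(den))
        frame_cands: list[float] = []
        if "wave" in corr:
            wr, wc = corr["wave"]
            wave_arc[t] = dist[int(wr), int(wc)] * px
            wave_present[t] = True
        elif n_bins > 3:
            peaks, _ = find_peaks(
                profile,
                height=wave_min_factor * background,
                prominence=wave_prominence_factor * background,
            )
            lo = soma_exclude_um / px
            hi = (length_um[t] - tip_exclude_um) / px if np.isfinite(length_um[t]) else np.inf
            keep = [p for p in peaks if lo <= p <= hi]
            frame_cands = [p * px for p in keep]
            if keep:
                wave_arc[t] = max(keep) * px
                wave_present[t] = True
        candidates_log.append(frame_cands)

    return Trajectory(
        times_s=stack.times_s(),
        soma_rc=soma_rc, hillock_rc=hillock_rc, edge_rc=edge_rc,
        length_um=length_um, wave_arc_um=wave_arc, wave_present=wave_present,
        gap=gap, pixel_size_um=px, wave_candidates=candidates_log,
    )


# ---------------------------------------------------------------------------
# kymograph
# ---------------------------------------------------------------------------

def build_kymograph(
    stack: CalibratedStack,
    backbone_polyline_px: np.ndarray,
    half_width_px: float = 3.0,
) -> np.ndarray:
    """Time x arc-length intensity, max-projected across the path's width.

    Row ``t`` samples frame ``t`` along the polyline at pixel pitch; each
    sample is the maximum over a perpendicular segment of +- ``half_width_px``.
    """
    poly = np.asarray(backbone_polyline_px, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
        raise ValidationError("backbone_polyline_px: expected (N >= 2, 2)")
    h, w = stack.shape
    if (poly[:, 0].min() < 0 or poly[:, 1].min() < 0
            or poly[:, 0].max() > h - 1 or poly[:, 1].max() > w - 1):
        raise GeometryError("backbone polyline escapes the frame")

    seg = np.diff(poly, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    n_cols = int(math.ceil(arc[-1])) + 1
    s = np.linspace(0.0, arc[-1], n_cols)
    pr = np.interp(s, arc, poly[:, 0])
    pc = np.interp(s, arc, poly[:, 1])
    tr = np.gradient(pr)
    tc = np.gradient(pc)
    norm = np.hypot(tr, tc)
    norm[norm == 0] = 1.0
    nr, nc = -tc / norm, tr / norm  # unit normal

    offsets = np.arange(-half_width_px, half_width_px + 0.5, 0.5)
    rows_s = pr[None, :] + offsets[:, None] * nr[None, :]
    cols_s = pc[None, :] + offsets[:, None] * nc[None, :]
    rows_s = np.clip(rows_s, 0, h - 1)
    cols_s = np.clip(cols_s, 0, w - 1)

    kymo = np.empty((stack.n_frames, n_cols))
    coords = np.stack([rows_s.ravel(), cols_s.ravel()])
    for t in range(stack.n_frames):
        vals = map_coordinates(stack.frames[t], coords, order=1)
        kymo[t] = vals.reshape(offsets.size, n_cols).max(axis=0)
    return kymo
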