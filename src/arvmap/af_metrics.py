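"""Analysis layer: focal-source scoring, organization, concordance, QS.

Implements the Focal Vector Score (FVS): a circular region of interest
around a candidate centrifugal center is divided into eight 45-degree
sectors; each sector scores +1 when more than 60% of its vectors point
away from the center (centrifugal), -1 when more than 60% point toward it,
and 0 otherwise; a cumulative FVS >= 3 declares a focal source.  Segments
whose vectors are directionally coherent (>70% within 45 degrees of the
segment's circular-mean direction) are organized, and a chamber is
organized when more than 70% of its 18 segments (i.e. >= 13) are.
Map-pair concordance classifies reproducibility as low (<30%), moderate
(30-70%) or high (>70%).  QS morphology (no initial R wave) supports
candidate focal origins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .vector_map import VectorMap


@dataclass(frozen=True)
class AnalysisConfig:
    """Scoring thresholds; defaults follow the published mapping protocol."""

    fvs_threshold: int = 3
    sector_fraction: float = 0.60
    roi_radius_cm: float = 0.4
    coherence_half_angle_deg: float = 45.0
    segment_coherent_fraction: float = 0.70
    chamber_fraction: float = 0.70
    concordance_match_radius_cm: float = 0.2
    concordance_half_angle_deg: float = 45.0
    min_roi_vectors: int = 8
    min_populated_sectors: int = 8
    min_segment_vectors: int = 5
    candidate_spacing_cm: float = 0.2
    qs_r_fraction_max: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sector_fraction", "segment_coherent_fraction", "chamber_fraction"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("coherence_half_angle_deg", "concordance_half_angle_deg"):
            if not (0 < getattr(self, name) <= 90):
                raise ValueError(f"{name} must lie in (0, 90]")


# --- radial classification and sector scoring -------------------------------


def classify_vector_radial(
    position: np.ndarray, direction: np.ndarray, center: np.ndarray
) -> str:
    """Classify one vector as centrifugal / centripetal / perpendicular.

    ``alpha`` is the angle between the vector direction and the outward
    radial at its position: centrifugal for alpha <= 45 deg, centripetal
    for alpha >= 135 deg, perpendicular otherwise.
    """
    radial = np.asarray(position, float) - np.asarray(center, float)
    r = np.hypot(*radial)
    if r < 1e-12:
        warnings.warn("vector at the candidate center classified perpendicular")
        return "perpendicular"
    d = np.asarray(direction, float)
    cos_a = float(np.clip((radial / r) @ (d / np.hypot(*d)), -1.0, 1.0))
    alpha = np.degrees(np.arccos(cos_a))
    if alpha <= 45.0:
        return "centrifugal"
    if alpha >= 135.0:
        return "centripetal"
    return "perpendicular"


def score_sector(
    classes: list[str], cfg: AnalysisConfig = AnalysisConfig()
) -> int:
    """+1 / -1 / 0 sector score from the radial classes of its vectors.

    Strictly more than ``sector_fraction`` (60%) of the sector's vectors
    must be centrifugal (+1) or centripetal (-1); empty, balanced or
    predominantly perpendicular sectors score 0.
    """
    n = len(classes)
    if n == 0:
        return 0
    cf = sum(c == "centrifugal" for c in classes) / n
    cp = sum(c == "centripetal" for c in classes) / n
    if cf > cfg.sector_fraction:
        return 1
    if cp > cfg.sector_fraction:
        return -1
    return 0


# --- focal vector score -----------------------------------------------------


@dataclass
class FocalCandidate:
    """Candidate focal-source center with its eight sector scores."""

    center: tuple[float, float]
    roi_radius_cm: float
    sector_scores: tuple[int, ...]
    fvs: int
    accepted: bool
    low_support: bool = False
    truncated: bool = False
    mean_certainty: float = 0.0
    n_roi_vectors: int = 0
    qs: bool | None = None


def compute_fvs(
    vmap: VectorMap,
    center: np.ndarray,
    cfg: AnalysisConfig = AnalysisConfig(),
    _tree: cKDTree | None = None,
) -> FocalCandidate:
    """Focal Vector Score at one candidate center.

    Vectors within the circular ROI are binned into eight equal 45-degree
    sectors (sector 1 starting at the +x axis, counterclockwise) and each
    sector scored by centrifugal/centripetal predominance; the FVS is the
    sector sum and the candidate is accepted at FVS >= ``fvs_threshold``.
    ROIs with fewer than ``min_roi_vectors`` vectors, or with fewer than
    ``min_populated_sectors`` non-empty sectors (one-sided coverage cannot
    witness a centrifugal pattern), are flagged low-support and never
    accepted; ROIs clipped by the sheet boundary are flagged truncated.
    """
    center = np.asarray(center, dtype=float)
    pos = vmap.positions
    tree = _tree if _tree is not None else cKDTree(pos)
    idx = np.asarray(tree.query_ball_point(center, cfg.roi_radius_cm), dtype=int)
    rel = pos[idx] - center if idx.size else np.empty((0, 2))
    angles = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    sector_idx = np.minimum((angles / (np.pi / 4)).astype(int), 7)
    # vectorized radial classification (same rule as classify_vector_radial)
    r = np.hypot(rel[:, 0], rel[:, 1])
    dirs_roi = vmap.directions[idx] if idx.size else np.empty((0, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_a = np.einsum("ij,ij->i", rel, dirs_roi) / np.where(r > 1e-12, r, 1.0)
    alpha = np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0)))
    centrifugal = (alpha <= 45.0) & (r > 1e-12)
    centripetal = (alpha >= 135.0) & (r > 1e-12)
    scores = []
    for s in range(8):
        in_s = sector_idx == s
        n = int(in_s.sum())
        if n == 0:
            scores.append(0)
        elif centrifugal[in_s].mean() > cfg.sector_fraction:
            scores.append(1)
        elif centripetal[in_s].mean() > cfg.sector_fraction:
            scores.append(-1)
        else:
            scores.append(0)
    fvs = int(sum(scores))
    populated = int(np.sum(np.bincount(sector_idx, minlength=8) > 0))
    low_support = (
        len(idx) < cfg.min_roi_vectors or populated < cfg.min_populated_sectors
    )
    g = vmap.geometry
    truncated = not (
        cfg.roi_radius_cm <= center[0] <= g.width - cfg.roi_radius_cm
        and cfg.roi_radius_cm <= center[1] <= g.height - cfg.roi_radius_cm
    )
    certs = [vmap.vectors[m].certainty for m in idx]
    return FocalCandidate(
        center=(float(center[0]), float(center[1])),
        roi_radius_cm=cfg.roi_radius_cm,
        sector_scores=tuple(scores),
        fvs=fvs,
        accepted=bool(fvs >= cfg.fvs_threshold and not low_support),
        low_support=low_support,
        truncated=truncated,
        mean_certainty=float(np.mean(certs)) if certs else 0.0,
        n_roi_vectors=len(idx),
    )


def detect_focal_sources(
    vmap: VectorMap,
    cfg: AnalysisConfig = AnalysisConfig(),
    spacing_cm: float | None = None,
    qs_lookup=None,
) -> list[FocalCandidate]:
    """Scan a regular candidate lattice for valid focal sources.

    The FVS is evaluated on a lattice of candidate centers (default 2 mm
    spacing); accepted candidates with overlapping ROIs are merged by
    non-maximum suppression (highest FVS wins, ties broken by mean
    certainty in the ROI).  When a ``qs_lookup(center) -> bool`` callable is given,
    each reported source carries the QS flag of the nearest electrode trace.
    """
    spacing = spacing_cm if spacing_cm is not None else cfg.candidate_spacing_cm
    g = vmap.geometry
    xs = np.arange(spacing / 2, g.width, spacing)
    ys = np.arange(spacing / 2, g.height, spacing)
    tree = cKDTree(vmap.positions)
    accepted: list[FocalCandidate] = []
    for y in ys:
        for x in xs:
            cand = compute_fvs(vmap, np.array([x, y]), cfg, _tree=tree)
            if cand.accepted:
                accepted.append(cand)
    accepted.sort(key=lambda c: (-c.fvs, -c.mean_certainty, c.center))
    kept: list[FocalCandidate] = []
    for cand in accepted:
        if all(
            np.hypot(cand.center[0] - k.center[0], cand.center[1] - k.center[1])
            > 2 * cfg.roi_radius_cm
            for k in kept
        ):
            if qs_lookup is not None:
                cand.qs = bool(qs_lookup(np.asarray(cand.center)))
            kept.append(cand)
    return kept


# --- organization -----------------------------------------------------------


@dataclass
class SegmentOrganization:
    segment_id: int
    organized: bool
    coherent_fraction: float
    n_vectors: int
    low_support: bool


@dataclass
class OrganizationResult:
    """Per-segment coherence and the chamber-level dichotomy."""

    per_segment: list[SegmentOrganization]
    n_organized: int
    chamber_class: str  # "organized" | "disorganized"


def circular_mean_direction(directions: np.ndarray) -> np.ndarray:
    m = np.asarray(directions, float).mean(axis=0)
    n = np.hypot(*m)
    if n < 1e-12:
        return np.array([1.0, 0.0])
    return m / n


def classify_organization(
    vmap: VectorMap, cfg: AnalysisConfig = AnalysisConfig()
) -> OrganizationResult:
    """Classify each segment and the chamber as organized or disorganized.

    A segment is organized when strictly more than 70% of its vectors lie
    within 45 degrees of the segment's circular-mean direction; segments
    with fewer than ``min_segment_vectors`` vectors are counted as not
    organized (low support).  The chamber is organized when strictly more
    than 70% of segments are organized (13 of 18).
    """
    ids = vmap.segment_ids()
    dirs = vmap.directions
    cos_thr = np.cos(np.deg2rad(cfg.coherence_half_angle_deg))
    per_segment = []
    n_org = 0
    for seg in range(1, vmap.partition.n_segments + 1):
        mask = ids == seg
        n = int(mask.sum())
        if n < cfg.min_segment_vectors:
            per_segment.append(
                SegmentOrganization(seg, False, 0.0, n, low_support=True)
            )
            continue
        d = dirs[mask]
        mean_dir = circular_mean_direction(d)
        frac = float(np.mean(d @ mean_dir >= cos_thr))
        organized = frac > cfg.segment_coherent_fraction
        n_org += int(organized)
        per_segment.append(
            SegmentOrganization(seg, organized, frac, n, low_support=False)
        )
    chamber = (
        "organized"
        if n_org > cfg.chamber_fraction * vmap.partition.n_segments
        else "disorganized"
    )
    return OrganizationResult(
        per_segment=per_segment, n_organized=n_org, chamber_class=chamber
    )


# --- concordance ------------------------------------------------------------


@dataclass
class ConcordanceResult:
    """Map-pair vector concordance (reproducibility)."""

    percent: float
    reproducibility_class: str  # "low" | "moderate" | "high"
    n_matched_locations: int


def _site_representatives(vmap: VectorMap) -> tuple[np.ndarray, np.ndarray]:
    """One vector per distinct map position: highest certainty wins."""
    pos = vmap.positions
    dirs = vmap.directions
    certs = np.array([v.certainty for v in vmap.vectors])
    keys = np.round(pos, 6)
    order = np.lexsort((-certs, keys[:, 1], keys[:, 0]))
    _, first = np.unique(keys[order], axis=0, return_index=True)
    sel = order[np.sort(first)]
    return pos[sel], dirs[sel]


def concordance(
    map_a: VectorMap, map_b: VectorMap, cfg: AnalysisConfig = AnalysisConfig()
) -> ConcordanceResult:
    """Directional concordance between two maps of the same chamber.

    Concordance is evaluated per mapped location: each map is first reduced
    to its most trustworthy vector per distinct position (repeated beats of
    one clique share a position), then every location of ``map_a`` is
    matched to the nearest location of ``map_b`` within the match radius; a
    matched pair is concordant when the angular difference is at most 45
    degrees.  Reproducibility is low below 30%, high strictly above 70%,
    moderate otherwise (both boundaries belong to moderate).
    """
    pa, da_all = _site_representatives(map_a)
    pb, db_all = _site_representatives(map_b)
    tree = cKDTree(pb)
    dist, idx = tree.query(
        pa, k=1, distance_upper_bound=cfg.concordance_match_radius_cm
    )
    matched = np.isfinite(dist)
    n_matched = int(matched.sum())
    if n_matched == 0:
        raise ValueError("maps do not overlap: zero matched locations")
    da = da_all[matched]
    db = db_all[idx[matched]]
    cos_thr = np.cos(np.deg2rad(cfg.concordance_half_angle_deg))
    concordant = np.einsum("ij,ij->i", da, db) >= cos_thr
    percent = 100.0 * float(concordant.mean())
    if percent < 30.0:
        cls = "low"
    elif percent > 70.0:
        cls = "high"
    else:
        cls = "moderate"
    return ConcordanceResult(
        percent=percent, reproducibility_class=cls, n_matched_locations=n_matched
    )


# --- QS morphology ----------------------------------------------------------


def qs_pattern(
    trace: np.ndarray,
    woi: tuple[float, float],
    sample_rate_hz: float,
    t_start_ms: float = 0.0,
    *,
    min_deflection_mv: float = 0.05,
    r_fraction_max: float = 0.1,
) -> tuple[bool, float]:
    """QS-morphology test of a unipolar electrogram inside the WOI.

    ``r_fraction`` is the positive-lobe amplitude divided by the total
    peak-to-peak; a QS complex (activation originating at the electrode)
    has essentially no initial positivity, ``r_fraction < 0.1``.  Raises on
    a flat trace (no deflection).
    """
    trace = np.asarray(trace, dtype=float)
    dt = 1000.0 / sample_rate_hz
    i0 = max(0, int(np.ceil((woi[0] - t_start_ms) / dt)))
    i1 = min(trace.size, int(np.floor((woi[1] - t_start_ms) / dt)) + 1)
    w = trace[i0:i1]
    if w.size == 0:
        raise ValueError("no deflection: empty window")
    pp = float(w.max() - w.min())
    if pp < min_deflection_mv:
        raise ValueError("no deflection: trace flat inside WOI")
    r_amp = max(float(w.max()), 0.0)
    r_fraction = r_amp / pp
    return r_fraction < r_fraction_max, r_fraction
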