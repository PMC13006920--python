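"""Omnipolar local-activation vectors from three-electrode cliques.

Each interior 2x2 cell of the 4x4 grid yields four right-triangle cliques
(one per omitted corner), 36 per pose.  For every clique and beat, the
local activation direction and speed follow from a plane fit to the three
(position, activation time) pairs, with the activation time of each
electrode marked at the steepest negative unipolar slope inside the WOI
(sub-sample refined).  A 2-D electric-field loop, assembled from the two
bipolar signals along the clique legs scaled by inverse edge length,
provides an orientation-free cross-check: the certainty score combines the
loop's planarity with the agreement between loop-derived and timing-derived
propagation axes.  Acceptance requires certainty, peak-to-peak voltage and
the beat's ventricular score to clear their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import Beat
from .sim_atrium import GridPose


class NoLocalActivationError(ValueError):
    """Raised when fewer than two electrodes show a deflection in the WOI."""


@dataclass(frozen=True)
class Clique:
    """Right-isoceles triangle of three neighbouring grid electrodes."""

    labels: tuple[str, str, str]
    positions: np.ndarray  # (3, 2) chamber frame, cm
    parent_cell: tuple[int, int]  # (row, col) of the 2x2 cell, 0-based
    right_angle_index: int  # vertex shared by the two orthogonal legs

    def __post_init__(self) -> None:
        p = self.positions
        area2 = abs(
            (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
            - (p[1, 1] - p[0, 1]) * (p[2, 0] - p[0, 0])
        )
        if area2 < 1e-9:
            raise ValueError("collinear clique electrodes")

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def build_cliques(pose: GridPose) -> list[Clique]:
    """All 36 three-electrode cliques of a 4x4 grid pose.

    Each of the 9 interior 2x2 cells contributes 4 right triangles, one per
    omitted corner; the right-angle vertex is the corner diagonal to the
    omitted one.
    """
    pos = pose.electrode_positions
    labels = pose.labels
    cliques: list[Clique] = []
    for r in range(3):
        for c in range(3):
            corners = [r * 4 + c, r * 4 + c + 1, (r + 1) * 4 + c, (r + 1) * 4 + c + 1]
            for omit in range(4):
                kept = [corners[i] for i in range(4) if i != omit]
                # right-angle vertex = corner diagonal to the omitted one
                diag = corners[3 - omit]
                cliques.append(
                    Clique(
                        labels=tuple(labels[i] for i in kept),
                        positions=pos[kept].copy(),
                        parent_cell=(r, c),
                        right_angle_index=kept.index(diag),
                    )
                )
    return cliques


@dataclass
class OmniVector:
    """One local activation vector with its quality metadata.

    ``direction`` is a unit 2-D vector in the chamber frame pointing along
    propagation (later activation downstream); ``None`` when the clique
    activated near-simultaneously and the direction is indeterminate.
    """

    position: np.ndarray  # clique centroid, chamber frame (cm)
    direction: np.ndarray | None
    speed_m_s: float
    certainty: float
    vpp_mv: float
    beat_index: int = 0
    pose_index: int = 0
    accepted: bool = False
    reject_reason: str = "pending"
    indeterminate: bool = False


@dataclass(frozen=True)
class AcceptanceConfig:
    """Vector acceptance thresholds (all inclusive at equality)."""

    certainty_min: float = 0.5
    vpp_min_mv: float = 0.3
    score_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.certainty_min <= 1):
            raise ValueError("certainty_min must lie in [0, 1]")


# --- activation-time marking ------------------------------------------------


def _central_diff(v: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) * (0.5 / dt)
    d[0] = (v[1] - v[0]) / dt
    d[-1] = (v[-1] - v[-2]) / dt
    return d


def _loop_eigen(loop: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Eigenvalues (desc) and principal axis of a 2-D point cloud covariance."""
    x = loop[:, 0]
    y = loop[:, 1]
    mx = x.mean()
    my = y.mean()
    n = max(x.size - 1, 1)
    sxx = float(((x - mx) ** 2).sum()) / n
    syy = float(((y - my) ** 2).sum()) / n
    sxy = float(((x - mx) * (y - my)).sum()) / n
    half_tr = 0.5 * (sxx + syy)
    disc = np.sqrt(0.25 * (sxx - syy) ** 2 + sxy**2)
    lam1 = half_tr + disc
    lam2 = half_tr - disc
    if abs(sxy) > 1e-15:
        axis = np.array([lam1 - syy, sxy])
    elif sxx >= syy:
        axis = np.array([1.0, 0.0])
    else:
        axis = np.array([0.0, 1.0])
    norm = np.hypot(*axis)
    return lam1, max(lam2, 0.0), axis / (norm if norm > 0 else 1.0)


def _steepest_negative_slope_time(
    v: np.ndarray, t: np.ndarray
) -> float:
    """Time of max -dV/dt with parabolic sub-sample refinement."""
    d = _central_diff(v, float(t[1] - t[0]))
    i = int(np.argmin(d))
    if 0 < i < d.size - 1:
        denom = d[i - 1] - 2 * d[i] + d[i + 1]
        if abs(denom) > 1e-12:
            off = 0.5 * (d[i - 1] - d[i + 1]) / denom
            off = float(np.clip(off, -1.0, 1.0))
            return float(t[i] + off * (t[1] - t[0]))
    return float(t[i])


def certainty_score(loop: np.ndarray, residual_rms_ms: float) -> float:
    """Confidence in [0, 1] for one clique vector.

    ``planarity = 1 - lambda2/lambda1`` of the E-field loop's 2-D covariance
    (1 for a perfectly linear loop, ~0 for isotropic noise) multiplied by
    ``exp(-residual/1 ms)`` where the residual measures how well the loop's
    principal axis predicts the observed activation times.  A zero-energy
    loop scores 0.
    """
    loop = np.asarray(loop, dtype=float)
    if loop.size == 0:
        return 0.0
    lam1, lam2, _ = _loop_eigen(loop)
    if lam1 <= 1e-12:
        return 0.0
    planarity = 1.0 - lam2 / lam1
    fit_quality = float(np.exp(-max(residual_rms_ms, 0.0) / 1.0))
    return float(np.clip(planarity * fit_quality, 0.0, 1.0))


def estimate_vector(
    clique: Clique,
    traces: np.ndarray,
    sample_rate_hz: float,
    woi: tuple[float, float],
    t_start_ms: float = 0.0,
    *,
    beat_index: int = 0,
    pose_index: int = 0,
    min_deflection_mv: float = 0.1,
) -> OmniVector:
    """Estimate one omnipolar vector from a clique's unipolar traces.

    ``traces`` is (n_samples, 3), column order matching ``clique.labels``.
    Raises :class:`NoLocalActivationError` when fewer than two electrodes
    carry a deflection (peak-to-peak >= ``min_deflection_mv``) inside the
    WOI.  Near-simultaneous activation across the clique (spread <= one
    sample) yields an indeterminate vector with certainty 0.
    """
    traces = np.asarray(traces, dtype=float)
    dt = 1000.0 / sample_rate_hz
    n = traces.shape[0]
    i0 = max(0, int(np.ceil((woi[0] - t_start_ms) / dt)))
    i1 = min(n, int(np.floor((woi[1] - t_start_ms) / dt)) + 1)
    if i1 - i0 < 5:
        raise NoLocalActivationError("window of interest too short")
    w = traces[i0:i1]
    t = t_start_ms + np.arange(i0, i1) * dt

    pp = w.max(axis=0) - w.min(axis=0)
    vpp = float(pp.max())
    if int(np.sum(pp >= min_deflection_mv)) < 2:
        raise NoLocalActivationError(
            "no local activation: fewer than two deflections in WOI"
        )

    times = np.array(
        [_steepest_negative_slope_time(w[:, k], t) for k in range(3)]
    )
    centroid = clique.centroid
    spread = float(times.max() - times.min())

    # E-field loop from the two orthogonal legs (bipoles / edge length).
    # The legs sense the wavefront at midpoints ~half a pitch apart, which
    # lags one component against the other; the lag is compensated by
    # cross-correlation alignment so a travelling plane wave yields the
    # linearly polarized loop the continuum E-field would show.
    i_ra = clique.right_angle_index
    others = [k for k in range(3) if k != i_ra]
    comps, units = [], []
    for k in others:
        edge = clique.positions[k] - clique.positions[i_ra]
        length = float(np.hypot(*edge))
        units.append(edge / length)
        comps.append((w[:, k] - w[:, i_ra]) / length)  # mV/cm
    b1, b2 = comps
    e1 = float(b1 @ b1)
    e2 = float(b2 @ b2)
    max_lag = max(1, int(round(12.0 / dt)))
    if min(e1, e2) > 1e-6 * max(e1, e2) and max(e1, e2) > 0:
        xc = np.correlate(b1, b2, mode="full")
        mid = b1.size - 1
        lo = max(0, mid - max_lag)
        hi = min(xc.size, mid + max_lag + 1)
        lag = int(np.argmax(np.abs(xc[lo:hi])) + lo - mid)
    else:
        lag = 0
    if lag > 0:
        a1, a2 = b1[lag:], b2[: b2.size - lag]
    elif lag < 0:
        a1, a2 = b1[: b1.size + lag], b2[-lag:]
    else:
        a1, a2 = b1, b2
    loop = np.outer(a1, units[0]) + np.outer(a2, units[1])

    if spread <= dt:
        return OmniVector(
            position=centroid,
            direction=None,
            speed_m_s=float("nan"),
            certainty=0.0,
            vpp_mv=vpp,
            beat_index=beat_index,
            pose_index=pose_index,
            indeterminate=True,
        )

    # plane fit t = a + g . x  ->  direction along +g, speed = 1/|g|
    A = np.column_stack([np.ones(3), clique.positions])
    coef = np.linalg.solve(A, times)
    g = coef[1:]
    gnorm = float(np.hypot(*g))
    direction = g / gnorm
    speed_m_s = 10.0 / gnorm  # cm/ms -> m/s

    # loop principal axis vs timing axis: residual in ms
    _, _, axis = _loop_eigen(loop)
    if float(axis @ direction) < 0:
        axis = -axis
    rel = clique.positions - centroid
    predicted = times.mean() + rel @ (axis * gnorm)
    residual = float(np.sqrt(np.mean((times - predicted) ** 2)))
    certainty = certainty_score(loop, residual)

    return OmniVector(
        position=centroid,
        direction=direction,
        speed_m_s=speed_m_s,
        certainty=certainty,
        vpp_mv=vpp,
        beat_index=beat_index,
        pose_index=pose_index,
    )


def accept_point(
    v: OmniVector, beat: Beat, cfg: AcceptanceConfig = AcceptanceConfig()
) -> OmniVector:
    """Apply the certainty / voltage / ventricular-score filters in order.

    Thresholds are inclusive at exact equality; the rejection reason names
    the first failed filter.  The vector is updated in place and returned.
    """
    if v.certainty < cfg.certainty_min or v.direction is None:
        v.accepted = False
        v.reject_reason = "certainty"
    elif v.vpp_mv < cfg.vpp_min_mv:
        v.accepted = False
        v.reject_reason = "vpp"
    elif beat.ventricular_score is not None and beat.ventricular_score < cfg.score_min:
        v.accepted = False
        v.reject_reason = "score"
    else:
        v.accepted = True
        v.reject_reason = "none"
    return v
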