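"""Kinematic simulation of atrial-fibrillation activation on a 2-D sheet.

The chamber is modelled as a flat rectangular sheet of atrial tissue.
Activation is purely kinematic (eikonal-style earliest arrival at a fixed
conduction velocity), not reaction-diffusion: each beat produces a surface
of local activation times (LAT) from which unipolar electrograms are
synthesized at the electrodes of a roving 4x4 grid catheter.

Supported activation patterns:

* ``focal``   -- periodic point source with cycle-length jitter; LAT grows
  radially with distance / conduction velocity.
* ``planar``  -- a plane wave crossing the sheet at a configurable angle.
* ``rotor``   -- an Archimedean-spiral phase map rotating once per cycle.
* ``chaotic`` -- per-beat re-randomized wavelet sources plus 0-2 straight
  lines of conduction block that wavefronts must detour around (earliest
  arrival computed on the node graph with blocked edges removed).

Unipolar morphology follows the classical rule that the initial positive
(R) deflection reflects tissue activated *before* the wavefront arrives
under the electrode: an electrode sitting on a focal origin sees no
approaching wavefront and records a monophasic negative (QS) complex.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

# --- fixed physical / catheter constants -----------------------------------

#: 1 m/s expressed in cm/ms.
CM_PER_MS_PER_M_S = 0.1

#: inter-electrode pitch of the 4x4 grid catheter (cm); equidistant layout.
GRID_PITCH_CM = 0.3

#: atrial deflection template: Gaussian lobe sigma and R/S lobe offset (ms);
#: total biphasic width ~10 ms.
TEMPLATE_SIGMA_MS = 2.0
TEMPLATE_LOBE_OFFSET_MS = 2.5

#: ventricular far-field template sigma (ms); width ~40 ms, low frequency.
FARFIELD_SIGMA_MS = 10.0

#: radius of the neighbourhood used to evaluate the fraction of surrounding
#: tissue already activated (drives R/S balance of the unipolar template).
LOCAL_CONTEXT_RADIUS_CM = 0.3

#: chaotic wavelet sources are drawn from the sheet extended by this margin
#: so wavefronts also sweep in across the sheet edges.
CHAOTIC_SOURCE_MARGIN_CM = 2.0

#: grid electrode labels, row-major: rows A-D, columns 1-4.
GRID_LABELS = tuple(f"{row}{col}" for row in "ABCD" for col in (1, 2, 3, 4))


def label_index(label: str) -> int:
    """Return the row-major index (0-15) of an electrode label like ``'B2'``."""
    return GRID_LABELS.index(label)


B2_INDEX = label_index("B2")
C2_INDEX = label_index("C2")


# --- geometry ---------------------------------------------------------------


@dataclass(frozen=True)
class SheetGeometry:
    """Rectangular tissue sheet, lower-left corner at the origin.

    Parameters
    ----------
    width, height:
        Sheet extent in cm (default 6 x 4 cm).
    node_spacing:
        Lattice spacing of the LAT surface in cm; must resolve the sheet
        (<= min(width, height)/10).
    """

    width: float = 6.0
    height: float = 4.0
    node_spacing: float = 0.1

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("sheet width and height must be positive")
        if not (0 < self.node_spacing <= min(self.width, self.height) / 10):
            raise ValueError(
                "node_spacing must be positive and <= min(width, height)/10"
            )

    @property
    def x_nodes(self) -> np.ndarray:
        n = int(round(self.width / self.node_spacing)) + 1
        return np.linspace(0.0, self.width, n)

    @property
    def y_nodes(self) -> np.ndarray:
        n = int(round(self.height / self.node_spacing)) + 1
        return np.linspace(0.0, self.height, n)

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) of the node lattice."""
        return (self.y_nodes.size, self.x_nodes.size)

    def node_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_nodes, self.y_nodes)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (pts[:, 0] >= margin)
            & (pts[:, 0] <= self.width - margin)
            & (pts[:, 1] >= margin)
            & (pts[:, 1] <= self.height - margin)
        )

    def bilinear(self, values: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of a node field at arbitrary points (cm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = self.node_spacing
        ny, nx = values.shape
        fx = np.clip(pts[:, 0] / h, 0, nx - 1 - 1e-9)
        fy = np.clip(pts[:, 1] / h, 0, ny - 1 - 1e-9)
        ix = fx.astype(int)
        iy = fy.astype(int)
        tx = fx - ix
        ty = fy - iy
        v00 = values[iy, ix]
        v01 = values[iy, ix + 1]
        v10 = values[iy + 1, ix]
        v11 = values[iy + 1, ix + 1]
        return (
            v00 * (1 - tx) * (1 - ty)
            + v01 * tx * (1 - ty)
            + v10 * (1 - tx) * ty
            + v11 * tx * ty
        )


# --- source specification ---------------------------------------------------

_KINDS = ("focal", "planar", "rotor", "chaotic")


@dataclass(frozen=True)
class SourceSpec:
    """Activation-pattern specification for one simulated rhythm.

    ``conduction_velocity`` is in m/s, ``cycle_length`` and ``cl_jitter_sd``
    in ms, positions in cm.  ``amplitude_map`` optionally scales the regional
    peak-to-peak voltage (callable (x, y) -> mV); otherwise ``amplitude_mv``
    applies everywhere.
    """

    kind: str
    cycle_length: float = 180.0
    cl_jitter_sd: float = 10.0
    conduction_velocity: float = 0.8
    center: tuple[float, float] | None = None
    planar_angle: float = 0.0
    n_wavelets: int = 4
    amplitude_mv: float = 1.0
    amplitude_map: Callable[[float, float], float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if not (0.2 < self.conduction_velocity < 2.0):
            raise ValueError("conduction_velocity must lie in (0.2, 2.0) m/s")
        if self.cl_jitter_sd < 0:
            raise ValueError("cl_jitter_sd must be nonnegative")
        if self.kind == "chaotic" and self.n_wavelets < 2:
            raise ValueError("chaotic pattern needs n_wavelets >= 2")
        if self.kind in ("focal", "rotor") and self.center is None:
            raise ValueError(f"{self.kind} source requires a center")

    @property
    def cv_cm_per_ms(self) -> float:
        return self.conduction_velocity * CM_PER_MS_PER_M_S

    def amplitude_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.amplitude_map is None:
            return np.full(pts.shape[0], self.amplitude_mv)
        return np.array([self.amplitude_map(x, y) for x, y in pts])


@dataclass
class ActivationField:
    """Ground-truth LAT surface (ms) over the sheet lattice for one beat."""

    beat_index: int
    onset_ms: float
    lat: np.ndarray  # (ny, nx)
    source_positions: list[tuple[float, float]]
    block_lines: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )


# --- beat onset train -------------------------------------------------------


def beat_onsets(
    spec: SourceSpec, duration_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative beat onsets: cycle length plus Gaussian jitter per beat."""
    onsets = []
    t = spec.cycle_length * 0.5
    while t < duration_ms:
        onsets.append(t)
        step = spec.cycle_length + rng.normal(0.0, spec.cl_jitter_sd)
        t += max(step, spec.cycle_length * 0.25)  # guard against collapse
    return np.asarray(onsets)


# --- node graph for obstacle detours ----------------------------------------


@lru_cache(maxsize=8)
def _grid_graph(ny: int, nx: int, h: float):
    """8-neighbour lattice edges: (src, dst, weight) arrays, undirected pairs."""
    offsets = [(0, 1, h), (1, 0, h), (1, 1, h * np.sqrt(2)), (1, -1, h * np.sqrt(2))]
    srcs, dsts, wts = [], [], []
    for dy, dx, w in offsets:
        y0 = np.arange(max(0, -dy), min(ny, ny - dy))
        x0 = np.arange(max(0, -dx), min(nx, nx - dx))
        YY, XX = np.meshgrid(y0, x0, indexing="ij")
        s = YY * nx + XX
        d = (YY + dy) * nx + (XX + dx)
        srcs.append(s.ravel())
        dsts.append(d.ravel())
        wts.append(np.full(s.size, w))
    return np.concatenate(srcs), np.concatenate(dsts), np.concatenate(wts)


def _segments_cross(p0, p1, q0, q1) -> np.ndarray:
    """Vectorized proper-intersection test of segments (p0->p1)[i] with (q0->q1)."""

    def orient(a, b, c):
        return (b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1]) - (
            b[..., 1] - a[..., 1]
        ) * (c[..., 0] - a[..., 0])

    d1 = orient(q0, q1, p0)
    d2 = orient(q0, q1, p1)
    d3 = orient(p0, p1, q0)
    d4 = orient(p0, p1, q1)
    # an edge endpoint lying exactly on the block line counts as blocked
    # (conservative: node-aligned lines must still interrupt conduction)
    return (d1 * d2 <= 0) & (d3 * d4 < 0) & ~((d1 == 0) & (d2 == 0))


def _geodesic_lat(
    geom: SheetGeometry,
    sources_cm: np.ndarray,
    block_lines: list[tuple[tuple[float, float], tuple[float, float]]],
    cv_cm_ms: float,
    margin_cm: float = 0.0,
) -> np.ndarray:
    """Earliest-arrival LAT (relative to onset) around straight block lines.

    Computed on a lattice extended by ``margin_cm`` on every side (so
    sources outside the mapped sheet model wavefronts entering it) and
    cropped back to the sheet.
    """
    h = geom.node_spacing
    m = int(round(margin_cm / h))
    ny0, nx0 = geom.shape
    ny, nx = ny0 + 2 * m, nx0 + 2 * m
    src, dst, wts = _grid_graph(ny, nx, h)
    off = m * h
    if block_lines:
        xs = np.arange(nx) * h - off
        ys = np.arange(ny) * h - off
        p0 = np.stack([xs[src % nx], ys[src // nx]], axis=-1)
        p1 = np.stack([xs[dst % nx], ys[dst // nx]], axis=-1)
        keep = np.ones(src.size, dtype=bool)
        for (a, b) in block_lines:
            keep &= ~_segments_cross(p0, p1, np.asarray(a, float), np.asarray(b, float))
        src, dst, wts = src[keep], dst[keep], wts[keep]
    n = ny * nx
    graph = csr_matrix(
        (np.concatenate([wts, wts]), (np.concatenate([src, dst]), np.concatenate([dst, src]))),
        shape=(n, n),
    )
    ixs = np.clip(np.round((sources_cm[:, 0] + off) / h).astype(int), 0, nx - 1)
    iys = np.clip(np.round((sources_cm[:, 1] + off) / h).astype(int), 0, ny - 1)
    idx = iys * nx + ixs
    dist = dijkstra(graph, directed=False, indices=idx, min_only=True)
    lat = dist.reshape(ny, nx)[m : m + ny0, m : m + nx0] / cv_cm_ms
    if not np.all(np.isfinite(lat)):
        # a block line isolated a region from every source: fall back to
        # straight-line conduction so the LAT stays finite everywhere
        X, Y = geom.node_mesh()
        euclid = np.min(
            [np.hypot(X - s[0], Y - s[1]) for s in sources_cm], axis=0
        ) / cv_cm_ms
        lat = np.where(np.isfinite(lat), lat, euclid)
    return lat


# --- activation series ------------------------------------------------------


def generate_activation_series(
    spec: SourceSpec,
    geom: SheetGeometry,
    duration_ms: float,
    rng: np.random.Generator | int | None = None,
) -> list[ActivationField]:
    """Generate one :class:`ActivationField` per beat over ``duration_ms``.

    Beat onsets advance by ``cycle_length`` plus Gaussian jitter.  All
    randomness (onset jitter, chaotic wavelet positions, block lines) is
    drawn from ``rng``; a fixed seed reproduces the series exactly.
    """
    if duration_ms < 2 * spec.cycle_length:
        raise ValueError("duration must cover at least two cycle lengths")
    if spec.center is not None and not geom.contains([spec.center])[0]:
        raise ValueError(f"source center {spec.center} lies outside the sheet")
    rng = np.random.default_rng(rng)
    X, Y = geom.node_mesh()
    v = spec.cv_cm_per_ms
    fields: list[ActivationField] = []

    for k, onset in enumerate(beat_onsets(spec, duration_ms, rng)):
        if spec.kind == "focal":
            cx, cy = spec.center
            lat = onset + np.hypot(X - cx, Y - cy) / v
            srcs = [tuple(map(float, spec.center))]
            blocks = []
        elif spec.kind == "planar":
            a = np.deg2rad(spec.planar_angle)
            proj = X * np.cos(a) + Y * np.sin(a)
            lat = onset + (proj - proj.min()) / v
            srcs = []
            blocks = []
        elif spec.kind == "rotor":
            cx, cy = spec.center
            theta = np.arctan2(Y - cy, X - cx)
            r = np.hypot(X - cx, Y - cy)
            wavelength = v * spec.cycle_length
            phase = np.mod(theta + 2 * np.pi * r / wavelength, 2 * np.pi)
            lat = onset + spec.cycle_length * phase / (2 * np.pi)
            srcs = [tuple(map(float, spec.center))]
            blocks = []
        else:  # chaotic: re-randomized wavelets + block lines each beat.
            # Wavelets are drawn from a margin-extended domain so wavefronts
            # also enter the mapped sheet from outside and the direction
            # distribution stays isotropic up to the sheet edges.
            m = CHAOTIC_SOURCE_MARGIN_CM
            pts = np.column_stack(
                [
                    rng.uniform(-m, geom.width + m, spec.n_wavelets),
                    rng.uniform(-m, geom.height + m, spec.n_wavelets),
                ]
            )
            blocks = []
            for _ in range(int(rng.integers(0, 3))):
                c = np.array(
                    [rng.uniform(0, geom.width), rng.uniform(0, geom.height)]
                )
                ang = rng.uniform(0, np.pi)
                half = rng.uniform(0.75, 1.5)
                d = np.array([np.cos(ang), np.sin(ang)]) * half
                blocks.append((tuple(c - d), tuple(c + d)))
            lat = onset + _geodesic_lat(
                geom, pts, blocks, v, margin_cm=CHAOTIC_SOURCE_MARGIN_CM
            )
            srcs = [tuple(map(float, p)) for p in pts]
        fields.append(
            ActivationField(
                beat_index=k,
                onset_ms=float(onset),
                lat=lat,
                source_positions=srcs,
                block_lines=blocks,
            )
        )
    return fields


def local_context(
    field_: ActivationField, geom: SheetGeometry, point: Sequence[float]
) -> float:
    """Fraction of tissue within ~3 mm of ``point`` activated before it.

    0 at a focal origin (everything activates later), ~0.5 on the flank of
    a travelling wave.  Controls the R/S balance of the unipolar template.
    """
    p = np.asarray(point, dtype=float)
    h = geom.node_spacing
    r = LOCAL_CONTEXT_RADIUS_CM
    k = int(np.ceil(r / h))
    offs = np.arange(-k, k + 1) * h
    OX, OY = np.meshgrid(offs, offs)
    mask = OX**2 + OY**2 <= r**2
    pts = np.column_stack([(p[0] + OX[mask]), (p[1] + OY[mask])])
    inside = geom.contains(pts)
    pts = pts[inside]
    if pts.shape[0] == 0:
        return 0.5
    lat_here = geom.bilinear(field_.lat, p[None, :])[0]
    lat_nb = geom.bilinear(field_.lat, pts)
    return float(np.mean(lat_nb < lat_here - 1e-9))


# --- unipolar synthesis -----------------------------------------------------


def _biphasic_shape(t_rel: np.ndarray, local_ctx: float) -> np.ndarray:
    """Unit-free biphasic template: R lobe weight = local_ctx, S = 1-local_ctx."""
    s = TEMPLATE_SIGMA_MS
    d = TEMPLATE_LOBE_OFFSET_MS
    g = lambda u: np.exp(-0.5 * (u / s) ** 2)
    return local_ctx * g(t_rel + d) - (1.0 - local_ctx) * g(t_rel - d)


@lru_cache(maxsize=4096)
def _shape_pp_cached(ctx_key: int) -> float:
    t = np.arange(-15.0, 15.0, 0.02)
    v = _biphasic_shape(t, ctx_key / 10000.0)
    return float(v.max() - v.min())


def _shape_pp(local_ctx: float) -> float:
    return _shape_pp_cached(int(round(local_ctx * 10000)))


def _farfield_shape(t_rel: np.ndarray) -> np.ndarray:
    s = FARFIELD_SIGMA_MS
    v = -(t_rel / s) * np.exp(-0.5 * (t_rel / s) ** 2)
    return v / (2 * np.exp(-0.5))  # normalized to unit peak-to-peak


def synthesize_unipolar(
    lat_at_electrode: float | Sequence[float],
    local_ctx: float | Sequence[float],
    amplitude_mv: float | Sequence[float],
    *,
    n_samples: int,
    sample_rate_hz: float,
    t_start_ms: float = 0.0,
    noise_sd_mv: float = 0.0,
    ventricular_period_ms: float = np.inf,
    ventricular_amplitude_mv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize one unipolar voltage trace (mV).

    One biphasic deflection per entry of ``lat_at_electrode`` (ms, absolute
    session time), peak-to-peak normalized to ``amplitude_mv``, with the
    positive (R) lobe weighted by ``local_ctx`` and the negative (S) lobe by
    ``1 - local_ctx`` — a focal-origin electrode (``local_ctx = 0``) yields
    a QS complex.  A wide low-frequency ventricular far-field template is
    superposed every ``ventricular_period_ms`` starting at session time 0,
    and white noise of sd ``noise_sd_mv`` is added when an ``rng`` is given.
    """
    lats = np.atleast_1d(np.asarray(lat_at_electrode, dtype=float))
    ctxs = np.broadcast_to(np.atleast_1d(np.asarray(local_ctx, float)), lats.shape)
    amps = np.broadcast_to(np.atleast_1d(np.asarray(amplitude_mv, float)), lats.shape)
    if np.any((ctxs < 0) | (ctxs > 1)):
        raise ValueError("local context must lie in [0, 1]")
    if np.any(amps <= 0):
        raise ValueError("amplitude must be positive")
    dt = 1000.0 / sample_rate_hz
    t = t_start_ms + np.arange(n_samples) * dt
    trace = np.zeros(n_samples)
    half_support = 6 * TEMPLATE_SIGMA_MS + TEMPLATE_LOBE_OFFSET_MS
    for lat, ctx, amp in zip(lats, ctxs, amps):
        lo = np.searchsorted(t, lat - half_support)
        hi = np.searchsorted(t, lat + half_support)
        if hi <= lo:
            continue
        trace[lo:hi] += (amp / _shape_pp(ctx)) * _biphasic_shape(t[lo:hi] - lat, ctx)
    if ventricular_amplitude_mv > 0 and np.isfinite(ventricular_period_ms):
        v_half = 5 * FARFIELD_SIGMA_MS
        k0 = int(np.floor((t[0] - v_half) / ventricular_period_ms))
        k1 = int(np.ceil((t[-1] + v_half) / ventricular_period_ms))
        for k in range(max(k0, 0), k1 + 1):
            vt = k * ventricular_period_ms
            lo = np.searchsorted(t, vt - v_half)
            hi = np.searchsorted(t, vt + v_half)
            if hi > lo:
                trace[lo:hi] += ventricular_amplitude_mv * _farfield_shape(
                    t[lo:hi] - vt
                )
    if noise_sd_mv > 0 and rng is not None:
        trace = trace + rng.normal(0.0, noise_sd_mv, n_samples)
    return trace


# --- grid catheter ----------------------------------------------------------


@dataclass(frozen=True)
class GridPose:
    """One placement of the 4x4 grid catheter on the sheet.

    Electrode positions are in chamber (sheet) coordinates; rows A-D run
    along the local +y axis, columns 1-4 along local +x, rotated by
    ``rotation_deg`` about the pose center.
    """

    center: tuple[float, float]
    rotation_deg: float = 0.0
    pitch_cm: float = GRID_PITCH_CM

    @property
    def electrode_positions(self) -> np.ndarray:
        offs = (np.arange(4) - 1.5) * self.pitch_cm
        local = np.array([[offs[c], offs[r]] for r in range(4) for c in range(4)])
        a = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return np.asarray(self.center, dtype=float) + local @ rot.T

    @property
    def labels(self) -> tuple[str, ...]:
        return GRID_LABELS

    def validate(self, geom: SheetGeometry) -> None:
        if not np.all(geom.contains(self.electrode_positions)):
            raise ValueError(
                f"grid pose at {self.center} (rot {self.rotation_deg} deg) "
                "places electrodes outside the sheet"
            )


# --- recording session ------------------------------------------------------


@dataclass
class RecordingSession:
    """Posed grid-catheter unipolar recordings plus appendage channels.

    ``signals[i]`` is an (n_samples, 16) array of mV traces for pose ``i``
    (columns ordered as :data:`GRID_LABELS`); pose ``i`` occupies session
    time ``[pose_start_ms[i], pose_start_ms[i] + dwell_s[i]*1000)``.
    Appendage channels span the whole session.
    """

    sample_rate_hz: float
    geometry: SheetGeometry
    spec: SourceSpec | None
    poses: list[GridPose]
    dwell_s: list[float]
    signals: list[np.ndarray]
    ventricular_period_ms: float
    ventricular_amplitude_mv: float
    noise_sd_mv: float
    seed: int
    appendage_positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    appendage_signals: dict[str, np.ndarray] = field(default_factory=dict)
    fields: list[ActivationField] | None = None

    @property
    def pose_start_ms(self) -> list[float]:
        starts = [0.0]
        for d in self.dwell_s[:-1]:
            starts.append(starts[-1] + d * 1000.0)
        return starts

    @property
    def duration_ms(self) -> float:
        return sum(self.dwell_s) * 1000.0

    def pose_time_axis(self, pose_index: int) -> np.ndarray:
        n = self.signals[pose_index].shape[0]
        dt = 1000.0 / self.sample_rate_hz
        return self.pose_start_ms[pose_index] + np.arange(n) * dt

    def reference_bipolar(self, pose_index: int) -> np.ndarray:
        """B2 - C2 bipolar reference signal for one pose (mV)."""
        s = self.signals[pose_index]
        return s[:, B2_INDEX] - s[:, C2_INDEX]

    def ventricular_event_times(self) -> np.ndarray:
        if not np.isfinite(self.ventricular_period_ms) or (
            self.ventricular_amplitude_mv <= 0
        ):
            return np.array([])
        n = int(self.duration_ms // self.ventricular_period_ms) + 1
        return np.arange(n) * self.ventricular_period_ms


def simulate_session(
    spec: SourceSpec,
    geom: SheetGeometry,
    itinerary: Sequence[GridPose],
    dwell_s: float | Sequence[float],
    *,
    sample_rate_hz: float = 1000.0,
    noise_sd_mv: float = 0.02,
    ventricular_period_ms: float = 800.0,
    ventricular_amplitude_mv: float = 0.5,
    seed: int = 0,
    appendage_positions: dict[str, tuple[float, float]] | None = None,
) -> RecordingSession:
    """Simulate a full mapping session over an itinerary of grid poses.

    Each pose records all 16 electrodes for its dwell time; the activation
    series runs continuously under the moving catheter.  Appendage channels
    (default LAA/RAA corners of the sheet) record for the whole session for
    AF-cycle-length estimation.  Deterministic under a fixed ``seed``.
    """
    dwells = (
        [float(dwell_s)] * len(itinerary)
        if np.isscalar(dwell_s)
        else [float(d) for d in dwell_s]
    )
    if len(dwells) != len(itinerary):
        raise ValueError("itinerary and dwell list lengths differ")
    for i, (pose, d) in enumerate(zip(itinerary, dwells)):
        if d * 1000.0 < 3 * spec.cycle_length:
            raise ValueError("dwell must cover at least three cycle lengths")
        try:
            pose.validate(geom)
        except ValueError as exc:
            raise ValueError(f"pose {i}: {exc}") from exc
    if appendage_positions is None:
        appendage_positions = {
            "LAA": (0.6, geom.height - 0.6),
            "RAA": (geom.width - 0.6, geom.height - 0.6),
        }

    rng = np.random.default_rng(seed)
    duration_ms = sum(dwells) * 1000.0
    fields = generate_activation_series(spec, geom, duration_ms, rng)

    # pre-interpolate every field's LAT at every electrode position once
    app_names = list(appendage_positions)
    all_pos = np.vstack(
        [pose.electrode_positions for pose in itinerary]
        + [[appendage_positions[n] for n in app_names]]
        if app_names
        else [pose.electrode_positions for pose in itinerary]
    )
    lat_matrix = np.array([geom.bilinear(f.lat, all_pos) for f in fields])

    def _trace(pos_idx: int, t0: float, n: int) -> np.ndarray:
        pos = all_pos[pos_idx]
        t1 = t0 + n * 1000.0 / sample_rate_hz
        lats, ctxs = [], []
        for fi, f in enumerate(fields):
            lat_e = float(lat_matrix[fi, pos_idx])
            if t0 - 50.0 <= lat_e <= t1 + 50.0:
                lats.append(lat_e)
                ctxs.append(local_context(f, geom, pos))
        amp = float(spec.amplitude_at(pos[None, :])[0])
        return synthesize_unipolar(
            lats if lats else [],
            ctxs if ctxs else 0.5,
            amp,
            n_samples=n,
            sample_rate_hz=sample_rate_hz,
            t_start_ms=t0,
            noise_sd_mv=noise_sd_mv,
            ventricular_period_ms=ventricular_period_ms,
            ventricular_amplitude_mv=ventricular_amplitude_mv,
            rng=rng,
        )

    signals = []
    t0 = 0.0
    for pi, (pose, d) in enumerate(zip(itinerary, dwells)):
        n = int(round(d * sample_rate_hz))
        traces = np.column_stack(
            [_trace(pi * 16 + k, t0, n) for k in range(16)]
        )
        signals.append(traces)
        t0 += d * 1000.0

    n_total = int(round(duration_ms * sample_rate_hz / 1000.0))
    n_grid = 16 * len(itinerary)
    app_signals = {
        name: _trace(n_grid + j, 0.0, n_total) for j, name in enumerate(app_names)
    }

    return RecordingSession(
        sample_rate_hz=sample_rate_hz,
        geometry=geom,
        spec=spec,
        poses=list(itinerary),
        dwell_s=dwells,
        signals=signals,
        ventricular_period_ms=ventricular_period_ms,
        ventricular_amplitude_mv=ventricular_amplitude_mv,
        noise_sd_mv=noise_sd_mv,
        seed=seed,
        appendage_positions=dict(appendage_positions),
        appendage_signals=app_signals,
        fields=fields,
    )


# --- canonical study scenarios ----------------------------------------------

DEFAULT_GEOMETRY = SheetGeometry()

#: margin keeping any rotated grid pose fully on the sheet (half diagonal of
#: the 0.9 cm electrode square plus a little slack).
POSE_MARGIN_CM = 0.7


def segment_center_itinerary(
    geom: SheetGeometry = DEFAULT_GEOMETRY, cols: int = 6, rows: int = 3
) -> list[GridPose]:
    """One pose per chamber segment (6x3 tiling), rotations cycled for realism."""
    poses = []
    i = 0
    for r in range(rows):
        for c in range(cols):
            cx = (c + 0.5) * geom.width / cols
            cy = (r + 0.5) * geom.height / rows
            cx = float(np.clip(cx, POSE_MARGIN_CM, geom.width - POSE_MARGIN_CM))
            cy = float(np.clip(cy, POSE_MARGIN_CM, geom.height - POSE_MARGIN_CM))
            poses.append(GridPose(center=(cx, cy), rotation_deg=(i * 20.0) % 90.0))
            i += 1
    return poses


def dense_itinerary(
    geom: SheetGeometry = DEFAULT_GEOMETRY, cols: int = 9, rows: int = 5
) -> list[GridPose]:
    """Overlapping pose tiling emulating continuous chamber-wide acquisition.

    Pose centers are spaced closely enough (~0.6 cm) that the clique
    footprints of neighbouring poses overlap, leaving no coverage gaps;
    rotations are cycled so no single catheter orientation dominates.
    """
    xs = np.linspace(POSE_MARGIN_CM, geom.width - POSE_MARGIN_CM, cols)
    ys = np.linspace(POSE_MARGIN_CM, geom.height - POSE_MARGIN_CM, rows)
    poses = []
    i = 0
    for cy in ys:
        for cx in xs:
            poses.append(
                GridPose(center=(float(cx), float(cy)), rotation_deg=(i * 20.0) % 90.0)
            )
            i += 1
    return poses


def scenario_spec(kind: str, *, angle_deg: float = 30.0) -> SourceSpec:
    """Canonical source specifications used throughout tests and examples."""
    if kind == "focal":
        return SourceSpec(kind="focal", center=(3.0, 2.0))
    if kind == "planar":
        return SourceSpec(kind="planar", planar_angle=angle_deg)
    if kind == "rotor":
        return SourceSpec(kind="rotor", center=(3.0, 2.0))
    if kind == "chaotic":
        return SourceSpec(kind="chaotic", n_wavelets=4)
    raise ValueError(f"unknown scenario kind {kind!r}")


def simulate_scenario(
    kind: str,
    seed: int,
    *,
    geom: SheetGeometry = DEFAULT_GEOMETRY,
    angle_deg: float = 30.0,
    dwell_s: float = 0.6,
) -> RecordingSession:
    """Simulate a canonical dense-coverage mapping session of the pattern."""
    return simulate_session(
        scenario_spec(kind, angle_deg=angle_deg),
        geom,
        dense_itinerary(geom),
        dwell_s,
        seed=seed,
    )
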