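"""Chamber vector maps: duplicate resolution and the 18-segment partition.

Accepted vectors from every pose and beat are pooled into one chamber map.
Where the catheter revisits a site, near-coincident vectors from different
poses are reduced to the most trustworthy one (highest certainty, then
higher voltage, then earlier beat); per-beat vectors from a single pose are
kept, as each beat contributes an independent sample of local propagation.
The chamber is tiled into 18 equal rectangular segments (6 columns x 3 rows
on the default sheet) for the organization classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .omnipolar import OmniVector
from .sim_atrium import SheetGeometry


@dataclass(frozen=True)
class SegmentPartition:
    """Equal-area rectangular tiling of the sheet, row-major ids 1..n."""

    geometry: SheetGeometry
    n_cols: int
    n_rows: int

    @property
    def n_segments(self) -> int:
        return self.n_cols * self.n_rows

    def segment_of(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = self.geometry
        cx = np.clip(
            (pts[:, 0] / g.width * self.n_cols).astype(int), 0, self.n_cols - 1
        )
        cy = np.clip(
            (pts[:, 1] / g.height * self.n_rows).astype(int), 0, self.n_rows - 1
        )
        return cy * self.n_cols + cx + 1

    def segment_bounds(self, segment_id: int) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of one segment tile."""
        g = self.geometry
        i = segment_id - 1
        r, c = divmod(i, self.n_cols)
        w = g.width / self.n_cols
        h = g.height / self.n_rows
        return (c * w, r * h, (c + 1) * w, (r + 1) * h)


def partition_chamber(
    geometry: SheetGeometry, n_segments: int = 18
) -> SegmentPartition:
    """Partition the chamber into ``n_segments`` equal rectangles.

    The cols x rows factorization closest to the sheet aspect ratio is
    chosen (6 x 3 for 18 segments on the default 6 x 4 cm sheet).
    """
    if n_segments <= 0:
        raise ValueError("n_segments must be positive")
    aspect = geometry.width / geometry.height
    best = None
    for rows in range(1, n_segments + 1):
        if n_segments % rows:
            continue
        cols = n_segments // rows
        score = abs(np.log((cols / rows) / aspect))
        if best is None or score < best[0]:
            best = (score, cols, rows)
    _, cols, rows = best
    return SegmentPartition(geometry=geometry, n_cols=cols, n_rows=rows)


@dataclass(frozen=True)
class DuplicatePolicy:
    """Spatial merge rule for revisited sites (different poses only)."""

    radius_cm: float = 0.1
    criterion: str = "highest_certainty_then_vpp"

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("radius must be positive")


@dataclass
class VectorMap:
    """Chamber-wide collection of accepted omnipolar vectors."""

    vectors: list[OmniVector]
    geometry: SheetGeometry
    partition: SegmentPartition
    map_label: str = ""

    @property
    def used_point_count(self) -> int:
        return len(self.vectors)

    # vectors are fixed once assembled, so the arrays are computed lazily once
    @cached_property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.vectors]).reshape(-1, 2)

    @cached_property
    def directions(self) -> np.ndarray:
        return np.array([v.direction for v in self.vectors]).reshape(-1, 2)

    def segment_ids(self) -> np.ndarray:
        return self.partition.segment_of(self.positions)

    def segment_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.segment_ids(), return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pose_index": [v.pose_index for v in self.vectors],
                "beat_index": [v.beat_index for v in self.vectors],
                "x_cm": self.positions[:, 0],
                "y_cm": self.positions[:, 1],
                "dir_x": self.directions[:, 0],
                "dir_y": self.directions[:, 1],
                "speed_m_s": [v.speed_m_s for v in self.vectors],
                "certainty": [v.certainty for v in self.vectors],
                "vpp_mv": [v.vpp_mv for v in self.vectors],
            }
        )


def assemble(
    vectors: list[OmniVector],
    policy: DuplicatePolicy = DuplicatePolicy(),
    geometry: SheetGeometry | None = None,
    partition: SegmentPartition | None = None,
    map_label: str = "",
) -> VectorMap:
    """Assemble accepted vectors into a chamber map with duplicate resolution.

    Vectors within ``policy.radius_cm`` of a better vector *from a different
    pose* are dropped; priority is certainty, then peak-to-peak voltage,
    then earlier beat (then pose and position, for determinism).  The
    procedure is idempotent and invariant to input order.
    """
    vecs = [v for v in vectors if v.accepted and v.direction is not None]
    if not vecs:
        raise ValueError("empty map: no accepted vectors to assemble")
    if geometry is None:
        from .sim_atrium import DEFAULT_GEOMETRY

        geometry = DEFAULT_GEOMETRY
    if partition is None:
        partition = partition_chamber(geometry)

    pos = np.array([v.position for v in vecs])
    if not np.all(geometry.contains(pos)):
        raise ValueError("vector positions outside chamber geometry")
    order = sorted(
        range(len(vecs)),
        key=lambda i: (
            -vecs[i].certainty,
            -vecs[i].vpp_mv,
            vecs[i].beat_index,
            vecs[i].pose_index,
            vecs[i].position[0],
            vecs[i].position[1],
        ),
    )
    tree = cKDTree(pos)
    kept_mask = np.zeros(len(vecs), dtype=bool)
    for i in order:
        neighbors = tree.query_ball_point(pos[i], policy.radius_cm)
        clash = any(
            kept_mask[j] and vecs[j].pose_index != vecs[i].pose_index
            for j in neighbors
            if j != i
        )
        if not clash:
            kept_mask[i] = True
    kept = [vecs[i] for i in range(len(vecs)) if kept_mask[i]]
    return VectorMap(
        vectors=kept, geometry=geometry, partition=partition, map_label=map_label
    )
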