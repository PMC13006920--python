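"""Focal Vector Score, organization, concordance, QS morphology."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from arvmap.af_metrics import (
    AnalysisConfig,
    classify_organization,
    classify_vector_radial,
    compute_fvs,
    concordance,
    detect_focal_sources,
    qs_pattern,
    score_sector,
)
from arvmap.sim_atrium import synthesize_unipolar
from conftest import radial_ring_points

CENTER = np.array([3.0, 2.0])


def rotate(points, directions, angle_deg, about):
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return (points - about) @ R.T + about, directions @ R.T


class TestRadialClassification:
    @pytest.mark.parametrize(
        "direction_angle,expected",
        [
            (0.0, "centrifugal"),      # exactly outward
            (45.0, "centrifugal"),     # inclusive boundary
            (46.0, "perpendicular"),
            (90.0, "perpendicular"),
            (134.0, "perpendicular"),
            (135.0, "centripetal"),    # inclusive boundary
            (180.0, "centripetal"),    # exactly inward
        ],
    )
    def test_cone_boundaries(self, direction_angle, expected):
        pos = CENTER + [0.3, 0.0]  # outward radial points along +x
        a = np.deg2rad(direction_angle)
        d = np.array([np.cos(a), np.sin(a)])
        assert classify_vector_radial(pos, d, CENTER) == expected

    def test_vector_at_center_is_perpendicular_with_warning(self):
        with pytest.warns(UserWarning):
            out = classify_vector_radial(CENTER, np.array([1.0, 0.0]), CENTER)
        assert out == "perpendicular"


class TestScoreSector:
    def test_seventy_percent_centrifugal_scores_plus_one(self):
        assert score_sector(["centrifugal"] * 7 + ["centripetal"] * 3) == 1

    def test_sixty_percent_exactly_scores_zero(self):
        assert score_sector(["centrifugal"] * 6 + ["perpendicular"] * 4) == 0

    def test_bidirectional_scores_zero(self):
        assert score_sector(["centrifugal"] * 5 + ["centripetal"] * 5) == 0

    def test_centripetal_majority_scores_minus_one(self):
        assert score_sector(["centripetal"] * 7 + ["centrifugal"] * 3) == -1

    def test_empty_sector_scores_zero(self):
        assert score_sector([]) == 0


class TestComputeFvs:
    def test_ideal_radial_field_scores_eight(self, make_map):
        pos, dirs = radial_ring_points(CENTER, [0.15, 0.25, 0.35])
        cand = compute_fvs(make_map(pos, dirs), CENTER)
        assert cand.sector_scores == (1,) * 8
        assert cand.fvs == 8 and cand.accepted

    def test_reversed_field_scores_minus_eight(self, make_map):
        pos, dirs = radial_ring_points(CENTER, [0.15, 0.25, 0.35])
        cand = compute_fvs(make_map(pos, -dirs), CENTER)
        assert cand.fvs == -8 and not cand.accepted

    def test_plane_wave_roi_scores_near_zero(self, make_map):
        pos, _ = radial_ring_points(CENTER, [0.12, 0.2, 0.28, 0.36], n_per_ring=32)
        dirs = np.tile([np.cos(0.6), np.sin(0.6)], (len(pos), 1))
        cand = compute_fvs(make_map(pos, dirs), CENTER)
        assert abs(cand.fvs) <= 1 and not cand.accepted

    def test_fvs_exactly_three_accepted(self, make_map):
        """Three centrifugal sectors, five perpendicular: cumulative score 3."""
        pos, dirs = radial_ring_points(CENTER, [0.15, 0.3])
        angles = np.degrees(np.arctan2(pos[:, 1] - 2.0, pos[:, 0] - 3.0)) % 360
        dirs = dirs.copy()
        tang = angles >= 135.0  # sectors 4..8 become tangential
        dirs[tang] = dirs[tang] @ np.array([[0.0, 1.0], [-1.0, 0.0]])
        cand = compute_fvs(make_map(pos, dirs), CENTER)
        assert cand.sector_scores == (1, 1, 1, 0, 0, 0, 0, 0)
        assert cand.fvs == 3 and cand.accepted

    def test_sparse_roi_flagged_low_support(self, make_map):
        pos, dirs = radial_ring_points(CENTER, [0.2], n_per_ring=6)
        cand = compute_fvs(make_map(pos, dirs), CENTER)
        assert cand.low_support and not cand.accepted

    def test_one_sided_coverage_not_accepted(self, make_map):
        """Half-plane coverage cannot witness a centrifugal pattern."""
        pos, dirs = radial_ring_points(CENTER, [0.15, 0.25, 0.35])
        keep = pos[:, 0] >= CENTER[0]
        cand = compute_fvs(make_map(pos[keep], dirs[keep]), CENTER)
        assert cand.low_support and not cand.accepted

    @pytest.mark.parametrize("angle", [30.0, 117.0, 245.0])
    def test_rotation_invariance_of_radial_fvs(self, make_map, angle):
        pos, dirs = radial_ring_points(CENTER, [0.15, 0.25, 0.35])
        rp, rd = rotate(pos, dirs, angle, CENTER)
        assert compute_fvs(make_map(rp, rd), CENTER).fvs == 8

    @given(seed=st.integers(0, 200))
    def test_fvs_bounds_and_sign_antisymmetry(self, geom, make_map, seed):
        rng = np.random.default_rng(seed)
        n = 48
        pos = CENTER + rng.uniform(-0.38, 0.38, (n, 2))
        pos = pos[geom.contains(pos)]
        ang = rng.uniform(0, 2 * np.pi, len(pos))
        dirs = np.column_stack([np.cos(ang), np.sin(ang)])
        fwd = compute_fvs(make_map(pos, dirs), CENTER)
        rev = compute_fvs(make_map(pos, -dirs), CENTER)
        assert -8 <= fwd.fvs <= 8
        assert rev.fvs == -fwd.fvs


class TestDetectFocalSources:
    def test_single_radial_source_found_once(self, make_map):
        pos, dirs = radial_ring_points(CENTER, [0.1, 0.2, 0.3, 0.38], n_per_ring=30)
        found = detect_focal_sources(make_map(pos, dirs))
        assert len(found) == 1
        assert np.hypot(found[0].center[0] - 3.0, found[0].center[1] - 2.0) <= 0.5

    def test_plane_wave_map_yields_no_sources(self, geom, make_map):
        xs, ys = np.meshgrid(np.arange(0.5, 5.6, 0.15), np.arange(0.5, 3.6, 0.15))
        pos = np.column_stack([xs.ravel(), ys.ravel()])
        dirs = np.tile([0.8, 0.6], (len(pos), 1))
        assert detect_focal_sources(make_map(pos, dirs)) == []

    def test_two_sources_three_cm_apart_both_found(self, make_map):
        c1, c2 = np.array([1.5, 2.0]), np.array([4.5, 2.0])
        p1, d1 = radial_ring_points(c1, [0.1, 0.2, 0.3], n_per_ring=24)
        p2, d2 = radial_ring_points(c2, [0.1, 0.2, 0.3], n_per_ring=24)
        found = detect_focal_sources(
            make_map(np.vstack([p1, p2]), np.vstack([d1, d2]))
        )
        assert len(found) == 2
        centers = sorted(f.center for f in found)
        assert np.hypot(centers[0][0] - 1.5, centers[0][1] - 2.0) <= 0.5
        assert np.hypot(centers[1][0] - 4.5, centers[1][1] - 2.0) <= 0.5

    def test_threshold_above_eight_never_accepts(self, make_map):
        pos, dirs = radial_ring_points(CENTER, [0.1, 0.2, 0.3, 0.38], n_per_ring=30)
        cfg = AnalysisConfig(fvs_threshold=9)
        assert detect_focal_sources(make_map(pos, dirs), cfg) == []


class TestOrganization:
    def grid_map(self, make_map, direction_fn, n=40):
        rng = np.random.default_rng(7)
        pos = np.column_stack(
            [rng.uniform(0.05, 5.95, 18 * n), rng.uniform(0.05, 3.95, 18 * n)]
        )
        dirs = direction_fn(pos, rng)
        return make_map(pos, dirs)

    def test_uniform_direction_fully_organized(self, make_map):
        vmap = self.grid_map(make_map, lambda p, r: np.tile([1.0, 0.0], (len(p), 1)))
        org = classify_organization(vmap)
        assert org.n_organized == 18 and org.chamber_class == "organized"
        assert all(s.coherent_fraction == 1.0 for s in org.per_segment)

    def test_random_directions_disorganized(self, make_map):
        """Circular-uniform directions leave ~25% within any 45-degree cone."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 7200
            pos = np.column_stack(
                [rng.uniform(0.05, 5.95, n), rng.uniform(0.05, 3.95, n)]
            )
            ang = rng.uniform(0, 2 * np.pi, n)
            dirs = np.column_stack([np.cos(ang), np.sin(ang)])
            org = classify_organization(make_map(pos, dirs))
            assert org.chamber_class == "disorganized"
            fracs += [s.coherent_fraction for s in org.per_segment if not s.low_support]
        # fractions hug 25% (the 90/360 cone) up to the sample-mean fit bias
        assert np.mean(fracs) == pytest.approx(0.25, abs=0.04)

    def test_chamber_boundary_thirteen_of_eighteen(self, make_map):
        """12 organized segments is disorganized; 13 is organized."""
        part = None
        for n_coherent in (12, 13):
            rng = np.random.default_rng(3)
            pos_list, dir_list = [], []
            for seg in range(18):
                col, row = seg % 6, seg // 6
                cx, cy = col + 0.5, (row + 0.5) * 4.0 / 3.0
                p = np.column_stack(
                    [rng.uniform(cx - 0.4, cx + 0.4, 20),
                     rng.uniform(cy - 0.5, cy + 0.5, 20)]
                )
                if seg < n_coherent:
                    d = np.tile([1.0, 0.0], (20, 1))
                else:
                    ang = rng.uniform(0, 2 * np.pi, 20)
                    d = np.column_stack([np.cos(ang), np.sin(ang)])
                pos_list.append(p)
                dir_list.append(d)
            vmap = make_map(np.vstack(pos_list), np.vstack(dir_list))
            org = classify_organization(vmap)
            assert org.n_organized == n_coherent
            expected = "disorganized" if n_coherent == 12 else "organized"
            assert org.chamber_class == expected

    def test_sparse_segments_count_as_not_organized(self, make_map):
        pos = np.array([[0.5, 0.5], [0.6, 0.5], [3.0, 2.0]])
        dirs = np.tile([1.0, 0.0], (3, 1))
        org = classify_organization(make_map(pos, dirs))
        assert org.n_organized == 0
        assert all(s.low_support for s in org.per_segment if s.n_vectors)

    def test_organization_invariant_under_half_turn(self, make_map):
        rng = np.random.default_rng(5)
        pos = np.column_stack(
            [rng.uniform(0.05, 5.95, 1440), rng.uniform(0.05, 3.95, 1440)]
        )
        ang = rng.normal(0.4, 0.5, 1440)
        dirs = np.column_stack([np.cos(ang), np.sin(ang)])
        a = classify_organization(make_map(pos, dirs))
        rp, rd = rotate(pos, dirs, 180.0, np.array([3.0, 2.0]))
        rp = np.clip(rp, [0.0, 0.0], [6.0 - 1e-9, 4.0 - 1e-9])
        b = classify_organization(make_map(rp, rd))
        assert a.n_organized == b.n_organized
        assert a.chamber_class == b.chamber_class


class TestConcordance:
    def test_map_against_itself_is_perfectly_concordant(self, focal_result):
        c = concordance(focal_result["map"], focal_result["map"])
        assert c.percent == 100.0 and c.reproducibility_class == "high"

    def test_reversed_directions_zero_concordance(self, focal_result, make_map):
        vmap = focal_result["map"]
        rev = make_map(vmap.positions, -vmap.directions)
        c = concordance(vmap, rev)
        assert c.percent == 0.0 and c.reproducibility_class == "low"

    @pytest.mark.parametrize(
        "n_concordant,expected",
        [(2, "low"), (3, "moderate"), (7, "moderate"), (8, "high")],
    )
    def test_printed_class_boundaries(self, make_map, n_concordant, expected):
        """30% and 70% belong to moderate; high requires strictly above 70."""
        pos = np.column_stack([np.linspace(1, 5, 10), np.full(10, 2.0)])
        dirs_a = np.tile([1.0, 0.0], (10, 1))
        dirs_b = dirs_a.copy()
        dirs_b[n_concordant:] = [-1.0, 0.0]
        c = concordance(make_map(pos, dirs_a), make_map(pos, dirs_b))
        assert c.percent == pytest.approx(10.0 * n_concordant)
        assert c.reproducibility_class == expected

    def test_directional_symmetry_on_dense_maps(self, make_map):
        rng = np.random.default_rng(9)
        pos_a = np.column_stack(
            [rng.uniform(0.3, 5.7, 800), rng.uniform(0.3, 3.7, 800)]
        )
        pos_b = pos_a + rng.normal(0, 0.03, pos_a.shape)
        pos_b = np.clip(pos_b, [0.0, 0.0], [6.0 - 1e-9, 4.0 - 1e-9])
        ang_a = rng.uniform(0, 2 * np.pi, 800)
        ang_b = ang_a + rng.normal(0, 0.6, 800)
        a = make_map(pos_a, np.column_stack([np.cos(ang_a), np.sin(ang_a)]))
        b = make_map(pos_b, np.column_stack([np.cos(ang_b), np.sin(ang_b)]))
        assert abs(concordance(a, b).percent - concordance(b, a).percent) <= 5.0

    def test_disjoint_maps_raise(self, make_map):
        a = make_map(np.array([[1.0, 1.0]] * 3), np.tile([1, 0], (3, 1)))
        b = make_map(np.array([[5.0, 3.0]] * 3), np.tile([1, 0], (3, 1)))
        with pytest.raises(ValueError, match="overlap"):
            concordance(a, b)


class TestQsPattern:
    fs = 1000.0

    def trace(self, ctx):
        return synthesize_unipolar(
            100.0, ctx, 1.0, n_samples=200, sample_rate_hz=self.fs
        )

    def test_focal_origin_trace_is_qs(self):
        qs, r = qs_pattern(self.trace(0.0), (70.0, 130.0), self.fs)
        assert qs and r < 0.1

    def test_symmetric_biphasic_is_not_qs(self):
        qs, r = qs_pattern(self.trace(0.5), (70.0, 130.0), self.fs)
        assert not qs and r == pytest.approx(0.5, abs=0.05)

    def test_downstream_morphology_not_qs(self):
        qs, _ = qs_pattern(self.trace(0.45), (70.0, 130.0), self.fs)
        assert not qs

    def test_flat_trace_raises(self):
        with pytest.raises(ValueError, match="no deflection"):
            qs_pattern(np.zeros(200), (70.0, 130.0), self.fs)
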