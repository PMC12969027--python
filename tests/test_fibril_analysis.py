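"""Helix metrics, end-to-end distance, strain ratio, force profile, SASA."""

import math

import numpy as np
import pytest

from colcg import constants as C
from colcg.cg_mapping import Bead, CGTrajectory
from colcg.fibril_analysis import (
    DegenerateHelixError,
    FibrilSegmentation,
    assign_parity_by_density,
    bead_sasa,
    bond_force_profile,
    end_to_end,
    helix_metrics,
    radii_for_beads,
    segment_fibril,
    strain_ratio,
    track_boundaries,
)
from colcg.fixtures import HelixSpec, ToyFibrilSpec, build_toy_fibril, build_triple_helix

from conftest import random_rotation


def _beads_at(points, res="GLY"):
    beads = [Bead("BB", "A", "H1", i + 1, res) for i in range(len(points))]
    return CGTrajectory(beads=beads, frames=np.asarray(points, float)[None])


class TestEndToEnd:
    def test_single_bead_groups(self):
        traj = _beads_at([[0, 0, 0], [0, 0, 335.0]])
        d = end_to_end(traj, [0], [1])
        np.testing.assert_allclose(d, [335.0])

    def test_coincident_group_members_use_shared_point(self):
        traj = _beads_at([[1, 1, 0]] * 3 + [[1, 1, 9.0]] * 3)
        d = end_to_end(traj, [0, 1, 2], [3, 4, 5])
        np.testing.assert_allclose(d, [9.0])

    def test_affine_stretch_scales_distance_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((40, 3)) * 5
        traj = _beads_at(pts)
        stretched = _beads_at(pts * 1.02)
        a = end_to_end(traj, np.arange(5), np.arange(35, 40))
        b = end_to_end(stretched, np.arange(5), np.arange(35, 40))
        assert b[0] == pytest.approx(1.02 * a[0], rel=1e-12)

    def test_empty_selection_rejected(self):
        traj = _beads_at([[0, 0, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="non-empty"):
            end_to_end(traj, [], [1])


class TestHelixMetrics:
    def test_recovers_experimental_collagen_geometry(self):
        spec = HelixSpec(n_residues=30, rise_per_residue=0.290,
                         residues_per_turn=3.28)
        traj = build_triple_helix(spec)
        hm = helix_metrics(traj, "A")
        assert hm.summary()["rise_per_residue"] == pytest.approx(0.290, rel=0.01)
        assert hm.summary()["residues_per_turn"] == pytest.approx(3.28, rel=0.01)

    def test_recovers_generator_parameters_of_wide_helix(self):
        spec = HelixSpec(n_residues=25, rise_per_residue=0.1,
                         residues_per_turn=4.0, helix_radius=0.3)
        traj = build_triple_helix(spec)
        hm = helix_metrics(traj, "A")
        assert hm.summary()["rise_per_residue"] == pytest.approx(0.1, rel=0.01)
        assert hm.summary()["residues_per_turn"] == pytest.approx(4.0, rel=0.01)

    def test_left_handed_helix_same_residues_per_turn(self):
        spec = HelixSpec(n_residues=20, handedness=-1)
        hm = helix_metrics(build_triple_helix(spec), "A")
        assert hm.summary()["residues_per_turn"] == pytest.approx(3.28, rel=0.01)
        assert hm.summary()["twist_per_residue"] < 0

    def test_straight_chain_flagged_degenerate(self):
        spec = HelixSpec(n_residues=10, helix_radius=0.0)
        traj = build_triple_helix(spec)
        with pytest.raises(DegenerateHelixError):
            helix_metrics(traj, "A")

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(1)
        traj = build_triple_helix(HelixSpec(n_residues=20))
        R = random_rotation(rng)
        t = rng.standard_normal(3) * 10
        moved = CGTrajectory(beads=traj.beads, frames=traj.frames @ R.T + t)
        a = helix_metrics(traj, "A").summary()
        b = helix_metrics(moved, "A").summary()
        assert b["rise_per_residue"] == pytest.approx(a["rise_per_residue"], abs=1e-9)
        assert b["residues_per_turn"] == pytest.approx(a["residues_per_turn"], abs=1e-9)

    def test_sliding_windows_pool_local_estimates(self):
        traj = build_triple_helix(HelixSpec(n_residues=30))
        hm = helix_metrics(traj, "A", window=7)
        assert hm.rise_per_residue.size == 30 - 7 + 1
        assert hm.summary()["rise_per_residue"] == pytest.approx(0.290, rel=0.01)


class TestSegmentFibril:
    def test_ten_equal_boundaries_give_five_and_four(self):
        seg = segment_fibril(np.arange(10) * 33.5, first_segment="overlap")
        assert seg.segment_indices("overlap").size == 5
        assert seg.segment_indices("gap").size == 4

    def test_single_d_band(self):
        seg = segment_fibril([0.0, 67.0])
        assert seg.reference_lengths.tolist() == [67.0]

    def test_non_monotonic_boundaries_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            segment_fibril([0.0, 50.0, 40.0])

    def test_jittered_boundaries_match_subtraction_oracle(self):
        rng = np.random.default_rng(6)
        bounds = np.sort(rng.uniform(0, 300, 9))
        seg = segment_fibril(bounds)
        np.testing.assert_allclose(seg.reference_lengths, np.diff(bounds))

    def test_density_parity_heuristic_identifies_overlap(self):
        traj, seg, _ = build_toy_fibril(ToyFibrilSpec(), n_frames=1,
                                        overlap_strain=0.0, gap_strain=0.0)
        flipped = FibrilSegmentation(
            boundaries=seg.boundaries,
            labels=["gap" if l == "overlap" else "overlap" for l in seg.labels],
            frame_boundaries=seg.frame_boundaries,
        )
        fixed = assign_parity_by_density(flipped, traj)
        assert fixed.labels == seg.labels  # overlap is the denser parity


def _planted_segmentation(n_frames, over_elong, gap_elong, n_bounds=10, l0=33.5):
    """Segmentation whose per-frame boundary motion encodes planted
    per-segment elongations (overlap first)."""
    bounds = np.arange(n_bounds) * l0
    labels = ["overlap" if k % 2 == 0 else "gap" for k in range(n_bounds - 1)]
    elong = np.zeros((n_frames, n_bounds - 1))
    for k, lab in enumerate(labels):
        elong[:, k] = over_elong[:, labels[:k + 1].count("overlap") - 1] \
            if lab == "overlap" else gap_elong[:, labels[:k + 1].count("gap") - 1]
    fb = np.empty((n_frames, n_bounds))
    fb[:, 0] = 0.0
    fb[:, 1:] = bounds[None, 1:] + np.cumsum(elong, axis=1)
    return FibrilSegmentation(boundaries=bounds, labels=labels, frame_boundaries=fb)


class TestStrainRatio:
    def test_half_elongation_gives_exactly_half(self):
        n_frames = 4
        over = np.full((n_frames, 5), 1.0)
        gap = np.full((n_frames, 4), 2.0)
        over[0] = gap[0] = 0.0  # reference frame
        seg = _planted_segmentation(n_frames, over, gap)
        out = strain_ratio(seg)
        assert np.isnan(out.ratio[0])  # 0/0 at the reference frame
        np.testing.assert_allclose(out.ratio[1:], 0.5)

    def test_identical_elongations_give_unity_and_zero_sigma(self):
        over = np.full((3, 5), 1.5)
        gap = np.full((3, 4), 1.5)
        over[0] = gap[0] = 0.0
        seg = _planted_segmentation(3, over, gap)
        out = strain_ratio(seg)
        np.testing.assert_allclose(out.ratio[1:], 1.0)
        np.testing.assert_allclose(out.sigma_ratio[1:], 0.0, atol=1e-12)

    def test_sigma_matches_monte_carlo_resampling_oracle(self):
        rng = np.random.default_rng(12)
        over = np.vstack([np.zeros(5), 1.0 + 0.2 * rng.standard_normal(5)])
        gap = np.vstack([np.zeros(4), 2.0 + 0.3 * rng.standard_normal(4)])
        seg = _planted_segmentation(2, over, gap)
        out = strain_ratio(seg)

        # brute-force propagation: resample segment elongations from
        # N(mean, SEM) and take the SD of the ratio
        draws = 200000
        num = rng.normal(over[1].mean(), over[1].std(ddof=1) / math.sqrt(5), draws)
        den = rng.normal(gap[1].mean(), gap[1].std(ddof=1) / math.sqrt(4), draws)
        mc = (num / den).std()
        assert out.sigma_ratio[1] == pytest.approx(mc, rel=0.05)

    def test_scale_covariance(self):
        rng = np.random.default_rng(13)
        over = np.vstack([np.zeros(5), rng.uniform(0.5, 1.5, 5)])
        gap = np.vstack([np.zeros(4), rng.uniform(1.0, 3.0, 4)])
        a = strain_ratio(_planted_segmentation(2, over, gap))
        b = strain_ratio(_planted_segmentation(2, 3.0 * over, 3.0 * gap))
        assert b.ratio[1] == pytest.approx(a.ratio[1], rel=1e-12)

    def test_zero_gap_elongation_masked(self):
        over = np.vstack([np.zeros(5), np.ones(5)])
        gap = np.zeros((2, 4))
        seg = _planted_segmentation(2, over, gap)
        out = strain_ratio(seg)
        assert np.isnan(out.ratio).all()

    def test_toy_fibril_pipeline_through_marker_tracking(self):
        traj, seg, _ = build_toy_fibril(ToyFibrilSpec(), n_frames=5)
        tracked = track_boundaries(
            FibrilSegmentation(boundaries=seg.boundaries, labels=list(seg.labels)),
            traj,
        )
        out = strain_ratio(tracked)
        np.testing.assert_allclose(out.ratio[1:], 0.5, atol=1e-9)


class TestBondForceProfile:
    def test_equilibrium_bonds_give_zero_force(self):
        traj, seg, topo = build_toy_fibril(ToyFibrilSpec(length=67.0), n_frames=1,
                                           overlap_strain=0.0, gap_strain=0.0)
        prof = bond_force_profile(traj, topo, n_bins=50)
        np.testing.assert_allclose(np.nan_to_num(prof.mean_force), 0.0, atol=1e-9)

    def test_unit_conversion_one_bond(self):
        beads = [Bead("BB", "A", "H1", 1, "GLY"), Bead("BB", "A", "H1", 2, "GLY")]
        traj = CGTrajectory(beads=beads,
                            frames=np.array([[[0, 0, 0], [0, 0, 0.36]]]))
        from colcg.boltzmann_inversion import BondedParameter
        from colcg.topology_builder import BeadEntry, Topology

        topo = Topology(
            "one_bond",
            [BeadEntry(1, "P2", "BB", "GLY"), BeadEntry(2, "P2", "BB", "GLY")],
            [BondedParameter("bond", (1, 2), 0.35, 18000.0)],
        )
        prof = bond_force_profile(traj, topo, n_bins=1)
        # F = 18000 * 0.01 kJ/mol/nm = 180 -> 298.9 pN
        assert prof.mean_force[0] == pytest.approx(180 * 1.66054, rel=1e-6)
        assert prof.mean_force[0] == pytest.approx(298.9, abs=0.05)

    def test_uniform_strain_profile_is_flat_and_matches_oracle(self):
        spec = ToyFibrilSpec(length=67.0)
        traj, _, topo = build_toy_fibril(spec, n_frames=2, overlap_strain=0.01,
                                         gap_strain=0.01)
        prof = bond_force_profile(traj, topo, n_bins=20)

        # brute-force per-bond oracle on the last frame
        forces = []
        xyz = traj.frames[-1]
        for b in topo.bonds:
            i, j = b.beads
            r = np.linalg.norm(xyz[j - 1] - xyz[i - 1])
            forces.append(b.force_constant * abs(r - b.eq_value) * C.PN_PER_KJ_MOL_NM)
        forces = np.asarray(forces)
        occupied = prof.count > 0
        # uniform affine strain => near-constant force within each spacing class
        assert prof.mean_force[occupied].max() <= forces.max() + 1e-9
        assert int(prof.count.sum()) == len(topo.bonds) * traj.n_frames

    def test_bond_count_conserved_across_bins(self):
        traj, _, topo = build_toy_fibril(ToyFibrilSpec(), n_frames=3)
        prof = bond_force_profile(traj, topo, n_bins=300)
        assert int(prof.count.sum()) == len(topo.bonds) * 3
        assert prof.bin_centers.size == 300


class TestBeadSasa:
    def test_single_sphere_area(self):
        total, per = bead_sasa(np.zeros((1, 3)), np.array([1.0]), probe=0.0)
        assert total == pytest.approx(4 * math.pi, rel=0.005)
        assert per[0] == total

    def test_distant_spheres_add_exactly(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        total, per = bead_sasa(coords, np.array([1.0, 1.0]), probe=0.2)
        single, _ = bead_sasa(np.zeros((1, 3)), np.array([1.0]), probe=0.2)
        assert total == pytest.approx(2 * single, rel=1e-12)

    def test_overlapping_spheres_match_mc_integration_oracle(self):
        coords = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        radii = np.array([1.0, 0.8])
        total, _ = bead_sasa(coords, radii, probe=0.0, n_points=4000)

        rng = np.random.default_rng(21)
        mc_total = 0.0
        n_mc = 200000
        for i in range(2):
            pts = rng.standard_normal((n_mc, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            pts = coords[i] + radii[i] * pts
            j = 1 - i
            exposed = np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            mc_total += 4 * math.pi * radii[i] ** 2 * exposed.mean()
        assert total == pytest.approx(mc_total, rel=0.01)

    def test_error_decreases_with_more_points(self):
        exact = 4 * math.pi
        errs = []
        for n in (60, 240, 960, 3840):
            total, _ = bead_sasa(np.zeros((1, 3)), np.array([1.0]), probe=0.0,
                                 n_points=n)
            errs.append(abs(total - exact))
        assert errs == sorted(errs, reverse=True) or errs[-1] < errs[0]

    def test_rotation_invariance_within_lattice_resolution(self):
        rng = np.random.default_rng(30)
        coords = rng.standard_normal((5, 3))
        radii = radii_for_beads(["P2", "SP1", "TC4", "P2", "TQ2p"])
        R = random_rotation(rng)
        a, _ = bead_sasa(coords, radii)
        b, _ = bead_sasa(coords @ R.T, radii)
        assert b == pytest.approx(a, rel=0.01)

    def test_translation_invariance_exact(self):
        rng = np.random.default_rng(31)
        coords = rng.standard_normal((4, 3))
        radii = np.full(4, 0.264)
        a, _ = bead_sasa(coords, radii)
        b, _ = bead_sasa(coords + 100.0, radii)
        assert b == pytest.approx(a, rel=1e-9)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            bead_sasa(np.zeros((1, 3)), np.array([-1.0]))
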