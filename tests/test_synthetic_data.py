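"""Generators must realize their stated ground truth exactly."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from fawps import (
    AffineTransform2D,
    CohortSpec,
    GroundTruthNeuronSpec,
    build_response_matrix,
    compute_osi,
    gen_cohort,
    gen_frame_stack,
    gen_label_volume,
    gen_landmark_pair,
    gen_response_tensor,
    gen_swc_neuron,
    kmeans_with_ch,
    segment_length_in_box,
)
from fawps.tuning_quantification import eval_model

from .conftest import make_spec


class TestResponseTensor:
    def test_noiseless_peak_equals_amplitude_for_all_directions(self):
        spec = make_spec(A=1.0, sf0=0.25, tf0=2.0, osi=0.0)
        t = gen_response_tensor(spec, noise_sd=0.0)
        # grid indices: tf=2 Hz is index 2, sf=0.25 cpd is index 2
        assert np.allclose(t.dff_max[2, 2, :, :], 1.0)

    def test_full_selectivity_zeroes_orthogonal_orientation(self):
        spec = make_spec(osi=1.0)  # pref horizontal: 90/270 suppressed
        t = gen_response_tensor(spec, noise_sd=0.0)
        vertical_idx = [i for i, d in enumerate(t.grid.directions) if d in (90.0, 270.0)]
        assert np.allclose(t.dff_max[:, :, vertical_idx, :], 0.0)

    def test_osi_target_realized_exactly_noiseless(self):
        for target in (0.0, 0.3, 0.72, 1.0):
            t = gen_response_tensor(make_spec(osi=target), noise_sd=0.0)
            osi = compute_osi(build_response_matrix(t))
            assert osi.osi == pytest.approx(target, abs=1e-12)

    def test_powerlaw_tilt_shifts_temporal_peak(self):
        # xi=0.5: at sf=0.5 the preferred TF moves to 2^1.5 = 2.83 Hz, so on
        # the grid the response at 4 Hz exceeds the response at 1 Hz
        spec = make_spec(A=1.0, sf0=0.25, tf0=2.0, xi=0.5)
        t = gen_response_tensor(spec, noise_sd=0.0)
        sf_idx = 3  # sf = 0.5 cpd
        tf_vals = {tf: t.dff_max[i, sf_idx, 0, 0] for i, tf in enumerate(t.grid.temporal_freqs)}
        assert tf_vals[4.0] > tf_vals[1.0]
        # brute-force agreement with the closed-form model
        expected = eval_model(0.5, 4.0, 1.0, 0.25, 2.0, 1.0, 1.0, 0.5)
        assert tf_vals[4.0] == pytest.approx(expected, rel=1e-12)

    def test_invalid_tuning_parameters_rejected(self):
        with pytest.raises(ValueError, match="invalid spec"):
            GroundTruthNeuronSpec(tuning_params=(-1.0, 0.25, 2.0, 1.0, 1.0, 0.0))
        with pytest.raises(ValueError, match="invalid spec"):
            GroundTruthNeuronSpec(tuning_params=(1.0, 0.25, 2.0, 1.0, 1.0, 0.0), osi_target=1.5)

    def test_same_seed_is_bit_identical(self):
        spec = make_spec(osi=0.4)
        a = gen_response_tensor(spec, noise_sd=2.0, seed=11)
        b = gen_response_tensor(spec, noise_sd=2.0, seed=11)
        assert np.array_equal(a.dff_max, b.dff_max)


class TestFrameStack:
    def test_zero_shifts_give_identical_frames(self):
        stack, truth = gen_frame_stack(5, np.zeros((5, 2), dtype=int), noise_sd=0.0)
        assert np.array_equal(truth, np.zeros((5, 2)))
        for f in stack[1:]:
            assert np.array_equal(f, stack[0])

    def test_planted_shift_stored_as_truth(self):
        sched = np.zeros((8, 2), dtype=int)
        sched[5] = (3, -2)
        _, truth = gen_frame_stack(8, sched, noise_sd=0.0)
        assert tuple(truth[5]) == (3, -2)

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        sched = rng.integers(-5, 6, size=(30, 2))
        a, ta = gen_frame_stack(30, sched, noise_sd=1.0, seed=7)
        b, tb = gen_frame_stack(30, sched, noise_sd=1.0, seed=7)
        assert np.array_equal(a, b) and np.array_equal(ta, tb)

    def test_oversized_shift_rejected(self):
        sched = np.zeros((3, 2), dtype=int)
        sched[1] = (40, 0)  # >= 64/4
        with pytest.raises(ValueError, match="¼ frame"):
            gen_frame_stack(3, sched)


class TestLabelVolume:
    def test_single_box_labels_everything(self):
        vol = gen_label_volume((4, 4, 4), 10.0, [(7, ((0, 0, 0), (40, 40, 40)))])
        assert np.all(vol.labels == 7)

    def test_abutting_boxes_half_open_ownership(self):
        vol = gen_label_volume(
            (2, 2, 4), 10.0,
            [(1, ((0, 0, 0), (20, 20, 20))), (2, ((20, 0, 0), (40, 20, 20)))],
        )
        assert np.all(vol.labels[:, :, :2] == 1)
        assert np.all(vol.labels[:, :, 2:] == 2)

    def test_box_voxel_count(self):
        vol = gen_label_volume((20, 20, 20), 10.0, [(3, ((0, 0, 0), (100, 100, 100)))])
        assert int((vol.labels == 3).sum()) == 1000

    def test_overlapping_boxes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_label_volume(
                (4, 4, 4), 10.0,
                [(1, ((0, 0, 0), (30, 30, 30))), (2, ((20, 0, 0), (40, 30, 30)))],
            )


class TestSwcNeuron:
    def test_straight_polyline_length(self, two_region_boxes):
        spec = make_spec(
            soma_xyz=(100.0, 500.0, 500.0),
            branch_plan=((np.array([[100.0, 500.0, 500.0], [900.0, 500.0, 500.0]]), 1),),
        )
        neuron, table = gen_swc_neuron(spec, node_spacing=5.0, region_boxes=two_region_boxes,
                                       id_to_acronym={1: "A", 2: "B"})
        assert table == pytest.approx({"A": 0.8})

    def test_soma_only_neuron_has_empty_table(self):
        neuron, table = gen_swc_neuron(make_spec(), node_spacing=5.0)
        assert table == {}
        assert len(neuron.nodes) == 1

    def test_boundary_crossing_split_half_half(self, two_region_boxes):
        spec = make_spec(
            soma_xyz=(0.0, 500.0, 500.0),
            branch_plan=((np.array([[0.0, 500.0, 500.0], [2000.0, 500.0, 500.0]]), 1),),
        )
        _, table = gen_swc_neuron(spec, node_spacing=7.0, region_boxes=two_region_boxes,
                                  id_to_acronym={1: "A", 2: "B"})
        assert table["A"] == pytest.approx(1.0)
        assert table["B"] == pytest.approx(1.0)

    def test_table_sums_to_total_polyline_length(self, two_region_boxes):
        rng = np.random.default_rng(3)
        wp = rng.uniform(50, 1950, size=(6, 3))
        wp[:, 1:] = rng.uniform(50, 950, size=(6, 2))
        soma = tuple(wp[0])
        spec = make_spec(soma_xyz=soma, branch_plan=((wp, 1),))
        _, table = gen_swc_neuron(spec, node_spacing=9.0, region_boxes=two_region_boxes,
                                  id_to_acronym={1: "A", 2: "B"})
        total_um = sum(np.linalg.norm(b - a) for a, b in zip(wp[:-1], wp[1:]))
        assert sum(table.values()) == pytest.approx(total_um / 1000.0, rel=1e-12)

    def test_resampling_preserves_geometry(self):
        spec = make_spec(
            soma_xyz=(0.0, 0.0, 0.0),
            branch_plan=((np.array([[0.0, 0.0, 0.0], [123.0, 45.0, 67.0]]), 1),),
        )
        for spacing in (3.0, 10.0, 50.0):
            neuron, _ = gen_swc_neuron(spec, node_spacing=spacing)
            xyz = neuron.nodes[["x", "y", "z"]].to_numpy()
            seglens = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            assert seglens.sum() == pytest.approx(np.linalg.norm([123.0, 45.0, 67.0]))


class TestSegmentClipping:
    def test_fully_inside(self):
        assert segment_length_in_box((1, 1, 1), (4, 1, 1), (0, 0, 0), (10, 10, 10)) == 3.0

    def test_fully_outside(self):
        assert segment_length_in_box((20, 1, 1), (30, 1, 1), (0, 0, 0), (10, 10, 10)) == 0.0

    def test_partial_overlap(self):
        assert segment_length_in_box((-5, 1, 1), (5, 1, 1), (0, 0, 0), (10, 10, 10)) == 5.0


class TestLandmarks:
    def test_identity_noiseless(self):
        P1, P2 = gen_landmark_pair(AffineTransform2D.identity(), 5, seed=1)
        assert np.allclose(P1, P2)

    def test_known_transform_applied_pointwise(self):
        th = np.deg2rad(30)
        t = AffineTransform2D(
            R=[[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]], T=[5.0, -3.0]
        )
        P1, P2 = gen_landmark_pair(t, 4, seed=2)
        assert np.allclose(P2, P1 @ t.R + t.T)

    def test_three_points_non_collinear(self):
        for seed in range(10):
            P1, _ = gen_landmark_pair(AffineTransform2D.identity(), 3, seed=seed)
            assert np.linalg.matrix_rank(P1 - P1.mean(axis=0), tol=1e-6) == 2


class TestCohort:
    def test_perfect_anti_ranking_gives_exact_minus_one(self):
        table, _ = gen_cohort(CohortSpec(n_neurons=12, planted_spearman=-1.0, seed=4))
        r = spearmanr(table["osi"], table["MOs"]).statistic
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_well_separated_centroids_recovered_by_kmeans(self):
        table, gt = gen_cohort(CohortSpec(n_neurons=38, seed=9))
        res = kmeans_with_ch(table[["r2", "osi"]].to_numpy(), seed=0)
        assert res.k == 3
        # label agreement up to permutation
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(gt["class_labels"], res.labels) > 0.9

    def test_same_seed_identical_tables(self):
        a, _ = gen_cohort(CohortSpec(seed=5))
        b, _ = gen_cohort(CohortSpec(seed=5))
        assert a.equals(b)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CohortSpec(n_neurons=1)
        with pytest.raises(ValueError):
            CohortSpec(planted_spearman=1.5)
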