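"""SWC IO and per-region axonal length quantification against analytic
clipping oracles."""

import io

import numpy as np
import pandas as pd
import pytest

from fawps import (
    NeuronReconstruction,
    ProjectionProfile,
    axon_length_by_region,
    define_targets,
    gen_label_volume,
    gen_swc_neuron,
    motif_membership,
    multitarget_stats,
    projection_matrix,
    read_swc,
    write_swc,
)

from .conftest import make_spec


@pytest.fixture
def ab_volume(two_region_boxes):
    return gen_label_volume((100, 100, 200), 10.0, two_region_boxes,
                            id_to_acronym={1: "A", 2: "B"})


class TestSwcIO:
    def test_two_node_file(self):
        n = read_swc(io.StringIO("# comment\n1 1 0 0 0 5 -1\n2 2 10 0 0 0.5 1\n"))
        assert len(n.nodes) == 2
        assert int(n.soma["id"]) == 1

    def test_dangling_parent_named_in_error(self):
        with pytest.raises(ValueError, match="99"):
            read_swc(io.StringIO("1 1 0 0 0 5 -1\n2 2 10 0 0 0.5 99\n"))

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            read_swc(io.StringIO("1 1 0 0 0 5 -1\n2 1 9 9 9 5 -1\n"))

    def test_round_trip_identity(self, tmp_path):
        spec = make_spec(soma_xyz=(1.5, 2.5, 3.5),
                         branch_plan=((np.array([[1.5, 2.5, 3.5], [100.0, 50.0, 25.0]]), 1),))
        neuron, _ = gen_swc_neuron(spec, node_spacing=7.0)
        path = tmp_path / "n.swc"
        write_swc(neuron, path)
        again = read_swc(path)
        pd.testing.assert_frame_equal(neuron.nodes, again.nodes, check_dtype=False,
                                      atol=1e-9)


class TestAxonLength:
    def test_straight_axon_inside_one_region(self, ab_volume):
        spec = make_spec(soma_xyz=(100.0, 500.0, 500.0),
                         branch_plan=((np.array([[100.0, 500.0, 500.0],
                                                 [900.0, 500.0, 500.0]]), 1),))
        neuron, _ = gen_swc_neuron(spec, node_spacing=5.0)
        prof = axon_length_by_region(neuron, ab_volume, step_um=1.0)
        assert prof.length_mm == pytest.approx({"A": 0.8})

    def test_boundary_crossing_matches_analytic_clip(self, ab_volume, two_region_boxes):
        spec = make_spec(soma_xyz=(0.0, 500.0, 500.0),
                         branch_plan=((np.array([[0.0, 500.0, 500.0],
                                                 [2000.0, 500.0, 500.0]]), 1),))
        neuron, analytic = gen_swc_neuron(spec, node_spacing=7.0,
                                          region_boxes=two_region_boxes,
                                          id_to_acronym={1: "A", 2: "B"})
        prof = axon_length_by_region(neuron, ab_volume, step_um=1.0)
        # one boundary crossing: each region within one step of the oracle
        for region in ("A", "B"):
            assert abs(prof.length_mm[region] - analytic[region]) <= 1.0 / 1000.0

    def test_dendrite_only_neuron_empty_profile(self):
        nodes = pd.DataFrame(
            [(1, 1, 0.0, 0.0, 0.0, 5.0, -1), (2, 3, 100.0, 0.0, 0.0, 0.5, 1)],
            columns=["id", "type", "x", "y", "z", "radius", "parent"],
        )
        vol = gen_label_volume((10, 10, 20), 10.0, [(1, ((0, 0, 0), (200, 100, 100)))],
                               id_to_acronym={1: "A"})
        prof = axon_length_by_region(NeuronReconstruction(nodes=nodes), vol)
        assert prof.length_mm == {}
        assert prof.total_mm == 0.0

    def test_total_invariant_to_resampling(self, ab_volume):
        wp = np.array([[100.0, 100.0, 500.0], [900.0, 300.0, 500.0], [1500.0, 800.0, 200.0]])
        totals = []
        for spacing in (3.0, 11.0, 47.0):
            spec = make_spec(soma_xyz=tuple(wp[0]), branch_plan=((wp, 1),))
            neuron, _ = gen_swc_neuron(spec, node_spacing=spacing)
            prof = axon_length_by_region(neuron, ab_volume, step_um=1.0)
            totals.append(prof.total_mm)
        assert np.ptp(totals) < 1e-9

    def test_nonpositive_step_rejected(self, ab_volume):
        neuron, _ = gen_swc_neuron(make_spec(), node_spacing=5.0)
        with pytest.raises(ValueError):
            axon_length_by_region(neuron, ab_volume, step_um=0.0)


class TestDefineTargets:
    def test_threshold_rule(self):
        prof = ProjectionProfile(length_mm={"A": 1.2, "B": 0.9})
        assert define_targets(prof) == {"A"}

    def test_empty_profile(self):
        assert define_targets(ProjectionProfile(length_mm={})) == set()

    def test_inclusive_at_exact_threshold(self):
        assert define_targets(ProjectionProfile(length_mm={"A": 1.0})) == {"A"}

    def test_outside_never_a_target(self):
        prof = ProjectionProfile(length_mm={"outside": 5.0, "A": 2.0})
        assert define_targets(prof) == {"A"}

    def test_lowering_threshold_monotone(self):
        rng = np.random.default_rng(1)
        prof = ProjectionProfile(length_mm={f"R{i}": rng.uniform(0, 3) for i in range(8)})
        prev = set()
        for thr in (2.0, 1.5, 1.0, 0.5, 0.0):
            cur = define_targets(prof, thr)
            assert prev <= cur
            prev = cur


class TestCohortStats:
    def profile(self, n_targets):
        return ProjectionProfile(length_mm={f"R{i}": 1.5 for i in range(n_targets)})

    def test_single_target_cohort_not_multitarget(self):
        stats = multitarget_stats([self.profile(1)] * 4)
        assert stats["fraction_multi_target"] == 0.0

    def test_counting_fractions(self):
        cohort = [self.profile(k) for k in (1, 2, 7, 8)]
        stats = multitarget_stats(cohort)
        assert stats["fraction_multi_target"] == 0.75
        assert stats["fraction_seven_plus"] == 0.5
        assert stats["mean_n_targets"] == pytest.approx(4.5)

    def test_summaries_match_bruteforce(self, two_region_boxes):
        rng = np.random.default_rng(12)
        profiles = []
        truth_totals = []
        for i in range(6):
            wp = np.column_stack([
                rng.uniform(50, 1950, 4), rng.uniform(50, 950, 4), rng.uniform(50, 950, 4)
            ])
            spec = make_spec(soma_xyz=tuple(wp[0]), branch_plan=((wp, 1),))
            _, analytic = gen_swc_neuron(spec, node_spacing=9.0,
                                         region_boxes=two_region_boxes,
                                         id_to_acronym={1: "A", 2: "B"})
            profiles.append(ProjectionProfile(length_mm=analytic))
            truth_totals.append(sum(analytic.values()))
        stats = multitarget_stats(profiles)
        assert stats["median_total_length_mm"] == pytest.approx(np.median(truth_totals))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            multitarget_stats([])


class TestProjectionMatrix:
    def test_single_class_probability_one(self):
        profs = [ProjectionProfile(length_mm={"A": 2.0}) for _ in range(3)]
        pm = projection_matrix(profs, class_labels=[1, 1, 1])
        assert pm.class_probabilities.loc[1, "A"] == 1.0

    def test_partial_class_probability(self):
        profs = [ProjectionProfile(length_mm={"MOs": 2.0 if i < 6 else 0.2})
                 for i in range(10)]
        pm = projection_matrix(profs, class_labels=[1] * 10)
        assert pm.class_probabilities.loc[1, "MOs"] == pytest.approx(0.6)

    def test_binarized_consistent_with_threshold(self):
        profs = [ProjectionProfile(length_mm={"A": 0.99}), ProjectionProfile(length_mm={"A": 1.0})]
        pm = projection_matrix(profs)
        assert list(pm.binarized["A"]) == [0, 1]

    def test_label_mismatch_rejected(self):
        profs = [ProjectionProfile(length_mm={"A": 2.0})]
        with pytest.raises(ValueError):
            projection_matrix(profs, class_labels=[1, 2])


class TestMotifs:
    OVIS6 = {"VISal", "VISam", "VISl", "VISli", "VISpm", "VISpor"}

    def prof(self, targets):
        return ProjectionProfile(length_mm={t: 2.0 for t in targets})

    def test_any_mode_intersection(self):
        assert motif_membership(self.prof({"VISal", "VISp"}), self.OVIS6, "any")

    def test_any_mode_disjoint(self):
        assert not motif_membership(self.prof({"VISp"}), self.OVIS6, "any")

    def test_all_mode_subset(self):
        assert motif_membership(self.prof(self.OVIS6), self.OVIS6, "all")
        assert not motif_membership(self.prof({"VISal"}), self.OVIS6, "all")

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            motif_membership(self.prof({"VISp"}), set(), "any")
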