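"""Complexity measures: estimators, effective information, MIP search,
main complex, and stochastic interaction."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from animaze.agents import (
    copy_gate_brain,
    disconnected_pairs_brain,
    mutual_copy_brain,
)
from animaze.brain import (
    Brain,
    Gate,
    decode_genome,
    exact_transition_model,
    random_genome,
)
from animaze.info import (
    ActivityRecord,
    JointDistribution,
    Partition,
    effective_information,
    find_mip,
    kl_divergence,
    main_complex,
    mip_normalization,
    mutual_information,
    mutual_information_from_pairs,
    phi_atomic,
    predictive_info,
    record_activity,
    smmi,
)
from animaze.maze import generate_maze
from oracles import (
    ei_enumeration_oracle,
    kl_bruteforce,
    mi_bruteforce,
    rgs_partitions,
)


# ---------------------------------------------------------------------------
# estimators


class TestMutualInformation:
    def test_product_joint_is_zero(self):
        p = np.outer([0.3, 0.7], [0.6, 0.4])
        assert mutual_information(p) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_one_bit_copy(self):
        assert mutual_information(np.diag([0.5, 0.5])) == pytest.approx(1.0)

    def test_against_bruteforce(self):
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        assert mutual_information(p) == pytest.approx(mi_bruteforce(p), abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([[0.5, 0.2], [0.1, 0.1]]))

    def test_plugin_converges_to_analytic(self):
        """Plug-in MI on samples from a known joint approaches the true
        value as sample size grows."""
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        true = mi_bruteforce(p)
        rng = np.random.default_rng(0)
        flat = p.ravel()
        errs = []
        for n in (10**3, 10**4, 10**5):
            draws = rng.choice(4, size=n, p=flat)
            errs.append(
                abs(mutual_information_from_pairs(draws // 2, draws % 2) - true)
            )
        assert errs[2] < errs[0]
        assert errs[2] < 0.01


class TestKL:
    def test_identical_is_zero(self):
        assert kl_divergence([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_point_mass_vs_uniform(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_against_bruteforce(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        assert kl_divergence(p, q) == pytest.approx(kl_bruteforce(p, q), abs=1e-12)

    def test_support_violation(self):
        with pytest.raises(ValueError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])


class TestRecordMeasures:
    def test_record_bookkeeping(self, random_brains):
        mazes = [generate_maze(height=8, n_walls=3, seed=s) for s in range(3)]
        rec = record_activity(random_brains(0), mazes, lifetime=50, seed=1)
        assert len(rec.states) == 150
        assert rec.n_episodes == 3
        rec2 = record_activity(random_brains(0), mazes, lifetime=50, seed=1)
        assert np.array_equal(rec.states, rec2.states)

    def test_zero_gate_brain_measures_zero(self, small_maze):
        rec = record_activity(Brain(gates=[]), [small_maze], lifetime=50, seed=0)
        assert ((rec.states >> 6) == 0).all()
        assert smmi(rec) == pytest.approx(0.0, abs=1e-12)

    def test_smmi_equals_sensor_entropy_for_wired_brain(self):
        """With b3 copied deterministically to b10, SMMI equals the
        plug-in entropy of the recorded b3 series."""
        brain = Brain(
            gates=[
                Gate(inputs=(3,), outputs=(10,), table=[[1, 0], [0, 1]])
            ]
        )
        # alternate door bit artificially via a synthetic record
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, size=400)
        states = np.zeros(400, dtype=np.int64)
        states |= bits << 3
        states[1:] |= (bits[:-1] << 10)
        rec = ActivityRecord(states=states, episode_starts=np.array([0]))
        p1 = bits[:-1].mean()
        h = -(p1 * math.log2(p1) + (1 - p1) * math.log2(1 - p1))
        assert smmi(rec) == pytest.approx(h, abs=1e-9)

    def test_smmi_upper_bound(self, random_brains):
        mazes = [generate_maze(height=8, n_walls=3, seed=s) for s in range(2)]
        for i in range(5):
            rec = record_activity(random_brains(i), mazes, lifetime=100, seed=i)
            assert 0 <= smmi(rec) <= 2.0 + 1e-9

    def test_predictive_info_two_cycle(self):
        """A deterministic period-2 orbit carries exactly 1 bit."""
        states = np.array([5, 9] * 200 + [5])  # 400 pairs, evenly split
        rec = ActivityRecord(states=states, episode_starts=np.array([0]))
        assert predictive_info(rec) == pytest.approx(1.0)

    def test_predictive_info_iid_shuffle_near_zero(self):
        rng = np.random.default_rng(3)
        states = rng.integers(0, 4, size=5000)
        rec = ActivityRecord(states=states, episode_starts=np.array([0]))
        # plug-in bias for a 4x4 table at n=5000 is ~ 9/(2 n ln 2)
        assert predictive_info(rec) < 0.01

    def test_pairs_respect_episode_boundaries(self):
        rec = ActivityRecord(
            states=np.array([1, 2, 3, 4]), episode_starts=np.array([0, 2])
        )
        x, y = rec.pairs()
        assert list(zip(x, y)) == [(1, 2), (3, 4)]


# ---------------------------------------------------------------------------
# effective information / phi


class TestEffectiveInformation:
    def test_independent_nodes_zero(self):
        # two gates with constant output distributions: parts factorize
        g1 = Gate(inputs=(6,), outputs=(6,), table=[[0.3, 0.7], [0.3, 0.7]])
        g2 = Gate(inputs=(7,), outputs=(7,), table=[[0.8, 0.2], [0.8, 0.2]])
        tm = exact_transition_model(Brain(gates=[g1, g2]), [6, 7])
        ei = effective_information(tm, Partition(((6,), (7,))))
        assert ei == pytest.approx(0.0, abs=1e-12)

    def test_mutual_copy_matches_enumeration_oracle(self, mutual_copy):
        tm = exact_transition_model(mutual_copy, [6, 7])
        parts = ((6,), (7,))
        assert effective_information(tm, Partition(parts)) == pytest.approx(
            ei_enumeration_oracle(tm, parts), abs=1e-10
        )

    def test_random_brain_matches_enumeration_oracle(self):
        brain = decode_genome(random_genome(600, 3, seed=11))
        nodes = [n for n in brain.active_nodes()][:4]
        if len(nodes) < 3:
            pytest.skip("fixture brain too small")
        tm = exact_transition_model(brain, nodes)
        for parts in [
            tuple((v,) for v in nodes),
            (tuple(nodes[:2]), tuple(nodes[2:])),
        ]:
            assert effective_information(tm, Partition(parts)) == pytest.approx(
                ei_enumeration_oracle(tm, parts), abs=1e-9
            )

    def test_partition_subset_mismatch(self, mutual_copy):
        tm = exact_transition_model(mutual_copy, [6, 7])
        with pytest.raises(ValueError):
            effective_information(tm, Partition(((6,), (8,))))


class TestNormalization:
    @pytest.mark.parametrize(
        "parts,expected",
        [
            (((6,), (7,)), 1),
            (((6,), (7,), (8,), (9,)), 3),
            (((6,), (7, 8, 9)), 1),
            (((6, 7), (8, 9)), 2),
        ],
    )
    def test_closed_forms(self, parts, expected):
        assert mip_normalization(Partition(parts)) == expected

    def test_single_part_rejected(self):
        with pytest.raises(ValueError):
            mip_normalization(Partition(((6, 7),)))


class TestFindMip:
    def test_mutual_copy_phi(self, mutual_copy):
        tm = exact_transition_model(mutual_copy, [6, 7])
        res = find_mip(tm)
        # the only non-total partition is the bipartition; each copied bit
        # contributes 1 bit of integrated information
        assert res.mip.parts == ((6,), (7,))
        assert res.phi == pytest.approx(2.0)

    def test_disconnected_parts_give_zero(self, disconnected_pairs):
        tm = exact_transition_model(disconnected_pairs, [6, 7, 8, 9])
        res = find_mip(tm, search="exhaustive")
        assert res.phi == pytest.approx(0.0, abs=1e-10)

    def test_exhaustive_matches_rgs_oracle(self):
        """The sympy-backed partition enumeration and an independent
        restricted-growth-string enumerator agree on the minimizer."""
        brain = decode_genome(random_genome(600, 3, seed=21))
        nodes = [n for n in brain.active_nodes()][:5]
        if len(nodes) < 3:
            pytest.skip("fixture brain too small")
        tm = exact_transition_model(brain, nodes)
        res = find_mip(tm, search="exhaustive")
        best = None
        for parts_pos in rgs_partitions(len(nodes)):
            if len(parts_pos) < 2:
                continue
            parts = tuple(
                tuple(nodes[i] for i in part) for part in parts_pos
            )
            ei = effective_information(tm, Partition(parts))
            k = mip_normalization(Partition(parts))
            if best is None or ei / k < best - 1e-12:
                best = ei / k
        assert res.normalized_phi == pytest.approx(best, abs=1e-9)

    def test_bipartition_candidates_are_superset_consistent(self):
        brain = decode_genome(random_genome(800, 4, seed=33))
        nodes = [n for n in brain.active_nodes()][:4]
        if len(nodes) < 4:
            pytest.skip("fixture brain too small")
        tm = exact_transition_model(brain, nodes)
        full = find_mip(tm, search="exhaustive")
        bi = find_mip(tm, search="bipartitions")
        assert full.normalized_phi <= bi.normalized_phi + 1e-12

    def test_singleton_rejected(self, mutual_copy):
        tm = exact_transition_model(mutual_copy, [6])
        with pytest.raises(ValueError):
            find_mip(tm)


class TestPhiAtomic:
    def test_independent_nodes_zero(self):
        g1 = Gate(inputs=(6,), outputs=(6,), table=[[0.3, 0.7], [0.3, 0.7]])
        g2 = Gate(inputs=(7,), outputs=(7,), table=[[0.8, 0.2], [0.8, 0.2]])
        tm = exact_transition_model(Brain(gates=[g1, g2]), [6, 7])
        assert phi_atomic(tm) == pytest.approx(0.0, abs=1e-12)

    def test_equals_effective_information_at_atomic_partition(self):
        """Entropy form and KL form agree to 1e-10 on random systems."""
        for s in range(20):
            brain = decode_genome(random_genome(500, 3, seed=100 + s))
            nodes = [n for n in brain.active_nodes()][:5]
            if len(nodes) < 2:
                continue
            tm = exact_transition_model(brain, nodes)
            atomic = Partition(tuple((v,) for v in nodes))
            assert phi_atomic(tm) == pytest.approx(
                effective_information(tm, atomic), abs=1e-10
            )

    def test_at_least_phi_mip(self):
        """The atomic partition is a candidate in the MIP minimization,
        so its ei can never fall below phi."""
        for s in range(10):
            brain = decode_genome(random_genome(800, 4, seed=200 + s))
            nodes = [n for n in brain.active_nodes()][:5]
            if len(nodes) < 2:
                continue
            tm = exact_transition_model(brain, nodes)
            assert phi_atomic(tm) >= find_mip(tm, search="exhaustive").phi - 1e-10


class TestMainComplex:
    def test_zero_gate_brain(self):
        res = main_complex(Brain(gates=[]))
        assert res.phi == 0.0

    def test_isolated_pair_found(self, mutual_copy):
        res = main_complex(mutual_copy)
        assert res.subset == (6, 7)
        assert res.phi == pytest.approx(2.0)

    def test_greedy_equals_exhaustive_on_small_brains(self):
        """For brains with few causally active nodes, greedy node removal
        finds the same maximum as a full power-set search."""
        for s in (5, 11, 17):
            brain = decode_genome(random_genome(400, 2, seed=s))
            active = brain.active_nodes()
            if not 2 <= len(active) <= 6:
                continue
            greedy = main_complex(brain)
            best = 0.0
            for k in range(2, len(active) + 1):
                for sub in itertools.combinations(active, k):
                    edges = brain.causal_edges()
                    from animaze.info import _phi_of_subset

                    best = max(best, _phi_of_subset(brain, sub, edges, "auto").phi)
            assert greedy.phi == pytest.approx(best, abs=1e-9)

    def test_disconnected_pairs_complex_is_one_pair(self, disconnected_pairs):
        res = main_complex(disconnected_pairs)
        assert res.phi == pytest.approx(2.0)
        assert res.subset in ((6, 7), (8, 9))
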