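import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excessbayes import (
    BlockPartition,
    ProbVector,
    SimulationConfig,
    articulated_relation,
    block_partition,
    boundary_set,
    excess_step,
    ideal_likelihood,
    joint_from_likelihood,
    make_fixture,
    renorm_over_data,
    renorm_over_hypotheses,
    run_bayesian_phase,
    run_excess_phase,
    subdiagonal_relation,
    threshold_relation,
)
from excessbayes.excess import partition_from_indicator
from excessbayes.probability import JointMatrix, data_labels, hyp_labels
from excessbayes.relation import BinaryRelation, FixtureSpec

FIG3_EXPERIENCED = [1, 2, 7, 8, 9, 10, 11, 12, 13, 14]  # complement of E


def fig3_config(**kw):
    base = dict(
        n=20, alpha=0.8, experienced=FIG3_EXPERIENCED, bayes_steps=30,
        excess_steps=30, seed=0, smoothing="none", snapshot_every=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def relation_with_diagonal(n, on_indices):
    """Square relation whose diagonal membership is exactly ``on_indices``
    (off-diagonal cells left empty; only the diagonal matters for blocks)."""
    hl, dl = hyp_labels(n), data_labels(n)
    pairs = {(hl[i - 1], dl[i - 1]) for i in on_indices}
    # keep every datum related to something so the relation is well formed
    return BinaryRelation(hl, dl, frozenset(pairs))


def square_joint(entries, state="renormalized"):
    entries = np.asarray(entries, dtype=float)
    n = entries.shape[0]
    return JointMatrix(data_labels(n), hyp_labels(n), entries, state=state)


class TestThresholdRelation:
    def test_ideal_joint_thresholds_to_diagonal(self):
        lik = ideal_likelihood(7, 1.0)
        j = joint_from_likelihood(lik, ProbVector.uniform(lik.hyp_labels))
        rel = threshold_relation(j, 0.1)
        assert rel.pairs == {(f"h{i}", f"d{i}") for i in range(1, 8)}

    def test_threshold_above_max_gives_empty_relation(self):
        lik = ideal_likelihood(4, 0.8)
        j = joint_from_likelihood(lik, ProbVector.uniform(lik.hyp_labels))
        assert threshold_relation(j, 1.0).pairs == frozenset()

    def test_zero_threshold_keeps_strictly_positive_cells(self):
        j = square_joint([[0.5, 0.0], [0.25, 0.25]], state="normalized")
        rel = threshold_relation(j, 0.0)
        assert len(rel.pairs) == 3

    def test_inclusive_comparison_keeps_boundary_cells(self):
        j = square_joint([[0.5, 0.1], [0.1, 0.3]], state="normalized")
        assert len(threshold_relation(j, 0.1).pairs) == 2
        assert len(threshold_relation(j, 0.1, inclusive=True).pairs) == 4


class TestBoundaryAndBlocks:
    def test_full_diagonal_has_only_the_sentinel(self):
        rel = relation_with_diagonal(8, range(1, 9))
        assert boundary_set(rel) == [8]

    def test_fig3_experienced_pattern_flips(self):
        rel = relation_with_diagonal(20, [1, 2] + list(range(7, 15)))
        assert boundary_set(rel) == [2, 6, 14, 20]

    def test_alternating_membership_flips_everywhere(self):
        rel = relation_with_diagonal(6, [1, 3, 5])
        assert boundary_set(rel) == [1, 2, 3, 4, 5, 6]

    def test_blocks_are_maximal_runs(self):
        rel = relation_with_diagonal(20, [1, 2] + list(range(7, 15)))
        part = block_partition(rel)
        assert part.blocks == ((1, 2), (3, 6), (7, 14), (15, 20))
        assert part.experienced_flags == (True, False, True, False)

    def test_worked_block_starts(self):
        # diagonal membership flipping at 2, 5, 11 gives the worked squares
        rel = relation_with_diagonal(20, [1, 2] + list(range(6, 12)))
        part = block_partition(rel)
        assert part.boundary_elements == (1, 3, 6, 12)
        assert part.blocks == ((1, 2), (3, 5), (6, 11), (12, 20))

    def test_single_block_for_full_diagonal(self):
        part = block_partition(relation_with_diagonal(5, range(1, 6)))
        assert part.blocks == ((1, 5),)
        assert part.experienced_flags == (True,)

    def test_partition_from_indicator_matches_relation_route(self):
        ind = np.zeros(20, dtype=bool)
        ind[[0, 1] + list(range(6, 14))] = True
        part = partition_from_indicator(ind)
        rel = relation_with_diagonal(20, [1, 2] + list(range(7, 15)))
        assert part == block_partition(rel)

    def test_non_square_relation_rejected(self):
        rel = BinaryRelation(hyp_labels(3), data_labels(2), {("h1", "d1")})
        with pytest.raises(ValueError):
            boundary_set(rel)


class TestRenormalization:
    def test_single_block_normalizes_each_datum(self):
        j = square_joint([[0.4, 0.1], [0.1, 0.4]], state="normalized")
        part = BlockPartition(2, (1,), ((1, 2),), (True,))
        out = renorm_over_hypotheses(j, part)
        np.testing.assert_allclose(out.entries, [[0.8, 0.2], [0.2, 0.8]])
        assert out.state == "renormalized"

    def test_singleton_blocks_amplify_off_block_mass(self):
        j = square_joint([[0.4, 0.1], [0.1, 0.4]], state="normalized")
        part = BlockPartition(2, (1, 2), ((1, 1), (2, 2)), (True, True))
        out = renorm_over_hypotheses(j, part)
        np.testing.assert_allclose(out.entries, [[1.0, 0.25], [0.25, 1.0]])

    def test_renorm_over_data_mirrors_hypothesis_renorm(self):
        j = square_joint([[0.4, 0.1], [0.1, 0.4]], state="normalized")
        part = BlockPartition(2, (1, 2), ((1, 1), (2, 2)), (True, True))
        out = renorm_over_data(j, part)
        np.testing.assert_allclose(out.entries, [[1.0, 0.25], [0.25, 1.0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_transpose_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.random((6, 6)) + 0.01
        part = BlockPartition(6, (1, 3, 5), ((1, 2), (3, 4), (5, 6)), (True, False, True))
        a = renorm_over_data(square_joint(e), part).entries
        b = renorm_over_hypotheses(square_joint(e.T), part).entries.T
        np.testing.assert_allclose(a, b, atol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_in_block_sums_are_exactly_one(self, seed):
        rng = np.random.default_rng(100 + seed)
        e = rng.random((7, 7)) + 0.01
        part = BlockPartition(7, (1, 4), ((1, 3), (4, 7)), (True, True))
        out = renorm_over_hypotheses(square_joint(e), part).entries
        for i in range(7):
            p, q = part.blocks[part.block_of(i + 1)]
            assert out[i, p - 1:q].sum() == pytest.approx(1.0, abs=1e-9)
        out2 = renorm_over_data(square_joint(e), part).entries
        for j in range(7):
            p, q = part.blocks[part.block_of(j + 1)]
            assert out2[p - 1:q, j].sum() == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(data=st.data())
    def test_zeros_ratios_and_off_block_growth_preserved(self, data):
        n = data.draw(st.integers(3, 6))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        e = rng.random((n, n))
        e[rng.random((n, n)) < 0.2] = 0.0
        e = e / max(e.sum(), 1e-9)
        split = data.draw(st.integers(2, n))
        part = BlockPartition(
            n, (1, split), ((1, split - 1), (split, n)), (True, False)
        )
        out = renorm_over_hypotheses(square_joint(e), part).entries
        # zero preservation
        assert np.all(out[e == 0] == 0)
        for i in range(n):
            p, q = part.blocks[part.block_of(i + 1)]
            s = e[i, p - 1:q].sum()
            if s <= 0:
                np.testing.assert_array_equal(out[i], e[i])
                continue
            # within-row ratio preservation
            nz = e[i] > 0
            ratio = out[i, nz] / e[i, nz]
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)
            # off-block entries never shrink when the in-block sum <= 1
            if s <= 1:
                off = np.ones(n, dtype=bool)
                off[p - 1:q] = False
                assert np.all(out[i, off] >= e[i, off] - 1e-15)

    def test_zero_block_sum_skips_or_raises(self):
        e = np.array([[0.0, 0.0], [0.3, 0.7]])
        part = BlockPartition(2, (1,), ((1, 2),), (True,))
        out = renorm_over_hypotheses(square_joint(e), part)
        np.testing.assert_array_equal(out.entries[0], e[0])
        with pytest.raises(ZeroDivisionError):
            renorm_over_hypotheses(square_joint(e), part, zero_block_sum="error")

    def test_experienced_only_mode_passes_unflagged_blocks_through(self):
        e = np.array([[0.4, 0.1], [0.1, 0.4]])
        part = BlockPartition(2, (1, 2), ((1, 1), (2, 2)), (True, False))
        out = renorm_over_hypotheses(square_joint(e), part, mode="experienced_only")
        np.testing.assert_allclose(out.entries, [[1.0, 0.25], [0.1, 0.4]])

    def test_inclusive_upper_sum_widens_the_domain(self):
        e = np.array([[0.2, 0.3, 0.5], [0.1, 0.1, 0.8], [0.3, 0.3, 0.4]])
        part = BlockPartition(3, (1, 3), ((1, 2), (3, 3)), (True, True))
        out = renorm_over_hypotheses(
            square_joint(e), part, sum_upper_inclusive=True
        ).entries
        # row 1's domain becomes h1..h3 (block end + 1)
        np.testing.assert_allclose(out[0], e[0] / e[0, :3].sum())


class TestExcessSteps:
    def test_alternation_applies_one_renorm_per_step(self):
        cfg = fig3_config(excess_steps=2)
        state = run_bayesian_phase(cfg)
        s1 = excess_step(state, cfg)
        # first step (data start): every experienced datum's in-block
        # hypothesis mass is exactly 1 -> Eq over hypotheses was applied
        part = s1.last_partition
        for i in range(1, 21):
            p, q = part.blocks[part.block_of(i)]
            s = s1.joint.entries[i - 1, p - 1:q].sum()
            assert s == pytest.approx(1.0, abs=1e-9) or s == pytest.approx(0.0, abs=1e-12)
        s2 = excess_step(s1, cfg)
        part2 = s2.last_partition
        # second step renormalized per hypothesis over data
        for j in range(1, 21):
            p, q = part2.blocks[part2.block_of(j)]
            s = s2.joint.entries[p - 1:q, j - 1].sum()
            assert s == pytest.approx(1.0, abs=1e-9) or s == pytest.approx(0.0, abs=1e-12)

    def test_block_normalized_joint_is_a_fixed_point(self):
        e = np.array([[0.8, 0.2], [0.2, 0.8]])
        part = BlockPartition(2, (1,), ((1, 2),), (True,))
        out = renorm_over_hypotheses(square_joint(e), part)
        np.testing.assert_allclose(out.entries, e)

    def test_zero_excess_steps_reduces_to_bayesian_phase(self):
        cfg = fig3_config(excess_steps=0)
        state, _ = run_excess_phase(cfg)
        ref = run_bayesian_phase(cfg)
        np.testing.assert_array_equal(state.joint.entries, ref.joint.entries)
        assert state.t == ref.t

    @pytest.mark.parametrize("seed", range(5))
    def test_relation_stabilizes_over_final_excess_steps(self, seed):
        cfg = fig3_config(seed=seed)
        state = run_bayesian_phase(cfg)
        pair_sets = []
        for _ in range(cfg.excess_steps):
            state = excess_step(state, cfg)
            pair_sets.append(
                threshold_relation(state.joint, cfg.relation_threshold).pairs
            )
        last10 = pair_sets[-10:]
        assert all(a <= b for a, b in zip(last10, last10[1:]))

    @pytest.mark.parametrize("seed", range(3))
    def test_fig3_protocol_yields_blocks_plus_background(self, seed):
        state, rel = run_excess_phase(fig3_config(seed=seed))
        part = state.last_partition
        assert len(part.blocks) >= 2
        expected = articulated_relation(
            part, state.joint.hyp_labels, state.joint.data_labels, "all_blocks"
        )
        assert rel.pairs == expected.pairs
        # in-block diagonal pairs present, in-block off-diagonals absent
        for k, (p, q) in enumerate(part.blocks):
            for i in range(p, q + 1):
                assert (f"h{i}", f"d{i}") in rel.pairs
                if i > p:
                    assert (f"h{p}", f"d{i}") not in rel.pairs

    def test_experienced_only_articulation_absorbs_unexperienced_blocks(self):
        part = partition_from_indicator([True, True, False, False, True])
        rel = articulated_relation(
            part, hyp_labels(5), data_labels(5), "experienced_only"
        )
        # unexperienced square fully related
        assert ("h3", "d4") in rel.pairs and ("h4", "d3") in rel.pairs
        # experienced squares diagonal only
        assert ("h1", "d2") not in rel.pairs
        assert ("h1", "d1") in rel.pairs

    def test_all_blocks_articulation_is_the_blocks_fixture(self):
        part = partition_from_indicator([True, True, False, False, False])
        rel = articulated_relation(part, hyp_labels(5), data_labels(5), "all_blocks")
        fixture = make_fixture(
            FixtureSpec(kind="blocks_with_background", block_sizes=[2, 3])
        )
        assert rel.pairs == fixture.pairs
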