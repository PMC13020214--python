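import math

import numpy as np
import pytest

from sapling.enumeration import (
    BeamConfig,
    EnumerationConfig,
    backbone_by_tau,
    beam_enumeration,
    fast_backbone_enumeration,
    mutation_order,
)
from sapling.likelihood import fit_frequencies
from sapling.oracle import solution_space
from sapling.simulate import SimulationConfig, simulate_instance
from sapling.trees import ReadCountData, canonical_key, is_ancestor, make_tree


class TestMutationOrder:
    def test_descending_column_sums(self):
        d = ReadCountData(["s"], ["x", "y", "z"], [[90, 40, 70]], [[100, 100, 100]])
        assert mutation_order(d) == ["x", "z", "y"]

    def test_ties_keep_input_order(self):
        d = ReadCountData(["s"], ["x", "y", "z"], [[50, 50, 50]], [[100, 100, 100]])
        assert mutation_order(d) == ["x", "y", "z"]

    def test_tie_break_on_counts(self, data_90_40_40):
        assert mutation_order(data_90_40_40) == [1, 2, 3]


class TestFastBackboneEnumeration:
    def test_ell_one_single_node(self, data_90_40_40):
        res = fast_backbone_enumeration(data_90_40_40, EnumerationConfig(rho=0.9, ell=1))
        assert res.S == [1] and len(res.trees) == 1 and len(res.trees[0]) == 1

    def test_three_way_tie(self, data_90_40_40):
        res = fast_backbone_enumeration(data_90_40_40, EnumerationConfig(rho=0.9, ell=3))
        keys = {canonical_key(t) for t in res.trees}
        want = {
            canonical_key(make_tree(p))
            for p in ({2: 1, 3: 1}, {2: 1, 3: 2}, {3: 1, 2: 3})
        }
        assert keys == want
        assert max(res.logliks) - min(res.logliks) < 1e-6

    def test_ell_two_single_chain(self, data_90_40_40):
        res = fast_backbone_enumeration(data_90_40_40, EnumerationConfig(rho=0.9, ell=2))
        assert len(res.trees) == 1
        assert canonical_key(res.trees[0]) == canonical_key(make_tree({2: 1}))

    def test_retained_set_contains_maximum(self, data_90_40_40):
        res = fast_backbone_enumeration(data_90_40_40, EnumerationConfig(rho=0.5, ell=3))
        best = max(res.logliks)
        assert any(math.isclose(ll, best, abs_tol=1e-9) for ll in res.logliks)
        assert all(ll >= best + math.log(0.5) - 1e-6 for ll in res.logliks)

    def test_history_reported(self, data_90_40_40):
        res = fast_backbone_enumeration(data_90_40_40, EnumerationConfig(rho=0.9, ell=3))
        assert res.history == [1, 1, 3]

    def test_rho_monotonicity(self):
        inst = simulate_instance(SimulationConfig(n=6, m=2, seed=4))
        keys = {}
        for rho in (0.95, 0.5):
            res = fast_backbone_enumeration(inst.data, EnumerationConfig(rho=rho, ell=6))
            keys[rho] = {canonical_key(t) for t in res.trees}
        assert keys[0.95] <= keys[0.5]

    def test_invalid_config(self, data_90_40_40):
        with pytest.raises(ValueError):
            EnumerationConfig(rho=0.9)  # neither ell nor tau
        with pytest.raises(ValueError):
            EnumerationConfig(rho=0.9, ell=2, tau=1)
        with pytest.raises(ValueError):
            fast_backbone_enumeration(data_90_40_40, EnumerationConfig(rho=0.9, ell=9))


class TestBackboneByTau:
    def test_large_tau_returns_all_mutations(self, data_90_40_40):
        res = backbone_by_tau(data_90_40_40, EnumerationConfig(rho=0.9, tau=1000))
        assert res.S == [1, 2, 3]

    def test_tau_one(self, data_90_40_40):
        res = backbone_by_tau(data_90_40_40, EnumerationConfig(rho=0.9, tau=1))
        assert res.S == [1, 2] and len(res.trees) == 1

    def test_tau_three(self, data_90_40_40):
        res = backbone_by_tau(data_90_40_40, EnumerationConfig(rho=0.9, tau=3))
        assert res.S == [1, 2, 3] and len(res.trees) == 3

    def test_matches_restarted_sweep(self):
        """The single-pass sweep equals rerunning the ell-enumeration."""
        inst = simulate_instance(SimulationConfig(n=6, m=2, seed=9))
        res = backbone_by_tau(inst.data, EnumerationConfig(rho=0.9, tau=2))
        rerun = fast_backbone_enumeration(
            inst.data, EnumerationConfig(rho=0.9, ell=res.ell_used)
        )
        assert {canonical_key(t) for t in res.trees} == {canonical_key(t) for t in rerun.trees}


class TestBeamEnumeration:
    def test_width_one_matches_brute_force(self, data_90_40_40):
        res = beam_enumeration(data_90_40_40, BeamConfig(width=1))
        space = solution_space(data_90_40_40, 1.0)
        assert len(res.trees) == 1
        assert math.isclose(res.logliks[0], space.max_loglik, abs_tol=1e-6)

    def test_wide_beam_equals_rho_zero_enumeration(self, data_90_40_40):
        res_beam = beam_enumeration(data_90_40_40, BeamConfig(width=10_000))
        res_rho = fast_backbone_enumeration(data_90_40_40, EnumerationConfig(rho=0.0, ell=3))
        assert {canonical_key(t) for t in res_beam.trees} == {
            canonical_key(t) for t in res_rho.trees
        }

    def test_two_mutations_exhaustive(self):
        d = ReadCountData(["s"], [1, 2], [[30, 80]], [[100, 100]])
        res = beam_enumeration(d, BeamConfig(width=1))
        # mutation 2 has the higher frequency: it must be the root
        assert canonical_key(res.trees[0]) == canonical_key(make_tree({1: 2}))
        better = max(
            fit_frequencies(d, make_tree(p)).loglik for p in ({1: 2}, {2: 1})
        )
        assert math.isclose(res.logliks[0], better, abs_tol=1e-6)

    def test_ranked_descending(self):
        inst = simulate_instance(SimulationConfig(n=5, m=2, seed=2))
        res = beam_enumeration(inst.data, BeamConfig(width=5))
        assert res.logliks == sorted(res.logliks, reverse=True)


def test_no_inversion_at_high_depth():
    """With essentially noise-free frequencies, no retained tree places a
    lower-frequency mutation above a higher-frequency one."""
    for seed in (1, 2, 3):
        inst = simulate_instance(SimulationConfig(n=6, m=3, depth_mean=1e5, seed=seed))
        res = fast_backbone_enumeration(inst.data, EnumerationConfig(rho=0.9, ell=6))
        order = mutation_order(inst.data)
        sums = dict(
            zip(inst.data.mutations, (inst.data.A / inst.data.D).sum(axis=0))
        )
        for t in res.trees:
            for pos, i in enumerate(order):
                for j in order[pos + 1:]:
                    if sums[i] > sums[j]:
                        assert not (is_ancestor(t, j, i) and i != j)
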