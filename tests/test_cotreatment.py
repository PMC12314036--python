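"""tSignal arithmetic, Diff Effect, rank-sum, BH, and the screen."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import triggernet as tn
from triggernet.knowledge_base import ValidationError

import oracles
from conftest import make_ensemble


class TestTSignal:
    def test_full_concordance_gives_minus_one(self):
        effs = tn.EffectorSet("p", {"A": 1, "B": -1, "C": 1})
        y = {"A": 1.0, "B": -1.0, "C": 1.0}
        assert tn.tsignal(y, effs) == -1.0

    def test_zero_activity_gives_zero(self):
        effs = tn.EffectorSet("p", {"A": 1, "B": -1})
        assert tn.tsignal({"A": 0.0, "B": 0.0}, effs) == 0.0

    def test_two_term_case(self):
        effs = tn.EffectorSet("p", {"A": 1, "B": -1})
        assert tn.tsignal({"A": 0.6, "B": 0.2}, effs) == pytest.approx(-0.2)

    def test_missing_effector_counts_as_zero(self):
        effs = tn.EffectorSet("p", {"A": 1, "B": 1})
        assert tn.tsignal({"A": 1.0}, effs) == pytest.approx(-0.5)

    @given(st.lists(st.tuples(st.sampled_from([-1, 1]),
                              st.floats(min_value=-1, max_value=1)),
                    min_size=1, max_size=8))
    def test_bounded_and_antisymmetric_in_expected_signs(self, pairs):
        effs = tn.EffectorSet("p", {f"P{i}": v for i, (v, _) in enumerate(pairs)})
        flipped = tn.EffectorSet("p", {f"P{i}": -v for i, (v, _) in enumerate(pairs)})
        y = {f"P{i}": float(a) for i, (_, a) in enumerate(pairs)}
        t = tn.tsignal(y, effs)
        assert abs(t) <= 1 + 1e-12
        assert tn.tsignal(y, flipped) == pytest.approx(-t)

    def test_linear_in_activity(self):
        effs = tn.EffectorSet("p", {"A": 1, "B": -1})
        y1 = {"A": 0.4, "B": -0.2}
        y2 = {"A": -0.1, "B": 0.5}
        combined = {p: y1[p] + y2[p] for p in y1}
        assert tn.tsignal(combined, effs) == pytest.approx(
            tn.tsignal(y1, effs) + tn.tsignal(y2, effs))


class TestDiffEffect:
    def test_empty_cotreatment_gives_exact_zero_differences(self, small_net):
        ens = make_ensemble(small_net, 4)
        btki = tn.DrugProfile("drug", [tn.DrugTarget("S")])
        cotx = tn.DrugProfile("empty", [])
        effs = tn.EffectorSet("p", {"E1": 1, "E3": -1})
        r = tn.diff_effect(small_net, ens, btki, cotx, effs)
        assert np.all(r.per_solution_diff == 0.0)

    def test_disconnected_cotreatment_gives_zero(self, ref_benchmark):
        b = ref_benchmark
        ens = b.planted_ensemble()
        null = tn.generate_null_cotreatment(b.net, b.processes, seed=11)
        r = tn.diff_effect(b.net, ens, b.drugs["drug_A"], null, b.processes[0])
        assert np.all(r.per_solution_diff == 0.0)

    def test_conflicting_clamp_directions_rejected(self, small_net):
        ens = make_ensemble(small_net, 2)
        btki = tn.DrugProfile("drug", [tn.DrugTarget("S", "inhibit")])
        cotx = tn.DrugProfile("cotx", [tn.DrugTarget("S", "activate")])
        effs = tn.EffectorSet("p", {"E1": 1})
        with pytest.raises(ValidationError, match="'S'"):
            tn.diff_effect(small_net, ens, btki, cotx, effs)

    def test_planted_antagonist_has_negative_mean_diff(self, ref_benchmark):
        b = ref_benchmark
        ens = b.planted_ensemble()
        ant = b.cotreatments["antagonist_class"]
        for effs in b.processes:
            r = tn.diff_effect(b.net, ens, b.drugs["drug_A"], ant, effs)
            assert r.mean_diff_effect < 0


class TestRankSum:
    def test_identical_samples_give_one(self):
        assert tn.rank_sum_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_exact_small_sample_enumeration(self):
        p = tn.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(oracles.brute_ranksum_exact([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.normal(size=4))
        b = list(rng.normal(size=5))
        assert tn.rank_sum_test(a, b) == pytest.approx(
            oracles.brute_ranksum_exact(a, b), abs=1e-12)

    def test_type_one_error_calibrated_under_null(self):
        """Monte-Carlo at n=30 per arm: rejection rate at alpha=0.05 stays
        near nominal."""
        rng = np.random.default_rng(2024)
        hits = sum(
            tn.rank_sum_test(rng.normal(size=30), rng.normal(size=30)) < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= hits / 2000 <= 0.065

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValidationError):
            tn.rank_sum_test([1.0], [2.0, 3.0])


class TestBH:
    def test_single_p_unchanged(self):
        assert tn.bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_step_up_example(self):
        assert tn.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_q_at_least_p_and_matches_hand_bh(self, ps):
        qs = tn.bh_adjust(ps)
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
        assert qs == pytest.approx(oracles.brute_bh(ps), abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    def test_invariant_under_input_permutation(self, ps, rnd):
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        qs = tn.bh_adjust(ps)
        qs_perm = tn.bh_adjust([ps[i] for i in idx])
        assert [qs[i] for i in idx] == pytest.approx(qs_perm, abs=1e-12)


class TestScreen:
    def test_infinite_diff_threshold_flags_nothing(self, ref_benchmark):
        b = ref_benchmark
        ens = b.planted_ensemble()
        # a planted single-solution ensemble has degenerate statistics, so
        # pad it with jittered copies for a meaningful rank-sum
        ens = make_ensemble(b.net, 5, seed=3)
        results = tn.interference_screen(
            b.net, ens, b.drugs["drug_A"],
            [b.cotreatments["antagonist_class"]], b.processes,
            diff_threshold=float("inf"),
        )
        assert all(not r.flagged for r in results)

    def test_null_flag_rate_within_binomial_bound(self, small_net):
        """200 seeded replicates of a no-op cotreatment: flag rate must
        stay within alpha + 2 binomial SE."""
        alpha = 0.05
        btki = tn.DrugProfile("drug", [tn.DrugTarget("S")])
        noop = tn.DrugProfile("noop", [tn.DrugTarget("X")])  # X cannot reach E3
        effs = tn.EffectorSet("p", {"E3": 1})
        flags = 0
        for rep in range(200):
            ens = make_ensemble(small_net, 5, seed=rep)
            res = tn.interference_screen(small_net, ens, btki, [noop], [effs], alpha=alpha)
            flags += sum(bool(r.flagged) for r in res)
        assert flags / 200 <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / 200)

    def test_sorted_by_q_then_effect(self, ref_benchmark):
        b = ref_benchmark
        ens = make_ensemble(b.net, 6, seed=1)
        null = tn.generate_null_cotreatment(b.net, b.processes, seed=5)
        results = tn.interference_screen(
            b.net, ens, b.drugs["drug_A"],
            [b.cotreatments["antagonist_class"], null], b.processes,
        )
        keys = [(r.q_value, -abs(r.mean_diff_effect)) for r in results]
        assert keys == sorted(keys)

    def test_writer_emits_complete_table(self, ref_benchmark, tmp_path):
        b = ref_benchmark
        ens = make_ensemble(b.net, 5, seed=2)
        results = tn.interference_screen(
            b.net, ens, b.drugs["drug_A"],
            [b.cotreatments["antagonist_class"]], b.processes,
        )
        out = tmp_path / "interference.tsv"
        tn.write_interference_tsv(results, out, "drug_A")
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 1 + len(results)
        assert lines[0].split("\t")[0] == "drug"
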