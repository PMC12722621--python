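"""Exact McNemar tests and discrete (Tarone) Bonferroni-Holm control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import shortcut_audit as sa
from shortcut_audit.cnn import RunResult
from shortcut_audit.stats import PairedOutcome


def _run(true, pred, config="B2", sampling=0, init=0):
    n = len(true)
    return RunResult(
        config, sampling, init, 0, 0, True, 1.0, 0.1,
        [f"i{k}" for k in range(n)],
        np.asarray(true), np.asarray(pred), np.linspace(0, 1, n),
    )


class TestPairedOutcome:
    def test_identical_predictions_no_discordance(self):
        true = [1, 0, 1, 0]
        a = _run(true, [1, 0, 0, 0], "A2")
        b = _run(true, [1, 0, 0, 0], "B2")
        out = sa.paired_outcome(a, b)
        assert out.n01 == out.n10 == 0

    def test_fully_discordant(self):
        true = [1] * 10
        ref = _run(true, [1] * 10, "A2")
        alt = _run(true, [0] * 10, "B2")
        out = sa.paired_outcome(ref, alt)
        assert (out.n01, out.n10) == (10, 0)

    def test_hand_built_six_image_table(self):
        true = [1, 1, 1, 0, 0, 0]
        ref = _run(true, [1, 1, 1, 0, 1, 1], "A2")  # correct on 1,2,3,4
        alt = _run(true, [1, 0, 0, 0, 0, 1], "B2")  # correct on 1,4,5
        out = sa.paired_outcome(ref, alt)
        assert (out.n01, out.n10) == (2, 1)
        assert out.n11 + out.n01 + out.n10 + out.n00 == 6

    def test_scope_restricts_to_true_class(self):
        true = [1, 1, 0, 0]
        ref = _run(true, [1, 0, 0, 0], "A2")
        alt = _run(true, [0, 0, 0, 1], "B2")
        sens = sa.paired_outcome(ref, alt, "sensitivity")
        assert sens.n11 + sens.n01 + sens.n10 + sens.n00 == 2
        spec = sa.paired_outcome(ref, alt, "specificity")
        assert spec.n11 + spec.n01 + spec.n10 + spec.n00 == 2

    def test_different_image_sets_raise(self):
        a = _run([1, 0], [1, 0], "A2")
        b = _run([1, 0, 1], [1, 0, 1], "B2")
        with pytest.raises(ValueError, match="different test images"):
            sa.paired_outcome(a, b)


class TestMcNemarExact:
    def test_symmetric_discordance_capped_at_one(self):
        p, _ = sa.mcnemar_exact(PairedOutcome(5, 3, 3, 2))
        assert p == 1.0

    def test_hand_enumerated_example(self):
        # n01=1, n10=5: p = 2 * P(X <= 1), X ~ Bin(6, 1/2) = 2 * 7/64
        p, _ = sa.mcnemar_exact(PairedOutcome(0, 1, 5, 0))
        assert p == pytest.approx(0.21875)

    def test_no_discordance_p_one(self):
        p, support = sa.mcnemar_exact(PairedOutcome(10, 0, 0, 2))
        assert p == 1.0
        assert list(support) == [1.0]

    def test_agrees_with_binomial_enumeration_up_to_n12(self):
        """Oracle equivalence on every discordant table with n <= 12."""
        for n in range(1, 13):
            for n01 in range(n + 1):
                n10 = n - n01
                p, support = sa.mcnemar_exact(PairedOutcome(0, n01, n10, 0))
                k = min(n01, n10)
                # independent enumeration: sum the binomial pmf directly
                tail = sum(binom.pmf(j, n, 0.5) for j in range(k + 1))
                expected = min(1.0, 2.0 * tail)
                assert p == pytest.approx(expected, rel=1e-12)
                assert np.all(np.diff(support) > 0)
                assert support.min() == pytest.approx(min(1.0, 2.0 * 0.5**n))


class TestMcNemarProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n01=st.integers(0, 40), n10=st.integers(0, 40))
    def test_p_value_lies_in_its_own_support(self, n01, n10):
        p, support = sa.mcnemar_exact(PairedOutcome(0, n01, n10, 0))
        assert 0.0 < p <= 1.0
        assert np.any(np.isclose(support, p))
        # symmetry in the discordant counts
        p_swapped, _ = sa.mcnemar_exact(PairedOutcome(0, n10, n01, 0))
        assert p == p_swapped


class TestDiscreteHolm:
    def test_classical_holm_with_dense_supports(self):
        dense = np.array([1e-6, 1.0])
        tests = [(0.01, dense), (0.03, dense), (0.04, dense)]
        rejected = sa.discrete_holm(tests, alpha=0.05)
        assert rejected == [True, False, False]

    def test_tarone_excludes_unattainable_tests(self):
        # a test whose minimal attainable p is 0.5 (two discordant pairs)
        # can never be significant at 0.05 and must not count toward the
        # family size
        coarse = np.array([0.5, 1.0])
        fine = np.array([0.001, 1.0])
        rejected = sa.discrete_holm([(0.5, coarse), (0.03, fine)], alpha=0.05)
        assert rejected == [False, True]  # effective family size is 1

    def test_single_test(self):
        assert sa.discrete_holm([(0.04, np.array([0.001]))], alpha=0.05) == [True]

    def test_empty_family(self):
        assert sa.discrete_holm([], alpha=0.05) == []

    def test_rejects_superset_of_bonferroni(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.integers(1, 8)
            ps = rng.uniform(0, 0.2, size=m)
            tests = [(p, np.array([p / 10, 1.0])) for p in ps]
            holm = sa.discrete_holm(tests, alpha=0.05)
            bonf = [p <= 0.05 / m for p in ps]
            for h, b in zip(holm, bonf):
                assert h or not b

    def test_monotone_in_p(self):
        dense = np.array([1e-9, 1.0])
        tests = [(0.001, dense), (0.012, dense), (0.04, dense), (0.3, dense)]
        rejected = sa.discrete_holm(tests, alpha=0.05)
        # once a test is not rejected, no larger p is rejected either
        seen_accept = False
        for rej in [r for _, r in sorted(zip([t[0] for t in tests], rejected))]:
            if not rej:
                seen_accept = True
            assert not (seen_accept and rej)


class TestRunFamily:
    def _sessions(self, n_images=20, flip_alt=0):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 2, size=n_images)
        pred = true.copy()
        sessions = {}
        for cid in ("A2", "B2"):
            runs = []
            for s in range(2):
                for i in range(2):
                    p = pred.copy()
                    if cid == "B2" and flip_alt:
                        p[:flip_alt] = 1 - p[:flip_alt]
                    runs.append(_run(true, p, cid, s, i))
            sessions[cid] = runs
        return sessions

    def test_identical_models_nothing_significant(self):
        report = sa.run_family(self._sessions(), "A2")
        assert report.n_significant == 0
        assert all(t.p_value == 1.0 for t in report.tests)

    def test_family_size_combinatorics(self):
        report = sa.run_family(self._sessions(), "A2")
        # 1 alternative config x 4 aligned pairs x 3 metrics
        assert len(report.tests) == 12

    def test_large_disagreement_detected(self):
        report = sa.run_family(self._sessions(n_images=40, flip_alt=25), "A2")
        assert report.n_significant > 0

    def test_fwer_controlled_under_null(self):
        """Family-wise error rate under exchangeable null errors stays at
        or below the nominal level (Monte-Carlo over 500 replicates)."""
        rng = np.random.default_rng(2024)
        n_rep = 500
        n_images = 30
        fw_errors = 0
        for _ in range(n_rep):
            true = rng.integers(0, 2, size=n_images)
            sessions = {}
            for cid in ("A2", "B2"):
                runs = []
                for s in range(2):
                    for i in range(2):
                        correct = rng.random(n_images) < 0.8
                        pred = np.where(correct, true, 1 - true)
                        runs.append(_run(true, pred, cid, s, i))
                sessions[cid] = runs
            report = sa.run_family(sessions, "A2")
            fw_errors += report.n_significant > 0
        assert fw_errors / n_rep <= 0.07

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            sa.run_family({"B2": []}, "A2")
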