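import numpy as np
import pytest

from bmsf.datamodel import ExpressionDataset, GeneSubset
from bmsf.filter import (
    AllGenesEliminatedError,
    InclusionScheme,
    TrainingCounter,
    count_trainings,
    evaluate_rows,
    filter_round,
    fit_surrogate,
    flip_column,
    generate_inclusion_scheme,
    make_schedule,
    pair_scores,
    run_filtering,
)
from bmsf.metrics import CVConfig
from bmsf.synthetic import SyntheticSpec, generate


class TestSchemeGeneration:
    def test_small_scheme_columns_balanced(self):
        scheme = generate_inclusion_scheme(4, GeneSubset(range(3)), seed=0)
        assert scheme.bits.shape == (4, 3)
        assert (scheme.bits.sum(axis=0) == 2).all()

    def test_large_scheme_columns_balanced(self):
        scheme = generate_inclusion_scheme(500, GeneSubset(range(2000)), seed=1)
        assert (scheme.bits.sum(axis=0) == 250).all()

    def test_odd_k_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_inclusion_scheme(5, GeneSubset(range(3)), seed=0)

    def test_unbalanced_bits_rejected(self):
        bad = np.array([[1, 1], [1, 0], [1, 1], [0, 0]])  # column 0 sums to 3
        with pytest.raises(ValueError, match="K/2"):
            InclusionScheme(bits=bad, column_map=(0, 1), seed=0)


class TestFlipColumn:
    def test_flip_complements_only_target(self):
        scheme = generate_inclusion_scheme(6, GeneSubset(range(4)), seed=2)
        flipped = flip_column(scheme, 1)
        np.testing.assert_array_equal(flipped.bits[:, 1], 1 - scheme.bits[:, 1])
        for c in (0, 2, 3):
            np.testing.assert_array_equal(flipped.bits[:, c], scheme.bits[:, c])
        assert (flipped.bits.sum(axis=0) == 3).all()

    def test_flip_is_involution(self):
        scheme = generate_inclusion_scheme(8, GeneSubset(range(5)), seed=3)
        twice = flip_column(flip_column(scheme, 2), 2)
        np.testing.assert_array_equal(twice.bits, scheme.bits)

    def test_out_of_range_rejected(self):
        scheme = generate_inclusion_scheme(4, GeneSubset(range(2)), seed=0)
        with pytest.raises(ValueError, match="out of range"):
            flip_column(scheme, 2)


class TestPairScores:
    def test_manual_k2_assignment(self):
        # column (0, 1): row 1 excludes the gene, row 2 includes it
        bits = np.array([[0], [1]])
        p = pair_scores(bits, [0.3, 0.5], [0.7, 0.9], col=0)
        np.testing.assert_allclose(p.Z0, [0.3, 0.9])
        np.testing.assert_allclose(p.Zi, [0.7, 0.5])

    def test_identical_phi_means_equal(self):
        bits = generate_inclusion_scheme(10, GeneSubset(range(3)), seed=4).bits
        phi = np.linspace(0, 1, 10)
        p = pair_scores(bits, phi, phi, col=1)
        assert p.Z0.mean() == pytest.approx(p.Zi.mean()) == pytest.approx(phi.mean())

    def test_partition_property(self):
        """Z0 and Zi jointly contain each phi0 and phi1 entry exactly once."""
        rng = np.random.default_rng(5)
        bits = generate_inclusion_scheme(20, GeneSubset(range(4)), seed=6).bits
        phi0, phi1 = rng.normal(size=20), rng.normal(size=20)
        for col in range(4):
            p = pair_scores(bits, phi0, phi1, col)
            combined = sorted(np.concatenate([p.Z0, p.Zi]))
            expected = sorted(np.concatenate([phi0, phi1]))
            np.testing.assert_allclose(combined, expected)


class TestSurrogate:
    def test_constant_response_predicts_constant(self):
        bits = generate_inclusion_scheme(20, GeneSubset(range(5)), seed=7).bits
        m = fit_surrogate(bits, np.full(20, 0.4))
        pred = m.predict(bits[:3].astype(float))
        np.testing.assert_allclose(pred, 0.4, atol=0.02)

    def test_linear_row_sum_response_fit(self):
        bits = generate_inclusion_scheme(40, GeneSubset(range(6)), seed=8).bits
        phi0 = bits.sum(axis=1) / 10.0
        m = fit_surrogate(bits, phi0)
        rmse = np.sqrt(np.mean((m.predict(bits.astype(float)) - phi0) ** 2))
        assert rmse < 0.01 + 0.05

    def test_prediction_deterministic(self):
        bits = generate_inclusion_scheme(30, GeneSubset(range(4)), seed=9).bits
        rng = np.random.default_rng(0)
        m = fit_surrogate(bits, rng.normal(size=30))
        row = bits[:1].astype(float)
        assert m.predict(row)[0] == m.predict(row)[0]


class TestEvaluateRows:
    def test_identical_rows_score_identically(self, separable_dataset):
        ds, _ = separable_dataset
        bits = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        scheme = InclusionScheme(bits=bits, column_map=(0, 5), seed=0)
        phi0 = evaluate_rows(ds, scheme, CVConfig(seed=1, n_folds=5))
        assert phi0[0] == phi0[1] and phi0[2] == phi0[3]

    def test_informative_rows_outscore_uninformative(self, separable_dataset):
        ds, _ = separable_dataset
        scheme = generate_inclusion_scheme(40, GeneSubset(range(8)), seed=10)
        phi0 = evaluate_rows(ds, scheme, CVConfig(seed=2, n_folds=5))
        has_signal = scheme.bits[:, 0] == 1  # gene 0 separates the classes
        assert phi0[has_signal].mean() > phi0[~has_signal].mean()

    def test_counter_counts_one_per_row(self, small_dataset):
        scheme = generate_inclusion_scheme(10, GeneSubset(range(5)), seed=11)
        counter = TrainingCounter()
        evaluate_rows(small_dataset, scheme, CVConfig(seed=0, n_folds=5), counter)
        assert counter.classification == 10


class TestFilterRound:
    def test_tie_keeps_gene(self):
        """A gene whose flipped predictions equal its originals is kept."""
        bits = generate_inclusion_scheme(10, GeneSubset(range(3)), seed=12).bits
        phi0 = np.full(10, 0.5)
        p = pair_scores(bits, phi0, phi0, col=0)
        assert not (p.Z0.mean() > p.Zi.mean())

    def test_round_budget_is_k_plus_one_svr(self, separable_dataset):
        ds, _ = separable_dataset
        counter = TrainingCounter()
        filter_round(
            ds, GeneSubset(range(8)), K=10, seed=13, cfg=CVConfig(seed=0), counter=counter
        )
        assert counter.classification == 10
        assert counter.regression == 1

    def test_survivors_partition_inputs(self, separable_dataset):
        ds, _ = separable_dataset
        genes = GeneSubset(range(8))
        rec = filter_round(ds, genes, K=20, seed=14, cfg=CVConfig(seed=0))
        assert sorted(rec.eliminated + rec.survivors) == list(range(8))
        assert set(rec.eliminated).isdisjoint(rec.survivors)


class TestRunFiltering:
    def test_revert_on_mu_drop(self, monkeypatch, small_dataset):
        """When the checkpoint drops after a round, the pre-round set wins."""
        import bmsf.filter as fmod

        # checkpoint oracle keyed on subset size: 5 genes -> 0.8, fewer -> 0.5
        def fake_cv_mcc(dataset, subset, cfg):
            return 0.8 if len(subset) == 5 else 0.5

        monkeypatch.setattr(fmod, "cv_mcc", fake_cv_mcc)

        def fake_round(dataset, genes, K, seed, cfg, counter=None, svr_params=None, round_index=1):
            idx = list(genes.indices)
            return fmod.RoundRecord(
                round_index=round_index,
                K_used=K,
                phi0=np.zeros(K),
                eliminated=idx[3:],
                survivors=idx[:3],
                mu_before=float("nan"),
                mu_after=float("nan"),
            )

        monkeypatch.setattr(fmod, "filter_round", fake_round)
        survivors, records = fmod.run_filtering(small_dataset, seed=0)
        assert list(survivors.indices) == list(range(5))  # pre-round set
        assert len(records) == 1

    def test_schedule_formula(self):
        assert make_schedule(6) == [500, 450, 400, 350, 300, 300]
        assert make_schedule(15)[:4] == [500, 450, 400, 350]
        assert make_schedule(15)[4:] == [300] * 11

    def test_seeded_determinism(self):
        ds, _ = generate(SyntheticSpec(n_per_class=10, n_genes=30, seed=5))
        kw = dict(schedule=[20, 20], seed=3, cfg=CVConfig(seed=3))
        s1, _ = run_filtering(ds, **kw)
        s2, _ = run_filtering(ds, **kw)
        assert s1.indices == s2.indices

    def test_monotone_gene_counts(self):
        ds, _ = generate(SyntheticSpec(n_per_class=10, n_genes=30, seed=6))
        _, records = run_filtering(
            ds, schedule=[20, 20, 20], seed=4, cfg=CVConfig(seed=4),
            stop_on_no_improvement=False,
        )
        for rec in records:
            assert set(rec.survivors) <= set(rec.survivors) | set(rec.eliminated)
            assert len(rec.survivors) <= len(rec.eliminated) + len(rec.survivors)
        for a, b in zip(records, records[1:]):
            assert set(b.survivors) | set(b.eliminated) == set(a.survivors)


class TestCountTrainings:
    def test_colon_schedule_totals(self):
        budget = count_trainings([500, 450, 400, 350] + [300] * 11)
        assert budget.classification == 5001
        assert budget.regression == 15
        assert budget.total == 5016

    def test_single_round(self):
        budget = count_trainings([300])
        assert (budget.classification, budget.regression, budget.total) == (301, 1, 302)

    def test_empty_schedule_counts_initial_evaluation(self):
        budget = count_trainings([])
        assert (budget.classification, budget.regression, budget.total) == (1, 0, 1)

    def test_odd_k_rejected(self):
        with pytest.raises(ValueError, match="even"):
            count_trainings([301])
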