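import numpy as np
import pandas as pd
import pytest

from gwpred import (
    PhenotypeTable,
    predictive_ability,
    run_cv,
    simulate_genotypes,
    simulate_trait,
    tukey_kramer_cld,
    tukey_kramer_pairwise,
)
from gwpred.cv import CvResultTable, make_model


class LinearStub:
    """Deterministic fast model: projects validation dosages on a fixed vector."""

    def __init__(self, name="stub", scale=1.0):
        self.name = name
        self.scale = scale

    def fit_predict(self, G_train, y_train, G_valid):
        w = np.sin(np.arange(G_valid.n_markers))
        return self.scale * (G_valid.dosage @ w)


class SplitRecorder:
    def __init__(self, name):
        self.name = name
        self.splits = []

    def fit_predict(self, G_train, y_train, G_valid):
        self.splits.append((tuple(G_train.sample_ids), tuple(G_valid.sample_ids)))
        return np.asarray(G_valid.dosage[:, 0], dtype=float)


class TestPredictiveAbility:
    def test_perfect_and_anti_correlation(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert predictive_ability(obs, obs) == pytest.approx(1.0)
        assert predictive_ability(obs, -obs) == pytest.approx(-1.0)

    def test_constant_prediction_gives_missing_sentinel(self):
        out = predictive_ability(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert np.isnan(out)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            predictive_ability(np.zeros(2), np.zeros(2))


@pytest.fixture(scope="module")
def cv_panel():
    G = simulate_genotypes(60, 40, seed=40)
    y, _ = simulate_trait(G, n_qtl=5, h2a=0.5, seed=41)
    return G, y


class TestRunCv:
    @pytest.mark.parametrize("n,expected_train", [(322, 290), (646, 581)])
    def test_split_sizes_match_study_populations(self, n, expected_train):
        G = simulate_genotypes(n, 30, seed=42)
        y, _ = simulate_trait(G, n_qtl=3, h2a=0.5, seed=43)
        res = run_cv([LinearStub()], G, y, n_cycles=2, seed=0)
        assert set(res.table["train_n"]) == {expected_train}
        assert set(res.table["valid_n"]) == {n - expected_train}

    def test_splits_are_partitions_and_shared_across_models(self, cv_panel):
        G, y = cv_panel
        rec1, rec2 = SplitRecorder("a"), SplitRecorder("b")
        run_cv([rec1, rec2], G, y, n_cycles=3, seed=1)
        assert rec1.splits == rec2.splits  # paired design
        for tr, va in rec1.splits:
            assert not set(tr) & set(va)
            assert set(tr) | set(va) == set(G.sample_ids)

    def test_seeded_reproducibility(self, cv_panel):
        G, y = cv_panel
        a = run_cv([LinearStub()], G, y, n_cycles=3, seed=5)
        b = run_cv([LinearStub()], G, y, n_cycles=3, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_constant_predictor_warns_and_records_missing(self, cv_panel):
        G, y = cv_panel

        class Constant:
            name = "const"

            def fit_predict(self, G_train, y_train, G_valid):
                return np.zeros(G_valid.n_samples)

        with pytest.warns(UserWarning, match="constant predictions"):
            res = run_cv([Constant()], G, y, n_cycles=2, seed=2)
        assert res.table["pa"].isna().all()

    def test_identical_models_share_one_letter(self, cv_panel):
        G, y = cv_panel
        res = run_cv([LinearStub("m1"), LinearStub("m2")], G, y, n_cycles=5, seed=3)
        cld = tukey_kramer_cld(res)
        letters = cld[y.trait]
        assert letters["m1"] == letters["m2"] == "a"

    def test_unknown_model_name_rejected(self, cv_panel):
        G, y = cv_panel
        with pytest.raises(ValueError, match="unknown model"):
            run_cv(["nonsense"], G, y, n_cycles=2)


class TestTukeyKramer:
    def test_clearly_separated_means_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        values = {
            "low": rng.normal(0.1, 0.01, 50),
            "high": rng.normal(0.7, 0.01, 50),
        }
        table, _ = tukey_kramer_pairwise(values)
        assert table["significant"].all()
        df = pd.DataFrame(
            [
                {"model": g, "trait": "t", "cycle": i, "pa": v}
                for g, vals in values.items()
                for i, v in enumerate(vals)
            ]
        )
        letters = tukey_kramer_cld(df)["t"]
        assert letters["low"] != letters["high"]

    def test_decisions_match_statsmodels_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        for trial in range(5):
            k = rng.integers(3, 6)
            values = {
                f"g{i}": rng.normal(rng.uniform(0, 0.5), 0.1, int(rng.integers(10, 30)))
                for i in range(k)
            }
            ours, _ = tukey_kramer_pairwise(values, alpha=0.05)
            flat = np.concatenate(list(values.values()))
            labels = np.concatenate([[g] * len(v) for g, v in values.items()])
            sm = pairwise_tukeyhsd(flat, labels, alpha=0.05)
            sm_pairs = {
                frozenset((sm.groupsunique[i], sm.groupsunique[j])): bool(r)
                for (i, j), r in zip(
                    [(i, j) for i in range(k) for j in range(i + 1, k)],
                    sm.reject,
                )
            }
            for row in ours.itertuples():
                key = frozenset((row.group1, row.group2))
                assert row.significant == sm_pairs[key], f"trial {trial}, {key}"

    def test_q_statistic_matches_brute_force(self):
        from scipy.stats import studentized_range

        rng = np.random.default_rng(11)
        values = {g: rng.normal(i * 0.1, 0.2, 20) for i, g in enumerate("abcd")}
        ours, means = tukey_kramer_pairwise(values, alpha=0.05)
        arrs = {g: np.asarray(v) for g, v in values.items()}
        N = sum(len(v) for v in arrs.values())
        mse = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / (N - 4)
        qc = studentized_range.ppf(0.95, 4, N - 4)
        for row in ours.itertuples():
            v1, v2 = arrs[row.group1], arrs[row.group2]
            q = abs(v1.mean() - v2.mean()) / np.sqrt(
                mse / 2 * (1 / len(v1) + 1 / len(v2))
            )
            assert row.q == pytest.approx(q)
            assert row.significant == (q > qc)

    def test_zero_variance_rejected(self):
        values = {"a": np.ones(5), "b": np.ones(5)}
        with pytest.raises(ValueError, match="zero within-group"):
            tukey_kramer_pairwise(values)

    def test_summary_includes_letters(self, cv_panel):
        G, y = cv_panel
        res = run_cv([LinearStub("m1"), LinearStub("m2", scale=-1.0)], G, y, n_cycles=4, seed=9)
        summ = res.summary()
        assert {"mean_pa", "sd_pa", "letters"} <= set(summ.columns)


def test_make_model_covers_all_names():
    names = ["GBLUP", "RKHS", "BRR", "BL", "BayesA", "BayesB", "BayesCpi"]
    names += [f"brnn{i}" for i in range(1, 11)] + [f"lstm{i}" for i in range(1, 7)]
    for n in names:
        m = make_model(n)
        assert hasattr(m, "fit_predict") and m.name == n
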