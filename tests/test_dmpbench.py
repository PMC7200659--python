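import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memsig.dmpbench import (
    ClassifierReport,
    benchmark_compare,
    fisher_caller,
    pooled_counts,
    rms_caller,
    rms_statistic,
    sd_caller,
    validate_dmps,
    wald_caller,
)
from tests.conftest import five_vs_five_manifest
from tests.test_bsio import make_table


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability does
    not exceed the observed table's."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(x):
        return (
            stats.hypergeom.pmf(x, n, row1, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


def pooled_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "m_c", "u_c", "m_t", "u_t"])
    df["diff"] = df["m_t"] / (df["m_t"] + df["u_t"]) - df["m_c"] / (df["m_c"] + df["u_c"])
    return df


class TestFisherCaller:
    def test_hand_example_called(self):
        pooled = pooled_frame([("Chr1", 1, "+", "CG", 2, 8, 8, 2)])
        out = fisher_caller(pooled)
        assert len(out) == 1
        assert out["p"].iloc[0] == pytest.approx(0.023, abs=0.001)

    def test_identical_proportions_not_called(self):
        pooled = pooled_frame([("Chr1", 1, "+", "CG", 5, 5, 5, 5)])
        assert len(fisher_caller(pooled)) == 0

    def test_small_diff_not_called_despite_significance(self):
        pooled = pooled_frame([("Chr1", 1, "+", "CG", 100, 400, 200, 300)])
        # diff = 0.2 < 0.25 even though the Fisher p is tiny
        assert stats.fisher_exact([[100, 400], [200, 300]])[1] < 0.05
        assert len(fisher_caller(pooled)) == 0

    def test_p_matches_enumeration_for_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            p_scipy = stats.fisher_exact([[a, b], [c, d]])[1]
            p_enum = fisher_p_enumeration(int(a), int(b), int(c), int(d))
            assert p_scipy == pytest.approx(p_enum, abs=1e-9)


class TestWaldCaller:
    def build(self, ctrl_levels, treat_levels, cov=30):
        from memsig.bsio import SampleManifest

        rows = [(f"C{i}", "control", 1, "WT") for i in range(len(ctrl_levels))] + [
            (f"T{i}", "treatment", 1, "MM") for i in range(len(treat_levels))
        ]
        man = SampleManifest(
            pd.DataFrame(rows, columns=["sample_id", "group", "generation", "phenotype"])
        )
        tables = {}
        for (sid, *_), lvl in zip(rows, list(ctrl_levels) + list(treat_levels)):
            m = int(round(lvl * cov))
            tables[sid] = make_table([("Chr1", 1, "+", "CG", m, cov - m)], sid)
        return tables, man

    def test_equal_means_not_called(self):
        tables, man = self.build([0.5, 0.5, 0.5], [0.5, 0.5])
        assert len(wald_caller(tables, man)) == 0

    def test_strong_separation_called_with_floor(self):
        # zero empirical variance: without the binomial floor z would be infinite
        tables, man = self.build([0.1, 0.1, 0.1], [0.9, 0.9, 0.9])
        out = wald_caller(tables, man)
        assert len(out) == 1
        assert out["p"].iloc[0] < 1e-4
        assert np.isfinite(out["p"].iloc[0])

    def test_single_replicate_is_error(self):
        tables, man = self.build([0.5], [0.5, 0.5])
        man = type(man)(man.entries.iloc[:3])
        with pytest.raises(ValueError):
            wald_caller({k: tables[k] for k in man.samples()}, man)


class TestRmsCaller:
    def test_independence_table_stat_zero_p_one(self):
        assert rms_statistic([[25, 25], [25, 25]]) == 0.0
        pooled = pooled_frame([("Chr1", 1, "+", "CG", 25, 25, 25, 25)])
        out = rms_caller(pooled, n_mc=200, seed=0, diff_min=-1.0, p_max=1.1)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_transpose_invariance(self):
        t = np.array([[8, 2], [5, 15]])
        assert rms_statistic(t) == pytest.approx(rms_statistic(t.T))

    def test_mc_p_close_to_exhaustive_enumeration(self):
        # all 2x2 tables with total n=20 under multinomial independence null
        obs = np.array([[8, 2], [2, 8]], dtype=float)
        n = 20
        pi = obs / n
        indep = np.outer(pi.sum(axis=1), pi.sum(axis=0)).ravel()
        stat_obs = rms_statistic(obs)
        p_exact = 0.0
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    t = np.array([[a, b], [c, d]], dtype=float)
                    if rms_statistic(t) >= stat_obs - 1e-12:
                        p_exact += stats.multinomial.pmf([a, b, c, d], n, indep)
        pooled = pooled_frame([("Chr1", 1, "+", "CG", 8, 2, 2, 8)])
        out = rms_caller(pooled, n_mc=4000, seed=1, p_max=1.1)
        p_mc = out["p"].iloc[0]
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc - p_exact) < 2 * se + 2 / 4000


class TestSdCaller:
    def test_delegates_to_pipeline(self, study, gen1_call):
        manifest, res = gen1_call
        _, tables = study.comparison(1, "WT", "MM")
        sites, result = sd_caller(tables, manifest, diff_min=0.2)
        expected = res.consensus_sites()
        assert set(map(tuple, sites[["chrom", "pos", "strand"]].to_numpy())) == set(
            map(tuple, expected[["chrom", "pos", "strand"]].to_numpy())
        )


def separable_frame(n=300, seed=0, permute=False):
    rng = np.random.default_rng(seed)
    half = n // 2
    df = pd.DataFrame(
        {
            "hd": np.r_[rng.normal(10, 1, half), rng.normal(1, 0.3, half)],
            "abs_tv": np.r_[rng.uniform(0.4, 0.8, half), rng.uniform(0.0, 0.1, half)],
            "log2_cov": rng.normal(5, 0.2, n),
            "is_cg": rng.integers(0, 2, n).astype(float),
            "is_chg": 0.0,
            "group": ["treatment"] * half + ["control"] * half,
            "sample_id": ["t1"] * half + ["c1"] * half,
        }
    )
    if permute:
        df["group"] = rng.permutation(df["group"].to_numpy())
    return df


class TestValidateDmps:
    def test_separable_data_is_perfect(self):
        r = validate_dmps(separable_frame(), n_boot=99, seed=0)
        assert r.accuracy == 1.0
        assert r.fdr == 0.0

    def test_permuted_labels_near_chance(self):
        r = validate_dmps(separable_frame(permute=True, seed=3), n_boot=199, seed=0)
        lo, hi = r.ci["accuracy"]
        assert lo <= 0.5 <= hi or abs(r.accuracy - 0.5) < 0.1

    def test_metrics_match_confusion_matrix_oracle(self):
        # recompute from an independent tally of predictions
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        df = separable_frame(seed=5, permute=True)
        r = validate_dmps(df, n_boot=9, seed=7)
        X = df[["hd", "abs_tv", "log2_cov", "is_cg", "is_chg"]].to_numpy()
        y = (df["group"] == "treatment").to_numpy(int)
        X_tr, X_te, y_tr, y_te = train_test_split(X, y, train_size=0.6, stratify=y, random_state=7)
        clf = make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=1000)).fit(X_tr, y_tr)
        yp = clf.predict(X_te)
        tp = int(((y_te == 1) & (yp == 1)).sum()); tn = int(((y_te == 0) & (yp == 0)).sum())
        fp = int(((y_te == 0) & (yp == 1)).sum()); fn = int(((y_te == 1) & (yp == 0)).sum())
        assert r.accuracy == pytest.approx((tp + tn) / len(y_te))
        assert r.sensitivity == pytest.approx(tp / (tp + fn))
        assert r.specificity == pytest.approx(tn / (tn + fp))
        assert r.fdr == pytest.approx(fp / (tp + fp) if tp + fp else 0.0)

    def test_invariant_to_row_order(self):
        df = separable_frame(seed=2)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = validate_dmps(df, n_boot=9, seed=0)
        r2 = validate_dmps(shuffled, n_boot=9, seed=0)
        assert r1.accuracy == pytest.approx(r2.accuracy)

    def test_single_class_is_error(self):
        df = separable_frame()
        df["group"] = "treatment"
        with pytest.raises(ValueError):
            validate_dmps(df)


class TestBenchmarkCompare:
    def report(self, name, acc):
        return ClassifierReport(name, acc, 0.9, 0.9, 0.05, 10)

    def test_ties_keep_input_order(self):
        out = benchmark_compare([self.report("a", 0.9), self.report("b", 0.9)])
        assert list(out["method"]) == ["a", "b"]

    def test_sorted_by_accuracy(self):
        out = benchmark_compare([self.report("a", 0.8), self.report("b", 0.95)])
        assert list(out["method"]) == ["b", "a"]

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            benchmark_compare([])


class TestNullErrorControl:
    def test_all_callers_control_false_positives_on_null_data(self):
        """On null data (no effects, no spontaneous events) each caller's
        site-level false-positive rate stays within 2x the nominal 5%."""
        from memsig.synthdata import build_toy_genome, simulate_counts
        from tests.test_synthdata import null_config

        cfg = null_config(seed=42)
        ann = build_toy_genome(cfg)
        man = five_vs_five_manifest()
        tables, _ = simulate_counts(ann, cfg, man)
        pooled = pooled_counts(tables, man)
        n_sites = len(pooled)
        sd_sites, _ = sd_caller(tables, man, diff_min=0.25)
        rates = {
            "fisher": len(fisher_caller(pooled)) / n_sites,
            "wald": len(wald_caller(tables, man)) / n_sites,
            "rms": len(rms_caller(pooled, n_mc=500, seed=0)) / n_sites,
            "sd": len(sd_sites) / n_sites,
        }
        for name, rate in rates.items():
            assert rate <= 0.10, f"{name} fpr={rate}"
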