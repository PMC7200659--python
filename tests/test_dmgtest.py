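import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memsig.bsio import GenomicAnnotation
from memsig.dmgtest import (
    GeneCountMatrix,
    bh_adjust,
    count_dmps_per_region,
    density_filter,
    glm_count_test,
    heritable_set,
    recurrence_closed_form,
    recurrence_simulation,
    te_proximity_enrichment,
)


def bh_oracle(p):
    """Independent step-up implementation of the BH definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@pytest.fixture
def annotation():
    feats = pd.DataFrame(
        {
            "chrom": ["Chr1", "Chr1", "Chr1"],
            "start": [2000, 3500, 9000],
            "end": [4000, 4100, 9300],
            "strand": ["+", "+", "+"],
            "feature_id": ["geneA", "te1", "geneB"],
            "feature_class": ["genic", "TE_related", "genic"],
        }
    )
    return GenomicAnnotation(feats, {"Chr1": 20_000})


class TestCountMatrix:
    def test_counts_respect_extended_boundaries(self, annotation):
        dmps = pd.DataFrame(
            {
                "chrom": "Chr1",
                "pos": [1500, 4999, 999, 5001],  # geneA extended region is [1000, 5000]
                "sample_id": "A",
            }
        )
        m = count_dmps_per_region(dmps, annotation, sample_ids=["A"])
        assert m.counts.loc["geneA", "A"] == 2

    def test_no_dmps_gives_zero_matrix(self, annotation):
        dmps = pd.DataFrame({"chrom": [], "pos": [], "sample_id": []})
        m = count_dmps_per_region(dmps, annotation, sample_ids=["A", "B"])
        assert (m.counts.to_numpy() == 0).all()


class TestDensityFilter:
    def matrix(self, counts):
        c = pd.DataFrame({f"s{i}": [v] for i, v in enumerate(counts)}, index=["g"])
        return GeneCountMatrix(c, pd.Series([4.0], index=["g"]))

    @pytest.mark.parametrize(
        "counts, kept",
        [((12, 11, 10, 13), True), ((12, 9, 11, 13), False), ((10, 10, 10, 10), True)],
    )
    def test_each_sample_scope_with_4kb_region(self, counts, kept):
        # threshold is 2.5/kb * 4 kb = 10, boundary included ("at least")
        out = density_filter(self.matrix(counts), scope="each_sample")
        assert (out == ["g"]) == kept

    def test_any_sample_scope(self):
        assert density_filter(self.matrix((0, 0, 0, 12)), scope="any_sample") == ["g"]


class TestGlmCountTest:
    def groups(self, n_c, n_t):
        g = {f"c{i}": "control" for i in range(n_c)}
        g.update({f"t{i}": "treatment" for i in range(n_t)})
        return g

    def matrix(self, ctrl, treat, region_kb=1.0):
        data = {f"c{i}": [v] for i, v in enumerate(ctrl)}
        data.update({f"t{i}": [v] for i, v in enumerate(treat)})
        return GeneCountMatrix(pd.DataFrame(data, index=["g"]), pd.Series([region_kb], index=["g"]))

    def test_hand_example_poisson_wald(self):
        # 2,2,2 vs 8,8,8: log2fc exactly 2; Wald z = ln4 / sqrt(1/6 + 1/24)
        m = self.matrix([2, 2, 2], [8, 8, 8])
        out = glm_count_test(m, self.groups(3, 3), min_density=0.0)
        row = out.iloc[0]
        assert row["log2fc"] == pytest.approx(2.0)
        z = np.log(4) / np.sqrt(1 / 6 + 1 / 24)
        p_expected = 2 * stats.norm.sf(z)
        assert row["p"] == pytest.approx(p_expected, rel=1e-3)
        assert row["model_used"] == "poisson"

    def test_poisson_branch_close_to_exact_conditional_test(self):
        # exact two-sample Poisson rate test: binomial on the treatment total.
        # The Wald p tracks the exact conditional p closely where decisions
        # are made (small p) and within normal-approximation error elsewhere.
        rng = np.random.default_rng(0)
        for _ in range(10):
            ctrl = rng.poisson(8, size=3) + 1
            treat = rng.poisson(24, size=3) + 1
            m = self.matrix(list(ctrl), list(treat))
            out = glm_count_test(m, self.groups(3, 3), min_density=0.0, mv_rate=0.0)
            total = int(ctrl.sum() + treat.sum())
            p_exact = stats.binomtest(int(treat.sum()), total, 0.5).pvalue
            p_wald = out.iloc[0]["p"]
            assert abs(p_wald - p_exact) <= max(0.005, 0.75 * p_exact)

    def test_identical_groups_not_dmg(self):
        m = self.matrix([5, 5, 5], [5, 5, 5])
        out = glm_count_test(m, self.groups(3, 3), min_density=0.0)
        assert out.iloc[0]["log2fc"] == 0.0
        assert out.iloc[0]["p"] > 0.9
        assert not out.iloc[0]["is_dmg"]

    def test_overdispersed_counts_use_negative_binomial(self):
        m = self.matrix([1, 30, 2, 25], [2, 40, 1, 35])
        out = glm_count_test(m, self.groups(4, 4), min_density=0.0)
        assert out.iloc[0]["model_used"] == "negbinomial"

    def test_separated_gene_uses_exact_fallback(self):
        m = self.matrix([0, 0, 0], [9, 11, 10])
        out = glm_count_test(m, self.groups(3, 3), min_density=0.0)
        row = out.iloc[0]
        assert row["model_used"] == "exact_poisson"
        assert row["p"] < 1e-6
        assert row["log2fc"] == pytest.approx(np.log2(10.5 / 0.5))


class TestBH:
    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))


class TestHeritableSet:
    def test_intersection_and_recurrence(self):
        inter, rec = heritable_set([{"A", "B", "C"}, {"A", "B"}, {"A", "C"}])
        assert inter == {"A"}
        assert rec.to_dict() == {"A": 3, "B": 2, "C": 2}
        assert rec.value_counts().sum() == 3  # sum over k of genes-with-count-k = |union|

    def test_disjoint_lists(self):
        inter, rec = heritable_set([{"A"}, {"B"}])
        assert inter == set()
        assert set(rec.index) == {"A", "B"}

    def test_repeated_list_is_identity(self):
        inter, _ = heritable_set([{"A", "B"}, {"A", "B"}])
        assert inter == {"A", "B"}


def poisson_binomial_oracle(universe, sizes):
    """P(first-list gene in >= k lists) by enumeration over the 2^(L-1)
    membership patterns of the other lists."""
    probs = [n / universe for n in sizes[1:]]
    out = {}
    for k in range(2, len(sizes) + 1):
        total = 0.0
        for pattern in itertools.product([0, 1], repeat=len(probs)):
            if 1 + sum(pattern) >= k:
                pr = 1.0
                for bit, p in zip(pattern, probs):
                    pr *= p if bit else (1 - p)
                total += pr
        out[k] = total
    return out


class TestRecurrence:
    def test_two_half_lists_expect_half(self):
        r = recurrence_simulation(10, [5, 5], reps=3000, seed=0)
        assert r.fraction_in_ge_k[2] == pytest.approx(0.5, abs=0.02)

    def test_three_half_lists_expect_three_quarters(self):
        r = recurrence_simulation(10, [5, 5, 5], reps=3000, seed=1)
        assert r.fraction_in_ge_k[2] == pytest.approx(0.75, abs=0.02)

    def test_closed_form_matches_enumeration_oracle(self):
        sizes = [6925, 5148, 5603, 7231, 7704, 6050]
        cf = recurrence_closed_form(27655, sizes)
        oracle = poisson_binomial_oracle(27655, sizes)
        for k in cf:
            assert cf[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_simulation_converges_to_closed_form(self):
        sizes = [6925, 5148, 5603, 7231, 7704, 6050]
        cf = recurrence_closed_form(27655, sizes)
        r = recurrence_simulation(27655, sizes, reps=200, seed=3)
        for k in (4, 5):
            se = np.sqrt(cf[k] * (1 - cf[k]) / (sizes[0] * 200))
            assert abs(r.fraction_in_ge_k[k] - cf[k]) < 5 * se

    def test_chi2_rejects_enriched_recurrence(self):
        observed = np.array([500, 300, 150, 40, 9, 1], dtype=float)
        r = recurrence_simulation(1000, [200] * 6, reps=50, seed=0, observed_hist=observed)
        assert r.chi2_p < 1e-6

    def test_oversized_list_is_error(self):
        with pytest.raises(ValueError):
            recurrence_simulation(10, [11], reps=1)


class TestTeProximity:
    @pytest.fixture
    def annotation(self):
        feats = pd.DataFrame(
            {
                "chrom": ["Chr1"] * 4,
                "start": [5000, 3500, 20000, 30000],
                "end": [6000, 4100, 21000, 30500],
                "strand": ["+"] * 4,
                "feature_id": ["geneNear", "te1", "geneFar", "te2"],
                "feature_class": ["genic", "TE_related", "genic", "TE_related"],
            }
        )
        return GenomicAnnotation(feats, {"Chr1": 50_000})

    def test_gap_boundaries(self, annotation):
        # geneNear: gap to te1 = 5000 - 4100 - 1 = 899 <= 1000 -> proximal
        # geneFar: nearest TE gap = 30000 - 21000 - 1 = 8999 -> not proximal
        table, _, _ = te_proximity_enrichment({"geneNear"}, annotation)
        assert table[0, 0] == 1 and table[0, 1] == 0
        table, _, _ = te_proximity_enrichment({"geneFar"}, annotation)
        assert table[0, 0] == 0 and table[0, 1] == 1

    def test_empty_set_is_error(self, annotation):
        with pytest.raises(ValueError):
            te_proximity_enrichment(set(), annotation)
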