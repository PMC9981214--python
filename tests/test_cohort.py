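"""Cohort statistics, with exact enumeration oracles for the rank methods."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from xenopurity.cohort import (
    BALBC_NUDE,
    NOD_SCID,
    TumorSample,
    balanced_strain_subset,
    cancer_purity_summary,
    early_late_pairing,
    load_syngeneic_table,
    purity_mutation_correlation,
    rank_sum_test,
    strain_comparison,
    within_between_differences,
)


def sample(sid, model="m1", cancer="CR", strain=NOD_SCID, passage=1, purity=0.8):
    return TumorSample(sid, model, cancer, strain, passage, purity)


# ------------------------------------------------- brute-force oracles


def mwu_oracle(x, y):
    """Exact permutation Mann-Whitney U and two-sided p by full enumeration."""

    def ustat(a, b):
        return sum((i > j) + 0.5 * (i == j) for i in a for j in b)

    u_obs = ustat(x, y)
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(ustat(a, b) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


def spearman_oracle(x, y):
    """Spearman rho from average ranks, computed from first principles."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestRankOracles:
    def test_rank_sum_matches_enumeration_on_small_inputs(self, rng):
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            # tie-free inputs: exact enumeration and scipy's exact method agree
            pooled = rng.permutation(100)[: n1 + n2].astype(float)
            x, y = list(pooled[:n1]), list(pooled[n1:])
            u, p = rank_sum_test(x, y)
            u_oracle, p_oracle = mwu_oracle(x, y)
            assert u == pytest.approx(u_oracle)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_spearman_matches_first_principles_with_ties(self, rng):
        from scipy.stats import spearmanr

        for _ in range(30):
            n = int(rng.integers(4, 9))
            x = list(rng.integers(0, 5, n).astype(float))
            y = list(rng.integers(0, 5, n).astype(float))
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearmanr(x, y).statistic == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestWithinBetween:
    def test_identical_samples_give_zero_within_difference(self):
        samples = [
            sample("a", model="m1", purity=0.8),
            sample("b", model="m1", purity=0.8),
            sample("c", model="m2", purity=0.6),
            sample("d", model="m2", purity=0.7),
        ]
        res = within_between_differences(samples)
        assert 0.0 in res.within
        assert res.median_between > 0

    def test_two_variance_cohort_orders_medians(self, rng):
        # model-level means sd 0.12, within-model sd 0.05: between-model
        # differences must dominate
        samples = []
        for m in range(12):
            mean = float(np.clip(0.8 + rng.normal(0, 0.12), 0.05, 0.95))
            for k in range(4):
                p = float(np.clip(mean + rng.normal(0, 0.05), 0, 1))
                samples.append(sample(f"m{m}k{k}", model=f"m{m}", passage=2, purity=p))
        res = within_between_differences(samples)
        assert res.median_between > res.median_within
        assert res.p_value < 0.05

    def test_pairs_require_identical_passage(self):
        samples = [sample("a", passage=1), sample("b", passage=2)]
        with pytest.raises(ValueError):
            within_between_differences(samples)

    def test_single_model_is_an_error(self):
        samples = [sample("a", purity=0.7), sample("b", purity=0.8)]
        with pytest.raises(ValueError):
            within_between_differences(samples)


class TestEarlyLate:
    def make_models(self, shift=0.01, n=10):
        samples = []
        for m in range(n):
            base = 0.5 + 0.04 * m
            samples.append(sample(f"e{m}", model=f"m{m}", passage=1, purity=base))
            samples.append(sample(f"l{m}", model=f"m{m}", passage=5, purity=base + shift))
        return samples

    def test_exact_shift_gives_perfect_correlation(self):
        res = early_late_pairing(self.make_models(shift=0.01))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.mean_diff == pytest.approx(0.01)

    def test_same_sample_never_used_twice(self):
        # models whose samples all sit at one passage: the two draws must
        # still be distinct samples
        samples = []
        for m in range(5):
            samples.append(sample(f"a{m}", model=f"m{m}", passage=3, purity=0.6 + 0.02 * m))
            samples.append(sample(f"b{m}", model=f"m{m}", passage=3, purity=0.7 + 0.02 * m))
        res = early_late_pairing(samples, seed=1)
        assert np.all(res.early != res.late)

    def test_independent_purities_give_near_zero_correlation(self, rng):
        samples = []
        for m in range(60):
            samples.append(
                sample(f"e{m}", model=f"m{m}", passage=1, purity=float(rng.uniform(0.3, 1)))
            )
            samples.append(
                sample(f"l{m}", model=f"m{m}", passage=6, purity=float(rng.uniform(0.3, 1)))
            )
        rs = [early_late_pairing(samples, seed=s).pearson_r for s in range(5)]
        assert abs(np.mean(rs)) < 0.3

    def test_seeded_choice_is_reproducible(self):
        samples = self.make_models() + [
            sample("extra", model="m0", passage=1, purity=0.99)
        ]
        a = early_late_pairing(samples, seed=7)
        b = early_late_pairing(samples, seed=7)
        assert np.all(a.early == b.early) and np.all(a.late == b.late)


class TestBalancedSubset:
    def make_cohort(self):
        samples = []
        for i in range(10):
            samples.append(sample(f"n{i}", model=f"nm{i}", cancer="CR", strain=NOD_SCID))
        for i in range(4):
            samples.append(sample(f"b{i}", model=f"bm{i}", cancer="CR", strain=BALBC_NUDE))
        for i in range(3):
            samples.append(sample(f"x{i}", model=f"xm{i}", cancer="PA", strain=NOD_SCID))
        return samples

    def test_min_rule(self):
        subset, composition = balanced_strain_subset(self.make_cohort(), seed=0)
        by_strain = {}
        for s in subset:
            by_strain.setdefault(s.strain, []).append(s)
        assert len(by_strain[NOD_SCID]) == len(by_strain[BALBC_NUDE]) == 4
        # PA absent from BALB/c nude: dropped entirely
        assert all(s.cancer == "CR" for s in subset)
        assert composition[NOD_SCID].sum() + composition[BALBC_NUDE].sum() == 8

    def test_already_balanced_input_kept_whole(self):
        samples = [
            sample("a", cancer="CR", strain=NOD_SCID),
            sample("b", cancer="CR", strain=BALBC_NUDE),
        ]
        subset, _ = balanced_strain_subset(samples, seed=0)
        assert sorted(s.sample_id for s in subset) == ["a", "b"]

    def test_no_overlapping_cancer_is_an_error(self):
        samples = [
            sample("a", cancer="CR", strain=NOD_SCID),
            sample("b", cancer="PA", strain=BALBC_NUDE),
        ]
        with pytest.raises(ValueError):
            balanced_strain_subset(samples, seed=0)

    def test_seeded_downsampling_reproducible(self):
        a, _ = balanced_strain_subset(self.make_cohort(), seed=3)
        b, _ = balanced_strain_subset(self.make_cohort(), seed=3)
        assert [s.sample_id for s in a] == [s.sample_id for s in b]


class TestStrainComparison:
    def make_shifted_cohort(self, rng, shift=0.07):
        samples = []
        for cancer in ["CR", "GA", "PA", "LU", "KI", "LI", "OV", "ES", "HN"]:
            base = float(rng.uniform(0.5, 0.9))
            for i in range(30):
                samples.append(
                    sample(
                        f"{cancer}n{i}", model=f"{cancer}nm{i}", cancer=cancer,
                        strain=NOD_SCID,
                        purity=float(np.clip(base + shift + rng.normal(0, 0.05), 0, 1)),
                    )
                )
                samples.append(
                    sample(
                        f"{cancer}b{i}", model=f"{cancer}bm{i}", cancer=cancer,
                        strain=BALBC_NUDE,
                        purity=float(np.clip(base + rng.normal(0, 0.05), 0, 1)),
                    )
                )
        return samples

    def test_shift_detected_in_pooled_medians(self, rng):
        res = strain_comparison(self.make_shifted_cohort(rng))
        diff = res.pooled_medians[NOD_SCID] - res.pooled_medians[BALBC_NUDE]
        assert diff == pytest.approx(0.07, abs=0.03)
        assert res.pooled_p < 0.01

    def test_per_cancer_medians_correlate_across_strains(self, rng):
        res = strain_comparison(self.make_shifted_cohort(rng))
        assert res.cross_strain_pearson_r > 0.8

    def test_identical_distributions_give_zero_median_difference(self):
        samples = []
        for i in range(10):
            for strain in (NOD_SCID, BALBC_NUDE):
                samples.append(
                    sample(f"{strain}{i}", model=f"m{strain}{i}", strain=strain, purity=0.1 * i + 0.05)
                )
        res = strain_comparison(samples)
        assert res.pooled_medians[NOD_SCID] == res.pooled_medians[BALBC_NUDE]


class TestCancerSummary:
    def test_min_n_boundary(self):
        samples = [sample(f"a{i}", model=f"m{i}", cancer="CR", purity=0.8) for i in range(20)]
        samples += [sample(f"b{i}", model=f"x{i}", cancer="PA", purity=0.6) for i in range(19)]
        table, _ = cancer_purity_summary(samples, min_n=20)
        assert table["cancer"].tolist() == ["CR"]

    def test_mean_of_medians(self):
        samples = [sample(f"a{i}", cancer="CR", purity=0.6) for i in range(20)]
        samples += [sample(f"b{i}", cancer="GA", purity=0.9) for i in range(20)]
        table, mean_of_medians = cancer_purity_summary(samples, min_n=20)
        assert mean_of_medians == pytest.approx(0.75)
        assert table.set_index("cancer")["median"].to_dict() == {"CR": 0.6, "GA": 0.9}

    def test_constant_purity_collapses_quartiles(self):
        samples = [sample(f"a{i}", cancer="CR", purity=0.8) for i in range(25)]
        table, _ = cancer_purity_summary(samples)
        row = table.iloc[0]
        assert row["q25"] == row["median"] == row["q75"] == 0.8


class TestPurityMutationCorrelation:
    def test_monotone_table_gives_plus_one(self):
        table = pd.DataFrame({"purity_pct": [70, 80, 90, 95], "n_somatic": [10, 20, 30, 40]})
        rho, _ = purity_mutation_correlation(table)
        assert rho == pytest.approx(1.0)

    def test_reversed_table_gives_minus_one(self):
        table = pd.DataFrame({"purity_pct": [70, 80, 90, 95], "n_somatic": [40, 30, 20, 10]})
        rho, _ = purity_mutation_correlation(table)
        assert rho == pytest.approx(-1.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            purity_mutation_correlation(pd.DataFrame({"purity_pct": [1, 2], "n_somatic": [3, 4]}))

    def test_packaged_table_loads_19_models(self):
        table = load_syngeneic_table()
        assert len(table) == 19
        assert set(table.columns) == {"model_name", "purity_pct", "n_somatic", "cancer"}
        # tied purities present (average-rank handling matters)
        assert (table["purity_pct"] == 94.3).sum() == 2
        assert (table["purity_pct"] == 96.3).sum() == 2
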