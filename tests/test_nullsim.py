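"""Null-background construction, embedding, FDR and grid simulation."""

import numpy as np
import pandas as pd
import pytest

from lipidmr import (
    NullSimConfig,
    SynthConfig,
    Thresholds,
    apply_thresholds,
    build_null_profiles,
    compute_fdr,
    embed_test_set,
    generate_mother_data,
    run_simulation_grid,
    summarize_replicates,
)
from lipidmr.exceptions import CapacityError, ValidationError
from lipidmr.gwas_io import EXPOSURES, TRAITS
from lipidmr.pleiotropy import classify_associations
from lipidmr.selection import select_stage1


@pytest.fixture(scope="module")
def mother_and_test():
    config = SynthConfig(m=4_000).scaled(0.05)  # ~17 test SNPs
    mother, _ = generate_mother_data(config, seed=21)
    test = apply_thresholds(mother, Thresholds(p_v=5e-08), reference=mother)
    return mother, test


class TestNullProfiles:
    def test_support_and_size(self, mother_and_test):
        mother, _ = mother_and_test
        config = NullSimConfig(p_low=1e-07, seed=1)
        null = build_null_profiles(mother, config)
        assert len(null) == len(mother)
        for t in TRAITS:
            assert null[f"p_{t}"].min() >= 1e-07
            assert null[f"p_{t}"].max() <= 1.0
            assert (null[f"n_{t}"] >= 1).all()

    def test_allele_multiset_preserved_per_trait(self, mother_and_test):
        mother, _ = mother_and_test
        null = build_null_profiles(mother, NullSimConfig(seed=2))
        for t in TRAITS:
            pairs_null = sorted(zip(null[f"a1_{t}"], null[f"a2_{t}"]))
            pairs_mother = sorted(zip(mother[f"a1_{t}"], mother[f"a2_{t}"]))
            assert pairs_null == pairs_mother

    def test_beta_moments_match_mother(self, mother_and_test):
        mother, _ = mother_and_test
        m = 78_112
        null = build_null_profiles(mother, NullSimConfig(m_null=m, seed=3))
        for t in TRAITS:
            mu = mother[f"beta_{t}"].mean()
            sd = mother[f"beta_{t}"].std(ddof=1)
            assert null[f"beta_{t}"].mean() == pytest.approx(mu, abs=3 * sd / np.sqrt(m))
            assert null[f"beta_{t}"].std(ddof=1) == pytest.approx(sd, rel=0.05)


class TestEmbed:
    def test_single_exposure_snp_preserves_its_pair(self, mother_and_test):
        mother, test = mother_and_test
        membership = classify_associations(test, 5e-08)
        singles = membership[membership[list(EXPOSURES)].sum(axis=1) == 1]
        null = build_null_profiles(mother, NullSimConfig(seed=4))
        sim, labels = embed_test_set(null, test, rng=5)
        sid = singles["snp_id"].iloc[0]
        x = next(x for x in EXPOSURES if singles[x].iloc[0])
        row = sim.loc[labels == sid].iloc[0]
        src = test.loc[test["snp_id"] == sid].iloc[0]
        for f in ("beta", "p", "n", "a1", "a2"):
            assert row[f"{f}_{x}"] == src[f"{f}_{x}"]
            assert row[f"{f}_cad"] == src[f"{f}_cad"]

    def test_multi_exposure_snp_duplicated_to_distinct_rows(self, mother_and_test):
        mother, test = mother_and_test
        membership = classify_associations(test, 5e-08)
        null = build_null_profiles(mother, NullSimConfig(seed=6))
        sim, labels = embed_test_set(null, test, rng=7)
        counts = labels.value_counts()
        for i in range(len(test)):
            sid = test["snp_id"].iloc[i]
            k = int(membership[list(EXPOSURES)].iloc[i].sum())
            assert counts.get(sid, 0) == k
        # total labelled rows equal total memberships
        assert labels.notna().sum() == int(membership[list(EXPOSURES)].to_numpy().sum())

    def test_capacity_error_when_null_too_small(self, mother_and_test):
        mother, test = mother_and_test
        tiny = build_null_profiles(mother, NullSimConfig(m_null=3, seed=8))
        with pytest.raises(CapacityError):
            embed_test_set(tiny, test, rng=9)

    def test_m_over_m_warning(self, mother_and_test):
        mother, test = mother_and_test
        small = build_null_profiles(mother, NullSimConfig(m_null=2_000, seed=10))
        with pytest.warns(UserWarning, match="m/M"):
            embed_test_set(small, test, rng=11)


class TestFdr:
    def test_all_labelled_is_zero(self):
        sel = pd.DataFrame({"snp_id": list("abc")}, index=[0, 1, 2])
        labels = pd.Series(["x", "y", "z"], index=[0, 1, 2])
        assert compute_fdr(sel, labels) == 0.0

    def test_fraction_unlabelled(self):
        idx = list(range(10))
        sel = pd.DataFrame({"snp_id": [f"s{i}" for i in idx]}, index=idx)
        labels = pd.Series([None] * 3 + ["t"] * 7, index=idx, dtype="object")
        assert compute_fdr(sel, labels) == pytest.approx(0.3)

    def test_empty_selection_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty selection"):
            assert compute_fdr(pd.DataFrame(), pd.Series(dtype="object")) == 0.0

    def test_random_label_patterns_match_direct_count(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            mask = rng.random(n) < 0.5
            labels = pd.Series(
                np.where(mask, "t", None), index=range(n), dtype="object"
            )
            sel = pd.DataFrame({"snp_id": [f"s{i}" for i in range(n)]}, index=range(n))
            assert compute_fdr(sel, labels) == pytest.approx((~mask).sum() / n)


class TestGrid:
    def test_analytic_zero_fdr_when_floor_exceeds_cutoff(self, mother_and_test):
        mother, test = mother_and_test
        config = NullSimConfig(
            p_low=1e-07, p_v=5e-08, pc_grid=(0.9, 0.99), pd_grid=(0.97,),
            replicates=2, seed=13,
        )
        summary = run_simulation_grid(mother, test, config)
        assert (summary.summary["fdr"] == 0.0).all()
        assert (summary.summary["n_false"] == 0.0).all()

    def test_no_embedding_selects_nothing(self, mother_and_test):
        mother, _ = mother_and_test
        null = build_null_profiles(mother, NullSimConfig(p_low=1e-07, seed=14))
        assert len(select_stage1(null, 5e-08)) == 0

    def test_null_stage1_survival_matches_linear_uniform_rate(self, mother_and_test):
        # with p_low < P_v the per-trait survival rate is
        # (P_v - p_low) / (1 - p_low); check the Monte-Carlo count
        mother, _ = mother_and_test
        p_low, p_v, m = 1e-12, 1e-03, 200_000
        null = build_null_profiles(mother, NullSimConfig(m_null=m, p_low=p_low, seed=15))
        rate = 1 - (1 - (p_v - p_low) / (1 - p_low)) ** 3
        expected = m * rate
        observed = len(select_stage1(null, p_v))
        assert observed == pytest.approx(expected, abs=4 * np.sqrt(expected))

    def test_fdr_monotone_in_null_floor(self, mother_and_test):
        # floor above the cutoff: FDR exactly 0; floor far below with a
        # permissive cutoff: false discoveries appear
        mother, test = mother_and_test
        grids = dict(pc_grid=(0.0,), pd_grid=(0.0,), replicates=3)
        clean = run_simulation_grid(
            mother, test, NullSimConfig(p_low=1e-07, p_v=5e-08, seed=16, **grids)
        )
        noisy = run_simulation_grid(
            mother, test, NullSimConfig(p_low=1e-12, p_v=1e-03, seed=16, **grids)
        )
        assert clean.summary["fdr"].iloc[0] == 0.0
        assert noisy.summary["fdr"].iloc[0] > 0.0

    def test_bit_identical_under_same_seed(self, mother_and_test):
        mother, test = mother_and_test
        config = NullSimConfig(pc_grid=(0.9,), pd_grid=(0.97,), replicates=2, seed=17)
        a = run_simulation_grid(mother, test, config)
        b = run_simulation_grid(mother, test, config)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_embedding_preserved_through_grid(self, mother_and_test):
        mother, test = mother_and_test
        config = NullSimConfig(pc_grid=(0.0,), pd_grid=(0.0,), replicates=1, seed=18)
        summary = run_simulation_grid(mother, test, config)
        row = summary.summary.iloc[0]
        assert row["n_selected"] >= len(test)
        assert row["fdr"] == 0.0


class TestSummarize:
    def test_single_replicate_passthrough(self):
        frame = pd.DataFrame(
            [{"rep": 0, "p_c": 0.9, "p_d": 0.9, "n_selected": 5, "fdr": 0.2, "flag": ""}]
        )
        summary = summarize_replicates(frame).summary
        assert summary["n_selected"].iloc[0] == 5
        assert summary["fdr"].iloc[0] == 0.2

    def test_identical_replicates_have_zero_dispersion(self):
        rows = [
            {"rep": r, "p_c": 0.9, "p_d": 0.9, "n_selected": 5, "fdr": 0.2, "flag": ""}
            for r in range(4)
        ]
        result = summarize_replicates(pd.DataFrame(rows))
        assert result.summary["fdr"].iloc[0] == 0.2
        assert result.replicates.groupby(["p_c", "p_d"])["fdr"].std().iloc[0] == 0.0

    def test_means_match_direct_average(self):
        rng = np.random.default_rng(19)
        rows = []
        for r in range(5):
            for pc in (0.9, 0.95):
                rows.append(
                    {"rep": r, "p_c": pc, "p_d": 0.9,
                     "n_selected": int(rng.integers(0, 50)),
                     "fdr": float(rng.random()), "flag": ""}
                )
        frame = pd.DataFrame(rows)
        summary = summarize_replicates(frame).summary
        for pc in (0.9, 0.95):
            direct = frame.loc[frame["p_c"] == pc, "fdr"].mean()
            got = summary.loc[summary["p_c"] == pc, "fdr"].iloc[0]
            assert got == pytest.approx(direct)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            NullSimConfig(p_low=0.0)
        with pytest.raises(ValidationError):
            NullSimConfig(replicates=0)
        with pytest.raises(ValidationError):
            NullSimConfig(pc_grid=())
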