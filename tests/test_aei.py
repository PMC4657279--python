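"""Allelic expression imbalance: filter cascade, CI tiers, and recurrence."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from braintx.aei import (
    GeneBin,
    TIER_2FOLD,
    TIER_NONE,
    TIER_STRINGENT,
    assign_snps_to_bins,
    filter_snp_calls,
    gene_level_aei,
    make_gene_bins,
    recurrence_summary,
)


def rows(*specs):
    """Build an allele-count frame from (rsid, pos, subject, region, ref, alt)."""
    return pd.DataFrame(
        [dict(zip(["rsid", "pos", "subject", "region", "ref_count", "alt_count"], s))
         for s in specs]
    ).assign(chrom="chr1")


def het_of(*pairs):
    return pd.DataFrame(pairs, columns=["subject", "rsid"])


class TestBinAssignment:
    BINS = [GeneBin.from_span("gA", "chr1", 5000, 8000, pad=1000)]

    def test_snp_within_pad_is_assigned(self):
        snps = rows(("rs1", 4200, "s1", "r1", 5, 5))
        out = assign_snps_to_bins(snps, self.BINS)
        assert out.to_dict("records") == [{"rsid": "rs1", "gene_id": "gA"}]

    def test_snp_outside_pad_is_dropped(self):
        snps = rows(("rs1", 3900, "s1", "r1", 5, 5))
        assert assign_snps_to_bins(snps, self.BINS).empty

    def test_shared_snps_give_overlapping_genes_identical_ratios(self):
        bins = [
            GeneBin.from_span("gA", "chr1", 1000, 3000),
            GeneBin.from_span("gB", "chr1", 1500, 3500),
        ]
        table = rows(
            ("rs1", 2000, "s1", "r1", 30, 10),
            ("rs2", 2500, "s1", "r1", 75, 25),
        )
        s2g = assign_snps_to_bins(table, bins)
        assert sorted(s2g["gene_id"].unique()) == ["gA", "gB"]
        calls = gene_level_aei(table, s2g)
        assert len(calls) == 2
        assert calls["mean_ratio"].nunique() == 1
        assert calls["ci_lower_95"].nunique() == 1


class TestFilterCascade:
    def test_coverage_then_recurrence_keeps_four_of_six(self):
        depths = [12, 11, 10, 9, 3, 50]
        table = rows(*[
            ("rs1", 100, "s1", f"r{i}", d - 4, 4) for i, d in enumerate(depths)
        ])
        het = het_of(("s1", "rs1"))
        out, attr = filter_snp_calls(table, het)
        assert len(out) == 4  # depths 12, 11, 10, 50 pass; 4 regions >= 3
        assert attr["dropped_low_coverage"] == 2

    def test_recurrence_below_three_regions_drops_all_rows(self):
        depths = [12, 11, 4, 4, 4, 4]
        table = rows(*[
            ("rs1", 100, "s1", f"r{i}", d - 2, 2) for i, d in enumerate(depths)
        ])
        out, attr = filter_snp_calls(table, het_of(("s1", "rs1")))
        assert out.empty
        assert attr["dropped_region_recurrence"] == 2

    def test_homozygous_snp_dropped_regardless_of_depth(self):
        table = rows(("rs1", 100, "s1", "r1", 100, 0))
        out, attr = filter_snp_calls(table, het_of(("s2", "rs1")))
        assert out.empty
        assert attr["dropped_not_heterozygous"] == 1

    def test_attrition_counts_balance(self, allele_counts, truth):
        out, attr = filter_snp_calls(allele_counts, truth.het_table())
        drops = (attr["dropped_not_heterozygous"]
                 + attr["dropped_low_coverage"]
                 + attr["dropped_region_recurrence"])
        assert attr["rows_in"] == attr["rows_out"] + drops
        assert attr["rows_out"] == len(out)


S2G = pd.DataFrame({"rsid": ["rs1", "rs2"], "gene_id": ["gA", "gA"]})


class TestGeneLevelCalls:
    def test_equal_ratios_collapse_ci_to_the_mean(self):
        table = rows(("rs1", 100, "s1", "r1", 30, 10),
                     ("rs2", 200, "s1", "r1", 75, 25))
        calls = gene_level_aei(table, S2G)
        row = calls.iloc[0]
        assert row["mean_ratio"] == pytest.approx(3.0)
        assert row["ci_lower_95"] == pytest.approx(3.0)
        assert row["n_snps"] == 2
        assert row["tier"] == TIER_STRINGENT  # mean depth 70 >= 30

    def test_balanced_counts_stay_untier_ed(self):
        table = rows(("rs1", 100, "s1", "r1", 20, 20),
                     ("rs2", 200, "s1", "r1", 21, 19))
        calls = gene_level_aei(table, S2G)
        row = calls.iloc[0]
        assert row["mean_ratio"] == pytest.approx((1.0 + 21 / 19) / 2, abs=1e-9)
        assert row["tier"] == TIER_NONE

    def test_single_snp_gene_yields_no_call(self):
        table = rows(("rs1", 100, "s1", "r1", 30, 10))
        assert gene_level_aei(table, S2G).empty

    def test_zero_minor_allele_uses_pseudocount(self):
        table = rows(("rs1", 100, "s1", "r1", 40, 0),
                     ("rs2", 200, "s1", "r1", 35, 5))
        calls = gene_level_aei(table, S2G)
        row = calls.iloc[0]
        assert np.isfinite(row["mean_ratio"])
        assert row["pseudocount_used"]
        assert row["mean_ratio"] == pytest.approx((40.5 / 0.5 + 7.0) / 2)

    def test_snps_closer_than_spacing_are_thinned_greedily(self):
        # rs1/rs2 are 30 bases apart: keep the deeper one (rs2), pair with rs3
        table = rows(("rs1", 100, "s1", "r1", 30, 10),
                     ("rs2", 130, "s1", "r1", 60, 20),
                     ("rs3", 300, "s1", "r1", 45, 15))
        s2g = pd.DataFrame({"rsid": ["rs1", "rs2", "rs3"], "gene_id": ["gA"] * 3})
        calls = gene_level_aei(table, s2g)
        assert calls.iloc[0]["n_snps"] == 2
        assert calls.iloc[0]["mean_depth"] == pytest.approx((80 + 60) / 2)

    def test_folding_symmetry_under_allele_swap(self, allele_counts, truth):
        filtered, _ = filter_snp_calls(allele_counts, truth.het_table())
        s2g = pd.concat(
            [
                pd.DataFrame({"rsid": [s["rsid"] for s in snps], "gene_id": gid})
                for gid, snps in truth.snps.items()
            ],
            ignore_index=True,
        )
        calls = gene_level_aei(filtered, s2g)
        swapped = filtered.rename(
            columns={"ref_count": "alt_count", "alt_count": "ref_count"}
        )
        calls_sw = gene_level_aei(swapped, s2g)
        pd.testing.assert_frame_equal(calls, calls_sw)

    def test_expected_ratio_monotone_in_skew(self):
        rng = np.random.default_rng(0)
        means = []
        for skew in (0.55, 0.65, 0.75, 0.85):
            depth = 200
            ref = rng.binomial(depth, skew, size=2000)
            folded = np.maximum(ref, depth - ref) / np.maximum(
                np.minimum(ref, depth - ref), 0.5
            )
            means.append(folded.mean())
        assert all(a < b for a, b in zip(means, means[1:]))


def brute_force_calls(table, het_pairs, s2g_pairs, min_cov=10, min_regions=3,
                      min_snps=2, min_spacing=51):
    """Row-by-row re-evaluation of every cascade rule, written independently."""
    surv = []
    for r in table.itertuples():
        if (r.subject, r.rsid) not in het_pairs:
            continue
        if r.ref_count + r.alt_count < min_cov:
            continue
        n_reg = len(
            {
                q.region
                for q in table.itertuples()
                if q.subject == r.subject and q.rsid == r.rsid
                and q.ref_count + q.alt_count >= min_cov
                and (q.subject, q.rsid) in het_pairs
            }
        )
        if n_reg >= min_regions:
            surv.append(r)
    calls = {}
    genes = {g for _, g in s2g_pairs}
    for gene in genes:
        snps_of_gene = {rs for rs, g in s2g_pairs if g == gene}
        samples = {(r.subject, r.region) for r in surv if r.rsid in snps_of_gene}
        for subj, reg in samples:
            here = [r for r in surv
                    if r.rsid in snps_of_gene and r.subject == subj
                    and r.region == reg]
            # greedy spaced subset by descending depth, ties to lower pos
            here.sort(key=lambda r: (-(r.ref_count + r.alt_count), r.pos))
            kept = []
            for r in here:
                if all(abs(r.pos - k.pos) >= min_spacing for k in kept):
                    kept.append(r)
            if len(kept) < min_snps:
                continue
            ratios = []
            for r in kept:
                a, b = float(r.ref_count), float(r.alt_count)
                if min(a, b) == 0:
                    a, b = a + 0.5, b + 0.5
                ratios.append(max(a, b) / min(a, b))
            logs = [math.log2(x) for x in ratios]
            n = len(logs)
            mean_log = sum(logs) / n
            var = sum((x - mean_log) ** 2 for x in logs) / (n - 1)
            hw = stats.t.ppf(0.975, n - 1) * math.sqrt(var / n)
            ci_lower = 2 ** (mean_log - hw)
            depth = sum(r.ref_count + r.alt_count for r in kept) / n
            tier = TIER_NONE
            if ci_lower > 2.0:
                tier = TIER_STRINGENT if depth >= 30 else TIER_2FOLD
            calls[(gene, subj, reg)] = (n, sum(ratios) / n, ci_lower, tier)
    return calls


@pytest.mark.parametrize("seed", range(4))
def test_cascade_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(60, 200))
    rsids = [f"rs{i}" for i in range(8)]
    pos_of = {rs: int(rng.integers(0, 2000)) for rs in rsids}
    table = pd.DataFrame(
        {
            "rsid": rng.choice(rsids, n),
            "subject": rng.choice(["s1", "s2", "s3"], n),
            "region": rng.choice([f"r{i}" for i in range(5)], n),
            "ref_count": rng.integers(0, 60, n),
            "alt_count": rng.integers(0, 60, n),
        }
    )
    table["pos"] = table["rsid"].map(pos_of)
    table["chrom"] = "chr1"
    table = table.drop_duplicates(["rsid", "subject", "region"]).reset_index(drop=True)
    het_pairs = {
        (s, rs) for s in ["s1", "s2", "s3"] for rs in rsids if rng.random() < 0.7
    }
    s2g_pairs = {
        (rs, g) for rs in rsids for g in ["gA", "gB"] if rng.random() < 0.6
    }
    het = pd.DataFrame(sorted(het_pairs), columns=["subject", "rsid"])
    s2g = pd.DataFrame(sorted(s2g_pairs), columns=["rsid", "gene_id"])

    filtered, _ = filter_snp_calls(table, het)
    calls = gene_level_aei(filtered, s2g)
    got = {
        (r.gene_id, r.subject, r.region): (r.n_snps, r.mean_ratio,
                                           r.ci_lower_95, r.tier)
        for r in calls.itertuples()
    }
    expected = brute_force_calls(table, het_pairs, s2g_pairs)
    assert set(got) == set(expected)
    for key, (n_snps, mean_ratio, ci_lower, tier) in expected.items():
        gn, gm, gc, gt = got[key]
        assert gn == n_snps
        assert gm == pytest.approx(mean_ratio, rel=1e-9)
        assert gc == pytest.approx(ci_lower, rel=1e-9)
        assert gt == tier


class TestRecurrence:
    CALLS = pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gA", "gB", "gB"],
            "subject": ["s1", "s4", "s2", "s1", "s2"],
            "region": ["BA22", "BA22", "BA10", "BA10", "BA22"],
            "n_snps": [2, 3, 2, 2, 2],
            "mean_ratio": [3.0, 3.4, 2.8, 4.0, 5.0],
            "ci_lower_95": [2.5] * 5,
            "mean_depth": [60.0] * 5,
            "tier": [TIER_STRINGENT] * 3 + [TIER_STRINGENT] * 2,
            "pseudocount_used": [False] * 5,
        }
    )

    def test_same_region_two_subjects_is_listed(self):
        out = recurrence_summary(self.CALLS)
        row = out[(out["gene_id"] == "gA") & (out["region"] == "BA22")].iloc[0]
        assert row["n_subjects"] == 2
        assert row["mean_aei_ratio"] == pytest.approx(3.2)
        assert row["avg_snps_per_sample"] == pytest.approx(2.5)

    def test_two_subjects_in_different_regions_not_listed(self):
        out = recurrence_summary(self.CALLS)
        assert "gB" not in set(out["gene_id"])

    def test_recurrent_planted_gene_recovered(self, sim_cfg):
        from braintx.simulate import SimConfig, simulate_all

        cfg = SimConfig(
            n_genes_per_class={"protein_coding": 12},
            n_stable_genes=0, n_selective_genes=0, n_switch_genes=0,
            n_aei_genes=4, aei_skew=0.8, depth_mean=120.0,
            snps_per_gene=(3, 4), seed=23,
        )
        models, truth, _, counts, _ = simulate_all(cfg)
        s2g = pd.concat(
            [pd.DataFrame({"rsid": [s["rsid"] for s in truth.snps[g]],
                           "gene_id": g}) for g in truth.snps],
            ignore_index=True,
        )
        filtered, _ = filter_snp_calls(counts, truth.het_table())
        calls = gene_level_aei(filtered, s2g)
        recur = recurrence_summary(calls)
        multi_het = [g for g in truth.aei_gene_ids
                     if len(truth.het_subjects[g]) >= 2]
        assert multi_het, "fixture must plant a multi-subject AEI gene"
        assert set(multi_het) & set(recur["gene_id"])
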