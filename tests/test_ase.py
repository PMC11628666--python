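"""Variant filtering, gene intersection, tag alleles, ASE proportions, patterns."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import invex
from invex import ase as am
from invex.containers import ValidationError, VariantTable


def _variant_table(sites, gt, dp, gq, ad_ref, ad_alt, samples=None):
    gt = np.asarray(gt)
    samples = samples or [f"s{j}" for j in range(gt.shape[1])]
    return VariantTable(
        sites=pd.DataFrame(sites),
        samples=samples,
        gt=gt,
        dp=np.asarray(dp),
        gq=np.asarray(gq),
        ad_ref=np.asarray(ad_ref),
        ad_alt=np.asarray(ad_alt),
    )


def _toy_five_sites():
    """QUAL/DP/indel toy: exactly two sites survive the site filters."""
    sites = {
        "chrom": ["Z"] * 5,
        "pos": [100, 200, 300, 400, 500],
        "ref": ["A", "C", "G", "T", "A"],
        "alt": ["G", "T", "GA", "C", "C"],  # site 3 is an indel
        "qual": [1000.0, 998.0, 1000.0, 1000.0, 1200.0],
        "info_dp": [700, 700, 700, 600, 650],
    }
    n, s = 5, 2
    dp = np.full((n, s), 20)
    return _variant_table(
        sites, np.ones((n, s), dtype=int), dp, np.full((n, s), 99), dp // 2, dp - dp // 2
    )


def test_filter_variants_site_rules_on_toy():
    out = am.filter_variants(_toy_five_sites(), min_site_dp=640)
    assert out.n_sites == 2
    assert list(out.sites["pos"]) == [100, 500]


def test_filter_variants_genotype_rules_and_complete_mode():
    sites = {"chrom": ["Z"], "pos": [100], "ref": ["A"], "alt": ["G"],
             "qual": [1000.0], "info_dp": [700]}
    gt = [[1, 1]]
    dp = [[7, 30]]  # first genotype below DP 8
    gq = [[99, 99]]
    vt = _variant_table(sites, gt, dp, gq, [[3, 15]], [[4, 15]])
    out = am.filter_variants(vt)
    assert out.n_sites == 1  # site kept
    assert out.gt[0, 0] == -1  # failing genotype set missing
    assert out.ad_ref[0, 0] == 0 and out.ad_alt[0, 0] == 0
    assert out.gt[0, 1] == 1
    complete = am.filter_variants(vt, require_complete=True)
    assert complete.n_sites == 0


def test_filter_variants_low_gq_sets_missing():
    sites = {"chrom": ["Z"], "pos": [50], "ref": ["A"], "alt": ["G"],
             "qual": [1000.0], "info_dp": [700]}
    vt = _variant_table(sites, [[2, 0]], [[30, 30]], [[9, 10]], [[0, 30]], [[30, 0]])
    out = am.filter_variants(vt)
    assert out.gt[0, 0] == -1 and out.gt[0, 1] == 0


# ------------------------------------------------------- gene intersection


def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).rename_axis("gene_id")


def test_map_variants_boundary_conventions():
    genes = pd.DataFrame(
        {"chrom": ["Z"], "start": [100], "end": [200]}, index=["gA"]
    )
    sites = {"chrom": ["Z"] * 3, "pos": [101, 200, 201], "ref": ["A"] * 3,
             "alt": ["G"] * 3, "qual": [1000.0] * 3, "info_dp": [700] * 3}
    n, s = 3, 1
    vt = _variant_table(sites, np.ones((n, s), int), np.full((n, s), 10),
                        np.full((n, s), 99), np.full((n, s), 5), np.full((n, s), 5))
    pairs = am.map_variants_to_genes(vt, genes)
    # first base of the interval (P = start+1) and last base (P = end) pair;
    # P = end+1 does not
    assert list(pairs["site_idx"]) == [0, 1]


def test_map_variants_overlapping_genes_pair_twice():
    genes = pd.DataFrame(
        {"chrom": ["Z", "Z"], "start": [100, 150], "end": [300, 400]},
        index=["gA", "gB"],
    )
    sites = {"chrom": ["Z"], "pos": [200], "ref": ["A"], "alt": ["G"],
             "qual": [1000.0], "info_dp": [700]}
    vt = _variant_table(sites, [[1]], [[10]], [[99]], [[5]], [[5]])
    pairs = am.map_variants_to_genes(vt, genes)
    assert sorted(pairs["gene_id"]) == ["gA", "gB"]


# ----------------------------------------------------------- tag alleles


def _assign_toy(aa_ref, aa_alt, bb_ref, bb_alt):
    sites = {"chrom": ["Z"], "pos": [100], "ref": ["A"], "alt": ["G"],
             "qual": [1000.0], "info_dp": [1000]}
    ad_ref = [[aa_ref, bb_ref]]
    ad_alt = [[aa_alt, bb_alt]]
    dp = (np.asarray(ad_ref) + np.asarray(ad_alt)).tolist()
    vt = _variant_table(sites, [[0, 2]], dp, [[99, 99]], ad_ref, ad_alt,
                        samples=["aa1", "bb1"])
    pairs = pd.DataFrame({"site_idx": [0], "gene_id": ["gA"]})
    kar = pd.Series({"aa1": "AA", "bb1": "BB"})
    return am.assign_tag_alleles(vt, pairs, kar)


def test_assign_fully_fixed_snp():
    tags = _assign_toy(aa_ref=50, aa_alt=0, bb_ref=0, bb_alt=50)
    row = tags.iloc[0]
    assert row["informative"]
    assert row["a_allele"] == "ref" and row["b_allele"] == "alt"
    assert row["aa_frac_a"] == pytest.approx(1.0)
    assert row["bb_frac_a"] == pytest.approx(0.0)


def test_assign_below_fixation_not_informative():
    tags = _assign_toy(aa_ref=30, aa_alt=20, bb_ref=0, bb_alt=50)
    assert not tags.iloc[0]["informative"]


def test_assign_depth_requirement():
    tags = _assign_toy(aa_ref=10, aa_alt=0, bb_ref=0, bb_alt=50)
    assert not tags.iloc[0]["informative"]  # AA pool below min_group_depth


def test_assign_no_homokaryotype_coverage_is_unassignable():
    tags = _assign_toy(aa_ref=0, aa_alt=0, bb_ref=0, bb_alt=50)
    assert not tags.iloc[0]["informative"]
    assert tags.iloc[0]["a_allele"] is None


def test_assignment_recovers_simulated_diagnostic_snps(small_dataset):
    ds = small_dataset
    v = am.filter_variants(ds.variants)
    z_genes = ds.counts["testis"].genes.query("chrom == 'Z'")
    pairs = am.map_variants_to_genes(v, z_genes)
    tags = am.assign_tag_alleles(v, pairs, ds.meta["karyotype"])
    keys = v.keys()
    informative = tags[tags["informative"]]
    assert len(informative) > 10
    correct = sum(
        ds.truth.diagnostic_snps.get(keys[i], {}).get("a_allele") == a
        for i, a in zip(informative["site_idx"], informative["a_allele"])
    )
    assert correct == len(informative)  # every informative call matches truth


# ------------------------------------------------------------- proportions


def _ase_fixture(ad_pairs, a_alleles=None):
    """ad_pairs: list of (ad_ref, ad_alt) for one sample at each SNP."""
    n = len(ad_pairs)
    sites = {"chrom": ["Z"] * n, "pos": list(range(100, 100 + n)),
             "ref": ["A"] * n, "alt": ["G"] * n,
             "qual": [1000.0] * n, "info_dp": [1000] * n}
    ad_ref = [[p[0]] for p in ad_pairs]
    ad_alt = [[p[1]] for p in ad_pairs]
    dp = (np.asarray(ad_ref) + np.asarray(ad_alt)).tolist()
    vt = _variant_table(sites, [[1]] * n, dp, [[99]] * n, ad_ref, ad_alt, samples=["ab1"])
    a_alleles = a_alleles or ["ref"] * n
    tags = pd.DataFrame(
        {"site_idx": range(n), "gene_id": "gA",
         "a_allele": a_alleles,
         "b_allele": ["alt" if a == "ref" else "ref" for a in a_alleles],
         "informative": True}
    )
    return vt, tags


def test_ase_proportion_arithmetic():
    vt, tags = _ase_fixture([(8, 2), (2, 8)])
    out = am.ase_proportion(vt, tags)
    assert out["p_a"].iloc[0] == pytest.approx(0.5)
    assert out["total_depth"].iloc[0] == 20
    assert out["n_informative_snps"].iloc[0] == 2


def test_ase_all_depth_on_a():
    vt, tags = _ase_fixture([(10, 0), (7, 0)])
    assert am.ase_proportion(vt, tags)["p_a"].iloc[0] == pytest.approx(1.0)


def test_ase_zero_depth_flagged_undefined():
    vt, tags = _ase_fixture([(0, 0)])
    out = am.ase_proportion(vt, tags)
    assert not out["defined"].iloc[0]
    assert np.isnan(out["p_a"].iloc[0])


@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
def test_ase_invariant_to_splitting_snp_depths(a1, b1, a2, b2):
    """One SNP with summed depths equals two SNPs with the same totals."""
    merged_vt, merged_tags = _ase_fixture([(a1 + a2, b1 + b2)])
    split_vt, split_tags = _ase_fixture([(a1, b1), (a2, b2)])
    merged = am.ase_proportion(merged_vt, merged_tags)
    split = am.ase_proportion(split_vt, split_tags)
    if merged["defined"].iloc[0]:
        assert merged["p_a"].iloc[0] == pytest.approx(split["p_a"].iloc[0])


def test_ase_label_swap_maps_p_to_one_minus_p():
    vt, tags = _ase_fixture([(8, 2), (9, 1)])
    p = am.ase_proportion(vt, tags)["p_a"].iloc[0]
    vt2, tags2 = _ase_fixture([(8, 2), (9, 1)], a_alleles=["alt", "alt"])
    p_swapped = am.ase_proportion(vt2, tags2)["p_a"].iloc[0]
    assert p_swapped == pytest.approx(1.0 - p)


def test_homokaryotypes_near_monoallelic_in_simulation(small_dataset):
    ds = small_dataset
    v = am.filter_variants(ds.variants)
    z_genes = ds.counts["testis"].genes.query("chrom == 'Z'")
    pairs = am.map_variants_to_genes(v, z_genes)
    tags = am.assign_tag_alleles(v, pairs, ds.meta["karyotype"])
    prof = am.ase_proportion(v, tags, ds.meta)
    prof = prof[prof["defined"]]
    kar = prof["sample_id"].map(ds.meta["karyotype"])
    leak = 1.0 - ds.config.fixation_level
    pooled_aa = prof.loc[kar == "AA"]
    pooled_bb = prof.loc[kar == "BB"]
    aa_mean = np.average(pooled_aa["p_a"], weights=pooled_aa["total_depth"])
    bb_mean = np.average(pooled_bb["p_a"], weights=pooled_bb["total_depth"])
    assert aa_mean > 1.0 - 5 * leak
    assert bb_mean < 5 * leak


def test_tissue_specific_ase_gene_detected(small_dataset):
    """The DMGDH-like planted gene: monoallelic in testis, balanced in liver."""
    ds = small_dataset
    v = am.filter_variants(ds.variants)
    z_genes = ds.counts["testis"].genes.query("chrom == 'Z'")
    pairs = am.map_variants_to_genes(v, z_genes)
    tags = am.assign_tag_alleles(v, pairs, ds.meta["karyotype"])
    prof = am.ase_proportion(v, tags, ds.meta)
    gene = sorted({g for g, _ in ds.truth.ase_truth})[0]
    ab_birds = ds.meta[(ds.meta["karyotype"] == "AB")]
    for bird in ab_birds["bird_id"].unique():
        vals = {}
        for tissue in ("testis", "liver"):
            sid = ab_birds[(ab_birds["bird_id"] == bird) & (ab_birds["tissue"] == tissue)].index[0]
            row = prof[(prof["gene_id"] == gene) & (prof["sample_id"] == sid)]
            vals[tissue] = row["p_a"].iloc[0]
        assert abs(vals["testis"] - vals["liver"]) > 0.3


# -------------------------------------------------------- dominance pattern


def _cells(aa, ab, bb, aa_l=None, ab_l=None, bb_l=None):
    aa_l = aa if aa_l is None else aa_l
    ab_l = ab if ab_l is None else ab_l
    bb_l = bb if bb_l is None else bb_l
    return pd.DataFrame(
        {"AA.EARLY": [aa], "AB.EARLY": [ab], "BB.EARLY": [bb],
         "AA.LATE": [aa_l], "AB.LATE": [ab_l], "BB.LATE": [bb_l]},
        index=["g0"],
    )


@pytest.mark.parametrize(
    "cells,expected",
    [
        (_cells(5.0, 4.9, 1.0, ab_l=4.8), "A_dominant"),
        (_cells(5.0, 1.1, 1.0), "B_dominant"),
        (_cells(5.0, 3.0, 1.0), "intermediate"),
        (_cells(5.0, 3.0, 1.0, ab_l=4.9), "divergent_over_time"),
        (_cells(5.0, 4.9, 1.0, ab_l=1.1), "switching"),
        (_cells(5.0, 4.9, 4.5), "unclassified"),  # |AA-BB| below min effect
    ],
)
def test_pattern_rule_evaluation(cells, expected):
    out = am.classify_pattern(cells)
    assert out["pattern"].iloc[0] == expected


def test_pattern_orientation_free():
    """Negating all means leaves the dominance score unchanged."""
    cells = _cells(5.0, 4.9, 1.0)
    flipped = -cells
    a = am.classify_pattern(cells)
    b = am.classify_pattern(flipped)
    assert a["delta_early"].iloc[0] == pytest.approx(b["delta_early"].iloc[0])
    assert a["pattern"].iloc[0] == b["pattern"].iloc[0]


def test_pattern_missing_cell_errors():
    cells = _cells(5.0, 4.0, 1.0)
    cells.loc["g0", "AB.LATE"] = np.nan
    with pytest.raises(ValidationError):
        am.classify_pattern(cells)


def test_planted_patterns_recovered_from_fitted_cell_means():
    """All five planted classes recovered from the DE fit at effect 3."""
    from invex import expression as ex

    cfg = invex.SimulationConfig(
        seed=21, n_autosomal_genes=30, n_z_genes=120, n_cis_de=20, n_trans_de=0,
        cis_effect_log2fc=3.0, snp_density_per_mb=0.0,
    )
    ds = invex.simulate_dataset(cfg)
    cm = ds.counts["testis"]
    meta = ds.meta[ds.meta["tissue"] == "testis"].loc[cm.counts.columns]
    design = ex.design_matrix(meta)
    kept = ex.prefilter_genes(cm.counts, design.sum(0).astype(int).tolist())
    sub = cm.subset_genes(kept)
    f = ex.tmm_factors(sub.counts)
    eff = sub.library_sizes * f
    lc = ex.log_cpm(sub.counts, eff)
    w = ex.mean_variance_weights(lc, design, effective_sizes=eff)
    res = ex.fit_moderated(lc, w, design, ex.build_contrasts("testis"))
    planted = [g for g in ds.truth.pattern_truth if g in res.cell_means.index]
    calls = am.classify_pattern(res.cell_means.loc[planted])
    agree = np.mean(
        [calls.loc[g, "pattern"] == ds.truth.pattern_truth[g] for g in planted]
    )
    assert agree >= 0.9
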