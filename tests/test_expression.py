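"""Prefilter, TMM, logCPM, precision weights, moderated contrasts, clustering."""
import numpy as np
import pandas as pd
import pytest

import invex
from invex import expression as ex
from invex.containers import ValidationError


def _frame(array, prefix="g"):
    array = np.asarray(array)
    return pd.DataFrame(
        array,
        index=[f"{prefix}{i}" for i in range(array.shape[0])],
        columns=[f"s{j}" for j in range(array.shape[1])],
    )


# ---------------------------------------------------------------- prefilter


def test_prefilter_rule_arithmetic():
    n = 32
    counts = _frame(
        np.vstack(
            [
                np.full(n, 9),  # all below the floor -> dropped
                np.full(n, 20),  # 32 supporting samples, total 640 -> kept
                np.r_[300, np.zeros(n - 1)],  # support 1 < smallest group -> dropped
            ]
        )
    )
    kept = ex.prefilter_genes(counts, group_sizes=[2, 6], min_per_sample=10, min_total=320)
    assert list(kept) == ["g1"]


def test_prefilter_uses_working_copy_totals():
    # entries below 10 are zeroed before the total-count rule
    counts = _frame(np.array([[9] * 30 + [40, 40]]))  # raw total 350, working total 80
    kept = ex.prefilter_genes(counts, group_sizes=[2], min_per_sample=10, min_total=320)
    assert len(kept) == 0


def test_prefilter_is_idempotent(small_dataset):
    counts = small_dataset.counts["testis"].counts
    first = ex.prefilter_genes(counts, group_sizes=[4])
    second = ex.prefilter_genes(counts.loc[first], group_sizes=[4])
    assert list(first) == list(second)


def test_prefilter_empty_matrix_errors():
    with pytest.raises(ValidationError):
        ex.prefilter_genes(pd.DataFrame(), group_sizes=[2])


# --------------------------------------------------------------------- TMM


def test_tmm_identical_columns_give_unit_factors():
    col = np.random.default_rng(0).integers(1, 500, 400)
    counts = _frame(np.tile(col[:, None], (1, 4)))
    assert np.allclose(ex.tmm_factors(counts), 1.0)


def test_tmm_pure_depth_change_gives_unit_factor():
    rng = np.random.default_rng(1)
    col = rng.integers(10, 500, 1000)
    counts = _frame(np.column_stack([col, 2 * col]))
    f = ex.tmm_factors(counts)
    assert np.allclose(f, 1.0, atol=1e-12)


def test_tmm_composition_bias_direction():
    """A sample where 5% of genes are 8-fold up gets a factor below 1."""
    rng = np.random.default_rng(2)
    mu = rng.uniform(50, 500, 2000)
    base = rng.poisson(mu)
    mu2 = mu.copy()
    mu2[:100] *= 8
    counts = _frame(np.column_stack([base, rng.poisson(mu2)]))
    f = ex.tmm_factors(counts)
    assert f.iloc[1] < 1.0 < f.iloc[0]
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)  # geometric mean one


def test_tmm_zero_library_errors():
    counts = _frame(np.array([[0, 5], [0, 7]]))
    with pytest.raises(ValidationError):
        ex.tmm_factors(counts)


# ------------------------------------------------------------------ logCPM


def test_log_cpm_identities():
    counts = _frame(np.array([[0], [999_999 // 2]]))
    eff = pd.Series([1e6 - 1.0], index=["s0"])
    lc = ex.log_cpm(counts, eff)
    assert lc.iloc[0, 0] == pytest.approx(-1.0)  # zero count -> log2(0.5)
    # y = N_eff/1e6 * c - 0.5 solves to exactly log2(c)
    c = 8.0
    y = (1e6 - 1.0 + 1.0) / 1e6 * c - 0.5
    lc2 = ex.log_cpm(_frame([[y]]), eff)
    assert lc2.iloc[0, 0] == pytest.approx(np.log2(c))


def test_log_cpm_scale_invariance():
    counts = _frame(np.array([[10, 20], [55, 7]]))
    eff = pd.Series([1000.0, 2000.0], index=["s0", "s1"])
    a = ex.log_cpm(counts, eff, prior=0.5)
    doubled = ex.log_cpm(2 * counts + 0.5, 2 * eff + 1.0, prior=0.5)
    assert np.allclose(a, doubled)


# ----------------------------------------------------------------- weights


def _two_group_design(n_per=4):
    samples = [f"s{j}" for j in range(2 * n_per)]
    design = pd.DataFrame(0.0, index=samples, columns=["A", "B"])
    design.iloc[:n_per, 0] = 1.0
    design.iloc[n_per:, 1] = 1.0
    return design


def test_weights_flat_trend_is_nearly_constant():
    rng = np.random.default_rng(3)
    y = _frame(rng.normal(6.0, 0.5, (1000, 16)))
    w = ex.mean_variance_weights(y, _two_group_design(n_per=8))
    ratio = w.to_numpy().max() / w.to_numpy().min()
    assert ratio < 1.2


def test_weights_invariant_to_gene_order():
    rng = np.random.default_rng(4)
    y = _frame(rng.normal(5, 1, (200, 8)) + rng.uniform(0, 5, 200)[:, None])
    design = _two_group_design()
    w = ex.mean_variance_weights(y, design)
    perm = rng.permutation(y.index)
    w_perm = ex.mean_variance_weights(y.loc[perm], design)
    assert np.allclose(w.loc[perm].to_numpy(), w_perm.to_numpy())


def test_weights_increase_with_abundance_for_counts():
    """On NB counts the mean-variance trend decreases, so weights rise."""
    rng = np.random.default_rng(5)
    mu = np.geomspace(5, 2000, 400)
    counts = _frame(rng.negative_binomial(10, 10 / (10 + mu[:, None]), (400, 8)))
    eff = counts.sum(axis=0).astype(float)
    lc = ex.log_cpm(counts, eff)
    w = ex.mean_variance_weights(lc, _two_group_design(), effective_sizes=eff)
    mean_w = w.mean(axis=1).to_numpy()
    assert np.corrcoef(np.log(mu), np.log(mean_w))[0, 1] > 0.8


# --------------------------------------------------------------- contrasts


def test_contrast_counts_and_zero_sums():
    testis = ex.build_contrasts("testis")
    liver = ex.build_contrasts("liver")
    assert testis.shape[1] == 6
    assert liver.shape[1] == 3
    assert np.allclose(testis.sum(axis=0), 0.0)
    assert np.allclose(liver.sum(axis=0), 0.0)
    with pytest.raises(ValidationError):
        ex.build_contrasts("spleen")


# ----------------------------------------------------------- moderated fit


def _hand_instance():
    """Two groups of three samples, one gene, unit weights."""
    y = np.array([5.1, 4.9, 5.3, 6.2, 6.0, 6.4])
    samples = [f"s{j}" for j in range(6)]
    frame = pd.DataFrame([y], index=["g0"], columns=samples)
    design = pd.DataFrame(0.0, index=samples, columns=["A", "B"])
    design.iloc[:3, 0] = 1.0
    design.iloc[3:, 1] = 1.0
    contrasts = pd.DataFrame({"A-B": [1.0, -1.0]}, index=["A", "B"])
    return frame, design, contrasts


def test_unmoderated_fit_equals_textbook_two_group_t():
    frame, design, contrasts = _hand_instance()
    y = frame.to_numpy()[0]
    mean_a, mean_b = y[:3].mean(), y[3:].mean()
    s2 = (np.sum((y[:3] - mean_a) ** 2) + np.sum((y[3:] - mean_b) ** 2)) / 4
    t_hand = (mean_a - mean_b) / np.sqrt(s2 * (1 / 3 + 1 / 3))
    res = ex.fit_moderated(frame, None, design, contrasts, prior_df=0)
    assert res.table["t"].iloc[0] == pytest.approx(t_hand)
    assert res.table["log_fc"].iloc[0] == pytest.approx(mean_a - mean_b)


def test_infinite_prior_df_pins_variance_to_prior():
    frame, design, contrasts = _hand_instance()
    res = ex.fit_moderated(frame, None, design, contrasts, prior_df=np.inf, prior_var=0.5)
    v = 1 / 3 + 1 / 3
    expected_t = res.table["log_fc"].iloc[0] / np.sqrt(0.5 * v)
    assert res.table["t"].iloc[0] == pytest.approx(expected_t)


def test_moderated_shrinks_between_gene_and_prior():
    rng = np.random.default_rng(6)
    y = _frame(rng.normal(5, 1, (300, 8)))
    design = _two_group_design()
    contrasts = pd.DataFrame({"A-B": [1.0, -1.0]}, index=["A", "B"])
    res = ex.fit_moderated(y, None, design, contrasts)
    d0, s02, d = res.prior_df, res.prior_var, res.residual_df
    if np.isinf(d0):
        return  # homogeneous variances: nothing to shrink
    post = (d0 * s02 + d * res.sigma2) / (d0 + d)
    lo = np.minimum(res.sigma2, s02)
    hi = np.maximum(res.sigma2, s02)
    assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()


def test_weighted_fit_matches_direct_wls():
    rng = np.random.default_rng(7)
    frame, design, contrasts = _hand_instance()
    w = pd.DataFrame([rng.uniform(0.5, 2.0, 6)], index=["g0"], columns=frame.columns)
    res = ex.fit_moderated(frame, w, design, contrasts, prior_df=0)
    wv = w.to_numpy()[0]
    y = frame.to_numpy()[0]
    ma = np.sum(wv[:3] * y[:3]) / np.sum(wv[:3])
    mb = np.sum(wv[3:] * y[3:]) / np.sum(wv[3:])
    s2 = (np.sum(wv[:3] * (y[:3] - ma) ** 2) + np.sum(wv[3:] * (y[3:] - mb) ** 2)) / 4
    v = 1 / np.sum(wv[:3]) + 1 / np.sum(wv[3:])
    assert res.table["t"].iloc[0] == pytest.approx((ma - mb) / np.sqrt(s2 * v))


# ----------------------------------------------------------- global decide


def test_bh_hand_example():
    table = pd.DataFrame(
        {
            "gene": ["g0", "g1", "g2", "g3"],
            "contrast": ["c"] * 4,
            "log_fc": [1.0, -1.0, 1.0, 1.0],
            "t": [1.0] * 4,
            "df": [4.0] * 4,
            "p_raw": [0.01, 0.02, 0.03, 0.04],
        }
    )
    res = ex.DEResult(
        table=table, cell_means=pd.DataFrame(), sigma2=pd.Series(dtype=float),
        residual_df=4.0, prior_df=0.0, prior_var=np.nan,
    )
    ex.global_decide(res, alpha=0.05)
    assert np.allclose(res.table["p_adj"], 0.04)
    assert (res.table["decision"] != "ns").all()
    assert res.table.loc[1, "decision"] == "down"


def test_all_p_one_yields_no_de():
    table = pd.DataFrame(
        {"gene": ["a", "b"], "contrast": ["c", "c"], "log_fc": [1.0, 2.0],
         "t": [0.0, 0.0], "df": [4.0, 4.0], "p_raw": [1.0, 1.0]}
    )
    res = ex.DEResult(table=table, cell_means=pd.DataFrame(),
                      sigma2=pd.Series(dtype=float), residual_df=4.0,
                      prior_df=0.0, prior_var=np.nan)
    ex.global_decide(res)
    assert (res.table["decision"] == "ns").all()
    assert len(res.de_genes) == 0


def test_adjusted_p_monotone_in_raw_p():
    rng = np.random.default_rng(8)
    p = rng.uniform(0, 1, 200)
    table = pd.DataFrame(
        {"gene": [f"g{i}" for i in range(200)], "contrast": "c",
         "log_fc": 1.0, "t": 1.0, "df": 4.0, "p_raw": p}
    )
    res = ex.DEResult(table=table, cell_means=pd.DataFrame(),
                      sigma2=pd.Series(dtype=float), residual_df=4.0,
                      prior_df=0.0, prior_var=np.nan)
    ex.global_decide(res)
    order = np.argsort(p)
    assert (np.diff(res.table["p_adj"].to_numpy()[order]) >= -1e-12).all()
    assert (res.table["p_adj"] >= res.table["p_raw"] - 1e-12).all()


# -------------------------------------------------------------- clustering


def test_cluster_recovers_planted_profiles():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(9)
    up = np.r_[np.zeros(6), np.ones(6)] * 4
    down = up[::-1]
    y = np.vstack(
        [up + rng.normal(0, 0.3, 12) for _ in range(20)]
        + [down + rng.normal(0, 0.3, 12) for _ in range(20)]
    )
    labels = ex.cluster_de_genes(_frame(y), k=2)
    truth = [0] * 20 + [1] * 20
    assert adjusted_rand_score(truth, labels) == 1.0


def test_cluster_duplicated_rows_share_label_and_k_edges():
    rng = np.random.default_rng(10)
    base = rng.normal(0, 1, (6, 10))
    y = _frame(np.vstack([base, base[0]]))
    labels = ex.cluster_de_genes(y, k=3)
    assert labels.iloc[0] == labels.iloc[-1]
    assert set(ex.cluster_de_genes(y, k=1)) == {1}
    with pytest.raises(ValidationError):
        ex.cluster_de_genes(y, k=10)


# --------------------------------------------------------------- pipeline


def test_de_count_invariant_to_sample_permutation(small_dataset):
    cm = small_dataset.counts["testis"]
    meta = small_dataset.meta[small_dataset.meta["tissue"] == "testis"]

    def run(counts, meta):
        meta = meta.loc[counts.columns]
        design = ex.design_matrix(meta)
        kept = ex.prefilter_genes(counts, design.sum(0).astype(int).tolist())
        sub = counts.loc[kept]
        f = ex.tmm_factors(sub)
        eff = sub.sum(0) * f
        lc = ex.log_cpm(sub, eff)
        w = ex.mean_variance_weights(lc, design, effective_sizes=eff)
        res = ex.global_decide(ex.fit_moderated(lc, w, design, ex.build_contrasts("testis")))
        return set(res.de_genes)

    rng = np.random.default_rng(12)
    perm = rng.permutation(cm.counts.columns)
    assert run(cm.counts, meta) == run(cm.counts[perm], meta)
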