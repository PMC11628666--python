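"""Count prefiltering, normalization, precision weights, moderated contrasts.

The differential-expression machinery follows the standard RNA-seq pipeline
for small designs: trimmed-mean-of-M-values (TMM) normalization factors,
log2 counts-per-million, a lowess mean-variance trend converted into
per-observation precision weights, per-gene weighted least squares on a
karyotype x development-group cell-means design, and empirical-Bayes variance
moderation of the contrast t-statistics. Significance is decided *globally*:
the Benjamini-Hochberg adjustment is applied to the pooled vector of all
gene x contrast p-values with a single cutoff.

Everything here is implemented from the published definitions of these
statistics; the heavy lifting for tails, smoothing and multiplicity goes
through scipy/statsmodels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess
from statsmodels.stats.multitest import multipletests

from .containers import (
    KARYOTYPES,
    STAGE_GROUPS,
    TISSUES,
    CountMatrix,
    ValidationError,
)

__all__ = [
    "prefilter_genes",
    "tmm_factors",
    "log_cpm",
    "mean_variance_weights",
    "design_matrix",
    "build_contrasts",
    "fit_moderated",
    "global_decide",
    "cluster_de_genes",
    "DEResult",
]

CELLS = tuple(f"{k}.{g}" for k in KARYOTYPES for g in STAGE_GROUPS)


# ---------------------------------------------------------------- prefilter


def prefilter_genes(
    counts: pd.DataFrame | CountMatrix,
    group_sizes: list[int] | tuple[int, ...],
    *,
    min_per_sample: int = 10,
    min_total: int = 320,
) -> pd.Index:
    """Select genes with enough support for the contrast analysis.

    Entries below ``min_per_sample`` are floored to zero on a working copy.
    A gene is retained iff the number of samples with working count
    >= ``min_per_sample`` reaches the smallest design-group size AND the
    working counts sum to at least ``min_total``. Downstream analysis then
    uses the *original* counts of the retained genes; the flooring exists
    only for filtering.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.empty:
        raise ValidationError("cannot prefilter an empty count matrix")
    if not group_sizes:
        raise ValidationError("group_sizes must list at least one design group")
    min_group = int(min(group_sizes))
    work = counts.where(counts >= min_per_sample, 0)
    support = (work >= min_per_sample).sum(axis=1)
    keep = (support >= min_group) & (work.sum(axis=1) >= min_total)
    return counts.index[keep]


# ------------------------------------------------------------ normalization


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Trimmed, inverse-variance-weighted mean of per-gene log-ratios."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_o = obs / n_obs
        p_r = ref / n_ref
        log_r = np.log2(p_o / p_r)
        abs_e = 0.5 * (np.log2(p_o) + np.log2(p_r))
        # delta-method variance of the log-ratio
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_l = stats.rankdata(log_r)
    rank_s = stats.rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    denom = np.nansum(1.0 / v[keep])
    f = np.nansum(log_r[keep] / v[keep]) / denom if denom > 0 else np.nan
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame | CountMatrix,
    *,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    ref_column: str | None = None,
) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean one.

    The reference sample is the one whose upper-quartile/library-size ratio is
    closest to the mean of that statistic; per-sample factors are 2 to the
    trimmed (``trim_m`` of M-values, ``trim_a`` of average abundances),
    inverse-variance-weighted mean of the per-gene log2 ratios against the
    reference.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValidationError(f"samples with zero library size: {bad}")
    f75 = np.quantile(x, 0.75, axis=0) / lib
    if ref_column is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_column)
    ref = x[:, ref_idx]
    n_ref = lib[ref_idx]
    factors = np.array(
        [_tmm_pair(x[:, j], ref, lib[j], n_ref, trim_m, trim_a) for j in range(x.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame | CountMatrix,
    effective_sizes: pd.Series | np.ndarray,
    *,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million: log2((y + prior) / (N_eff + 1) * 1e6)."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    eff = np.asarray(effective_sizes, dtype=float)
    if (eff <= 0).any():
        raise ValidationError("effective library sizes must be positive")
    return np.log2((counts + prior).div(eff + 1.0, axis=1) * 1e6)


# -------------------------------------------------------- precision weights


def mean_variance_weights(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    *,
    effective_sizes: pd.Series | np.ndarray | None = None,
    span: float = 0.5,
) -> pd.DataFrame:
    """Per-observation precision weights from the lowess mean-variance trend.

    Per gene, residual standard deviations come from an unweighted fit of
    ``design``; sqrt(sd) is smoothed against mean log-count with a lowess
    trend (span 0.5) and the trend value predicted at each fitted log-count
    gives the weight ``t**-4``. When ``effective_sizes`` is omitted the
    log-CPM scale is used for the abscissa instead of log-counts; the two
    differ per sample only by a log-library-size shift.
    """
    y = logcpm.to_numpy(dtype=float)
    x_mat = design.to_numpy(dtype=float)
    n, p = x_mat.shape
    if y.shape[1] != n:
        raise ValidationError("design rows must match logCPM columns")
    if np.linalg.matrix_rank(x_mat) < p:
        raise ValidationError("design matrix is not full rank")
    df_resid = n - p
    if df_resid < 1:
        raise ValidationError("fewer than one residual degree of freedom per gene")
    beta, *_ = np.linalg.lstsq(x_mat, y.T, rcond=None)
    fitted = (x_mat @ beta).T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)

    if effective_sizes is not None:
        eff = np.asarray(effective_sizes, dtype=float)
        shift = np.log2(eff + 1.0) - np.log2(1e6)
        sx = y.mean(axis=1) + shift.mean()
        fitted_x = fitted + shift[None, :]
    else:
        sx = y.mean(axis=1)
        fitted_x = fitted

    smooth = _lowess(np.sqrt(sigma), sx, frac=span, it=3, return_sorted=True)
    pred = np.interp(fitted_x, smooth[:, 0], smooth[:, 1])
    pred = np.maximum(pred, 1e-6)
    w = pred**-4.0
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


# --------------------------------------------------------- design/contrasts


def design_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Cell-means indicator design (samples x karyotype.stage_group cells)."""
    for col in ("karyotype", "stage_group"):
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks column {col!r}")
    cell = meta["karyotype"].astype(str) + "." + meta["stage_group"].astype(str)
    design = pd.DataFrame(0.0, index=meta.index, columns=list(CELLS))
    for s, c in cell.items():
        if c not in design.columns:
            raise ValidationError(f"sample {s!r} falls in unknown design cell {c!r}")
        design.loc[s, c] = 1.0
    empty = design.columns[design.sum(axis=0) == 0].tolist()
    if empty:
        raise ValidationError(f"design cells without samples: {empty}")
    return design


def build_contrasts(tissue: str) -> pd.DataFrame:
    """Named karyotype contrasts on the six cell means.

    Testis: the three pairwise karyotype differences within EARLY and within
    LATE (six contrasts). Liver: karyotype means first averaged over the two
    development groups (equal weights), then the three pairwise differences.
    Every column sums to zero.
    """
    if tissue not in TISSUES:
        raise ValidationError(f"unknown tissue {tissue!r}; expected one of {list(TISSUES)}")
    pairs = [("AA", "AB"), ("AA", "BB"), ("AB", "BB")]
    contrasts = pd.DataFrame(index=list(CELLS), dtype=float)
    if tissue == "testis":
        for grp in STAGE_GROUPS:
            for k1, k2 in pairs:
                name = f"{k1}-{k2}.{grp}"
                col = pd.Series(0.0, index=contrasts.index)
                col[f"{k1}.{grp}"] = 1.0
                col[f"{k2}.{grp}"] = -1.0
                contrasts[name] = col
    else:
        for k1, k2 in pairs:
            name = f"{k1}-{k2}"
            col = pd.Series(0.0, index=contrasts.index)
            for grp in STAGE_GROUPS:
                col[f"{k1}.{grp}"] = 0.5
                col[f"{k2}.{grp}"] = -0.5
            contrasts[name] = col
    return contrasts


# ----------------------------------------------------------- moderated fit


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def _fit_log_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df, prior variance) on log variances.

    Matches the moments of log s^2 around the scaled-F model: the excess
    variance of log s^2 over trigamma(df/2) identifies the prior df, the mean
    identifies the prior variance.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValidationError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(((e - emean) ** 2).sum() / (e.size - 1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion in the log variances: infinite prior df, and
        # the common variance is simply the mean residual variance
        d0 = np.inf
        s02 = float(s2[ok].mean())
    return d0, s02


@dataclass
class DEResult:
    """Per gene x contrast effect sizes and moderated statistics.

    ``table`` is long-form with columns gene, contrast, log_fc, t, df, p_raw
    (and p_adj/decision after :func:`global_decide`). ``cell_means`` keeps the
    fitted karyotype x stage-group means for downstream dominance-pattern
    classification.
    """

    table: pd.DataFrame
    cell_means: pd.DataFrame
    sigma2: pd.Series
    residual_df: float
    prior_df: float
    prior_var: float
    alpha: float | None = None
    contrast_names: list[str] = field(default_factory=list)

    @property
    def de_genes(self) -> pd.Index:
        """Genes significant in at least one contrast (after global_decide)."""
        if "decision" not in self.table.columns:
            raise ValidationError("run global_decide before asking for DE genes")
        hits = self.table.loc[self.table["decision"] != "ns", "gene"]
        return pd.Index(pd.unique(hits))


def fit_moderated(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: pd.DataFrame,
    contrasts: pd.DataFrame,
    *,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DEResult:
    """Weighted least squares per gene with empirical-Bayes moderated t.

    Per gene the design cell means are estimated by weighted least squares;
    for each contrast c the effect is c'beta with unscaled variance
    c'(X'WX)^-1 c. The residual variances are shrunk toward a prior estimated
    by method of moments on their logs; the moderated t uses the posterior
    variance with prior-df + residual-df degrees of freedom.

    ``prior_df=0`` disables moderation (ordinary weighted t); ``prior_df=inf``
    requires ``prior_var`` and replaces every variance with it.
    """
    genes = logcpm.index
    y = logcpm.to_numpy(dtype=float)
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if y.shape[1] != n:
        raise ValidationError("design rows must match logCPM columns")
    if np.linalg.matrix_rank(x) < p:
        raise ValidationError("design matrix is not full rank")
    df_resid = n - p
    if df_resid < 1:
        raise ValidationError("zero residual degrees of freedom")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = weights.to_numpy(dtype=float)
        if (w <= 0).any():
            raise ValidationError("precision weights must be strictly positive")
    c_mat = contrasts.reindex(design.columns).to_numpy(dtype=float)
    if np.isnan(c_mat).any():
        raise ValidationError("contrast rows do not match the design columns")

    xtwx = np.einsum("np,gn,nq->gpq", x, w, x)
    xtwy = np.einsum("np,gn,gn->gp", x, w, y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    resid = y - beta @ x.T
    s2 = np.einsum("gn,gn->g", w, resid**2) / df_resid
    cov_unscaled = np.linalg.inv(xtwx)
    var_c = np.einsum("pc,gpq,qc->gc", c_mat, cov_unscaled, c_mat)
    log_fc = beta @ c_mat

    if prior_df is None:
        d0, s02 = _fit_log_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValidationError("prior_df must be non-negative")
        if np.isinf(d0):
            if prior_var is None:
                raise ValidationError("prior_var is required when prior_df is infinite")
            s02 = float(prior_var)
        elif d0 == 0:
            s02 = float(prior_var) if prior_var is not None else float("nan")
        else:
            s02 = (
                float(prior_var)
                if prior_var is not None
                else _fit_log_variance_prior(s2, df_resid)[1]
            )

    pooled_df = float(df_resid) * len(genes)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = pooled_df
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        # total df capped at the pooled residual df: the prior cannot carry
        # more information than the data it was estimated from
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = min(d0 + df_resid, pooled_df)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / np.sqrt(s2_post[:, None] * var_c)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)

    long = pd.DataFrame(
        {
            "gene": np.repeat(genes.to_numpy(), c_mat.shape[1]),
            "contrast": np.tile(np.array(contrasts.columns), len(genes)),
            "log_fc": log_fc.ravel(),
            "t": t.ravel(),
            "df": df_total if np.isfinite(df_total) else np.inf,
            "p_raw": p_raw.ravel(),
        }
    )
    return DEResult(
        table=long,
        cell_means=pd.DataFrame(beta, index=genes, columns=design.columns),
        sigma2=pd.Series(s2, index=genes, name="sigma2"),
        residual_df=float(df_resid),
        prior_df=float(d0),
        prior_var=float(s02),
        contrast_names=list(contrasts.columns),
    )


def global_decide(result: DEResult, alpha: float = 0.05) -> DEResult:
    """Benjamini-Hochberg on the pooled gene x contrast p-values.

    One adjustment across the whole matrix; decisions are up/down by the sign
    of the effect where the adjusted p falls below ``alpha``. A gene counts as
    differentially expressed if it is significant in at least one contrast.
    """
    table = result.table.copy()
    if table["p_raw"].isna().any():
        raise ValidationError("p-values missing for some gene x contrast cells")
    _, p_adj, _, _ = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")
    table["p_adj"] = p_adj
    decision = np.where(
        p_adj < alpha, np.where(table["log_fc"] > 0, "up", "down"), "ns"
    )
    table["decision"] = decision
    result.table = table
    result.alpha = alpha
    return result


# -------------------------------------------------------------- clustering


def cluster_de_genes(logcpm_de: pd.DataFrame, k: int = 10) -> pd.Series:
    """Cluster DE genes into k expression-profile clusters.

    Rows are standardized to Z-scores across samples, then hierarchically
    clustered (Euclidean distance, Ward linkage) and the tree cut at ``k``
    clusters. Deterministic for fixed input.
    """
    n = len(logcpm_de)
    if k < 1:
        raise ValidationError("k must be at least 1")
    if k > n:
        raise ValidationError(f"cannot cut {n} genes into {k} clusters")
    x = logcpm_de.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    if k == 1 or n == 1:
        labels = np.ones(n, dtype=int)
    else:
        labels = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust")
    return pd.Series(labels, index=logcpm_de.index, name="cluster")
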