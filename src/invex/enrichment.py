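"""Genomic-location enrichment of DE genes and chromosome-Z bias tests.

Three views of "where are the differentially expressed genes":

* sliding-window enrichment -- hypergeometric upper-tail test per window of
  the chromosome (windows tile with step = window_size / steps_per_window),
  BH-adjusted across all windows, overlapping significant windows merged
  into enriched regions;
* chromosome bias -- Yates-corrected chi-squared (1 df goodness-of-fit) of
  the observed Z vs autosome DE counts against the genomic distribution of
  genes;
* Z:autosome ratio -- ratio of the median normalized expression of Z-linked
  genes to autosomal genes per sample group, a probe for chromosome-wide
  dosage effects.

Scaffolds (chromosome labels that are neither Z nor autosome-like) are
excluded from the Z/autosome partitions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError

__all__ = [
    "make_windows",
    "window_enrichment",
    "WindowEnrichmentResult",
    "chrom_bias_test",
    "ChromBiasResult",
    "z_autosome_ratio",
    "split_z_autosome",
]


# ---------------------------------------------------------------- windows


def make_windows(
    chrom_lengths: Mapping[str, int],
    window_size: int,
    steps_per_window: int = 4,
) -> pd.DataFrame:
    """Tile chromosomes with windows stepping by window_size/steps_per_window.

    Each basepair belongs to exactly ``steps_per_window`` windows except near
    the chromosome ends; window ends are clamped to the chromosome length.
    """
    if window_size <= 0 or steps_per_window <= 0:
        raise ValidationError("window_size and steps_per_window must be positive")
    step = window_size // steps_per_window
    if step == 0:
        raise ValidationError("window_size must be at least steps_per_window")
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length), step):
            rows.append((chrom, start, min(start + window_size, int(length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class WindowEnrichmentResult:
    windows: pd.DataFrame  # chrom,start,end,n_expressed,n_de,p,q,significant
    regions: pd.DataFrame  # merged overlapping significant windows

    @property
    def n_significant(self) -> int:
        return int(self.windows["significant"].sum())


def _merge_windows(sig: pd.DataFrame) -> pd.DataFrame:
    regions = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end = row["start"], row["end"]
            elif row["start"] <= cur_end:
                cur_end = max(cur_end, row["end"])
            else:
                regions.append((chrom, cur_start, cur_end))
                cur_start, cur_end = row["start"], row["end"]
        if cur_start is not None:
            regions.append((chrom, cur_start, cur_end))
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


def window_enrichment(
    de_genes: Iterable[str],
    expressed: pd.DataFrame,
    window_size: int,
    *,
    steps_per_window: int = 4,
    fdr: float = 0.01,
    chrom_lengths: Mapping[str, int] | None = None,
) -> WindowEnrichmentResult:
    """Hypergeometric window enrichment of DE genes among expressed genes.

    ``expressed`` is indexed by gene id with columns chrom and start; a gene
    belongs to a window iff its start coordinate falls inside it. Per window
    the upper-tail hypergeometric probability of drawing that many DE genes
    in the window's expressed genes (from the totals) is computed, BH-adjusted
    across all windows, and overlapping significant windows are merged into
    enriched regions.
    """
    de = pd.Index(pd.unique(pd.Series(list(de_genes))))
    missing = de.difference(expressed.index)
    if len(missing):
        raise ValidationError(
            f"DE genes absent from the expressed background: {missing[:5].tolist()}"
        )
    n_total = len(expressed)
    k_total = len(de)
    if chrom_lengths is None:
        chrom_lengths = {
            chrom: int(grp["start"].max()) + 1
            for chrom, grp in expressed.groupby("chrom", sort=False)
        }
    windows = make_windows(chrom_lengths, window_size, steps_per_window)

    is_de = expressed.index.isin(de)
    n_exp = np.zeros(len(windows), dtype=int)
    n_de = np.zeros(len(windows), dtype=int)
    for chrom, grp in expressed.groupby("chrom", sort=False):
        wsel = windows["chrom"] == chrom
        if not wsel.any():
            continue
        starts = grp["start"].to_numpy()
        de_mask = is_de[expressed["chrom"].to_numpy() == chrom]
        order = np.argsort(starts)
        starts = starts[order]
        de_sorted = de_mask[order]
        de_cum = np.concatenate([[0], np.cumsum(de_sorted)])
        w = windows.loc[wsel]
        lo = np.searchsorted(starts, w["start"].to_numpy(), side="left")
        hi = np.searchsorted(starts, w["end"].to_numpy(), side="left")
        n_exp[wsel.to_numpy()] = hi - lo
        n_de[wsel.to_numpy()] = de_cum[hi] - de_cum[lo]

    p = stats.hypergeom.sf(n_de - 1, n_total, k_total, n_exp)
    p = np.clip(p, 0.0, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    windows = windows.assign(
        n_expressed=n_exp, n_de=n_de, p=p, q=q, significant=(q < fdr) & (n_de > 0)
    )
    regions = _merge_windows(windows.loc[windows["significant"]])
    return WindowEnrichmentResult(windows=windows, regions=regions)


# ---------------------------------------------------------- chromosome bias


def split_z_autosome(
    chroms: pd.Series,
    *,
    z_label: str = "Z",
    autosomes: Sequence[str] | None = None,
) -> pd.Series:
    """Classify chromosome labels as 'Z', 'autosome' or 'scaffold'.

    With ``autosomes=None`` any purely numeric label counts as an autosome;
    everything that is neither Z nor autosome-like is a scaffold and is
    excluded from the bias tests and expression ratios.
    """
    labels = chroms.astype(str)
    if autosomes is None:
        is_auto = labels.str.fullmatch(r"\d+")
    else:
        is_auto = labels.isin(set(map(str, autosomes)))
    out = pd.Series("scaffold", index=chroms.index, dtype=object)
    out[is_auto] = "autosome"
    out[labels == z_label] = "Z"
    return out


@dataclass
class ChromBiasResult:
    n_de_z: int
    n_de_autosome: int
    n_genes_z: int
    n_genes_autosome: int
    statistic: float
    p_value: float
    df: int
    low_expected: bool
    mode: str


def chrom_bias_test(
    de_genes: Iterable[str],
    universe: pd.Series,
    *,
    z_label: str = "Z",
    autosomes: Sequence[str] | None = None,
    mode: str = "goodness_of_fit",
) -> ChromBiasResult:
    """Yates-corrected chi-squared test for Z overrepresentation of DE genes.

    ``universe`` maps gene id -> chromosome label for the background gene set
    (scaffolds are dropped). The headline mode is a 1-df goodness-of-fit of
    the observed (Z, autosome) DE counts against expectations proportional to
    the background; ``mode='contingency'`` instead runs the 2x2 test of DE
    membership against chromosome class.
    """
    part = split_z_autosome(universe, z_label=z_label, autosomes=autosomes)
    keep = part != "scaffold"
    part = part[keep]
    genes_z = int((part == "Z").sum())
    genes_auto = int((part == "autosome").sum())
    if genes_z == 0 or genes_auto == 0:
        raise ValidationError("universe must contain both Z and autosomal genes")
    de = pd.Index(pd.unique(pd.Series(list(de_genes)))).intersection(part.index)
    o_z = int((part.loc[de] == "Z").sum())
    o_a = len(de) - o_z

    if mode == "contingency":
        table = np.array([[o_z, o_a], [genes_z - o_z, genes_auto - o_a]])
        chi2, p, df, expected = stats.chi2_contingency(table, correction=True)
        low = bool((expected < 1).any())
        return ChromBiasResult(o_z, o_a, genes_z, genes_auto, float(chi2), float(p), int(df), low, mode)
    if mode != "goodness_of_fit":
        raise ValidationError(f"unknown chrom bias mode {mode!r}")

    n_de = o_z + o_a
    total = genes_z + genes_auto
    e_z = n_de * genes_z / total
    e_a = n_de * genes_auto / total
    low = e_z < 1 or e_a < 1
    if n_de == 0:
        return ChromBiasResult(0, 0, genes_z, genes_auto, 0.0, 1.0, 1, low, mode)
    x2 = (abs(o_z - e_z) - 0.5) ** 2 / e_z + (abs(o_a - e_a) - 0.5) ** 2 / e_a
    p = float(stats.chi2.sf(x2, 1))
    return ChromBiasResult(o_z, o_a, genes_z, genes_auto, float(x2), p, 1, low, mode)


# --------------------------------------------------------- Z:autosome ratio


def z_autosome_ratio(
    logcpm: pd.DataFrame,
    gene_chroms: pd.Series,
    meta: pd.DataFrame,
    *,
    group_cols: Sequence[str] = ("karyotype", "tissue", "timepoint"),
    z_label: str = "Z",
    autosomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median Z expression over median autosomal expression per sample group.

    Computed over the retained (expressed) genes only; scaffolds excluded.
    Groups with an autosomal median of zero get a NaN ratio and an
    ``undefined`` flag instead of an error.
    """
    part = split_z_autosome(gene_chroms.loc[logcpm.index], z_label=z_label, autosomes=autosomes)
    z_genes = part.index[part == "Z"]
    auto_genes = part.index[part == "autosome"]
    if len(z_genes) == 0 or len(auto_genes) == 0:
        raise ValidationError("need at least one Z and one autosomal gene retained")
    rows = []
    for key, grp in meta.groupby(list(group_cols), sort=True):
        samples = [s for s in grp.index if s in logcpm.columns]
        if not samples:
            continue
        z_med = float(np.median(logcpm.loc[z_genes, samples].to_numpy()))
        a_med = float(np.median(logcpm.loc[auto_genes, samples].to_numpy()))
        undefined = a_med == 0
        ratio = np.nan if undefined else z_med / a_med
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(group_cols, key)) | {
            "z_median": z_med,
            "autosome_median": a_med,
            "ratio": ratio,
            "undefined": undefined,
        })
    return pd.DataFrame(rows)
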