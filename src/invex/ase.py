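"""Allele-specific expression from inversion-diagnostic SNPs.

In a heterokaryotype (AB) every read at a SNP that is (near-)fixed for
different alleles in the AA and BB homokaryotype groups can be attributed to
the A or the B* inversion haplotype. This module filters the variant calls,
intersects them with genes, assigns the A/B* alleles per SNP from the pooled
homokaryotype allelic depths, quantifies per-gene A-allele expression
proportions, and classifies the dominance pattern of heterokaryotype
expression relative to the two homokaryotypes.

The variant filters default to the stringent transcriptome settings
(QUAL >= 999, site INFO/DP >= 640, per-genotype DP >= 8 and GQ >= 10,
indels dropped). Tag-SNP assignment formalizes a manual-curation step with an
explicit rule: a SNP is informative iff one allele reaches the fixation
threshold in the pooled AA depths while staying below 1-threshold in the
pooled BB depths, with both pools sufficiently deep. Heterokaryotype samples
never influence the assignment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    STAGE_GROUPS,
    ValidationError,
    VariantTable,
    normalize_karyotype,
)

__all__ = [
    "filter_variants",
    "map_variants_to_genes",
    "assign_tag_alleles",
    "ase_proportion",
    "classify_pattern",
    "PATTERNS",
]

PATTERNS = (
    "A_dominant",
    "B_dominant",
    "intermediate",
    "divergent_over_time",
    "switching",
    "unclassified",
)


# ------------------------------------------------------------------ filter


def filter_variants(
    variants: VariantTable,
    *,
    min_qual: float = 999,
    min_site_dp: int = 640,
    min_sample_dp: int = 8,
    min_gq: int = 10,
    drop_indels: bool = True,
    require_complete: bool = False,
) -> VariantTable:
    """Site- and genotype-level variant filtering.

    Sites with QUAL < ``min_qual``, indels, or INFO/DP < ``min_site_dp`` are
    removed. Genotypes with DP < ``min_sample_dp`` or GQ < ``min_gq`` are set
    missing (their allelic depths are zeroed so they cannot contribute
    downstream). With ``require_complete`` any site left with a missing
    genotype is removed (the merged-tissue, no-missing-data mode).
    """
    qual = variants.sites["qual"].to_numpy(dtype=float)
    info_dp = variants.sites["info_dp"].to_numpy(dtype=float)
    site_keep = (qual >= min_qual) & (info_dp >= min_site_dp)
    if drop_indels:
        site_keep &= ~variants.is_indel()
    out = variants.take_sites(site_keep)

    bad = (out.dp < min_sample_dp) | (out.gq < min_gq)
    out.gt[bad] = -1
    out.ad_ref[bad] = 0
    out.ad_alt[bad] = 0
    if require_complete:
        out = out.take_sites(~(out.gt == -1).any(axis=1))
    return out


# ------------------------------------------------------- gene intersection


def map_variants_to_genes(variants: VariantTable, genes: pd.DataFrame) -> pd.DataFrame:
    """Intersect variants with gene intervals.

    ``genes`` is indexed by gene id with 0-based half-open columns
    chrom/start/end; a variant at 1-based position P pairs with gene
    [start, end) iff start <= P-1 < end. A variant inside overlapping genes
    yields one pair per gene. Returns columns site_idx, gene_id.
    """
    pairs: list[tuple[int, str]] = []
    pos0 = variants.sites["pos"].to_numpy(dtype=np.int64) - 1
    chroms = variants.sites["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        vsel = np.flatnonzero(chroms == chrom)
        if not len(vsel):
            continue
        vpos = pos0[vsel]
        order = np.argsort(vpos, kind="stable")
        vsel, vpos = vsel[order], vpos[order]
        gsel = genes.loc[genes["chrom"] == chrom]
        for gene_id, row in gsel.iterrows():
            lo = np.searchsorted(vpos, row["start"], side="left")
            hi = np.searchsorted(vpos, row["end"], side="left")
            pairs.extend((int(vsel[i]), gene_id) for i in range(lo, hi))
    out = pd.DataFrame(pairs, columns=["site_idx", "gene_id"])
    return out.sort_values(["site_idx", "gene_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------- tag assignment


def assign_tag_alleles(
    variants: VariantTable,
    pairs: pd.DataFrame,
    karyotypes: pd.Series,
    *,
    fixation: float = 0.9,
    min_group_depth: int = 20,
) -> pd.DataFrame:
    """Assign the A- and B*-haplotype alleles per (variant, gene) pair.

    Allelic depths are pooled across the AA samples and across the BB samples
    (heterokaryotypes never contribute). The candidate A allele is the
    AA-major allele; the SNP is informative iff that allele's pooled fraction
    is >= ``fixation`` in AA and <= 1-``fixation`` in BB, with both pooled
    depths >= ``min_group_depth``. Sites without AA or BB coverage are marked
    unassignable rather than raising.

    Returns the tag-SNP table with columns site_idx, chrom, pos, gene_id,
    a_allele ('ref'/'alt' or None), b_allele, aa_frac_a, bb_frac_a, aa_depth,
    bb_depth, informative.
    """
    kar = pd.Series({s: normalize_karyotype(k) for s, k in karyotypes.items()})
    aa_idx = variants.sample_index([s for s in variants.samples if kar.get(s) == "AA"])
    bb_idx = variants.sample_index([s for s in variants.samples if kar.get(s) == "BB"])

    aa_ref = variants.ad_ref[:, aa_idx].sum(axis=1)
    aa_alt = variants.ad_alt[:, aa_idx].sum(axis=1)
    bb_ref = variants.ad_ref[:, bb_idx].sum(axis=1)
    bb_alt = variants.ad_alt[:, bb_idx].sum(axis=1)
    aa_depth = aa_ref + aa_alt
    bb_depth = bb_ref + bb_alt

    rows = []
    for site_idx, gene_id in pairs.itertuples(index=False):
        i = int(site_idx)
        site = variants.sites.iloc[i]
        if aa_depth[i] == 0 or bb_depth[i] == 0:
            rows.append(
                dict(site_idx=i, chrom=site["chrom"], pos=int(site["pos"]),
                     gene_id=gene_id, a_allele=None, b_allele=None,
                     aa_frac_a=np.nan, bb_frac_a=np.nan,
                     aa_depth=int(aa_depth[i]), bb_depth=int(bb_depth[i]),
                     informative=False)
            )
            continue
        a_allele = "ref" if aa_ref[i] >= aa_alt[i] else "alt"
        if a_allele == "ref":
            aa_frac = aa_ref[i] / aa_depth[i]
            bb_frac = bb_ref[i] / bb_depth[i]
        else:
            aa_frac = aa_alt[i] / aa_depth[i]
            bb_frac = bb_alt[i] / bb_depth[i]
        informative = (
            aa_frac >= fixation
            and bb_frac <= 1.0 - fixation
            and aa_depth[i] >= min_group_depth
            and bb_depth[i] >= min_group_depth
        )
        rows.append(
            dict(site_idx=i, chrom=site["chrom"], pos=int(site["pos"]),
                 gene_id=gene_id, a_allele=a_allele,
                 b_allele="alt" if a_allele == "ref" else "ref",
                 aa_frac_a=float(aa_frac), bb_frac_a=float(bb_frac),
                 aa_depth=int(aa_depth[i]), bb_depth=int(bb_depth[i]),
                 informative=bool(informative))
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- proportions


def ase_proportion(
    variants: VariantTable,
    tags: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per gene x sample A-allele expression proportion.

    p_A = sum of A-allele depths over all informative SNPs in the gene,
    divided by the total depth over those SNPs. Rows with zero informative
    depth are flagged undefined (p_a = NaN). When ``meta`` (indexed by sample
    id with a tissue column) is given, the tissue is attached.
    """
    info = tags.loc[tags["informative"]]
    rows = []
    for gene_id, grp in info.groupby("gene_id", sort=True):
        idx = grp["site_idx"].to_numpy(dtype=int)
        a_is_ref = (grp["a_allele"] == "ref").to_numpy()
        ad_a = np.where(a_is_ref[:, None], variants.ad_ref[idx], variants.ad_alt[idx])
        total = variants.ad_ref[idx] + variants.ad_alt[idx]
        a_sum = ad_a.sum(axis=0)
        t_sum = total.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_a = np.where(t_sum > 0, a_sum / np.maximum(t_sum, 1), np.nan)
        for j, sample in enumerate(variants.samples):
            rows.append(
                dict(gene_id=gene_id, sample_id=sample,
                     p_a=float(p_a[j]) if t_sum[j] > 0 else np.nan,
                     n_informative_snps=int((total[:, j] > 0).sum()),
                     total_depth=int(t_sum[j]),
                     defined=bool(t_sum[j] > 0))
            )
    out = pd.DataFrame(rows)
    if meta is not None and len(out):
        out["tissue"] = out["sample_id"].map(meta["tissue"])
    return out


# -------------------------------------------------------- dominance pattern


def _group_label(delta: float, tau: float) -> str:
    if delta >= 1.0 - tau:
        return "A"
    if delta <= tau:
        return "B"
    return "I"


_COMBINE = {
    ("A", "A"): "A_dominant",
    ("B", "B"): "B_dominant",
    ("I", "I"): "intermediate",
    ("I", "A"): "divergent_over_time",
    ("I", "B"): "divergent_over_time",
    ("A", "I"): "divergent_over_time",
    ("B", "I"): "divergent_over_time",
    ("A", "B"): "switching",
    ("B", "A"): "switching",
}


def classify_pattern(
    cell_means: pd.DataFrame,
    *,
    tau: float = 0.25,
    min_effect_log2: float = 1.0,
) -> pd.DataFrame:
    """Classify heterokaryotype dominance patterns from fitted cell means.

    ``cell_means`` is genes x the six karyotype.stage_group cells (mean
    logCPM). Per stage group the dominance score

        delta = (mu_AB - mu_BB) / (mu_AA - mu_BB)

    is 1 when the heterokaryotype matches AA and 0 when it matches BB
    (the expression is orientation-free: negating all means leaves delta
    unchanged). Per group the heterokaryotype is A-like (delta >= 1-tau),
    B-like (delta <= tau) or intermediate; the EARLY/LATE pair of labels maps
    onto the pattern taxonomy. Genes whose homokaryotype separation
    |mu_AA - mu_BB| falls below ``min_effect_log2`` in either group are
    unclassified.
    """
    needed = [f"{k}.{g}" for g in STAGE_GROUPS for k in ("AA", "AB", "BB")]
    missing = [c for c in needed if c not in cell_means.columns]
    if missing:
        raise ValidationError(f"cell means lack columns {missing}")
    if cell_means[needed].isna().any().any():
        bad = cell_means.index[cell_means[needed].isna().any(axis=1)][:5].tolist()
        raise ValidationError(f"missing cell means for genes {bad}")
    rows = []
    for gene, m in cell_means.iterrows():
        deltas: dict[str, float] = {}
        labels: dict[str, str] = {}
        classifiable = True
        for grp in STAGE_GROUPS:
            sep = m[f"AA.{grp}"] - m[f"BB.{grp}"]
            if abs(sep) < min_effect_log2:
                classifiable = False
                deltas[grp] = np.nan
                labels[grp] = "NA"
                continue
            delta = (m[f"AB.{grp}"] - m[f"BB.{grp}"]) / sep
            deltas[grp] = float(delta)
            labels[grp] = _group_label(delta, tau)
        pattern = (
            _COMBINE[(labels["EARLY"], labels["LATE"])] if classifiable else "unclassified"
        )
        rows.append(
            dict(gene_id=gene, delta_early=deltas["EARLY"], delta_late=deltas["LATE"],
                 label_early=labels["EARLY"], label_late=labels["LATE"], pattern=pattern)
        )
    return pd.DataFrame(rows).set_index("gene_id", drop=False)
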