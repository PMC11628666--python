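"""Genotype polarization, fixed-difference block segmentation, pairwise r2.

Transcriptome-derived genotypes along the Z chromosome are polarized toward
the AA karyotype (the allele most common among AA individuals becomes the
zero state), which makes inversion blocks visible as homozygous/heterozygous
bands: inside an inverted region AA individuals sit at dosage ~0, BB at ~2
and AB at ~1.

Block segmentation turns the visual delineation of such bands into a testable
rule: per SNP the absolute pooled allele-frequency difference between the AA
and BB groups is smoothed with a centred moving average over ``m_snps`` SNPs;
maximal runs with smoothed differentiation above the threshold are candidate
blocks, whose edges are then refined outward over contiguous raw
per-SNP values still above the threshold (the centred average alone erodes
block edges by about half the smoothing window, which would bias the
breakpoint estimates inward). Breakpoints are the refined outermost SNP
positions extended half-way to the neighbouring SNP.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ValidationError, VariantTable, normalize_karyotype

__all__ = [
    "PolarizedGenotypes",
    "polarize",
    "BlockSegmentation",
    "segment_blocks",
    "pairwise_r2",
    "plot_genotypes",
]

logger = logging.getLogger("invex.landscape")


@dataclass
class PolarizedGenotypes:
    """Dosages of the non-AA-major allele per SNP (rows) and sample (columns).

    ``dosage`` is int8 with -1 for missing; ``flipped`` records the SNPs whose
    alternate allele was the AA-major allele and was therefore re-coded to 0.
    """

    chrom: np.ndarray
    positions: np.ndarray
    snp_ids: list[str]
    samples: list[str]
    dosage: np.ndarray
    flipped: np.ndarray

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.positions), len(self.samples)):
            raise ValidationError("dosage matrix shape does not match SNPs x samples")


def _karyotype_series(karyotypes: pd.Series | dict, samples: list[str]) -> pd.Series:
    kar = pd.Series(karyotypes)
    out = {}
    for s in samples:
        if s in kar.index:
            out[s] = normalize_karyotype(kar[s])
    return pd.Series(out)


def polarize(
    variants: VariantTable | PolarizedGenotypes,
    karyotypes: pd.Series | dict,
) -> PolarizedGenotypes:
    """Re-code genotype dosages so the AA-major allele is the zero state.

    At each SNP the allele with majority dosage among the AA samples is coded
    0 and every sample becomes the count of the other allele; ties are broken
    toward the reference allele (no flip). SNPs with no genotyped AA sample
    are dropped with a log record; an entirely empty AA group is an error.
    Polarizing an already-polarized matrix is a no-op (idempotent).
    """
    if isinstance(variants, PolarizedGenotypes):
        chrom = variants.chrom
        pos = variants.positions
        snp_ids = list(variants.snp_ids)
        samples = list(variants.samples)
        dosage = variants.dosage.copy()
        prior_flip = variants.flipped.copy()
    else:
        chrom = variants.sites["chrom"].to_numpy()
        pos = variants.sites["pos"].to_numpy(dtype=np.int64)
        snp_ids = variants.keys().tolist()
        samples = list(variants.samples)
        dosage = variants.gt.astype(np.int8).copy()
        prior_flip = np.zeros(len(pos), dtype=bool)

    kar = _karyotype_series(karyotypes, samples)
    aa_cols = [i for i, s in enumerate(samples) if kar.get(s) == "AA"]
    if not aa_cols:
        raise ValidationError("no AA samples available for polarization")
    aa = dosage[:, aa_cols].astype(float)
    aa[aa < 0] = np.nan
    n_called = np.sum(~np.isnan(aa), axis=1)
    keep = n_called > 0
    if (~keep).any():
        logger.info("dropping %d SNPs with no genotyped AA sample", int((~keep).sum()))
    with np.errstate(invalid="ignore"):
        mean_alt = np.nansum(aa, axis=1) / (2.0 * np.maximum(n_called, 1))
    flip = (mean_alt > 0.5) & keep  # strict: ties stay on the reference allele

    out = dosage.copy()
    missing = out < 0
    out[flip] = 2 - out[flip]
    out[missing] = -1
    return PolarizedGenotypes(
        chrom=chrom[keep],
        positions=pos[keep],
        snp_ids=[s for s, k in zip(snp_ids, keep) if k],
        samples=samples,
        dosage=out[keep],
        flipped=(prior_flip ^ flip)[keep],
    )


# ------------------------------------------------------------ segmentation


@dataclass
class BlockSegmentation:
    per_snp: pd.DataFrame  # chrom,pos,d,smoothed
    blocks: pd.DataFrame  # chrom,start,end,n_snps
    breakpoints: list[int]


def _group_allele_freq(dosage: np.ndarray, cols: list[int]) -> np.ndarray:
    sub = dosage[:, cols].astype(float)
    sub[sub < 0] = np.nan
    called = np.sum(~np.isnan(sub), axis=1)
    with np.errstate(invalid="ignore"):
        out = np.nansum(sub, axis=1) / (2.0 * np.maximum(called, 1))
    out[called == 0] = np.nan
    return out


def segment_blocks(
    polarized: PolarizedGenotypes,
    karyotypes: pd.Series | dict,
    *,
    m_snps: int = 11,
    threshold: float = 0.8,
) -> BlockSegmentation:
    """Delineate fixed-difference blocks between the homokaryotype groups.

    Per SNP d = |AF_AA - AF_BB| from pooled allele frequencies; a centred
    moving average over ``m_snps`` SNPs is thresholded to find candidate
    runs, run edges are refined outward over contiguous raw d >= threshold,
    and block bounds extend half-way to the neighbouring SNP.
    """
    n = len(polarized.positions)
    if n < m_snps:
        raise ValidationError(f"need at least m_snps={m_snps} SNPs, got {n}")
    kar = _karyotype_series(karyotypes, list(polarized.samples))
    aa_cols = [i for i, s in enumerate(polarized.samples) if kar.get(s) == "AA"]
    bb_cols = [i for i, s in enumerate(polarized.samples) if kar.get(s) == "BB"]
    if not aa_cols or not bb_cols:
        raise ValidationError("segmentation needs both AA and BB samples")

    per_snp_frames = []
    blocks = []
    breakpoints: list[int] = []
    order = np.lexsort((polarized.positions, polarized.chrom))
    chrom_sorted = polarized.chrom[order]
    for chrom in pd.unique(chrom_sorted):
        sel = order[chrom_sorted == chrom]
        pos = polarized.positions[sel]
        dosage = polarized.dosage[sel]
        af_aa = _group_allele_freq(dosage, aa_cols)
        af_bb = _group_allele_freq(dosage, bb_cols)
        d = np.abs(af_aa - af_bb)
        d = np.nan_to_num(d, nan=0.0)
        smoothed = (
            pd.Series(d).rolling(m_snps, center=True, min_periods=1).mean().to_numpy()
        )
        per_snp_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "d": d, "smoothed": smoothed})
        )
        above = smoothed >= threshold
        i = 0
        m = len(pos)
        while i < m:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < m and above[j + 1]:
                j += 1
            # refine edges over contiguous raw differentiation
            lo, hi = i, j
            while lo - 1 >= 0 and d[lo - 1] >= threshold:
                lo -= 1
            while hi + 1 < m and d[hi + 1] >= threshold:
                hi += 1
            start = int(pos[lo] - (pos[lo] - pos[lo - 1]) // 2) if lo > 0 else int(pos[lo])
            end = int(pos[hi] + (pos[hi + 1] - pos[hi]) // 2) if hi < m - 1 else int(pos[hi])
            blocks.append((chrom, start, end, hi - lo + 1))
            breakpoints.extend([start, end])
            i = j + 1

    return BlockSegmentation(
        per_snp=pd.concat(per_snp_frames, ignore_index=True),
        blocks=pd.DataFrame(blocks, columns=["chrom", "start", "end", "n_snps"]),
        breakpoints=breakpoints,
    )


# ------------------------------------------------------------- pairwise r2


def pairwise_r2(
    polarized: PolarizedGenotypes,
    max_pairs: int | None = None,
) -> pd.DataFrame:
    """Squared Pearson correlation of dosage vectors for SNP pairs.

    Correlations use the samples non-missing at both SNPs; pairs where either
    SNP has fewer than two shared calls or zero variance are flagged
    ``degenerate`` with a NaN r2. With ``max_pairs`` the pair list is evenly
    subsampled (deterministically) to that many pairs.
    """
    n = len(polarized.positions)
    pairs = list(combinations(range(n), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        idx = np.unique(np.linspace(0, len(pairs) - 1, max_pairs).astype(int))
        pairs = [pairs[i] for i in idx]
    dosage = polarized.dosage.astype(float)
    dosage[dosage < 0] = np.nan
    rows = []
    for i, j in pairs:
        xi, xj = dosage[i], dosage[j]
        ok = ~np.isnan(xi) & ~np.isnan(xj)
        degenerate = ok.sum() < 2 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0
        if degenerate:
            r2 = np.nan
        else:
            r = np.corrcoef(xi[ok], xj[ok])[0, 1]
            r2 = float(r * r)
        rows.append(
            dict(snp_i=polarized.snp_ids[i], snp_j=polarized.snp_ids[j],
                 pos_i=int(polarized.positions[i]), pos_j=int(polarized.positions[j]),
                 n=int(ok.sum()), r2=r2, degenerate=bool(degenerate))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- plotting


def plot_genotypes(
    polarized: PolarizedGenotypes,
    karyotypes: pd.Series | dict,
    path: str,
) -> None:
    """Write a samples x SNPs genotype heatmap PNG (three-colour coding)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    kar = _karyotype_series(karyotypes, list(polarized.samples))
    order = sorted(range(len(polarized.samples)), key=lambda i: kar.get(polarized.samples[i], "?"))
    img = polarized.dosage[:, order].T.astype(float)
    img[img < 0] = np.nan
    cmap = ListedColormap(["#d62728", "#2ca02c", "#1f77b4"])  # hom-ref, het, hom-alt
    fig, ax = plt.subplots(figsize=(10, max(2, 0.15 * len(order))))
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0, vmax=2, interpolation="nearest")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([polarized.samples[i] for i in order], fontsize=5)
    ax.set_xlabel("SNP index along chromosome")
    ax.set_title("Polarized genotypes (0 = AA-major allele)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
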