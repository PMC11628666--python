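"""Shared vocabulary, exceptions and in-memory containers.

Coordinate conventions used throughout the package:

* gene intervals are stored 0-based half-open (BED convention);
* variant positions are 1-based (VCF convention).

A variant at 1-based position ``P`` lies inside a gene ``[start, end)``
iff ``start <= P - 1 < end``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

KARYOTYPES = ("AA", "AB", "BB")
TISSUES = ("testis", "liver")
STAGES = ("inactive", "accelerating_I", "accelerating_II", "active")
STAGE_GROUPS = ("EARLY", "LATE")
EARLY_STAGES = ("inactive", "accelerating_I")
LATE_STAGES = ("accelerating_II", "active")
TIMEPOINT_TO_STAGE = {
    1: "inactive",
    2: "accelerating_I",
    3: "accelerating_II",
    4: "active",
}

# the derived B and C inversion haplotypes are analysed as one merged class B*;
# we write the karyotypes AA / AB / BB for AA / AB* / B*B*.
_KARYOTYPE_ALIASES = {
    "AA": "AA",
    "AB": "AB",
    "AB*": "AB",
    "A/B": "AB",
    "BB": "BB",
    "B*B*": "BB",
    "B/B": "BB",
}
_MERGED_HINTS = {"AC": "AB", "CA": "AB", "BC": "BB", "CB": "BB", "CC": "BB"}


class InvexError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(InvexError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(InvexError):
    """Invalid or inconsistent input data."""


class PipelineError(InvexError):
    """A pipeline stage failed; the message names the stage."""


def normalize_karyotype(label: object) -> str:
    """Map a karyotype label onto the canonical {AA, AB, BB} vocabulary.

    Labels that name the unmerged B/C haplotypes (e.g. ``"AC"``) raise a
    :class:`ValidationError` suggesting the merged class.
    """
    lab = str(label).strip()
    if lab in _KARYOTYPE_ALIASES:
        return _KARYOTYPE_ALIASES[lab]
    if lab.upper() in _MERGED_HINTS:
        raise ValidationError(
            f"unknown karyotype {label!r}: the derived B and C inversion haplotypes "
            f"are analysed as the merged class B*; use {_MERGED_HINTS[lab.upper()]!r}"
        )
    raise ValidationError(
        f"unknown karyotype {label!r}; expected one of {list(KARYOTYPES)}"
    )


GENE_COLUMNS = ("chrom", "start", "end", "strand", "biotype")


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (index = gene id, BED coordinates)."""
    if genes.index.has_duplicates:
        dups = genes.index[genes.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated gene ids in annotation: {dups[:5]}")
    missing = [c for c in ("chrom", "start", "end") if c not in genes.columns]
    if missing:
        raise ValidationError(f"gene annotation lacks required columns {missing}")
    out = genes.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] < 0).any() or (out["end"] <= out["start"]).any():
        bad = out.index[(out["start"] < 0) | (out["end"] <= out["start"])][:5].tolist()
        raise ValidationError(f"invalid gene coordinates (need 0 <= start < end): {bad}")
    if "strand" not in out.columns:
        out["strand"] = "+"
    if "biotype" not in out.columns:
        out["biotype"] = "protein_coding"
    return out


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with gene genomic annotation.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``genes`` is indexed by gene id with columns chrom/start/end/strand/biotype
    and must cover every row of ``counts``.
    """

    counts: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicated gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicated sample ids in count matrix")
        vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        self.genes = validate_gene_table(self.genes)
        missing = self.counts.index.difference(self.genes.index)
        if len(missing):
            raise ValidationError(
                f"annotation does not cover {len(missing)} genes, e.g. {missing[:5].tolist()}"
            )
        # keep annotation aligned with the count rows
        self.genes = self.genes.loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        idx = pd.Index(gene_ids)
        return CountMatrix(self.counts.loc[idx], self.genes.loc[idx])


METADATA_REQUIRED = ("sample_id", "karyotype", "tissue", "timepoint")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample metadata table.

    Returns a copy indexed by sample id with canonical karyotype labels,
    lower-case tissue labels and integer timepoints in 1..4.
    """
    df = meta.copy()
    if "sample_id" not in df.columns:
        if df.index.name == "sample_id":
            df = df.reset_index()
        else:
            raise ValidationError("metadata lacks a sample_id column")
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata lacks required columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample ids in metadata: {dups[:5]}")
    df["karyotype"] = [normalize_karyotype(k) for k in df["karyotype"]]
    df["tissue"] = df["tissue"].astype(str).str.lower()
    bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
    if bad_tissue:
        raise ValidationError(f"unknown tissue labels {bad_tissue}; expected {list(TISSUES)}")
    df["timepoint"] = df["timepoint"].astype(int)
    if not df["timepoint"].isin(TIMEPOINT_TO_STAGE).all():
        bad = sorted(set(df["timepoint"]) - set(TIMEPOINT_TO_STAGE))
        raise ValidationError(f"timepoints outside 1..4: {bad}")
    return df.set_index("sample_id", drop=False)


@dataclass
class VariantTable:
    """Variant calls with per-sample GT/DP/GQ/AD, 1-based positions.

    ``sites`` holds site-level fields (chrom, pos, ref, alt, qual, info_dp)
    with a 0..n-1 RangeIndex aligned to the per-sample arrays. ``gt`` is the
    alternate-allele dosage (0/1/2, -1 = missing).
    """

    sites: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n, s = len(self.sites), len(self.samples)
        for name in ("gt", "dp", "gq", "ad_ref", "ad_alt"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n, s):
                raise ValidationError(
                    f"per-sample array {name} has shape {arr.shape}, expected {(n, s)}"
                )
            setattr(self, name, arr)
        missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in self.sites.columns]
        if missing:
            raise ValidationError(f"variant table lacks site columns {missing}")
        if "qual" not in self.sites.columns:
            self.sites["qual"] = np.nan
        if "info_dp" not in self.sites.columns:
            self.sites["info_dp"] = self.dp.sum(axis=1)
        if n:
            for chrom, grp in self.sites.groupby("chrom", sort=False):
                if not grp["pos"].is_monotonic_increasing:
                    raise ValidationError(f"variant positions not sorted within {chrom}")
            if (self.ad_ref + self.ad_alt > self.dp).any():
                raise ValidationError("allelic depths exceed sample depth (AD sum > DP)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_indel(self) -> np.ndarray:
        ref = self.sites["ref"].astype(str).str.len()
        alt = self.sites["alt"].astype(str).str.len()
        return ((ref != 1) | (alt != 1)).to_numpy()

    def keys(self) -> pd.Series:
        """Variant keys 'chrom:pos' aligned with the site index."""
        return self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)

    def take_sites(self, mask: Sequence[bool] | np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return VariantTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            gt=self.gt[idx].copy(),
            dp=self.dp[idx].copy(),
            gq=self.gq[idx].copy(),
            ad_ref=self.ad_ref[idx].copy(),
            ad_alt=self.ad_alt[idx].copy(),
        )

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"sample {exc.args[0]!r} absent from variant table") from exc
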