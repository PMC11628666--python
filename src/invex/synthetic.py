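"""Synthetic inversion-karyotype transcriptome datasets with known truth.

The generator emulates the structure of a two-tissue (testis, liver) RNA-seq
study of three Z-chromosome inversion karyotypes (AA, AB, BB — with B the
merged derived haplotype class B*) sampled across four timepoints of testis
development:

* a 3 karyotypes x 4 timepoints design of birds, each contributing a testis
  and a liver sample (the default design has 32 birds);
* negative-binomial gene counts with gene-specific baselines, a LATE-stage
  trajectory in testis, and planted karyotype effects: *cis* effects confined
  to Z genes inside the configured inversion regions, *trans* effects on
  autosomal genes, with heterokaryotype cell means placed according to a
  dominance pattern (A-dominant, B-dominant, intermediate, divergent over
  time, switching);
* variant calls along Z with per-sample GT/DP/GQ/AD: diagnostic SNPs inside
  the inversion regions are near-fixed for opposite alleles in the AA and BB
  groups (haplotype-level leakage 1 - fixation_level), while SNPs outside the
  regions segregate independently of karyotype; heterokaryotype allelic
  depths at diagnostic SNPs are Binomial(depth, p_A) with gene- and
  tissue-specific A-allele proportions (the DMGDH-like case: monoallelic in
  testis, balanced in liver);
* histology section counts per bird consistent with the planted stage;
* a machine-readable truth record (DE genes per contrast, ASE proportions,
  diagnostic SNP alleles, inversion breakpoints, dominance patterns).

One global seed drives a single documented pseudo-random stream; per-component
substreams are spawned deterministically, so equal configurations with equal
seeds give byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    KARYOTYPES,
    STAGE_GROUPS,
    STAGES,
    TIMEPOINT_TO_STAGE,
    TISSUES,
    ConfigurationError,
    CountMatrix,
    ValidationError,
    VariantTable,
    normalize_karyotype,
    validate_metadata,
)
from .expression import build_contrasts
from .staging import stage_group

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "SimulatedDataset",
    "TABLE1_DESIGN",
    "DEFAULT_INVERSION_REGIONS",
    "PATTERN_DELTAS",
    "simulate_dataset",
    "simulate_histology",
    "gene_annotation",
]

# birds per karyotype x timepoint cell of the default design (32 birds)
TABLE1_DESIGN: tuple[tuple[str, int, int], ...] = (
    ("AA", 1, 3), ("AA", 2, 3), ("AA", 3, 3), ("AA", 4, 3),
    ("AB", 1, 2), ("AB", 2, 3), ("AB", 3, 2), ("AB", 4, 3),
    ("BB", 1, 2), ("BB", 2, 2), ("BB", 3, 3), ("BB", 4, 3),
)

DEFAULT_INVERSION_REGIONS: tuple[tuple[int, int], ...] = (
    (22_500_000, 27_900_000),
    (33_500_000, 39_900_000),
    (64_000_000, 68_900_000),
)

# heterokaryotype dominance score targets (EARLY, LATE); the score is 1 when
# AB matches AA and 0 when AB matches BB
PATTERN_DELTAS = {
    "A_dominant": (0.95, 0.95),
    "B_dominant": (0.05, 0.05),
    "intermediate": (0.5, 0.5),
    "divergent_over_time": (0.5, 0.95),
    "switching": (0.95, 0.05),
}
_PATTERN_CYCLE = tuple(PATTERN_DELTAS)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_autosomal_genes: int = 400
    n_z_genes: int = 200
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 120_000_000, "2": 160_000_000, "Z": 75_000_000}
    )
    inversion_regions: list[tuple[int, int]] = field(
        default_factory=lambda: [tuple(r) for r in DEFAULT_INVERSION_REGIONS]
    )
    design: list[tuple[str, int, int]] = field(
        default_factory=lambda: [tuple(r) for r in TABLE1_DESIGN]
    )
    nb_mean_range: tuple[float, float] = (20.0, 500.0)
    nb_dispersion: float = 0.1
    cis_effect_log2fc: float = 2.0
    trans_effect_log2fc: float = 2.0
    n_cis_de: int = 30
    n_trans_de: int = 30
    # (gene id, tissue, A-allele proportion in AB birds); None -> a default
    # DMGDH-like case is planted (monoallelic in testis, balanced in liver)
    ase_genes: list[tuple[str, str, float]] | None = None
    ase_snps_per_gene: int = 3
    snp_density_per_mb: float = 2.0
    fixation_level: float = 0.98
    mean_allelic_depth: float = 50.0
    stage_effect_sd: float = 0.8
    library_size_sd_log2: float = 0.25

    def validate(self) -> None:
        if self.n_autosomal_genes < 0 or self.n_z_genes < 0:
            raise ConfigurationError("n_autosomal_genes/n_z_genes must be non-negative")
        if "Z" not in self.chromosome_lengths:
            raise ConfigurationError("chromosome_lengths must include chromosome Z")
        if any(length <= 0 for length in self.chromosome_lengths.values()):
            raise ConfigurationError("chromosome_lengths entries must be positive")
        z_len = self.chromosome_lengths["Z"]
        regions = sorted(tuple(map(int, r)) for r in self.inversion_regions)
        for start, end in regions:
            if not (0 <= start < end <= z_len):
                raise ConfigurationError(
                    f"inversion_regions entry ({start}, {end}) outside chromosome Z (length {z_len})"
                )
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            if s2 < e1:
                raise ConfigurationError("inversion_regions must be non-overlapping")
        if not self.design:
            raise ConfigurationError("design must list at least one (karyotype, timepoint, n) cell")
        for kar, tp, n in self.design:
            normalize_karyotype(kar)
            if tp not in TIMEPOINT_TO_STAGE:
                raise ConfigurationError(f"design timepoint {tp} outside 1..4")
            if n < 0:
                raise ConfigurationError("design bird counts must be non-negative")
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise ConfigurationError("nb_mean_range must satisfy 0 < low <= high")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if self.n_cis_de < 0 or self.n_trans_de < 0:
            raise ConfigurationError("n_cis_de/n_trans_de must be non-negative")
        if not 0.5 < self.fixation_level <= 1.0:
            raise ConfigurationError("fixation_level must be in (0.5, 1]")
        if self.mean_allelic_depth <= 0:
            raise ConfigurationError("mean_allelic_depth must be positive")
        if self.snp_density_per_mb < 0:
            raise ConfigurationError("snp_density_per_mb must be non-negative")
        if self.ase_genes is not None:
            for gene, tissue, p in self.ase_genes:
                if tissue not in TISSUES:
                    raise ConfigurationError(f"ase_genes tissue {tissue!r} unknown")
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError("ase_genes proportions must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    de_genes_by_contrast: dict[str, set[str]]
    ase_truth: dict[tuple[str, str], float]
    diagnostic_snps: dict[str, dict]
    breakpoints: list[int]
    pattern_truth: dict[str, str]

    @property
    def de_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.de_genes_by_contrast.values():
            out |= genes
        return out

    def de_genes_for_tissue(self, tissue: str) -> set[str]:
        out: set[str] = set()
        for key, genes in self.de_genes_by_contrast.items():
            if key.startswith(f"{tissue}:"):
                out |= genes
        return out

    def to_json(self) -> str:
        payload = {
            "de_genes_by_contrast": {
                k: sorted(v) for k, v in self.de_genes_by_contrast.items()
            },
            "ase_truth": {f"{g}|{t}": p for (g, t), p in self.ase_truth.items()},
            "diagnostic_snps": self.diagnostic_snps,
            "breakpoints": self.breakpoints,
            "pattern_truth": self.pattern_truth,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        return cls(
            de_genes_by_contrast={
                k: set(v) for k, v in payload["de_genes_by_contrast"].items()
            },
            ase_truth={
                tuple(k.split("|")): p for k, p in payload["ase_truth"].items()
            },
            diagnostic_snps=payload["diagnostic_snps"],
            breakpoints=list(payload["breakpoints"]),
            pattern_truth=dict(payload["pattern_truth"]),
        )


@dataclass
class SimulatedDataset:
    counts: dict[str, CountMatrix]
    variants: VariantTable
    histology: pd.DataFrame
    meta: pd.DataFrame
    truth: SimTruth
    config: SimulationConfig

    def write(self, outdir) -> None:
        from . import io as _io

        _io.write_dataset(self, outdir)


# ------------------------------------------------------------- gene layout


def _allocate(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` items by weights."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base.tolist()


def gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene layout: genes evenly spaced along each chromosome."""
    rows = []
    counter = 1
    autosomes = [c for c in config.chromosome_lengths if c != "Z"]
    alloc = dict(
        zip(
            autosomes,
            _allocate(config.n_autosomal_genes, [config.chromosome_lengths[c] for c in autosomes]),
        )
    )
    alloc["Z"] = config.n_z_genes
    for chrom in list(autosomes) + ["Z"]:
        n = alloc.get(chrom, 0)
        if n == 0:
            continue
        length = config.chromosome_lengths[chrom]
        spacing = length / n
        gene_len = int(max(200, min(20_000, spacing * 0.5)))
        for i in range(n):
            start = int(i * spacing + 0.25 * spacing)
            rows.append(
                {
                    "gene_id": f"g{counter:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_len,
                    "strand": "+" if i % 2 == 0 else "-",
                    "biotype": "lncRNA" if i % 5 == 4 else "protein_coding",
                }
            )
            counter += 1
    return pd.DataFrame(rows).set_index("gene_id")


def _genes_in_regions(genes: pd.DataFrame, regions: Iterable[tuple[int, int]]) -> pd.Index:
    z = genes[genes["chrom"] == "Z"]
    mask = np.zeros(len(z), dtype=bool)
    for start, end in regions:
        mask |= (z["start"].to_numpy() >= start) & (z["start"].to_numpy() < end)
    return z.index[mask]


def _default_ase_genes(config: SimulationConfig, genes: pd.DataFrame) -> list[tuple[str, str, float]]:
    if not config.inversion_regions:
        return []
    last = sorted(config.inversion_regions)[-1]
    candidates = _genes_in_regions(genes, [last])
    if not len(candidates):
        return []
    gene = candidates[0]
    return [(gene, "testis", 0.95), (gene, "liver", 0.5)]


# ---------------------------------------------------------------- metadata


_FAMILIES_PER_KARYOTYPE = {"AA": 4, "AB": 3, "BB": 2}


def _metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    bird_no = 0
    kar_counts: dict[str, int] = {k: 0 for k in KARYOTYPES}
    birds = []
    for kar_raw, tp, n in config.design:
        kar = normalize_karyotype(kar_raw)
        for _ in range(n):
            bird_no += 1
            kar_counts[kar] += 1
            fam = f"{kar}f{(kar_counts[kar] - 1) % _FAMILIES_PER_KARYOTYPE[kar] + 1}"
            birds.append((f"b{bird_no:02d}", kar, tp, fam))
    for tissue in TISSUES:
        suffix = "T" if tissue == "testis" else "L"
        for bird_id, kar, tp, fam in birds:
            stage = TIMEPOINT_TO_STAGE[tp]
            rows.append(
                {
                    "sample_id": f"{bird_id}_{suffix}",
                    "bird_id": bird_id,
                    "karyotype": kar,
                    "tissue": tissue,
                    "timepoint": tp,
                    "stage": stage,
                    "stage_group": stage_group(stage),
                    "has_division": tp >= 2,
                    "family": fam,
                }
            )
    return validate_metadata(pd.DataFrame(rows))


# --------------------------------------------------------------- histology


def simulate_histology(
    stage: str,
    n_sections: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Section counts of elongating spermatids (ES) and spermatogonia (SP).

    The emitted counts pool to a maturation index inside the stage's defining
    window: inactive and accelerating_I sections carry no elongating
    spermatids; accelerating_II pools to MI in [-0.7, 0.1]; active pools to
    MI in (0.1, 0.7]. Out-of-window draws are rejected and redrawn so the
    planted stage is always recoverable.
    """
    if stage not in STAGES:
        raise ValidationError(f"unknown stage label {stage!r}; expected one of {list(STAGES)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_sections == 0:
        return pd.DataFrame(columns=["section_id", "ES", "SP"]).astype(
            {"section_id": int, "ES": int, "SP": int}
        )
    if n_sections < 0:
        raise ValidationError("n_sections must be non-negative")
    if stage in ("inactive", "accelerating_I"):
        sp = rng.poisson(25, n_sections)
        if sp.sum() == 0:
            sp[0] = 1
        es = np.zeros(n_sections, dtype=int)
    else:
        lo, hi = (-0.6, 0.0) if stage == "accelerating_II" else (0.2, 0.6)
        in_lo, in_hi = (-0.7, 0.1) if stage == "accelerating_II" else (0.1, 0.7)
        es = sp = None
        for _ in range(200):
            target = rng.uniform(lo, hi)
            totals = rng.poisson(30, n_sections) + 1
            es_try = rng.binomial(totals, (1.0 + target) / 2.0)
            sp_try = totals - es_try
            pooled = (es_try.sum() - sp_try.sum()) / totals.sum()
            ok = (in_lo <= pooled <= in_hi) if stage == "accelerating_II" else (in_lo < pooled <= in_hi)
            if ok and es_try.sum() > 0:
                es, sp = es_try, sp_try
                break
        if es is None:  # deterministic fallback, exactly inside the window
            if stage == "accelerating_II":
                es = np.full(n_sections, 7)
                sp = np.full(n_sections, 13)
            else:
                es = np.full(n_sections, 14)
                sp = np.full(n_sections, 6)
    return pd.DataFrame(
        {"section_id": np.arange(1, n_sections + 1), "ES": es.astype(int), "SP": sp.astype(int)}
    )


# ------------------------------------------------------------------ counts


def _plant_effects(
    config: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, dict[tuple[str, str], float]], dict[str, str]]:
    """Choose DE genes and their karyotype cell-mean offsets (log2)."""
    eligible_cis = sorted(_genes_in_regions(genes, config.inversion_regions))
    if config.n_cis_de > len(eligible_cis):
        raise ConfigurationError(
            f"n_cis_de={config.n_cis_de} exceeds the {len(eligible_cis)} Z genes "
            "inside inversion_regions"
        )
    autosomal = sorted(genes.index[genes["chrom"] != "Z"])
    if config.n_trans_de > len(autosomal):
        raise ConfigurationError(
            f"n_trans_de={config.n_trans_de} exceeds the {len(autosomal)} autosomal genes"
        )
    cis = sorted(rng.choice(eligible_cis, size=config.n_cis_de, replace=False))
    trans = sorted(rng.choice(autosomal, size=config.n_trans_de, replace=False))

    offsets: dict[str, dict[tuple[str, str], float]] = {}
    patterns: dict[str, str] = {}
    for rank, gene in enumerate(cis):
        patterns[gene] = _PATTERN_CYCLE[rank % len(_PATTERN_CYCLE)]
        offsets[gene] = _pattern_offsets(config.cis_effect_log2fc, patterns[gene])
    for gene in trans:
        patterns[gene] = "intermediate"
        offsets[gene] = _pattern_offsets(config.trans_effect_log2fc, "intermediate")
    return offsets, patterns


def _pattern_offsets(effect: float, pattern: str) -> dict[tuple[str, str], float]:
    deltas = PATTERN_DELTAS[pattern]
    out: dict[tuple[str, str], float] = {}
    for grp, delta in zip(STAGE_GROUPS, deltas):
        out[("AA", grp)] = effect / 2.0
        out[("BB", grp)] = -effect / 2.0
        out[("AB", grp)] = -effect / 2.0 + delta * effect
    return out


def _true_de_sets(
    offsets: dict[str, dict[tuple[str, str], float]]
) -> dict[str, set[str]]:
    truth: dict[str, set[str]] = {}
    for tissue in TISSUES:
        contrasts = build_contrasts(tissue)
        for name in contrasts.columns:
            col = contrasts[name]
            genes = set()
            for gene, off in offsets.items():
                val = sum(
                    coef * off[tuple(cell.split("."))]
                    for cell, coef in col.items()
                    if coef != 0
                )
                if abs(val) > 1e-9:
                    genes.add(gene)
            truth[f"{tissue}:{name}"] = genes
    return truth


def _simulate_counts(
    config: SimulationConfig,
    genes: pd.DataFrame,
    meta: pd.DataFrame,
    offsets: dict[str, dict[tuple[str, str], float]],
    base_log2: np.ndarray,
    stage_delta: np.ndarray,
    tissue: str,
    rng: np.random.Generator,
) -> CountMatrix:
    sub = meta[meta["tissue"] == tissue]
    g = len(genes)
    n = len(sub)
    lib_offset = rng.normal(0.0, config.library_size_sd_log2, n)
    mean_log2 = np.tile(base_log2[:, None], (1, n)) + lib_offset[None, :]
    is_late = (sub["stage_group"] == "LATE").to_numpy()
    if tissue == "testis":
        mean_log2[:, is_late] += stage_delta[:, None]
    gene_pos = {gid: i for i, gid in enumerate(genes.index)}
    kar_grp = list(zip(sub["karyotype"], sub["stage_group"]))
    for gene, off in offsets.items():
        row = gene_pos[gene]
        adj = np.array([off[(k, grp)] for k, grp in kar_grp])
        mean_log2[row, :] += adj
    mu = np.power(2.0, mean_log2)
    if config.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    frame = pd.DataFrame(counts.astype(np.int64), index=genes.index, columns=sub.index)
    frame.columns.name = None
    return CountMatrix(frame, genes)


# ---------------------------------------------------------------- variants


def _snp_positions(
    config: SimulationConfig,
    genes: pd.DataFrame,
    ase_genes: list[tuple[str, str, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """SNP positions on Z, each inside a gene (transcriptome variants)."""
    z_genes = genes[genes["chrom"] == "Z"]
    rows = []
    length = config.chromosome_lengths["Z"]
    n_snps = int(round(config.snp_density_per_mb * length / 1e6))
    if n_snps > 0 and len(z_genes) > 0:
        picks = np.floor(np.linspace(0, len(z_genes) - 1e-9, n_snps)).astype(int)
        for i in picks:
            row = z_genes.iloc[int(i)]
            pos0 = int(rng.integers(row["start"], row["end"]))
            rows.append({"pos": pos0 + 1, "gene_id": z_genes.index[int(i)]})
    for gene in sorted({g for g, _, _ in ase_genes}):
        if gene not in z_genes.index:
            raise ConfigurationError(
                f"ase_genes entry {gene!r} is not a Z-chromosome gene in the annotation"
            )
        row = z_genes.loc[gene]
        for _ in range(config.ase_snps_per_gene):
            pos0 = int(rng.integers(row["start"], row["end"]))
            rows.append({"pos": pos0 + 1, "gene_id": gene})
    snp = pd.DataFrame(rows, columns=["pos", "gene_id"])
    snp = snp.drop_duplicates("pos").sort_values("pos", kind="stable").reset_index(drop=True)
    in_region = np.zeros(len(snp), dtype=bool)
    for start, end in config.inversion_regions:
        in_region |= (snp["pos"] - 1 >= start) & (snp["pos"] - 1 < end)
    snp["diagnostic"] = in_region
    return snp


_BASES = np.array(list("ACGT"))


def _simulate_variants(
    config: SimulationConfig,
    genes: pd.DataFrame,
    meta: pd.DataFrame,
    ase_truth: dict[tuple[str, str], float],
    rng_geno: np.random.Generator,
    rng_depth: dict[str, np.random.Generator],
) -> tuple[VariantTable, dict[str, dict]]:
    ase_list = [(g, t, p) for (g, t), p in sorted(ase_truth.items())]
    snp = _snp_positions(config, genes, ase_list, rng_geno)
    birds = meta.drop_duplicates("bird_id")[["bird_id", "karyotype"]]
    bird_ids = birds["bird_id"].tolist()
    bird_kar = birds["karyotype"].to_numpy()
    n_snps, n_birds = len(snp), len(bird_ids)
    fix = config.fixation_level

    a_is_alt = np.zeros(n_snps, dtype=bool)
    gt_bird = np.zeros((n_snps, n_birds), dtype=np.int8)
    n_a_alleles = np.zeros((n_snps, n_birds), dtype=np.int8)
    diagnostic_truth: dict[str, dict] = {}
    for i in range(n_snps):
        if snp.loc[i, "diagnostic"]:
            a_is_alt[i] = rng_geno.random() < 0.5
            n_a = np.empty(n_birds, dtype=np.int64)
            for j, kar in enumerate(bird_kar):
                if kar == "AA":
                    n_a[j] = rng_geno.binomial(2, fix)
                elif kar == "BB":
                    n_a[j] = rng_geno.binomial(2, 1.0 - fix)
                else:  # heterokaryotype: genuinely het at diagnostic SNPs
                    n_a[j] = 1
            n_a_alleles[i] = n_a
            gt_bird[i] = n_a if a_is_alt[i] else 2 - n_a
            diagnostic_truth[f"Z:{int(snp.loc[i, 'pos'])}"] = {
                "a_allele": "alt" if a_is_alt[i] else "ref",
                "b_allele": "ref" if a_is_alt[i] else "alt",
                "gene_id": snp.loc[i, "gene_id"],
            }
        else:
            f_alt = rng_geno.uniform(0.2, 0.8)
            gt_bird[i] = rng_geno.binomial(2, f_alt, n_birds)

    ref_alt = np.empty((n_snps, 2), dtype="<U1")
    for i in range(n_snps):
        ref, alt = rng_geno.choice(4, size=2, replace=False)
        ref_alt[i] = (_BASES[ref], _BASES[alt])

    samples = meta.index.tolist()
    bird_col = {b: i for i, b in enumerate(bird_ids)}
    n_samples = len(samples)
    dp = np.zeros((n_snps, n_samples), dtype=np.int32)
    ad_alt = np.zeros((n_snps, n_samples), dtype=np.int32)
    gt = np.zeros((n_snps, n_samples), dtype=np.int16)
    snp_gene = snp["gene_id"].to_numpy()
    diag = snp["diagnostic"].to_numpy()
    for j, sample in enumerate(samples):
        tissue = meta.loc[sample, "tissue"]
        kar = meta.loc[sample, "karyotype"]
        rng_d = rng_depth[tissue]
        b = bird_col[meta.loc[sample, "bird_id"]]
        g_bird = gt_bird[:, b].astype(np.int64)
        gt[:, j] = g_bird
        depth = rng_d.poisson(config.mean_allelic_depth, n_snps)
        p_alt = np.full(n_snps, 0.5)
        if kar == "AB":
            for i in np.flatnonzero(diag):
                p_a = ase_truth.get((snp_gene[i], tissue), 0.5)
                p_alt[i] = p_a if a_is_alt[i] else 1.0 - p_a
        alt_depth = np.where(
            g_bird == 0, 0, np.where(g_bird == 2, depth, rng_d.binomial(depth, p_alt))
        )
        dp[:, j] = depth
        ad_alt[:, j] = alt_depth

    sites = pd.DataFrame(
        {
            "chrom": "Z",
            "pos": snp["pos"].astype(np.int64),
            "ref": ref_alt[:, 0],
            "alt": ref_alt[:, 1],
            "qual": 1000.0,
            "info_dp": dp.sum(axis=1),
        }
    )
    table = VariantTable(
        sites=sites,
        samples=samples,
        gt=gt,
        dp=dp,
        gq=np.full((n_snps, n_samples), 99, dtype=np.int32),
        ad_ref=dp - ad_alt,
        ad_alt=ad_alt,
    )
    return table, diagnostic_truth


# ------------------------------------------------------------------ driver


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate counts, variants, histology and metadata with known truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(6)
    rng_layout = np.random.default_rng(streams[0])
    rng_hist = np.random.default_rng(streams[1])
    rng_counts = {
        "testis": np.random.default_rng(streams[2]),
        "liver": np.random.default_rng(streams[3]),
    }
    rng_geno = np.random.default_rng(streams[4])
    depth_streams = streams[5].spawn(2)
    rng_depth = {
        "testis": np.random.default_rng(depth_streams[0]),
        "liver": np.random.default_rng(depth_streams[1]),
    }

    genes = gene_annotation(config)
    meta = _metadata(config)

    ase_entries = (
        config.ase_genes if config.ase_genes is not None else _default_ase_genes(config, genes)
    )
    for gene, tissue, _ in ase_entries:
        if gene not in genes.index:
            raise ConfigurationError(f"ase_genes entry {gene!r} absent from the annotation")
        if gene not in set(_genes_in_regions(genes, config.inversion_regions)):
            raise ConfigurationError(
                f"ase_genes entry {gene!r} lies outside the inversion regions; "
                "it would carry no diagnostic SNPs"
            )
    ase_truth = {(g, t): float(p) for g, t, p in ase_entries}

    offsets, patterns = _plant_effects(config, genes, rng_layout)
    base_log2 = rng_layout.uniform(
        np.log2(config.nb_mean_range[0]), np.log2(config.nb_mean_range[1]), len(genes)
    )
    stage_delta = rng_layout.normal(0.0, config.stage_effect_sd, len(genes)) * (
        rng_layout.random(len(genes)) < 0.5
    )

    counts = {
        tissue: _simulate_counts(
            config, genes, meta, offsets, base_log2, stage_delta, tissue, rng_counts[tissue]
        )
        for tissue in TISSUES
    }
    meta = meta.copy()
    meta["library_size"] = 0
    for tissue in TISSUES:
        libs = counts[tissue].library_sizes
        meta.loc[libs.index, "library_size"] = libs.astype(int)

    hist_rows = []
    testis_birds = meta[meta["tissue"] == "testis"]
    for bird_id, stage in zip(testis_birds["bird_id"], testis_birds["stage"]):
        sections = simulate_histology(stage, 5, rng_hist)
        sections.insert(0, "bird_id", bird_id)
        hist_rows.append(sections)
    histology = (
        pd.concat(hist_rows, ignore_index=True)
        if hist_rows
        else pd.DataFrame(columns=["bird_id", "section_id", "ES", "SP"])
    )

    variants, diagnostic_truth = _simulate_variants(
        config, genes, meta, ase_truth, rng_geno, rng_depth
    )

    breakpoints: list[int] = []
    for start, end in sorted(config.inversion_regions):
        breakpoints.extend([int(start), int(end)])

    truth = SimTruth(
        de_genes_by_contrast=_true_de_sets(offsets),
        ase_truth=ase_truth,
        diagnostic_snps=diagnostic_truth,
        breakpoints=breakpoints,
        pattern_truth=patterns,
    )
    return SimulatedDataset(
        counts=counts,
        variants=variants,
        histology=histology,
        meta=meta,
        truth=truth,
        config=config,
    )
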