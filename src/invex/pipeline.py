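"""End-to-end pipeline driver: staging -> DE -> enrichment -> ASE -> landscape.

Each stage reads validated inputs, writes its outputs under the run
directory, and appends itself to a JSON run manifest (package version, seed,
thresholds, SHA-256 digests of the inputs), so a run is self-describing and
reruns with the same configuration produce identical result digests. A stage
failure aborts the run with the stage name; outputs of completed stages are
left in place.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import ase as ase_mod
from . import enrichment as enrich_mod
from . import expression as expr_mod
from . import io as io_mod
from . import landscape as land_mod
from . import staging as staging_mod
from .containers import ConfigurationError, PipelineError, ValidationError

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_NAMES"]

logger = logging.getLogger("invex.pipeline")

STAGE_NAMES = ("staging", "de", "enrich", "ase", "landscape")

# testis uses 4 Mb windows; the sparser liver gene set uses 8 Mb
DEFAULT_WINDOW_SIZES = {"testis": 4_000_000, "liver": 8_000_000}


@dataclass
class PipelineConfig:
    counts: dict[str, str]  # tissue -> counts TSV path
    metadata: str
    annotation: str
    vcf: str | None = None
    histology: str | None = None
    outdir: str = "invex_out"
    tissues: tuple[str, ...] = ("testis", "liver")
    seed: int = 0
    skip: tuple[str, ...] = ()
    # thresholds
    min_per_sample: int = 10
    min_total: int = 320
    alpha: float = 0.05
    n_clusters: int = 10
    window_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_WINDOW_SIZES))
    steps_per_window: int = 4
    window_fdr: float = 0.01
    min_qual: float = 999
    min_site_dp: int = 640
    min_sample_dp: int = 8
    min_gq: int = 10
    fixation: float = 0.9
    min_group_depth: int = 20
    tau: float = 0.25
    min_effect_log2: float = 1.0
    m_snps: int = 11
    block_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for tissue, path in self.counts.items():
            if not Path(path).exists():
                raise ConfigurationError(f"counts[{tissue}]: file not found: {path}")
        for name in ("metadata", "annotation"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigurationError(f"{name}: file not found: {path}")
        for name in ("vcf", "histology"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{name}: file not found: {path}")
        bad = set(self.skip) - set(STAGE_NAMES)
        if bad:
            raise ConfigurationError(f"skip: unknown stage names {sorted(bad)}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.window_fdr < 1:
            raise ConfigurationError("window_fdr must lie in (0, 1)")
        if not 0.5 <= self.fixation <= 1:
            raise ConfigurationError("fixation must lie in [0.5, 1]")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _thresholds(cfg: PipelineConfig) -> dict:
    skip = {"counts", "metadata", "annotation", "vcf", "histology", "outdir", "skip"}
    out = {}
    for name in cfg.__dataclass_fields__:
        if name in skip:
            continue
        val = getattr(cfg, name)
        out[name] = list(val) if isinstance(val, tuple) else val
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns {stage: result object}."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger("invex").handlers:
        logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
    logger.info("thresholds: %s", json.dumps(_thresholds(cfg), sort_keys=True))

    inputs = {"metadata": cfg.metadata, "annotation": cfg.annotation}
    inputs |= {f"counts_{t}": p for t, p in cfg.counts.items()}
    if cfg.vcf:
        inputs["vcf"] = cfg.vcf
    if cfg.histology:
        inputs["histology"] = cfg.histology
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": _thresholds(cfg),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "stages": [],
        "outputs": [],
    }

    results: dict[str, object] = {}
    meta = io_mod.read_metadata(cfg.metadata)
    genes = io_mod.read_annotation(cfg.annotation)
    counts = {
        t: io_mod.read_counts(cfg.counts[t], genes) for t in cfg.tissues if t in cfg.counts
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].extend(str(p.relative_to(out)) for p in paths)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def run_stage(stage: str, fn) -> None:
        if stage in cfg.skip:
            logger.info("[%s] skipped by flag", stage)
            return
        logger.info("[%s] starting", stage)
        try:
            fn()
        except Exception as exc:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("[%s] done", stage)

    # ---------------------------------------------------------- staging
    def _staging() -> None:
        if cfg.histology is None:
            raise ValidationError("staging requires a histology table")
        hist = io_mod.read_histology(cfg.histology)
        division = (
            meta.drop_duplicates("bird_id").set_index("bird_id")["has_division"].to_dict()
            if "has_division" in meta.columns
            else {b: True for b in hist["bird_id"].unique()}
        )
        calls = staging_mod.call_stages(hist, division)
        calls.to_csv(out / "stage_calls.tsv", sep="\t", index=False)
        results["staging"] = calls
        record("staging", out / "stage_calls.tsv")

    run_stage("staging", _staging)

    # --------------------------------------------------------------- de
    de_results: dict[str, expr_mod.DEResult] = {}
    logcpms: dict[str, pd.DataFrame] = {}

    def _de() -> None:
        for tissue, cm in counts.items():
            sub_meta = meta[meta["tissue"] == tissue].loc[cm.counts.columns]
            design = expr_mod.design_matrix(sub_meta)
            group_sizes = design.sum(axis=0).astype(int).tolist()
            kept = expr_mod.prefilter_genes(
                cm.counts, group_sizes,
                min_per_sample=cfg.min_per_sample, min_total=cfg.min_total,
            )
            filtered = cm.subset_genes(kept)
            factors = expr_mod.tmm_factors(filtered.counts)
            eff = filtered.library_sizes * factors
            logcpm = expr_mod.log_cpm(filtered.counts, eff)
            weights = expr_mod.mean_variance_weights(logcpm, design, effective_sizes=eff)
            contrasts = expr_mod.build_contrasts(tissue)
            result = expr_mod.fit_moderated(logcpm, weights, design, contrasts)
            expr_mod.global_decide(result, alpha=cfg.alpha)
            result.table.to_csv(out / f"de_{tissue}.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"sample_id": factors.index, "tmm_factor": factors.to_numpy(),
                 "effective_size": eff.to_numpy()}
            ).to_csv(out / f"normalization_{tissue}.tsv", sep="\t", index=False)
            de_results[tissue] = result
            logcpms[tissue] = logcpm
            de_genes = result.de_genes
            if len(de_genes) >= cfg.n_clusters:
                labels = expr_mod.cluster_de_genes(logcpm.loc[de_genes], k=cfg.n_clusters)
                labels.rename_axis("gene_id").reset_index().to_csv(
                    out / f"clusters_{tissue}.tsv", sep="\t", index=False
                )
        results["de"] = de_results
        record("de", *(out / f"de_{t}.tsv" for t in de_results))

    run_stage("de", _de)

    # ----------------------------------------------------------- enrich
    def _enrich() -> None:
        if not de_results:
            raise ValidationError("enrichment requires the DE stage")
        rows = []
        written = []
        for tissue, result in de_results.items():
            expressed = counts[tissue].genes.loc[logcpms[tissue].index, ["chrom", "start"]]
            de_genes = result.de_genes
            wr = enrich_mod.window_enrichment(
                de_genes, expressed, cfg.window_sizes.get(tissue, 4_000_000),
                steps_per_window=cfg.steps_per_window, fdr=cfg.window_fdr,
            )
            wr.windows.to_csv(out / f"windows_{tissue}.tsv", sep="\t", index=False)
            with open(out / f"enriched_regions_{tissue}.bed", "w") as fh:
                for _, r in wr.regions.iterrows():
                    fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\n")
            written += [out / f"windows_{tissue}.tsv", out / f"enriched_regions_{tissue}.bed"]
            universe = counts[tissue].genes["chrom"]
            for contrast in result.contrast_names:
                tab = result.table
                hits = tab.loc[
                    (tab["contrast"] == contrast) & (tab["decision"] != "ns"), "gene"
                ]
                bias = enrich_mod.chrom_bias_test(hits, universe)
                rows.append(
                    {"tissue": tissue, "contrast": contrast, "n_de_z": bias.n_de_z,
                     "n_de_autosome": bias.n_de_autosome, "x2": bias.statistic,
                     "p": bias.p_value, "low_expected": bias.low_expected}
                )
            ratio = enrich_mod.z_autosome_ratio(
                logcpms[tissue], counts[tissue].genes["chrom"],
                meta[meta["tissue"] == tissue],
            )
            ratio.to_csv(out / f"z_autosome_ratio_{tissue}.tsv", sep="\t", index=False)
            written.append(out / f"z_autosome_ratio_{tissue}.tsv")
        pd.DataFrame(rows).to_csv(out / "chrom_bias.tsv", sep="\t", index=False)
        written.append(out / "chrom_bias.tsv")
        results["enrich"] = rows
        record("enrich", *written)

    run_stage("enrich", _enrich)

    # -------------------------------------------------------------- ase
    def _ase() -> None:
        if cfg.vcf is None:
            raise ValidationError("the ASE stage requires a VCF")
        variants = io_mod.read_vcf(cfg.vcf)
        filtered = ase_mod.filter_variants(
            variants, min_qual=cfg.min_qual, min_site_dp=cfg.min_site_dp,
            min_sample_dp=cfg.min_sample_dp, min_gq=cfg.min_gq,
        )
        z_genes = genes[genes["chrom"] == "Z"]
        pairs = ase_mod.map_variants_to_genes(filtered, z_genes)
        karyotypes = meta.loc[[s for s in filtered.samples if s in meta.index], "karyotype"]
        tags = ase_mod.assign_tag_alleles(
            filtered, pairs, karyotypes,
            fixation=cfg.fixation, min_group_depth=cfg.min_group_depth,
        )
        tags.to_csv(out / "tag_snps.tsv", sep="\t", index=False)
        profile = ase_mod.ase_proportion(filtered, tags, meta)
        profile.to_csv(out / "ase.tsv", sep="\t", index=False)
        written = [out / "tag_snps.tsv", out / "ase.tsv"]
        if "testis" in de_results:
            patterns = ase_mod.classify_pattern(
                de_results["testis"].cell_means.loc[de_results["testis"].de_genes],
                tau=cfg.tau, min_effect_log2=cfg.min_effect_log2,
            )
            patterns.to_csv(out / "patterns.tsv", sep="\t", index=False)
            written.append(out / "patterns.tsv")
        results["ase"] = profile
        record("ase", *written)

    run_stage("ase", _ase)

    # -------------------------------------------------------- landscape
    def _landscape() -> None:
        if cfg.vcf is None:
            raise ValidationError("the landscape stage requires a VCF")
        variants = io_mod.read_vcf(cfg.vcf)
        filtered = ase_mod.filter_variants(
            variants, min_qual=cfg.min_qual, min_site_dp=cfg.min_site_dp,
            min_sample_dp=cfg.min_sample_dp, min_gq=cfg.min_gq, require_complete=True,
        )
        karyotypes = meta.loc[[s for s in filtered.samples if s in meta.index], "karyotype"]
        pol = land_mod.polarize(filtered, karyotypes)
        seg = land_mod.segment_blocks(
            pol, karyotypes, m_snps=cfg.m_snps, threshold=cfg.block_threshold
        )
        pd.DataFrame(pol.dosage, index=pol.snp_ids, columns=pol.samples).to_csv(
            out / "polarized_genotypes.tsv", sep="\t", index_label="snp"
        )
        seg.per_snp.to_csv(out / "differentiation.tsv", sep="\t", index=False)
        with open(out / "blocks.bed", "w") as fh:
            for _, r in seg.blocks.iterrows():
                fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\n")
        pd.DataFrame({"breakpoint_bp": seg.breakpoints}).to_csv(
            out / "breakpoints.tsv", sep="\t", index=False
        )
        land_mod.plot_genotypes(pol, karyotypes, str(out / "genotype_heatmap.png"))
        results["landscape"] = seg
        record(
            "landscape", out / "polarized_genotypes.tsv", out / "differentiation.tsv",
            out / "blocks.bed", out / "breakpoints.tsv",
        )

    run_stage("landscape", _landscape)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results
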