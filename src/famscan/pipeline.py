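"""End-to-end orchestration: simulate -> scan -> family test -> haplotype
grouping -> expression fit, with a machine-readable manifest.

Identical config + seed yields a byte-identical output bundle (no timestamps
are written).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .exprmod import fit_models, gene_calls
from .famtest import family_chisq, family_fraction
from .haplogroup import classify_gene_diversity, group_gene
from .selscan import decile_flag, genome_scan
from .simpanel import (
    PanelConfig,
    simulate_expression,
    simulate_strain_panel,
    write_bed,
    write_expression,
    write_family_list,
    write_vcf,
)
from .variants import count_snps, gene_haplotypes, read_gene_models, read_vcf

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "famscan_run"
    seed: int = 0
    # panel
    n_strains: int = 50
    n_genes: int = 200
    n_family_genes: int = 12
    family_tag: str = "fam"
    snp_rate: float = 0.003
    class_snps_variable: tuple[int, ...] = (0, 30, 95)
    class_probs: tuple[float, ...] = (0.7, 0.2, 0.1)
    n_variable_genes: int = 3
    noise_snps: float = 1.0
    missing_rate: float = 0.01
    # thresholds
    scan_quantile: float = 0.9
    family_fdr: float = 1e-4
    fdr_g: float = 0.05
    fdr_t: float = 0.1
    cluster_cut: float = 0.2
    variable_min_snps: int = 10
    # expression
    n_features: int = 400
    n_reps: int = 8
    expr_sigma: float = 0.5
    expr_frac_de: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.scan_quantile < 1:
            raise ConfigError("scan_quantile must be in (0, 1)")
        for a in (self.family_fdr, self.fdr_g, self.fdr_t):
            if not 0 < a < 1:
                raise ConfigError("FDR thresholds must be in (0, 1)")
        if not 0 < self.cluster_cut < 1:
            raise ConfigError("cluster_cut must be in (0, 1)")
        if self.n_family_genes > self.n_genes:
            raise ConfigError("more family genes than genes")
        if self.n_variable_genes > self.n_family_genes:
            raise ConfigError("more variable genes than family genes")


def _panel_config(cfg: RunConfig) -> PanelConfig:
    ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    # family genes in one contiguous cluster mid-panel
    start = cfg.n_genes // 3
    family = tuple(ids[start:start + cfg.n_family_genes])
    variable = family[:cfg.n_variable_genes]
    return PanelConfig(
        n_strains=cfg.n_strains,
        n_genes=cfg.n_genes,
        family_gene_ids=family,
        family_tag=cfg.family_tag,
        snp_rate=cfg.snp_rate,
        class_snps={g: cfg.class_snps_variable for g in variable},
        class_probs=cfg.class_probs,
        noise_snps=cfg.noise_snps,
        missing_rate=cfg.missing_rate,
        seed=cfg.seed,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full simulate-then-analyze pipeline; returns the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        pcfg = _panel_config(cfg)
        panel = simulate_strain_panel(pcfg)
        write_vcf(panel.calls, out / "panel.vcf")
        write_bed(panel.genes, out / "genes.bed")
        write_family_list(panel.genes, out / "family.tsv")
        panel.class_truth.to_csv(out / "truth_classes.tsv", sep="\t",
                                 index=False)
        panel.count_truth.to_csv(out / "truth_counts.tsv", sep="\t",
                                 index=False)

        rng = np.random.default_rng(cfg.seed + 1)
        design = pd.DataFrame({
            "genotype": ["ref"] * 2 * cfg.n_reps + ["alt"] * 2 * cfg.n_reps,
            "treatment": (["mock"] * cfg.n_reps + ["infected"] * cfg.n_reps)
            * 2,
        })
        n_de = max(1, int(cfg.expr_frac_de * cfg.n_features))
        effects = pd.DataFrame({
            "mu": rng.normal(8.0, 1.0, cfg.n_features),
            "beta_g": np.where(np.arange(cfg.n_features) < n_de,
                               rng.normal(0, 2.0, cfg.n_features), 0.0),
            "beta_t": np.where(
                (np.arange(cfg.n_features) >= n_de)
                & (np.arange(cfg.n_features) < 2 * n_de),
                rng.normal(0, 2.0, cfg.n_features), 0.0),
            "beta_gxt": np.where(
                (np.arange(cfg.n_features) >= 2 * n_de)
                & (np.arange(cfg.n_features) < 3 * n_de),
                rng.normal(0, 2.0, cfg.n_features), 0.0),
        }, index=[f"spot{i:05d}" for i in range(cfg.n_features)])
        em = simulate_expression(design, effects, sigma=cfg.expr_sigma,
                                 seed=cfg.seed + 2)
        em.feature_genes = pd.Series(
            [f"gene{i // 2:05d}" for i in range(cfg.n_features)],
            index=em.values.index)
        write_expression(em, out / "expression.tsv",
                         out / "expression_samples.tsv")

        stage = "variants"
        vcs = read_vcf(out / "panel.vcf")
        genes = read_gene_models(
            out / "genes.bed",
            {g.gene_id: g.family for g in panel.genes if g.family})
        counts = count_snps(vcs, genes)
        counts.to_csv(out / "counts.tsv", sep="\t", index=False)

        stage = "selscan"
        scan = genome_scan(vcs, genes, quantile=cfg.scan_quantile)
        threshold, scan = decile_flag(scan, q=cfg.scan_quantile)
        scan.to_csv(out / "tajima.tsv", sep="\t", index=False)

        stage = "famtest"
        q_f = family_fraction(genes, cfg.family_tag)
        fam = family_chisq(
            counts, [g.gene_id for g in genes if g.family == cfg.family_tag],
            q_f=q_f, alpha_fdr=cfg.family_fdr)
        fam.to_csv(out / "family_test.tsv", sep="\t", index=False)

        stage = "haplogroup"
        diversity = classify_gene_diversity(
            counts[counts["gene_id"] != "__intergenic__"],
            v_min=cfg.variable_min_snps)
        diversity.to_csv(out / "gene_diversity.tsv", sep="\t", index=False)
        hap_summaries = {}
        gene_by_id = {g.gene_id: g for g in genes}
        for gid in diversity.loc[diversity["label"] == "variable", "gene_id"]:
            h = gene_haplotypes(vcs, gene_by_id[gid])
            res = group_gene(h, gene_id=gid, cut_fraction=cfg.cluster_cut)
            res.to_frame().to_csv(out / f"haplogroup_{gid}.tsv", sep="\t",
                                  index=False)
            hap_summaries[gid] = {
                "k": res.k,
                "class_sizes": res.class_sizes,
                "class_median_snps": res.class_median_snps,
                "few_haplotype_flag": bool(res.few_haplotype_flag),
            }

        stage = "exprmod"
        fits = fit_models(em, model="GxT",
                          term_fdr={"G": cfg.fdr_g, "T": cfg.fdr_t,
                                    "G:T": cfg.fdr_t})
        fits.to_csv(out / "expr_fits.tsv", sep="\t", index=False)
        calls = gene_calls(fits, em.feature_genes)
        calls.to_csv(out / "expr_gene_calls.tsv", sep="\t", index=False)
    except Exception as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    summary = {
        "strains": cfg.n_strains,
        "genes": cfg.n_genes,
        "sites": int(vcs.n_sites),
        "family_more": int((fam["verdict"] == "more").sum()),
        "family_less": int((fam["verdict"] == "less").sum()),
        "family_ns": int((fam["verdict"] == "ns").sum()),
        "tajima_threshold": threshold,
        "genes_top_decile": int(scan["top_decile"].sum()),
        "family_genes_top_decile": int(
            (scan["top_decile"] & scan["family"].notna()).sum()),
        "haplogroups": hap_summaries,
        "de_genes_per_term": {
            t: int(calls.loc[(calls["term"] == t) & calls["significant"],
                             "gene"].nunique())
            for t in ("G", "T", "G:T")
        },
    }
    cfg_dict = asdict(cfg)
    cfg_dict.pop("out_dir")  # paths excluded so equal configs give
    # byte-identical bundles regardless of destination
    manifest = {
        "famscan_version": __version__,
        "config": cfg_dict,
        "thresholds": {
            "scan_quantile": cfg.scan_quantile,
            "family_fdr": cfg.family_fdr,
            "fdr_g": cfg.fdr_g,
            "fdr_t": cfg.fdr_t,
            "cluster_cut": cfg.cluster_cut,
        },
        "seed": cfg.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return summary
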