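"""Variant panel and annotation I/O, plus per-gene summaries.

Filtering on read: only biallelic SNP records are kept; homozygous diploid
calls collapse to haploid; heterozygous calls become missing (isotype panels
are expected homozygous, so het calls are treated as artifacts).
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import DataError
from .types import GeneModel, HaplotypeMatrix, VariantCallSet

log = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "read_gene_models",
    "read_family_list",
    "count_snps",
    "gene_haplotypes",
    "INTERGENIC",
]

INTERGENIC = "__intergenic__"


def _is_snp(ref: str, alts: tuple[str, ...]) -> bool:
    return (
        len(alts) == 1
        and alts[0] is not None
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in "ACGT"
        and alts[0] in "ACGT"
    )


def _gt_to_haploid(gt: tuple) -> int:
    """Collapse a GT tuple to {0, 1, -1}; het diploid -> missing."""
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return -1
    if len(set(alleles)) > 1:
        return -1  # heterozygous
    return 1 if alleles[0] == 1 else 0


def read_vcf(path: str | Path,
             sample_subset: Optional[Sequence[str]] = None) -> VariantCallSet:
    """Read a VCF into a haploid biallelic SNP call set.

    Multi-allelic and non-SNP records are dropped (counts logged). Raises
    :class:`DataError` on parse failure (with the offending record) or when
    no samples remain.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(samples)
        if missing:
            raise DataError(f"samples not in VCF: {sorted(missing)}")
        samples = list(sample_subset)
    if not samples:
        raise DataError(f"VCF {path} has no samples")

    chroms, poss, refs, alts = [], [], [], []
    columns: list[np.ndarray] = []
    n_dropped = 0
    lineno = 0
    try:
        for rec in vf:
            lineno += 1
            ralts = tuple(rec.alts) if rec.alts else ()
            if not _is_snp(rec.ref, ralts):
                n_dropped += 1
                continue
            col = np.fromiter(
                (_gt_to_haploid(rec.samples[s].get("GT", (None,)))
                 for s in samples),
                dtype=np.int8, count=len(samples),
            )
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(ralts[0])
            columns.append(col)
    except (OSError, ValueError) as exc:
        raise DataError(
            f"malformed VCF record near record {lineno} of {path}: {exc}"
        ) from exc
    finally:
        vf.close()
    if n_dropped:
        log.info("read_vcf: dropped %d non-biallelic-SNP records from %s",
                 n_dropped, path)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs,
                          "alt": alts})
    calls = (np.column_stack(columns) if columns
             else np.zeros((len(samples), 0), dtype=np.int8))
    return VariantCallSet(sites=sites, calls=calls, strain_ids=samples)


def read_family_list(path: str | Path) -> dict[str, str]:
    """TSV of (gene_id, family) -> mapping. A headerless 2-column file or a
    file with a 'gene_id'/'family' header both work."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["gene_id", "family"])
    return dict(zip(df["gene_id"], df["family"]))


def read_gene_models(path: str | Path,
                     family_list: Optional[dict[str, str]] = None
                     ) -> list[GeneModel]:
    """Read gene models from BED (4+ columns) or GFF3.

    Coordinates are normalized to 0-based half-open (BED is already; GFF3 is
    1-based inclusive). Genes absent from ``family_list`` get ``family=None``.
    """
    path = Path(path)
    family_list = family_list or {}
    suffix = path.suffix.lower()
    if suffix in (".bed",):
        genes = _read_bed(path)
    elif suffix in (".gff", ".gff3"):
        genes = _read_gff3(path)
    else:
        raise DataError(f"unknown annotation format: {path.name} "
                        "(expected .bed, .gff or .gff3)")
    out = []
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise DataError(f"duplicate gene id {g.gene_id}")
        seen.add(g.gene_id)
        out.append(GeneModel(gene_id=g.gene_id, chrom=g.chrom, start=g.start,
                             end=g.end, family=family_list.get(g.gene_id)))
    return out


def _read_bed(path: Path) -> list[GeneModel]:
    genes = []
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}:{i}: BED needs >= 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise DataError(f"{path}:{i}: non-integer coordinates") from exc
            genes.append(GeneModel(gene_id=parts[3], chrom=parts[0],
                                   start=start, end=end))
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(str(path), dbfn=":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:  # gffutils raises assorted types
        raise DataError(f"cannot parse GFF3 {path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        gid = gid.removeprefix("gene:")
        # GFF3 1-based inclusive -> 0-based half-open
        genes.append(GeneModel(gene_id=gid, chrom=feat.seqid,
                               start=feat.start - 1, end=feat.end))
    return genes


def _site_gene_index(vcs: VariantCallSet, genes: Sequence[GeneModel]
                     ) -> dict[str, np.ndarray]:
    """Boolean site mask per gene id (sites may hit multiple genes)."""
    pos0 = vcs.sites["pos"].to_numpy() - 1
    chroms = vcs.sites["chrom"].to_numpy()
    return {
        g.gene_id: (chroms == g.chrom) & (pos0 >= g.start) & (pos0 < g.end)
        for g in genes
    }


def count_snps(vcs: VariantCallSet, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-strain per-gene alternate-allele counts.

    Missing calls contribute 0. Sites covered by no gene are tallied into a
    per-strain ``__intergenic__`` bucket. A site inside overlapping genes
    counts toward each of them (per-gene statistics stay self-contained).
    Returns a long table (strain, gene_id, snp_count).
    """
    alt = vcs.calls == 1
    masks = _site_gene_index(vcs, genes)
    covered = np.zeros(vcs.n_sites, dtype=bool)
    rows = []
    for g in genes:
        m = masks[g.gene_id]
        covered |= m
        counts = alt[:, m].sum(axis=1)
        for s, c in zip(vcs.strain_ids, counts):
            rows.append((s, g.gene_id, int(c)))
    inter = alt[:, ~covered].sum(axis=1)
    for s, c in zip(vcs.strain_ids, inter):
        rows.append((s, INTERGENIC, int(c)))
    return pd.DataFrame(rows, columns=["strain", "gene_id", "snp_count"])


def gene_haplotypes(vcs: VariantCallSet, gene: GeneModel) -> HaplotypeMatrix:
    """Restrict the call matrix to the sites inside one gene span."""
    pos0 = vcs.sites["pos"].to_numpy() - 1
    mask = ((vcs.sites["chrom"].to_numpy() == gene.chrom)
            & (pos0 >= gene.start) & (pos0 < gene.end))
    return HaplotypeMatrix(
        data=vcs.calls[:, mask].copy(),
        positions=pos0[mask],
        sample_ids=list(vcs.strain_ids),
    )
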