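"""Group strains into discrete haplotype classes per gene.

Distances are SNP mismatch counts with pairwise deletion, rescaled to the
gene's site count; grouping is agglomerative complete-linkage clustering with
the tree cut at a height proportional to the gene's site count. Strains are
sorted lexicographically before clustering so results are input-order
invariant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigError, DataError
from .types import HaplotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "HaplotypeGroupResult",
    "gene_distance",
    "cluster_strains",
    "group_gene",
    "classify_gene_diversity",
]


@dataclass
class HaplotypeGroupResult:
    gene_id: str
    assignments: dict[str, int]         # strain -> class label (0 = largest)
    k: int
    class_sizes: list[int]
    class_median_snps: list[float]      # median alt count vs reference
    missingness: dict[str, float]       # per-strain missing fraction
    few_haplotype_flag: bool

    def to_frame(self) -> pd.DataFrame:
        strains = sorted(self.assignments)
        return pd.DataFrame({
            "strain": strains,
            "class_label": [self.assignments[s] for s in strains],
            "missing_frac": [self.missingness[s] for s in strains],
        })


def gene_distance(h: HaplotypeMatrix) -> np.ndarray:
    """Pairwise rescaled mismatch distances.

    d(a, b) = (#sites where both non-missing and calls differ)
              * n_sites / (#shared non-missing sites).
    Pairs sharing no site get NaN (flagged via log).
    """
    if h.n_samples < 2:
        raise DataError("gene_distance needs >= 2 strains")
    n, s = h.data.shape
    if s == 0:
        return np.zeros((n, n))
    present = (h.data != -1).astype(np.float64)
    ones = np.where(h.data == 1, 1.0, 0.0)
    zeros = present - ones
    mism = ones @ zeros.T + zeros @ ones.T
    shared = present @ present.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = mism * (s / shared)
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        log.warning("gene_distance: %d strain pairs share no called site",
                    int(np.isnan(d).sum() / 2))
    return d


def cluster_strains(dist: np.ndarray, sample_ids: list[str], n_sites: int,
                    cut_fraction: float = 0.2) -> dict[str, int]:
    """Complete-linkage clustering cut at ``cut_fraction * n_sites``.

    Strains whose distance row contains missing entries are held out of the
    linkage and then assigned to the class of their nearest resolved
    neighbor. Class labels are ordered by descending class size (ties broken
    by smallest member id).
    """
    if not 0 < cut_fraction < 1:
        raise ConfigError("cut_fraction must be in (0, 1)")
    n = len(sample_ids)
    if dist.shape != (n, n):
        raise DataError("distance matrix shape does not match sample ids")
    order = np.argsort(np.asarray(sample_ids, dtype=object), kind="stable")
    ids = [sample_ids[i] for i in order]
    d = dist[np.ix_(order, order)]

    resolved = ~np.isnan(d).any(axis=1)
    if not resolved.any():
        raise DataError("no strain has a fully resolved distance row")
    dr = d[np.ix_(resolved, resolved)]
    res_ids = [sid for sid, r in zip(ids, resolved) if r]
    height = cut_fraction * max(n_sites, 1)
    if len(res_ids) == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(dr, checks=False), method="complete")
        labels = fcluster(z, t=height, criterion="distance")
    raw = dict(zip(res_ids, (int(l) for l in labels)))

    # nearest resolved neighbor for held-out strains
    res_idx = np.flatnonzero(resolved)
    for i, sid in enumerate(ids):
        if resolved[i]:
            continue
        cand = d[i, res_idx]
        ok = ~np.isnan(cand)
        if not ok.any():
            raise DataError(f"strain {sid} shares no called site with any "
                            "resolved strain")
        j = res_idx[ok][int(np.argmin(cand[ok]))]
        raw[sid] = raw[ids[j]]
        log.warning("cluster_strains: %s assigned by nearest neighbor %s",
                    sid, ids[j])

    # relabel by descending class size, ties by smallest member id
    members: dict[int, list[str]] = {}
    for sid, lab in raw.items():
        members.setdefault(lab, []).append(sid)
    ranked = sorted(members, key=lambda l: (-len(members[l]),
                                            min(members[l])))
    remap = {old: new for new, old in enumerate(ranked)}
    return {sid: remap[lab] for sid, lab in raw.items()}


def group_gene(h: HaplotypeMatrix, gene_id: str = "",
               cut_fraction: float = 0.2) -> HaplotypeGroupResult:
    """Distance + clustering + per-class summaries for one gene."""
    dist = gene_distance(h)
    assignments = cluster_strains(dist, h.sample_ids, h.n_sites, cut_fraction)
    k = len(set(assignments.values()))
    alt_counts = (h.data == 1).sum(axis=1)
    counts_by = dict(zip(h.sample_ids, alt_counts))
    sizes, medians = [], []
    for label in range(k):
        mem = [s for s, l in assignments.items() if l == label]
        sizes.append(len(mem))
        medians.append(float(np.median([counts_by[s] for s in mem])))
    if h.n_sites > 0:
        miss = (h.data == -1).mean(axis=1)
    else:
        miss = np.zeros(h.n_samples)
    missingness = dict(zip(h.sample_ids, (float(m) for m in miss)))
    top3 = sum(sorted(sizes, reverse=True)[:3])
    flag = k <= 3 and top3 >= 0.9 * h.n_samples
    return HaplotypeGroupResult(
        gene_id=gene_id, assignments=assignments, k=k, class_sizes=sizes,
        class_median_snps=medians, missingness=missingness,
        few_haplotype_flag=flag,
    )


def classify_gene_diversity(counts: pd.DataFrame, v_min: int = 10
                            ) -> pd.DataFrame:
    """Label each gene 'variable' iff any strain carries >= v_min SNPs."""
    per_gene = counts.groupby("gene_id", sort=True)["snp_count"].max()
    return pd.DataFrame({
        "gene_id": per_gene.index,
        "max_snps": per_gene.to_numpy(),
        "label": np.where(per_gene.to_numpy() >= v_min, "variable",
                          "conserved"),
    }).reset_index(drop=True)
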