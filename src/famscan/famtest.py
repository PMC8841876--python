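"""Per-strain gene-family variation test.

Each strain's SNP count inside the family is compared with the count expected
from its genome-wide (genic) total under a proportional model, using a 1-df
chi-square goodness-of-fit test, followed by Benjamini-Hochberg FDR control
across strains. Verdicts: 'more' / 'less' when significant, else 'ns'.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .types import GeneModel
from .variants import INTERGENIC

__all__ = ["family_fraction", "family_chisq", "bh_adjust"]

LOW_POWER_TOTAL = 20  # strains with fewer genic SNPs are flagged low-power


def family_fraction(genes: Sequence[GeneModel], family: str,
                    weighting: str = "length") -> float:
    """Expected per-SNP probability of landing in the family.

    ``weighting='length'`` uses summed gene spans (SNP opportunity scales
    with sequence length); ``'count'`` uses gene counts instead.
    """
    fam = [g for g in genes if g.family == family]
    if not fam:
        raise ConfigError(f"family {family!r} matches no genes")
    if weighting == "length":
        total = sum(g.length for g in genes)
        num = sum(g.length for g in fam)
    elif weighting == "count":
        total = len(genes)
        num = len(fam)
    else:
        raise ConfigError(f"unknown weighting {weighting!r}")
    if total == 0:
        raise ConfigError("zero total gene span")
    return num / total


def bh_adjust(p: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ConfigError("bh_adjust expects a 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def family_chisq(counts: pd.DataFrame, family_gene_ids: Sequence[str],
                 q_f: float, alpha_fdr: float = 1e-4) -> pd.DataFrame:
    """Per-strain 1-df chi-square test of family vs genome-wide variation.

    ``counts`` is the long (strain, gene_id, snp_count) table from
    :func:`famscan.variants.count_snps`; the intergenic bucket is excluded so
    totals match the genic proportionality model behind ``q_f``. Strains with
    zero genic SNPs are reported with NaN statistics and verdict 'ns'.
    """
    if not 0 < q_f < 1:
        raise ConfigError(f"degenerate expected-count model: q_f={q_f}")
    fam = set(family_gene_ids)
    genic = counts[counts["gene_id"] != INTERGENIC]
    per_strain = genic.groupby("strain", sort=True)["snp_count"].sum()
    fam_counts = (
        genic[genic["gene_id"].isin(fam)]
        .groupby("strain", sort=True)["snp_count"].sum()
        .reindex(per_strain.index, fill_value=0)
    )
    total = per_strain.to_numpy(dtype=float)
    o_f = fam_counts.to_numpy(dtype=float)
    if (o_f > total).any():
        raise DataError("family counts exceed totals")
    with np.errstate(divide="ignore", invalid="ignore"):
        e_f = total * q_f
        e_r = total * (1.0 - q_f)
        chi2 = (o_f - e_f) ** 2 / e_f + ((total - o_f) - e_r) ** 2 / e_r
    testable = total > 0
    p = np.full(total.shape, np.nan)
    p[testable] = stats.chi2.sf(chi2[testable], df=1)
    q = np.full(total.shape, np.nan)
    if testable.any():
        q[testable] = bh_adjust(p[testable])
    verdict = np.full(total.shape, "ns", dtype=object)
    sig = testable & (q < alpha_fdr)
    verdict[sig & (o_f > e_f)] = "more"
    verdict[sig & (o_f < e_f)] = "less"
    return pd.DataFrame({
        "strain": per_strain.index,
        "family_snps": o_f.astype(int),
        "total_snps": total.astype(int),
        "expected_family_snps": e_f,
        "chi2": chi2,
        "p": p,
        "fdr_q": q,
        "verdict": verdict,
        "low_power": total < LOW_POWER_TOTAL,
    }).reset_index(drop=True)
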