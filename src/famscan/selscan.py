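"""Per-gene neutrality statistics: S, pi, Watterson's theta and Tajima's D.

All statistics are computed from first principles on haplotype matrices.
Missing data policy: ``n_used`` counts strains with at least one non-missing
call in the gene; S counts sites still segregating among non-missing calls;
pi uses pairwise deletion with per-pair renormalization to the gene's
segregating-site count. D is undefined (NaN) when S == 0, n_used < 2 or the
variance term vanishes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .types import GeneModel, HaplotypeMatrix, VariantCallSet
from .variants import gene_haplotypes

__all__ = [
    "TajimaRecord",
    "tajima_constants",
    "tajimas_d",
    "genome_scan",
    "decile_flag",
]


@dataclass
class TajimaRecord:
    gene_id: str
    n_used: int
    S: int
    pi: float
    theta_w: float
    D: float  # NaN when undefined
    family: Optional[str] = None
    top_decile: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.D)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants for sample size n (n >= 2)."""
    if n < 2:
        raise ConfigError(f"tajima constants need n >= 2, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _pairwise_pi(data: np.ndarray) -> float:
    """Mean pairwise difference with pairwise deletion.

    ``data`` holds only segregating columns. Each pair's mismatch count over
    its shared non-missing sites is rescaled by S / shared; pairs sharing no
    site are dropped from the average.
    """
    n, s = data.shape
    if s == 0 or n < 2:
        return 0.0
    present = (data != -1).astype(np.float64)
    ones = np.where(data == 1, 1.0, 0.0)  # missing counts as 0, masked below
    # xor counts over shared sites: a=1,b=0 plus a=0,b=1 (both present)
    zeros = present - ones
    mism = ones @ zeros.T + zeros @ ones.T
    shared = present @ present.T
    iu = np.triu_indices(n, k=1)
    mism, shared = mism[iu], shared[iu]
    ok = shared > 0
    if not ok.any():
        return float("nan")
    contrib = mism[ok] * (s / shared[ok])
    return float(contrib.sum() / ok.sum())


def tajimas_d(h: HaplotypeMatrix, gene_id: str = "",
              family: Optional[str] = None) -> TajimaRecord:
    """Tajima's D (and its ingredients) for one locus.

    Returns a record with ``D = NaN`` rather than raising when the statistic
    is undefined.
    """
    if h.n_samples < 2:
        raise DataError("tajimas_d needs a matrix with >= 2 rows")
    present = h.mask_missing()
    used_rows = present.any(axis=1) if h.n_sites > 0 else np.ones(
        h.n_samples, dtype=bool)
    n_used = int(used_rows.sum()) if h.n_sites > 0 else h.n_samples
    data = h.data[used_rows] if h.n_sites > 0 else h.data

    # segregating among non-missing calls
    if h.n_sites > 0:
        pres = data != -1
        any_one = ((data == 1) & pres).any(axis=0)
        any_zero = ((data == 0) & pres).any(axis=0)
        seg = any_one & any_zero
        data = data[:, seg]
    s = int(data.shape[1])

    if n_used < 2 or s == 0:
        return TajimaRecord(gene_id=gene_id, n_used=n_used, S=s, pi=0.0,
                            theta_w=0.0, D=float("nan"), family=family)
    k = tajima_constants(n_used)
    pi = _pairwise_pi(data)
    theta_w = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var > 0:
        d = (pi - theta_w) / np.sqrt(var)
    elif abs(pi - theta_w) < 1e-12:
        d = 0.0  # n=2: numerator is identically 0 along with the variance
    else:
        d = float("nan")
    return TajimaRecord(gene_id=gene_id, n_used=n_used, S=s, pi=pi,
                        theta_w=theta_w, D=float(d), family=family)


def genome_scan(vcs: VariantCallSet, genes: Sequence[GeneModel],
                quantile: float = 0.9) -> pd.DataFrame:
    """One TajimaRecord per gene, with the top-decile flag applied.

    Returns a table with columns gene_id, family, n_used, S, pi, theta_w, D,
    top_decile. Genes with undefined D are carried (D = NaN, never flagged).
    """
    records = []
    for g in genes:
        h = gene_haplotypes(vcs, g)
        records.append(tajimas_d(h, gene_id=g.gene_id, family=g.family))
    table = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "family": [r.family for r in records],
            "n_used": [r.n_used for r in records],
            "S": [r.S for r in records],
            "pi": [r.pi for r in records],
            "theta_w": [r.theta_w for r in records],
            "D": [r.D for r in records],
        }
    )
    if np.isfinite(table["D"]).any():
        _, table = decile_flag(table, q=quantile)
    else:
        table["top_decile"] = False
    return table


def decile_flag(table: pd.DataFrame, q: float = 0.9
                ) -> tuple[float, pd.DataFrame]:
    """Flag genes with D strictly above the nearest-rank empirical quantile.

    The threshold is the ceil(q*m)-th order statistic of the m defined D
    values. Undefined D is never flagged.
    """
    if not 0 < q < 1:
        raise ConfigError(f"quantile level must be in (0, 1), got {q}")
    d = table["D"].to_numpy(dtype=float)
    defined = np.isfinite(d)
    if not defined.any():
        raise DataError("decile_flag: no defined D values")
    vals = np.sort(d[defined])
    m = vals.size
    rank = int(np.ceil(q * m))  # 1-based nearest-rank
    threshold = float(vals[rank - 1])
    out = table.copy()
    out["top_decile"] = defined & (d > threshold)
    return threshold, out
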