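"""Core domain types shared across modules.

Conventions
-----------
* Haplotype / call matrices are ``int8`` with values ``0`` (reference /
  ancestral), ``1`` (alternate / derived) and ``-1`` (missing).
* Gene coordinates are 0-based half-open; VCF site positions are 1-based.
  A site at VCF position ``P`` belongs to gene ``[s, e)`` iff ``s <= P-1 < e``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

MISSING = np.int8(-1)


@dataclass
class HaplotypeMatrix:
    """Binary sample x site matrix for one locus.

    Parameters
    ----------
    data
        ``(n_samples, n_sites)`` int8 array in {0, 1, -1}.
    positions
        Strictly increasing site coordinates, one per column.
    sample_ids
        Row labels.
    """

    data: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise DataError("haplotype matrix must be 2-dimensional")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape[0] != self.data.shape[1]:
            raise DataError(
                f"{self.positions.shape[0]} positions for {self.data.shape[1]} sites"
            )
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise DataError("site positions must be strictly increasing")
        if len(self.sample_ids) != self.data.shape[0]:
            raise DataError("sample_ids length does not match matrix rows")
        bad = ~np.isin(self.data, [-1, 0, 1])
        if bad.any():
            raise DataError("haplotype entries must be in {0, 1, -1}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def mask_missing(self) -> np.ndarray:
        """Boolean array, True where the call is present."""
        return self.data != MISSING


@dataclass
class VariantCallSet:
    """Haploid biallelic SNP calls for many strains, genome-wide.

    ``sites`` has columns ``chrom, pos, ref, alt`` (pos 1-based, as in VCF),
    sorted by (chrom, pos) and unique. ``calls`` is strains x sites int8 in
    {0, 1, -1}.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    strain_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(self.sites.columns):
            raise DataError(f"sites table needs columns {sorted(required)}")
        if self.calls.shape != (len(self.strain_ids), len(self.sites)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.sites)} sites"
            )
        keys = list(zip(self.sites["chrom"], self.sites["pos"]))
        if len(set(keys)) != len(keys):
            raise DataError("duplicate site keys in variant call set")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class GeneModel:
    """One gene: 0-based half-open span plus optional family tag."""

    gene_id: str
    chrom: str
    start: int
    end: int
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_vcf_pos(self, pos: int) -> bool:
        """True iff the 1-based VCF position falls inside the span."""
        return self.start <= pos - 1 < self.end


@dataclass
class ExpressionMatrix:
    """Features (spots) x samples normalized log2 intensities with metadata.

    ``samples`` is indexed by sample id and carries the design factors
    (genotype, treatment, optionally time and batch). ``feature_genes``
    optionally maps feature (spot) ids to gene names for spot-to-gene
    aggregation.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    feature_genes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise DataError("expression columns must match sample metadata index")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataError("expression values must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]
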