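"""Synthetic data generators.

Three kinds of inputs are produced, matching the statistical structure the
downstream analyses assume:

* coalescent haplotype samples under neutral, balanced (two deeply diverged
  classes) and star genealogies;
* a multi-strain haploid biallelic SNP panel with an embedded gene family in
  which most family genes are near-monomorphic and a minority segregate as a
  few diverged haplotype classes;
* factorial (genotype x treatment) and time-series expression matrices.

Coalescent conventions: time in units of 2N generations; theta is the
per-locus scaled mutation rate; mutations on a branch of length ``l`` are
Poisson(theta/2 * l) under the infinite-sites model. Site positions are drawn
uniformly on an integer interval, with collisions re-drawn.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .types import ExpressionMatrix, GeneModel, HaplotypeMatrix, VariantCallSet

__all__ = [
    "SimConfig",
    "PanelConfig",
    "PanelResult",
    "simulate_neutral",
    "simulate_balanced",
    "simulate_star",
    "simulate_strain_panel",
    "simulate_expression",
    "write_vcf",
    "write_bed",
]

_LOCUS_SPAN = 1_000_000  # default integer coordinate range for simulated loci


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Configuration for a single-locus genealogy simulation.

    ``subtree_theta`` (balanced mode only) overrides the mutation rate used
    inside the two class subtrees; the two long root branches always use
    ``theta``. Leave ``None`` to mutate everything at ``theta``.
    """

    n: int
    theta: float
    mode: str = "neutral"
    t_split: float = 10.0
    class_frac: float = 0.5
    seed: int = 0
    subtree_theta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError(f"sample size n={self.n} must be >= 2")
        if self.theta < 0:
            raise ConfigError("theta must be >= 0")
        if self.mode not in ("neutral", "balanced", "star"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "balanced":
            if not 0 < self.class_frac < 1:
                raise ConfigError("class_frac must be in (0, 1)")
            if self.t_split <= 0:
                raise ConfigError("t_split must be > 0")


@dataclass(frozen=True)
class PanelConfig:
    """Configuration for the multi-strain panel generator.

    ``class_snps`` maps each *variable* family gene to its per-class
    prototype SNP counts versus the reference (class 0 should normally be the
    reference-like class with 0 SNPs); ``class_probs`` are the class
    assignment probabilities, shared across variable genes but drawn
    independently per gene. Family genes without an entry in ``class_snps``
    stay monomorphic. ``snp_rate`` is the per-strain, per-bp background SNP
    rate over non-family genes; ``intergenic_rate`` likewise over the gaps
    between genes.
    """

    n_strains: int = 50
    n_genes: int = 100
    family_gene_ids: tuple[str, ...] = ()
    family_tag: str = "fam"
    snp_rate: float = 0.002
    intergenic_rate: float = 0.0
    class_snps: Mapping[str, Sequence[int]] = field(default_factory=dict)
    class_probs: Sequence[float] = (1.0,)
    noise_snps: float = 0.0
    missing_rate: float = 0.0
    gene_length: int = 1000
    gene_gap: int = 500
    chroms: tuple[str, ...] = ("I", "II", "III", "IV", "V", "X")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_genes < 1:
            raise ConfigError("n_strains and n_genes must be >= 1")
        if self.snp_rate < 0 or self.intergenic_rate < 0 or self.noise_snps < 0:
            raise ConfigError("rates must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.size < 1 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("class_probs must be non-negative and sum to 1")
        for gid, counts in self.class_snps.items():
            if len(counts) != probs.size:
                raise ConfigError(
                    f"gene {gid}: {len(counts)} class prototypes for "
                    f"{probs.size} class probabilities"
                )

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

def _coalescent_branches(
    n: int, rng: np.random.Generator
) -> list[tuple[frozenset[int], float]]:
    """Neutral n-coalescent: list of (leaf set below branch, branch length).

    Successive coalescences with Exp(k(k-1)/2) waiting times for k active
    lineages; the root lineage carries no branch.
    """
    if n == 1:
        return []
    active: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    birth = [0.0] * n
    t = 0.0
    branches: list[tuple[frozenset[int], float]] = []
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        branches.append((active[i], t - birth[i]))
        branches.append((active[j], t - birth[j]))
        merged = active[i] | active[j]
        # remove higher index first
        for idx in (j, i):
            del active[idx]
            del birth[idx]
        active.append(merged)
        birth.append(t)
    return branches


def _draw_positions(
    n_sites: int, rng: np.random.Generator, lo: int = 0, hi: int = _LOCUS_SPAN
) -> np.ndarray:
    """Distinct integer positions in [lo, hi), collisions re-drawn."""
    if n_sites > hi - lo:
        raise ConfigError("more sites requested than available positions")
    chosen: set[int] = set()
    while len(chosen) < n_sites:
        draw = rng.integers(lo, hi, size=n_sites - len(chosen))
        chosen.update(int(p) for p in draw)
    return np.array(sorted(chosen), dtype=np.int64)


def _mutate(
    branches: Sequence[tuple[frozenset[int], float]],
    n: int,
    theta: float,
    rng: np.random.Generator,
    rates: Optional[Sequence[float]] = None,
) -> HaplotypeMatrix:
    """Drop infinite-sites mutations on branches and assemble the matrix.

    ``rates`` optionally gives a per-branch mutation rate overriding theta.
    """
    carriers: list[frozenset[int]] = []
    for b, (leaves, length) in enumerate(branches):
        rate = theta if rates is None else rates[b]
        m = rng.poisson(rate / 2.0 * length)
        carriers.extend([leaves] * int(m))
    s = len(carriers)
    data = np.zeros((n, s), dtype=np.int8)
    for col, leaves in enumerate(carriers):
        data[list(leaves), col] = 1
    positions = _draw_positions(s, rng)
    # columns inherit a random association with sorted positions
    order = rng.permutation(s)
    data = data[:, order]
    return HaplotypeMatrix(data=data, positions=positions,
                           sample_ids=[f"s{i:03d}" for i in range(n)])


def simulate_neutral(cfg: SimConfig) -> HaplotypeMatrix:
    """Sample one locus under the standard neutral coalescent."""
    if cfg.mode != "neutral":
        raise ConfigError(f"simulate_neutral called with mode={cfg.mode!r}")
    rng = np.random.default_rng(cfg.seed)
    branches = _coalescent_branches(cfg.n, rng)
    return _mutate(branches, cfg.n, cfg.theta, rng)


def simulate_balanced(cfg: SimConfig) -> HaplotypeMatrix:
    """Two neutral subgenealogies joined through long root branches.

    Each class subtree is extended by a root branch of length ``t_split``
    before joining; mutations on those two long branches create the
    intermediate-frequency variants characteristic of old balanced
    polymorphisms.
    """
    if cfg.mode != "balanced":
        raise ConfigError(f"simulate_balanced called with mode={cfg.mode!r}")
    n1 = int(round(cfg.class_frac * cfg.n))
    n2 = cfg.n - n1
    if n1 < 1 or n2 < 1:
        raise ConfigError(
            f"class sizes {n1}/{n2} from class_frac={cfg.class_frac}, n={cfg.n}"
        )
    rng = np.random.default_rng(cfg.seed)
    sub_theta = cfg.theta if cfg.subtree_theta is None else cfg.subtree_theta
    b1 = _coalescent_branches(n1, rng)
    b2 = [
        (frozenset(i + n1 for i in leaves), length)
        for leaves, length in _coalescent_branches(n2, rng)
    ]
    branches = list(b1) + list(b2)
    rates = [sub_theta] * len(branches)
    branches.append((frozenset(range(n1)), cfg.t_split))
    branches.append((frozenset(range(n1, cfg.n)), cfg.t_split))
    rates += [cfg.theta, cfg.theta]
    return _mutate(branches, cfg.n, cfg.theta, rng, rates=rates)


def simulate_star(cfg: SimConfig) -> HaplotypeMatrix:
    """Star genealogy: n external branches of length 1; all mutations are
    singletons."""
    if cfg.mode != "star":
        raise ConfigError(f"simulate_star called with mode={cfg.mode!r}")
    rng = np.random.default_rng(cfg.seed)
    branches = [(frozenset([i]), 1.0) for i in range(cfg.n)]
    return _mutate(branches, cfg.n, cfg.theta, rng)


def simulate(cfg: SimConfig) -> HaplotypeMatrix:
    """Dispatch on ``cfg.mode``."""
    return {
        "neutral": simulate_neutral,
        "balanced": simulate_balanced,
        "star": simulate_star,
    }[cfg.mode](cfg)


def replicate_seeds(root_seed: int, n_reps: int) -> list[int]:
    """Independent child seeds so replicate r is reproducible in isolation."""
    ss = np.random.SeedSequence(root_seed)
    return [int(c.generate_state(1)[0]) for c in ss.spawn(n_reps)]


# ---------------------------------------------------------------------------
# strain panel
# ---------------------------------------------------------------------------

@dataclass
class PanelResult:
    """Generator output plus ground truth for round-trip testing."""

    calls: VariantCallSet
    genes: list[GeneModel]
    class_truth: pd.DataFrame   # strain, gene_id, class_label
    count_truth: pd.DataFrame   # strain, gene_id, snp_count (post-missingness)


def _layout_genes(cfg: PanelConfig) -> list[GeneModel]:
    """Lay genes out contiguously, split about evenly across chromosomes."""
    ids = cfg.gene_ids()
    family = set(cfg.family_gene_ids)
    unknown = family - set(ids)
    if unknown:
        raise ConfigError(f"family gene ids not in panel: {sorted(unknown)}")
    per_chrom = int(np.ceil(cfg.n_genes / len(cfg.chroms)))
    genes = []
    for i, gid in enumerate(ids):
        chrom = cfg.chroms[i // per_chrom]
        slot = i % per_chrom
        start = cfg.gene_gap + slot * (cfg.gene_length + cfg.gene_gap)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                start=start,
                end=start + cfg.gene_length,
                family=cfg.family_tag if gid in family else None,
            )
        )
    return genes


def _check_no_overlap(genes: Sequence[GeneModel]) -> None:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                raise DataError(
                    f"overlapping gene intervals on {chrom}: "
                    f"{a.gene_id} and {b.gene_id}"
                )


def simulate_strain_panel(cfg: PanelConfig) -> PanelResult:
    """Generate a CeNDR-like haploid SNP panel with an embedded gene family.

    Background SNPs are scattered per strain over non-family genes (and
    optionally intergenic gaps); each variable family gene draws a haplotype
    class per strain, copies that class's prototype site set and perturbs it
    with ``Poisson(noise_snps)`` site toggles; missingness is applied
    uniformly at rate ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _layout_genes(cfg)
    _check_no_overlap(genes)
    gene_by_id = {g.gene_id: g for g in genes}
    strains = [f"strain{(i + 1):04d}" for i in range(cfg.n_strains)]
    family = set(cfg.family_gene_ids)
    n_classes = len(np.asarray(cfg.class_probs))

    # alt carriers per (chrom, 1-based pos): strain index list
    carriers: dict[tuple[str, int], list[int]] = {}

    def add_call(chrom: str, pos1: int, strain_idx: int) -> None:
        carriers.setdefault((chrom, pos1), []).append(strain_idx)

    # --- background over non-family genes
    for g in genes:
        if g.gene_id in family:
            continue
        lam = cfg.snp_rate * g.length
        for s in range(cfg.n_strains):
            m = rng.poisson(lam)
            if m:
                for p in _draw_positions(min(m, g.length), rng, g.start, g.end):
                    add_call(g.chrom, int(p) + 1, s)

    # --- optional intergenic background in the gaps before each gene
    if cfg.intergenic_rate > 0:
        for g in genes:
            lo, hi = g.start - cfg.gene_gap, g.start
            lam = cfg.intergenic_rate * (hi - lo)
            for s in range(cfg.n_strains):
                m = rng.poisson(lam)
                if m:
                    for p in _draw_positions(min(m, hi - lo), rng, lo, hi):
                        add_call(g.chrom, int(p) + 1, s)

    # --- variable family genes: haplotype-class structure
    truth_rows = []
    for gid in sorted(cfg.class_snps):
        if gid not in family:
            raise ConfigError(f"class_snps gene {gid} is not a family gene")
        g = gene_by_id[gid]
        protos = [int(c) for c in cfg.class_snps[gid]]
        # disjoint prototype site sets per class, plus a pool for noise sites
        need = sum(protos) + 25
        if need > g.length:
            raise ConfigError(f"gene {gid} too short for {need} prototype sites")
        pool = _draw_positions(need, rng, g.start, g.end)
        pool = pool[rng.permutation(len(pool))]
        class_sites: list[np.ndarray] = []
        off = 0
        for c in protos:
            class_sites.append(np.sort(pool[off:off + c]))
            off += c
        noise_pool = pool[off:]
        assignments = rng.choice(n_classes, size=cfg.n_strains,
                                 p=np.asarray(cfg.class_probs, dtype=float))
        for s in range(cfg.n_strains):
            cls = int(assignments[s])
            sites = set(int(p) for p in class_sites[cls])
            if cfg.noise_snps > 0:
                n_tog = int(rng.poisson(cfg.noise_snps))
                togglable = np.concatenate([class_sites[cls], noise_pool])
                for p in rng.choice(togglable, size=min(n_tog, len(togglable)),
                                    replace=False):
                    sites.symmetric_difference_update({int(p)})
            for p in sites:
                add_call(g.chrom, p + 1, s)
            truth_rows.append({"strain": strains[s], "gene_id": gid,
                               "class_label": cls})

    # --- assemble call matrix
    chrom_order = {c: i for i, c in enumerate(cfg.chroms)}
    keys = sorted(carriers, key=lambda k: (chrom_order.get(k[0], 99), k[1]))
    bases = np.array(list("ACGT"))
    n_sites = len(keys)
    calls = np.zeros((cfg.n_strains, n_sites), dtype=np.int8)
    for j, k in enumerate(keys):
        calls[carriers[k], j] = 1
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = -1
    refs = bases[rng.integers(0, 4, size=n_sites)]
    alts = np.array([bases[(list(bases).index(r) + 1) % 4] for r in refs])
    sites = pd.DataFrame({
        "chrom": [k[0] for k in keys],
        "pos": [k[1] for k in keys],
        "ref": refs,
        "alt": alts,
    })
    vcs = VariantCallSet(sites=sites, calls=calls, strain_ids=strains)

    # --- truth tables
    class_truth = pd.DataFrame(
        truth_rows, columns=["strain", "gene_id", "class_label"]
    )
    count_truth = _truth_counts(vcs, genes)
    return PanelResult(calls=vcs, genes=genes, class_truth=class_truth,
                       count_truth=count_truth)


def _truth_counts(vcs: VariantCallSet, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Post-missingness per-strain per-gene alt counts, straight from calls."""
    rows = []
    pos0 = vcs.sites["pos"].to_numpy() - 1
    chroms = vcs.sites["chrom"].to_numpy()
    alt = vcs.calls == 1
    for g in genes:
        in_gene = (chroms == g.chrom) & (pos0 >= g.start) & (pos0 < g.end)
        counts = alt[:, in_gene].sum(axis=1)
        for s, c in zip(vcs.strain_ids, counts):
            rows.append({"strain": s, "gene_id": g.gene_id, "snp_count": int(c)})
    return pd.DataFrame(rows, columns=["strain", "gene_id", "snp_count"])


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    design: pd.DataFrame,
    effects: pd.DataFrame,
    sigma: float,
    seed: int = 0,
    batch_offsets: Optional[Mapping[str, float]] = None,
) -> ExpressionMatrix:
    """Factorial / time-series expression matrix on the log2 scale.

    ``design`` rows are samples with columns ``genotype`` and ``treatment``
    (two levels each; the lexicographically second level is coded 1) and
    optionally ``time`` (numeric) and ``batch``. ``effects`` is indexed by
    feature id with any of the columns ``mu, beta_g, beta_t, beta_gxt, slope``
    (missing columns default to 0). The model is

        y = mu + beta_g*G + beta_t*T + beta_gxt*G*T + slope*time
            + batch_offset + N(0, sigma^2)
    """
    if not {"genotype", "treatment"}.issubset(design.columns):
        raise ConfigError("design needs 'genotype' and 'treatment' columns")
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    eff = effects.copy()
    for col in ("mu", "beta_g", "beta_t", "beta_gxt", "slope"):
        if col not in eff.columns:
            eff[col] = 0.0
    g_levels = sorted(design["genotype"].astype(str).unique())
    t_levels = sorted(design["treatment"].astype(str).unique())
    if len(g_levels) > 2 or len(t_levels) > 2:
        raise ConfigError("simulate_expression supports two-level factors")
    gvec = (design["genotype"].astype(str) == g_levels[-1]).to_numpy(float) \
        if len(g_levels) == 2 else np.zeros(len(design))
    tvec = (design["treatment"].astype(str) == t_levels[-1]).to_numpy(float) \
        if len(t_levels) == 2 else np.zeros(len(design))
    time = design["time"].to_numpy(float) if "time" in design.columns \
        else np.zeros(len(design))
    boff = np.zeros(len(design))
    if "batch" in design.columns and batch_offsets:
        boff = design["batch"].astype(str).map(
            lambda b: float(batch_offsets.get(b, 0.0))).to_numpy()
    mu = eff["mu"].to_numpy(float)[:, None]
    y = (
        mu
        + np.outer(eff["beta_g"].to_numpy(float), gvec)
        + np.outer(eff["beta_t"].to_numpy(float), tvec)
        + np.outer(eff["beta_gxt"].to_numpy(float), gvec * tvec)
        + np.outer(eff["slope"].to_numpy(float), time)
        + boff[None, :]
    )
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=y.shape)
    sample_ids = [f"sample{(i + 1):03d}" for i in range(len(design))]
    values = pd.DataFrame(y, index=eff.index, columns=sample_ids)
    samples = design.copy()
    samples.index = pd.Index(sample_ids, name="sample")
    return ExpressionMatrix(values=values, samples=samples)


# ---------------------------------------------------------------------------
# writers (plain-text formats only)
# ---------------------------------------------------------------------------

def write_vcf(vcs: VariantCallSet, path: str | Path,
              contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write a minimal VCF 4.2 with haploid GT fields."""
    path = Path(path)
    chroms = list(dict.fromkeys(vcs.sites["chrom"]))
    gt_map = {0: "0", 1: "1", -1: "."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famscan\n")
        for c in chroms:
            ln = (contig_lengths or {}).get(c, 100_000_000)
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vcs.strain_ids) + "\n")
        for j, row in enumerate(vcs.sites.itertuples(index=False)):
            gts = "\t".join(gt_map[int(v)] for v in vcs.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def write_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """BED: chrom, start, end, gene_id, family tag ('.' when untagged)."""
    with Path(path).open("w") as fh:
        for g in genes:
            tag = g.family if g.family else "."
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{tag}\n")


def write_family_list(genes: Sequence[GeneModel], path: str | Path) -> None:
    """TSV of (gene_id, family) for tagged genes."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\tfamily\n")
        for g in genes:
            if g.family:
                fh.write(f"{g.gene_id}\t{g.family}\n")


def write_expression(em: ExpressionMatrix, values_path: str | Path,
                     samples_path: str | Path) -> None:
    em.values.to_csv(values_path, sep="\t", index_label="feature")
    em.samples.to_csv(samples_path, sep="\t")
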