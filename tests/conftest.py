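import numpy as np
import pytest

from famscan.simpanel import PanelConfig, simulate_strain_panel
from famscan.types import HaplotypeMatrix


@pytest.fixture(scope="session")
def three_class_panel():
    """Panel with one variable family gene segregating as 3 classes
    (prototype SNP counts 0/30/95, small within-class noise)."""
    cfg = PanelConfig(
        n_strains=60,
        n_genes=40,
        family_gene_ids=("g0010", "g0011", "g0012"),
        snp_rate=0.002,
        class_snps={"g0011": (0, 30, 95)},
        class_probs=(0.5, 0.3, 0.2),
        noise_snps=1.0,
        missing_rate=0.0,
        seed=42,
    )
    return cfg, simulate_strain_panel(cfg)


def brute_force_pi(data: np.ndarray) -> float:
    """Independent oracle: enumerate all sample pairs; pairwise deletion with
    renormalization to the segregating-site count; pairs with no shared site
    are dropped."""
    pres = data != -1
    seg = ((data == 1) & pres).any(axis=0) & ((data == 0) & pres).any(axis=0)
    d = data[:, seg]
    s = d.shape[1]
    if s == 0:
        return 0.0
    n = d.shape[0]
    total, used = 0.0, 0
    for a in range(n):
        for b in range(a + 1, n):
            both = (d[a] != -1) & (d[b] != -1)
            if not both.any():
                continue
            total += (d[a][both] != d[b][both]).sum() * s / both.sum()
            used += 1
    return total / used if used else float("nan")


def brute_force_tajima(data: np.ndarray) -> float:
    """Hand evaluation of Tajima's D from the textbook constants."""
    pres = data != -1
    rows = pres.any(axis=1)
    d = data[rows]
    n = d.shape[0]
    pres = d != -1
    seg = ((d == 1) & pres).any(axis=0) & ((d == 0) & pres).any(axis=0)
    s = int(seg.sum())
    if n < 2 or s == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = brute_force_pi(d)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        # n=2 and n=3 degenerate cases: variance constants vanish and, with
        # complete data, the numerator vanishes identically too -> D = 0;
        # a non-zero numerator (possible under missingness) stays undefined
        return 0.0 if abs(pi - s / a1) < 1e-12 else float("nan")
    return (pi - s / a1) / np.sqrt(var)


def random_haplotype_matrix(rng, n_max=6, s_max=6, missing_frac=0.0):
    n = int(rng.integers(2, n_max + 1))
    s = int(rng.integers(0, s_max + 1))
    data = rng.integers(0, 2, size=(n, s)).astype(np.int8)
    if missing_frac > 0 and s > 0:
        mask = rng.random(data.shape) < missing_frac
        data[mask] = -1
    return HaplotypeMatrix(data=data, positions=np.arange(s),
                           sample_ids=[f"s{i}" for i in range(n)])
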