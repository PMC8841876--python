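"""Factorial expression analysis.

Pipeline pieces: log2-ratio transform against the per-feature mean, PCA
variance decomposition (samples as observations), per-spot ordinary least
squares with sequential (type-I) F tests and per-term BH FDR, spot-to-gene
aggregation (a gene is called when any of its spots is), time-series trend,
hypergeometric category enrichment with Bonferroni correction, and qPCR
reference-gene normalization.

Input is assumed to be a *normalized* log2 intensity matrix; raw two-color
array processing happens upstream. When a ``batch`` factor is present, the
matrix is batch mean-centered per feature before fitting.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .famtest import bh_adjust
from .types import ExpressionMatrix

__all__ = [
    "log2_ratio",
    "pca_variance",
    "center_batches",
    "apply_blacklist",
    "fit_models",
    "gene_calls",
    "time_trend",
    "hypergeom_enrich",
    "qpcr_normalize",
    "DEFAULT_TERM_FDR",
]

MODELS = {"G": ["G"], "GxT": ["G", "T", "G:T"], "DGT": ["D", "G", "T"]}
DEFAULT_TERM_FDR = {
    "G": {"G": 0.05},
    "GxT": {"G": 0.05, "T": 0.1, "G:T": 0.1},
    "DGT": {"D": 0.05, "G": 0.05, "T": 0.05},
}


def log2_ratio(values: pd.DataFrame) -> pd.DataFrame:
    """R_ij = log2(y_ij / mean_j'(y_ij')) on linear-scale intensities.

    The per-feature geometric identity mean_j 2**R_ij == 1 holds exactly.
    """
    arr = values.to_numpy(dtype=float)
    if (arr <= 0).any():
        bad = values.index[(arr <= 0).any(axis=1)]
        raise DataError(f"non-positive intensities for features: "
                        f"{list(bad[:5])}")
    row_mean = arr.mean(axis=1, keepdims=True)
    return pd.DataFrame(np.log2(arr / row_mean), index=values.index,
                        columns=values.columns)


def pca_variance(r: pd.DataFrame, threshold: float = 0.049
                 ) -> tuple[np.ndarray, pd.DataFrame, int]:
    """PCA with samples as observations and features as variables.

    Data are centered (per feature), not scaled. Returns (variance
    fractions, sample scores, number of axes with fraction > threshold).
    """
    x = r.to_numpy(dtype=float).T  # samples x features
    n = x.shape[0]
    if n < 2:
        raise DataError("pca_variance needs >= 2 samples")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = pd.DataFrame(u * s, index=r.columns,
                          columns=[f"PC{i + 1}" for i in range(len(s))])
    n_axes = int((frac > threshold).sum())
    return frac, scores, n_axes


def center_batches(em: ExpressionMatrix) -> ExpressionMatrix:
    """Per-batch, per-feature mean-centering. No-op without a batch column."""
    if "batch" not in em.samples.columns:
        return em
    vals = em.values.copy()
    for _, idx in em.samples.groupby("batch").groups.items():
        cols = list(idx)
        vals[cols] = vals[cols].sub(vals[cols].mean(axis=1), axis=0)
    return ExpressionMatrix(values=vals, samples=em.samples,
                            feature_genes=em.feature_genes)


def apply_blacklist(em: ExpressionMatrix,
                    blacklist: Sequence[str]) -> ExpressionMatrix:
    """Drop excluded features (e.g. probes known to misalign to the
    alternative genotype's genome)."""
    keep = ~em.values.index.isin(set(blacklist))
    fg = em.feature_genes[keep] if em.feature_genes is not None else None
    return ExpressionMatrix(values=em.values.loc[keep], samples=em.samples,
                            feature_genes=fg)


def _dummy(values: pd.Series) -> tuple[np.ndarray, int]:
    """Treatment-coded dummies (first level dropped), levels sorted."""
    levels = sorted(values.astype(str).unique())
    cols = np.column_stack([
        (values.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]
    ]) if len(levels) > 1 else np.zeros((len(values), 0))
    return cols, len(levels) - 1


def _design_blocks(samples: pd.DataFrame, model: str
                   ) -> tuple[np.ndarray, list[str], list[int]]:
    """Design matrix [intercept | term blocks...] plus term names and dfs."""
    if model not in MODELS:
        raise ConfigError(f"unknown model {model!r}; choose from "
                          f"{sorted(MODELS)}")
    factor_col = {"G": "genotype", "T": "treatment", "D": "time"}
    blocks, names, dfs = [], [], []
    cache: dict[str, tuple[np.ndarray, int]] = {}
    for term in MODELS[model]:
        if term == "G:T":
            g, _ = cache["G"]
            t, _ = cache["T"]
            cols = np.concatenate(
                [g[:, [i]] * t for i in range(g.shape[1])], axis=1
            ) if g.shape[1] and t.shape[1] else np.zeros((len(samples), 0))
            df = cols.shape[1]
        else:
            col = factor_col[term]
            if col not in samples.columns:
                raise ConfigError(f"model {model} needs sample column "
                                  f"{col!r}")
            cols, df = _dummy(samples[col])
            cache[term] = (cols, df)
        if df == 0:
            raise ConfigError(f"term {term} has a single level; design is "
                              "rank deficient")
        blocks.append(cols)
        names.append(term)
        dfs.append(df)
    x = np.column_stack([np.ones((len(samples), 1)), *blocks])
    return x, names, dfs


def fit_models(em: ExpressionMatrix, model: str = "GxT",
               term_fdr: Optional[Mapping[str, float]] = None
               ) -> pd.DataFrame:
    """OLS per feature with sequential (type-I) sum-of-squares F tests.

    Terms enter in the model's stated order; with balanced designs this
    coincides with marginal tests. Returns a long table (feature, term, ss,
    F, p, q, significant) where q is BH-adjusted per term across features and
    ``significant`` applies the per-term FDR threshold (defaults:
    FDR < 0.05 for G and D, FDR < 0.1 for T and G:T in the factorial model).
    """
    em = center_batches(em)
    x, names, dfs = _design_blocks(em.samples, model)
    n, p_cols = x.shape
    df_res = n - p_cols
    if df_res <= 0:
        raise ConfigError("no residual degrees of freedom")
    q_mat, r_mat = np.linalg.qr(x)
    if np.abs(np.diag(r_mat)).min() < 1e-10:
        raise ConfigError("design matrix is rank deficient")
    y = em.values.to_numpy(dtype=float).T  # samples x features
    coefs = q_mat.T @ y  # p_cols x features
    total_ss = (y**2).sum(axis=0)
    rss = total_ss - (coefs**2).sum(axis=0)
    rss = np.maximum(rss, 0.0)
    ms_res = rss / df_res
    # degenerate noiseless fits: a term is perfect only if its SS is real
    ss_tol = 1e-10 * (total_ss + 1.0)
    thresholds = dict(DEFAULT_TERM_FDR[model])
    if term_fdr:
        thresholds.update(term_fdr)
    rows = []
    start = 1  # skip intercept row
    for term, df in zip(names, dfs):
        ss = (coefs[start:start + df] ** 2).sum(axis=0)
        start += df
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df) / ms_res
        zero_resid = ms_res <= 0
        f = np.where(zero_resid, np.where(ss > ss_tol, np.inf, 0.0), f)
        p = stats.f.sf(f, df, df_res)
        p = np.where(np.isnan(p), 1.0, p)
        q = bh_adjust(p)
        alpha = thresholds.get(term, 0.05)
        rows.append(pd.DataFrame({
            "feature": em.values.index,
            "term": term,
            "ss": ss,
            "F": f,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }))
    return pd.concat(rows, ignore_index=True)


def gene_calls(fits: pd.DataFrame, feature_genes: pd.Series) -> pd.DataFrame:
    """Aggregate spot-level significance to genes: a gene is significant for
    a term iff at least one of its spots is. Returns (gene, term,
    n_spots_significant, significant)."""
    merged = fits.merge(feature_genes.rename("gene"), left_on="feature",
                        right_index=True, how="left")
    merged = merged.dropna(subset=["gene"])
    grp = merged.groupby(["gene", "term"], sort=True)["significant"]
    out = grp.agg(n_spots_significant="sum", significant="any").reset_index()
    out["n_spots_significant"] = out["n_spots_significant"].astype(int)
    return out


def time_trend(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature Pearson r (and regression slope) of expression vs time.

    Time is numeric here. Features with zero expression variance get NaN and
    ``defined = False``.
    """
    if "time" not in em.samples.columns:
        raise ConfigError("time_trend needs a 'time' sample column")
    t = em.samples["time"].to_numpy(dtype=float)
    if np.unique(t).size < 3:
        raise ConfigError("time_trend needs >= 3 distinct time points")
    y = em.values.to_numpy(dtype=float)
    tc = t - t.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=1))
    st = np.sqrt((tc**2).sum())
    cov = yc @ tc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sy * st)
        slope = cov / (tc**2).sum()
    defined = sy > 0
    r = np.where(defined, r, np.nan)
    return pd.DataFrame({"feature": em.values.index, "r": r, "slope": slope,
                         "defined": defined}).set_index("feature")


def hypergeom_enrich(hits: set[str], universe: set[str],
                     categories: Mapping[str, set[str]],
                     min_category: int = 3, min_overlap: int = 2
                     ) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with Bonferroni correction.

    Categories are intersected with the universe first; categories with size
    <= min_category or overlap <= min_overlap are excluded *before* testing,
    and the Bonferroni factor counts only tested categories. Gene sets are
    sets of unique gene names (not spots).
    """
    if not hits <= universe:
        raise DataError("hits must be a subset of the universe")
    n_pop = len(universe)
    n_draw = len(hits)
    tested = []
    for cid, members in categories.items():
        cat = members & universe
        overlap = len(cat & hits)
        if len(cat) <= min_category or overlap <= min_overlap:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, n_pop, len(cat), n_draw))
        tested.append((cid, len(cat), overlap, p))
    m = len(tested)
    return pd.DataFrame(
        [
            {"category": cid, "category_size": size, "overlap": ov,
             "p": p, "p_bonferroni": min(p * m, 1.0)}
            for cid, size, ov, p in tested
        ],
        columns=["category", "category_size", "overlap", "p", "p_bonferroni"],
    )


def qpcr_normalize(q_gene: np.ndarray | Sequence[float],
                   q_ref1: np.ndarray | Sequence[float],
                   q_ref2: np.ndarray | Sequence[float]) -> np.ndarray:
    """Normalize qPCR quantities against two reference genes:

        E = Q_G / (Q_ref1/mean(Q_ref1) + Q_ref2/mean(Q_ref2))
    """
    q_gene = np.asarray(q_gene, dtype=float)
    q_ref1 = np.asarray(q_ref1, dtype=float)
    q_ref2 = np.asarray(q_ref2, dtype=float)
    if not (q_gene.shape == q_ref1.shape == q_ref2.shape):
        raise DataError("qpcr_normalize: mismatched vector lengths")
    if (q_ref1 <= 0).any() or (q_ref2 <= 0).any():
        raise DataError("reference quantities must be positive")
    denom = q_ref1 / q_ref1.mean() + q_ref2 / q_ref2.mean()
    return q_gene / denom
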