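"""Expression screening: fold-change filter, PCA outliers, growth correlation.

The screen takes a genes x samples fold-change matrix (relative to an
unsupplemented control) and reproduces three generic stages:

1. keep genes with at least a +/-50% expression change in any sample
   (FC >= 1.5 or <= 0.5 by default);
2. project the surviving genes onto the top two principal components of their
   (log2-transformed, column-centered) expression profiles, and flag outlier
   genes whose distance from the score centroid exceeds mean + k*SD;
3. rank genes by the Pearson correlation of their day-4/5/7 time profile with
   the culture's growth profile for the same condition.

With only three timepoints the correlation is coarse; ties are broken by
profile magnitude and constant profiles are reported but left unranked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


def _matrix(expr: pd.DataFrame) -> tuple[pd.Index, np.ndarray]:
    if expr.columns[0] == "gene":
        genes = pd.Index(expr["gene"])
        values = expr.iloc[:, 1:].to_numpy(dtype=float)
    else:
        genes = expr.index
        values = expr.to_numpy(dtype=float)
    return genes, values


def fold_change_filter(
    expr: pd.DataFrame, threshold: float = 1.5, mode: str = "symmetric"
) -> list[str]:
    """Genes with a +/-50%-style change in at least one sample (inclusive).

    ``mode='symmetric'`` keeps FC >= threshold or FC <= 2 - threshold (the
    plain reading of "50% change" around the control level: 0.5 and 1.5 for
    the default threshold); ``mode='reciprocal'`` uses FC <= 1/threshold.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    genes, values = _matrix(expr)
    if (values <= 0).any():
        raise ValueError("fold changes must be strictly positive")
    if mode == "symmetric":
        lower = 2.0 - threshold
    elif mode == "reciprocal":
        lower = 1.0 / threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = (values >= threshold).any(axis=1)
    if lower > 0:
        keep |= (values <= lower).any(axis=1)
    return list(genes[keep])


def pca_project(expr: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """2-D PCA scores per gene (genes are observations, samples features).

    Profiles are log2-transformed by default to stabilize the multiplicative
    fold-change scale, then column-centered; scores are projections on the
    top-2 right singular directions, PC1 variance >= PC2 variance.
    """
    genes, values = _matrix(expr)
    if values.shape[0] < 3 or values.shape[1] < 2:
        raise ValueError("need >= 3 genes and >= 2 samples")
    if log_transform:
        if (values <= 0).any():
            raise ValueError("fold changes must be strictly positive")
        values = np.log2(values)
    if np.allclose(values, values[0:1, :]):
        raise ValueError("zero-variance expression matrix")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(values)
    out = pd.DataFrame(scores, columns=["PC1", "PC2"], index=genes)
    out.attrs["explained_variance"] = pca.explained_variance_.tolist()
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out


def detect_outlier_genes(scores: pd.DataFrame, k: float = 2.0) -> list[str]:
    """Genes whose distance from the score centroid exceeds mean + k*SD."""
    if len(scores) < 5:
        raise ValueError("need >= 5 genes to call outliers")
    pts = scores[["PC1", "PC2"]].to_numpy(dtype=float)
    dist = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    cut = dist.mean() + k * dist.std()
    return list(scores.index[dist > cut])


def correlate_with_growth(
    expr: pd.DataFrame, growth_profile, days=(4, 5, 7)
) -> pd.DataFrame:
    """Pearson r of each gene's time profile against the growth profile.

    ``expr`` holds one column per timepoint for a single condition (gene
    column or gene index as in the other screen stages).  Genes with constant
    profiles get r = NaN and are excluded from the ranking (rank NaN); ties
    are broken by the largest absolute log2 fold change in the profile.
    """
    growth = np.asarray(growth_profile, dtype=float)
    genes, values = _matrix(expr)
    if values.shape[1] != growth.size:
        raise ValueError("gene profiles and growth profile differ in length")
    if np.ptp(growth) == 0:
        raise ValueError("constant growth profile: correlation undefined")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    g_centered = growth - growth.mean()
    g_norm = np.linalg.norm(g_centered)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered @ g_centered / (norms * g_norm)
    r = np.where(norms > 0, r, np.nan)
    magnitude = np.abs(np.log2(np.maximum(values, 1e-300))).max(axis=1)
    out = pd.DataFrame({"gene": genes, "r": r, "magnitude": magnitude})
    out = out.sort_values(
        ["r", "magnitude"], ascending=[False, False], na_position="last"
    ).reset_index(drop=True)
    ranked = out["r"].notna()
    out["rank"] = np.where(ranked, np.arange(1, len(out) + 1), np.nan)
    return out
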