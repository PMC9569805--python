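"""PCA of expression with per-transcript variable contributions.

Samples are observations, transcripts are variables. Expression is
log2(TPM + 1)-transformed and mean-centered (not unit-scaled) before the
decomposition. The contribution of transcript t to component k is

    contrib(t, k) = 100 · loading(t, k)² / Σ_t loading(t, k)²,

so contributions sum to 100 per component. Each transcript is then
assigned to the considered component where its contribution is largest
("PC-related" transcripts); ties break deterministically to the lowest
component index. Component signs are fixed so the largest-|loading|
transcript of each component loads positively, making outputs reproducible
across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ExpressionMatrix

__all__ = ["PcaResult", "run_pca", "variable_contributions", "pc_related_transcripts"]


@dataclass
class PcaResult:
    scores: pd.DataFrame          # sample × PC
    loadings: pd.DataFrame        # transcript × PC
    variance_explained: pd.Series  # percent per PC, non-increasing
    contributions: pd.DataFrame   # transcript × PC, percent (sums to 100)


def run_pca(
    matrix: ExpressionMatrix,
    n_components: int = 4,
    log_transform: bool = True,
    scale: bool = False,
) -> PcaResult:
    """Centered PCA of samples over transcript features.

    Constant transcripts are dropped (with unit scaling they would divide
    by zero; without it they carry no variance either way).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 transcripts and 2 samples")
    X = matrix.T.to_numpy(dtype=float)  # samples × transcripts
    if log_transform:
        X = np.log2(X + 1.0)
    keep = X.std(axis=0) > 0
    transcripts = matrix.index[keep]
    X = X[:, keep]
    if scale:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    n_components = min(n_components, min(X.shape) - 1 if min(X.shape) > 1 else 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # transcripts × PCs
    # sign convention: top-|loading| transcript positive per component
    for k in range(loadings.shape[1]):
        top = np.argmax(np.abs(loadings[:, k]))
        if loadings[top, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    pcs = [f"PC{k + 1}" for k in range(n_components)]
    result = PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=pcs),
        loadings=pd.DataFrame(loadings, index=transcripts, columns=pcs),
        variance_explained=pd.Series(
            100.0 * pca.explained_variance_ratio_, index=pcs
        ),
        contributions=pd.DataFrame(),
    )
    result.contributions = variable_contributions(result)
    return result


def variable_contributions(result: PcaResult) -> pd.DataFrame:
    """Percent contribution of each transcript to each component."""
    sq = result.loadings.to_numpy() ** 2
    norms = sq.sum(axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm principal component")
    return pd.DataFrame(
        100.0 * sq / norms[None, :],
        index=result.loadings.index,
        columns=result.loadings.columns,
    )


def pc_related_transcripts(
    result: PcaResult, pcs: list[str] | None = None
) -> pd.Series:
    """Assign each transcript to its argmax-contribution component.

    Considered components default to all computed ones; the returned Series
    maps transcript id -> component label and partitions the transcripts.
    """
    contrib = result.contributions if not result.contributions.empty else variable_contributions(result)
    if pcs is not None:
        missing = [p for p in pcs if p not in contrib.columns]
        if missing:
            raise ValueError(f"unknown components: {missing}")
        contrib = contrib[pcs]
    # idxmax ties resolve to the first (lowest-index) column
    return contrib.idxmax(axis=1).rename("pc")
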