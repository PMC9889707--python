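"""Reporting plumbing: PCA summaries and feature-table CSV round-trips.

PCA is descriptive only (it feeds no model decision): component scores per
sample, loadings per feature and variance explained per component, with a
deterministic sign convention (the largest-magnitude loading of each
component is made positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .gating import is_feature_column


@dataclass
class PCASummary:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained: np.ndarray


def pca_summary(table: pd.DataFrame, n_components: int = 2) -> PCASummary:
    """PCA of the feature columns of a (z-scored) FeatureTable.

    Rank-deficient inputs are handled by truncating to the available rank.
    """
    cols = [c for c in table.columns if is_feature_column(c)]
    if len(table) < 2 or len(cols) < 2:
        raise ValueError("PCA needs >=2 samples and >=2 features")
    x = table[cols].to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    n_components = max(1, min(n_components, rank))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()
    for j in range(n_components):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    index = (
        table["sample_id"] if "sample_id" in table.columns else table.index
    )
    return PCASummary(
        scores=pd.DataFrame(scores, columns=comp_names, index=index),
        loadings=pd.DataFrame(loadings, columns=comp_names, index=cols),
        variance_explained=pca.explained_variance_ratio_,
    )


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"sample_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"features file {path} missing columns: {sorted(missing)}")
    return table


def require_columns(table: pd.DataFrame, columns: list[str], context: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"{context}: missing column(s) {missing}")
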