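"""Functional-profile normalization and PCA ordination.

Samples (metagenomes) are rows, functional categories (e.g. subsystem
annotations) are columns.  Counts are converted to per-sample relative
abundances, optionally z-standardized per category, and ordinated by PCA so
that ecosystems with distinct functional repertoires separate in the first
components.  Covariance PCA on relative abundances is the default;
correlation PCA (standardized columns) is available via the normalization
mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # categories x components
    explained_variance_fraction: np.ndarray
    column_means: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def normalize_profiles(matrix: pd.DataFrame,
                       mode: str = "relative") -> pd.DataFrame:
    """Scale each sample's counts to fractions; optionally z-score columns.

    mode="relative": rows sum to 1.  mode="relative+standardize":
    additionally center/scale each category to mean 0, sd 1 (population
    sd); zero-variance categories are dropped with a warning.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative values in profile matrix")
    sums = matrix.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    rel = matrix.div(sums, axis=0)
    if mode == "relative":
        return rel
    if mode == "relative+standardize":
        sd = rel.std(axis=0, ddof=0)
        dead = sd[sd == 0].index
        if len(dead):
            warnings.warn(f"dropping zero-variance categories: {list(dead)}",
                          stacklevel=2)
            rel = rel.drop(columns=dead)
            sd = sd.drop(index=dead)
        return (rel - rel.mean(axis=0)) / sd
    raise ValueError(f"unknown mode {mode!r}")


def pca(matrix: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Principal component analysis by SVD of the column-centered matrix.

    Explained-variance fractions are singular-value energies relative to
    the total variance.  Sign convention: the largest-magnitude entry of
    each loading vector is positive, making results reproducible across
    SVD implementations.
    """
    n_samples, n_cats = matrix.shape
    if n_samples < 2 or n_cats < 2:
        raise ValueError("need at least 2 samples and 2 categories")
    max_comp = min(n_samples - 1, n_cats)
    if n_components > max_comp:
        raise ValueError(f"n_components {n_components} exceeds "
                         f"min(n_samples - 1, n_categories) = {max_comp}")
    x = matrix.to_numpy(dtype=float)
    means = x.mean(axis=0)
    xc = x - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)

    # deterministic sign: largest |loading| entry positive per component
    for j in range(vt.shape[0]):
        i = int(np.abs(vt[j]).argmax())
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]

    total_var = float((s ** 2).sum())
    frac = (s[:n_components] ** 2) / total_var if total_var > 0 \
        else np.zeros(n_components)
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    scores = pd.DataFrame(u[:, :n_components] * s[:n_components],
                          index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(vt[:n_components].T, index=matrix.columns,
                            columns=comp_names)
    return PcaResult(scores, loadings, frac,
                     pd.Series(means, index=matrix.columns))


def plot_scores(result: PcaResult,
                labels: Optional[pd.Series] = None,
                path: Optional[str] = None):
    """PC1 x PC2 scatter, colour-coded by ecosystem label; saves to
    ``path`` when given, otherwise returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pcs = result.scores.iloc[:, :2]
    if labels is not None:
        for lab in sorted(labels.unique()):
            sub = pcs.loc[labels[labels == lab].index]
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(lab), s=25)
        ax.legend(fontsize=8)
    else:
        ax.scatter(pcs.iloc[:, 0], pcs.iloc[:, 1], s=25)
    ev = result.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    if len(ev) > 1:
        ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
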