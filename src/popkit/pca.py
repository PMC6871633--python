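"""Principal component analysis of population allele-frequency matrices.

PCA is run on the population × locus matrix of reference-allele frequencies,
column-centered (per-locus mean removed) and, by default, unscaled: the
covariance convention, the simplest reading of "PCA of the SNP frequencies".
A ``scale=True`` option divides each locus column by its standard deviation
(correlation PCA) for data sources that used that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .panel import PopFrequencyTable

__all__ = ["PcaResult", "pca_populations", "pca_plot_table"]


@dataclass
class PcaResult:
    """Scores (population × component), percent variance explained per
    component (non-increasing), and loadings (locus × component)."""

    scores: pd.DataFrame
    var_explained: np.ndarray
    loadings: pd.DataFrame

    @property
    def n_components(self) -> int:
        return len(self.var_explained)


def pca_populations(
    freqs: PopFrequencyTable, n_components: int = 3, scale: bool = False
) -> PcaResult:
    """Centered PCA of the reference-allele frequency matrix.

    Deterministic sign convention: each component is oriented so its
    largest-magnitude loading is positive.  Requesting more components than
    populations (or loci) raises.
    """
    X = freqs.freq.astype(float)
    n_pops, n_loci = X.shape
    if n_pops < 2 or n_loci < 2:
        raise ValueError("PCA needs at least 2 populations and 2 loci")
    max_rank = min(n_pops - 1, n_loci)
    if n_components > max_rank:
        raise ValueError(
            f"{n_components} components requested but matrix supports at most {max_rank}"
        )
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # loci x components
    # sign convention: largest-|loading| entry positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=freqs.pop_ids, columns=cols),
        var_explained=model.explained_variance_ratio_ * 100.0,
        loadings=pd.DataFrame(loadings, index=freqs.panel.locus_ids, columns=cols),
    )


def pca_plot_table(
    result: PcaResult,
    freqs: PopFrequencyTable,
    region_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Scatter-ready table: population abbreviation, geographic region label,
    and component scores.  Populations without a region label are marked
    ``unassigned``; label keys that match no population trigger a warning.
    """
    region_labels = dict(region_labels or {})
    abbrevs = [p.abbrev for p in freqs.populations]
    unknown = sorted(set(region_labels) - set(abbrevs))
    if unknown:
        warnings.warn(f"region labels for unknown populations ignored: {unknown}")
    out = pd.DataFrame(
        {
            "pop_abbrev": abbrevs,
            "region": [region_labels.get(a, "unassigned") for a in abbrevs],
        },
        index=result.scores.index,
    )
    return pd.concat([out, result.scores], axis=1)
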