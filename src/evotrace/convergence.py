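"""Phenotypic-convergence quantification: expression and metabolome analysis.

The transcriptome side follows the standard microarray post-processing
chain: quantile normalization across samples, removal of genes below the
quantification limit in any sample, log10 ratios against the parent column,
PCA of the gene-centered log matrix with per-strain time-ordered "orbits" in
the PC1/PC2 plane, and Pearson correlations of endpoint log-ratio vectors
between strain pairs.  The metabolome side adds internal-standard
relative-peak-area quantification to absolute concentrations (uM).

All logs are base 10 (configurable); PCA is computed by SVD of the
gene-centered matrix with samples as observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (DataIntegrityError, DegenerateDataError,
                     InvalidArgumentError)

DEFAULT_QUANTIFICATION_LIMIT = 100.0


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-sorted means.

    After normalization all column value multisets are identical and ranks
    within each column are preserved; tied entries receive the mean of the
    reference values their ranks span.  Idempotent.
    """
    if matrix.shape[1] < 2:
        raise InvalidArgumentError("need >= 2 columns")
    if matrix.isna().any().any():
        raise InvalidArgumentError("matrix must be complete (no NaN)")
    X = matrix.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        ranks = sps.rankdata(X[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_quantification_limit(matrix: pd.DataFrame,
                                limit: float = DEFAULT_QUANTIFICATION_LIMIT
                                ) -> pd.DataFrame:
    """Keep genes whose value exceeds the quantification limit in EVERY
    sample; values at or below the limit anywhere drop the gene."""
    keep = (matrix > limit).all(axis=1)
    return matrix[keep]


def log_ratio_vs_reference(matrix: pd.DataFrame, reference_column: str,
                           base: float = 10.0) -> pd.DataFrame:
    """Per-gene log(value / reference) for every sample column.

    The reference column maps to all-zero ratios.
    """
    if reference_column not in matrix.columns:
        raise InvalidArgumentError(f"no column {reference_column!r}")
    ref = matrix[reference_column]
    if (ref <= 0).any():
        raise DataIntegrityError("non-positive reference values")
    if (matrix <= 0).any().any():
        raise DataIntegrityError("non-positive values in matrix")
    return np.log(matrix.div(ref, axis=0)) / np.log(base)


@dataclass
class PCAResult:
    """Sample scores, gene loadings and explained-variance fractions."""

    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # genes x components
    explained_variance_ratio: np.ndarray


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA by SVD of the gene-centered matrix (samples as observations)."""
    if matrix.shape[1] < 3:
        raise InvalidArgumentError("need >= 3 samples")
    X = matrix.to_numpy(dtype=float).T          # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise DegenerateDataError("constant matrix has no principal axes")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    evr = var / var.sum()
    k = min(n_components, len(S))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * S[:k], index=matrix.columns,
                          columns=comp_names)
    loadings = pd.DataFrame(Vt[:k].T, index=matrix.index, columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=evr)


def pca_orbits(log_matrix: pd.DataFrame, metadata: pd.DataFrame,
               n_components: int = 2
               ) -> tuple[PCAResult, dict[str, pd.DataFrame]]:
    """PCA plus per-strain orbits: scores ordered by timepoint within strain.

    All strain x timepoint samples (plus the parent) are fit jointly so the
    orbits are directly comparable; each orbit is anchored at the parent
    sample's score.  ``metadata`` must index every column with ``strain``
    and ``time_h`` fields.
    """
    result = pca_scores(log_matrix, n_components)
    orbits: dict[str, pd.DataFrame] = {}
    meta = metadata.loc[log_matrix.columns]
    parent_cols = meta.index[meta["strain"] == "parent"]
    anchor = (result.scores.loc[parent_cols[0]]
              if len(parent_cols) else None)
    for strain in sorted(set(meta["strain"]) - {"parent"}):
        cols = meta[meta["strain"] == strain].sort_values("time_h")
        orbit = result.scores.loc[cols.index].copy()
        orbit.insert(0, "time_h", cols["time_h"].to_numpy())
        if anchor is not None:
            head = pd.DataFrame([[0.0, *anchor.to_numpy()]],
                                columns=orbit.columns, index=["parent"])
            if not (cols["time_h"] == 0).any():
                orbit = pd.concat([head, orbit])
        orbits[strain] = orbit
    return result, orbits


def orbit_divergence(orbits: dict[str, pd.DataFrame]) -> pd.Series:
    """Mean Euclidean distance of each strain's orbit to the consensus orbit
    (the point-wise mean over strains at matching timepoints)."""
    times = sorted(set.intersection(
        *[set(o["time_h"]) for o in orbits.values()]))
    comps = [c for c in next(iter(orbits.values())).columns if c != "time_h"]
    stacked = {
        s: o.set_index("time_h").loc[times, comps].to_numpy()
        for s, o in orbits.items()
    }
    consensus = np.mean(list(stacked.values()), axis=0)
    return pd.Series({
        s: float(np.linalg.norm(a - consensus, axis=1).mean())
        for s, a in stacked.items()
    })


def pairwise_change_correlation(logratios: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-gene log-ratio vectors between columns.

    Symmetric with unit diagonal; a zero-variance column yields NaN against
    every other column (undefined correlation) rather than an error.
    """
    if logratios.shape[1] < 2:
        raise InvalidArgumentError("need >= 2 strains")
    return logratios.corr(method="pearson")


def quantify_metabolite(sample_area: float, sample_is_area: float,
                        std_area: float, std_is_area: float,
                        std_conc: float) -> float:
    """Concentration from internal-standard relative peak areas.

    conc = [(sample_area / sample_IS_area) / (std_area / std_IS_area)]
           x std_conc.  A zero sample area reads as below detection (0 uM);
    zero internal-standard or standard areas are data errors.
    """
    if sample_is_area <= 0 or std_is_area <= 0:
        raise DataIntegrityError("internal-standard peak area must be > 0")
    if std_area <= 0 or std_conc <= 0:
        raise DataIntegrityError("standard area/concentration must be > 0")
    if sample_area < 0:
        raise InvalidArgumentError("negative peak area")
    rel_sample = sample_area / sample_is_area
    rel_std = std_area / std_is_area
    return rel_sample / rel_std * std_conc


def expression_convergence(values: pd.DataFrame, metadata: pd.DataFrame,
                           parent_column: str = "parent",
                           limit: float = DEFAULT_QUANTIFICATION_LIMIT,
                           endpoint_time: Optional[float] = None):
    """Full convergence chain on an expression matrix.

    quantile normalize -> limit filter -> log10 -> joint PCA orbits ->
    endpoint log-ratio correlation matrix.  Returns (pca_result, orbits,
    endpoint_correlations, n_kept_genes).
    """
    norm = quantile_normalize(values)
    kept = filter_quantification_limit(norm, limit)
    logm = np.log10(kept)
    result, orbits = pca_orbits(logm, metadata)
    ratios = log_ratio_vs_reference(kept, parent_column)
    meta = metadata.loc[kept.columns]
    tmax = endpoint_time if endpoint_time is not None else meta["time_h"].max()
    end_cols = meta.index[(meta["time_h"] == tmax)
                          & (meta["strain"] != "parent")]
    endpoint = ratios[list(end_cols)]
    endpoint.columns = [meta.loc[c, "strain"] for c in end_cols]
    corr = pairwise_change_correlation(endpoint)
    return result, orbits, corr, len(kept)
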