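"""FPKM computation, 2-fold differential calling, the 0/1/2 response coding
into 8 groups, and hierarchical/correlation clustering of genes and samples.

Coding convention: each differential gene gets a two-character string over
{0,1,2} — first character for the induction comparison (+Dox vs No Dox),
second for the inhibitor comparison (+Dox+JQ1 vs +Dox); '1' = up >=
threshold-fold, '0' = down, '2' = unchanged.  Genes coding "22" are by
definition not part of the 8 response groups.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "fpkm",
    "condition_means",
    "call_differential",
    "code_genes",
    "cluster_genes",
    "sample_correlation",
    "ALL_CODES",
    "RESPONSE_CODES",
]

ALL_CODES = tuple(f"{a}{b}" for a in "012" for b in "012")
RESPONSE_CODES = tuple(c for c in ALL_CODES if c != "22")  # the 8 groups

DEFAULT_COMPARISONS = (("Dox", "noDox"), ("Dox_JQ1", "Dox"))


def fpkm(counts: pd.DataFrame, gene_length_bp: pd.Series,
         library_size: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million: counts * 1e9 / (length * library).

    `counts` is genes x samples; `library_size` defaults to each sample's
    column sum."""
    lengths = gene_length_bp.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    lib = counts.sum(axis=0) if library_size is None else library_size
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    return counts * 1e9 / np.outer(lengths, lib)


def condition_means(fpkm_table: pd.DataFrame,
                    sample_condition: dict[str, str]) -> pd.DataFrame:
    """Average replicate FPKM per condition (genes x conditions)."""
    cond = pd.Series(sample_condition).reindex(fpkm_table.columns)
    if cond.isna().any():
        missing = list(fpkm_table.columns[cond.isna()])
        raise ValueError(f"samples without a condition: {missing}")
    return fpkm_table.T.groupby(cond.values).mean().T


def call_differential(cond_fpkm: pd.DataFrame, threshold: float = 2.0,
                      min_expr: float = 1.0,
                      pseudocount: float = 1.0) -> pd.Index:
    """Genes whose max pairwise condition fold (with pseudocount) reaches
    `threshold` and whose max condition FPKM reaches `min_expr`."""
    if cond_fpkm.shape[1] < 2:
        raise ValueError("need >= 2 conditions")
    vals = cond_fpkm.to_numpy(dtype=float) + pseudocount
    max_fold = np.ones(len(cond_fpkm))
    for i, j in itertools.combinations(range(vals.shape[1]), 2):
        ratio = vals[:, i] / vals[:, j]
        max_fold = np.maximum(max_fold, np.maximum(ratio, 1.0 / ratio))
    expressed = cond_fpkm.max(axis=1).to_numpy() >= min_expr
    return cond_fpkm.index[(max_fold >= threshold) & expressed]


def _code_char(fold: np.ndarray, threshold: float) -> np.ndarray:
    return np.where(fold >= threshold, "1",
                    np.where(fold <= 1.0 / threshold, "0", "2"))


def code_genes(cond_fpkm: pd.DataFrame,
               comparisons=DEFAULT_COMPARISONS,
               threshold: float = 2.0, pseudocount: float = 1.0,
               differential: pd.Index | None = None) -> pd.DataFrame:
    """Two-character 0/1/2 response codes over the two pairwise comparisons.

    Returns a DataFrame (index = gene) with fc1, fc2, code, and `grouped`
    (True for the 8 response groups; genes coding "22" are differential with
    respect to comparisons outside the coded pair and are not grouped).
    When `differential` is given, only those genes are coded."""
    if len(comparisons) != 2:
        raise ValueError("exactly two comparisons define the code")
    for a, b in comparisons:
        for cond in (a, b):
            if cond not in cond_fpkm.columns:
                raise KeyError(f"unknown condition {cond!r}")
    table = cond_fpkm if differential is None else cond_fpkm.loc[differential]
    vals = table.to_numpy(dtype=float) + pseudocount
    cols = list(table.columns)
    folds = []
    for a, b in comparisons:
        folds.append(vals[:, cols.index(a)] / vals[:, cols.index(b)])
    fc1, fc2 = folds
    code = np.char.add(_code_char(fc1, threshold), _code_char(fc2, threshold))
    df = pd.DataFrame({"fc1": fc1, "fc2": fc2, "code": code},
                      index=table.index)
    df["grouped"] = df["code"] != "22"
    return df


def _correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """1 - Pearson between rows; zero-variance rows sit at distance 1 from
    everything (their correlation is undefined)."""
    m = np.asarray(matrix, dtype=float)
    sd = m.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist[sd == 0, :] = 1.0
    dist[:, sd == 0] = 1.0
    np.fill_diagonal(dist, 0.0)
    # guard tiny negative rounding
    return np.clip(dist, 0.0, 2.0)


def cluster_genes(log_fpkm: pd.DataFrame):
    """Agglomerative clustering of genes: distance 1 - Pearson, average
    linkage; deterministic leaf order (scipy's index-based tie breaking).

    Input is expected to be log2(FPKM + 1) of the differential genes.
    Returns (ordered gene ids, linkage matrix)."""
    if len(log_fpkm) < 2:
        return list(log_fpkm.index), np.empty((0, 4))
    dist = _correlation_distance(log_fpkm.to_numpy())
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    return [log_fpkm.index[i] for i in order], Z


def sample_correlation(matrix: pd.DataFrame):
    """Pearson correlation between samples (rows = samples, columns =
    features) and the same clustering as cluster_genes.

    For ChIP samples the features are CPM on the union of all peaks; for RNA
    samples, log2(FPKM + 1) of the differential genes.
    Returns (correlation DataFrame, ordered sample ids, linkage)."""
    m = matrix.to_numpy(dtype=float)
    if np.any(m.std(axis=1) == 0):
        bad = [matrix.index[i] for i in np.flatnonzero(m.std(axis=1) == 0)]
        raise ValueError(f"zero-variance samples: {bad}")
    corr = pd.DataFrame(np.corrcoef(m), index=matrix.index,
                        columns=matrix.index)
    if len(matrix) < 2:
        return corr, list(matrix.index), np.empty((0, 4))
    dist = _correlation_distance(m)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [matrix.index[i] for i in hierarchy.leaves_list(Z)]
    return corr, order, Z
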