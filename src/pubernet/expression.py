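"""Expression-matrix handling: RPKM computation, noise filtering, log2
transform and PCA-based sample quality control.

The central container is :class:`ExpressionMatrix`, a genes x samples table
of non-negative abundances tagged with the scale it lives on (``counts``,
``rpkm`` or ``log2``).  The canonical preprocessing path for a bulk RNA-seq
count matrix is::

    rpkm   = compute_rpkm(counts, gene_lengths)
    rpkm   = filter_expressed(rpkm, groupings, threshold=0.2)
    logex  = log2_transform(rpkm, offset=1.0)
    report = pca_outliers(logex)

The 0.2-RPKM noise floor (a gene is "expressed" when its mean RPKM reaches
0.2 in at least one sample group) is a convention widely used in bovine
transcriptomics; the boundary is inclusive (>= 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

SCALES = ("counts", "rpkm", "log2")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by gene ID with sample IDs as columns.
    scale:
        One of ``counts``, ``rpkm``, ``log2``.  Counts and RPKM values
        must be non-negative; log2 values are unrestricted.
    """

    data: pd.DataFrame
    scale: str = "rpkm"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        if self.scale in ("counts", "rpkm") and (self.data.to_numpy() < 0).any():
            raise ValueError(f"{self.scale} values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class QCReport:
    """PCA-based sample QC summary.

    ``scores`` holds per-sample coordinates on the first components,
    ``variance_explained`` the corresponding variance fractions (each in
    [0, 1], non-increasing) and ``outliers`` the flagged sample IDs.
    """

    scores: pd.DataFrame
    variance_explained: np.ndarray
    outliers: list[str] = field(default_factory=list)
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if ((ve < 0) | (ve > 1)).any():
            raise ValueError("variance fractions must lie in [0, 1]")
        if (np.diff(ve) > 1e-12).any():
            raise ValueError("variance fractions must be non-increasing")
        unknown = set(self.outliers) - set(self.scores.index)
        if unknown:
            raise ValueError(f"outlier IDs not among samples: {sorted(unknown)}")


def compute_rpkm(counts: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[g, s] = count[g, s] * 1e9 / (length_bp[g] * total_reads[s])

    where total_reads is the column sum of the count matrix.
    """
    if counts.scale != "counts":
        raise ValueError(f"expected a counts matrix, got scale={counts.scale!r}")
    lengths = gene_lengths.reindex(counts.gene_ids)
    missing = lengths.index[lengths.isna()]
    if len(missing):
        raise ValueError(f"no length for gene(s): {missing.tolist()[:5]}")
    bad = lengths.index[lengths <= 0]
    if len(bad):
        raise ValueError(f"non-positive length for gene(s): {bad.tolist()[:5]}")
    totals = counts.data.sum(axis=0)
    empty = totals.index[totals <= 0]
    if len(empty):
        raise ValueError(f"sample(s) with zero total reads: {empty.tolist()[:5]}")
    rpkm = counts.data.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(rpkm, scale="rpkm")


def filter_expressed(
    rpkm: ExpressionMatrix,
    groupings: Mapping[str, str],
    threshold: float = 0.2,
) -> ExpressionMatrix:
    """Keep genes whose mean RPKM reaches ``threshold`` in >= 1 group.

    ``groupings`` maps every sample ID to a group label (e.g. tissue or
    pubertal stage).  The boundary is inclusive: a group mean of exactly
    ``threshold`` keeps the gene.  Gene order is preserved; an empty
    result is returned (not an error) when nothing passes.
    """
    if rpkm.scale != "rpkm":
        raise ValueError(f"expected an rpkm matrix, got scale={rpkm.scale!r}")
    if not groupings:
        raise ValueError("empty sample grouping")
    uncovered = set(rpkm.sample_ids) - set(groupings)
    if uncovered:
        raise ValueError(f"samples missing from grouping: {sorted(uncovered)}")
    labels = pd.Series({s: groupings[s] for s in rpkm.sample_ids})
    group_means = rpkm.data.T.groupby(labels).mean().T
    keep = (group_means >= threshold).any(axis=1)
    return ExpressionMatrix(rpkm.data.loc[keep], scale="rpkm")


def log2_transform(rpkm: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """value -> log2(value + offset); requires offset > 0 or all values > 0."""
    if rpkm.scale != "rpkm":
        raise ValueError(f"expected an rpkm matrix, got scale={rpkm.scale!r}")
    vals = rpkm.data.to_numpy()
    if offset <= 0 and (vals <= 0).any():
        raise ValueError(
            "non-positive argument to log2: need offset > 0 or strictly positive values"
        )
    out = pd.DataFrame(
        np.log2(vals + offset), index=rpkm.gene_ids, columns=rpkm.sample_ids
    )
    return ExpressionMatrix(out, scale="log2")


def pca_outliers(
    expr: ExpressionMatrix,
    n_components: int = 2,
    sd_multiplier: float = 3.0,
) -> QCReport:
    """Flag samples far from the PCA centroid.

    Samples are projected onto the first ``n_components`` principal
    components of the centered (unscaled) log2 matrix; a sample is an
    outlier when its Euclidean distance from the score centroid exceeds
    ``sd_multiplier`` population SDs of all samples' distances.  This is
    an explicit, reproducible stand-in for the by-eye cluster inspection
    normally used to drop a faulty library.
    """
    if expr.n_samples < 3:
        raise ValueError("PCA QC requires at least 3 samples")
    k = min(n_components, expr.n_samples - 1, expr.n_genes)
    # samples are observations, genes are features
    x = expr.data.to_numpy().T
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    score_df = pd.DataFrame(
        scores, index=expr.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    sd = dist.std()  # population SD
    if sd > 0:
        flagged = score_df.index[dist > sd_multiplier * sd].tolist()
    else:
        flagged = []
    return QCReport(
        scores=score_df,
        variance_explained=pca.explained_variance_ratio_,
        outliers=flagged,
        sd_multiplier=sd_multiplier,
    )
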