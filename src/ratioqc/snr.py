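"""Signal-to-noise ratio (SNR) metrics for multi-group replicated designs.

The headline metric is the PCA-weighted SNR: samples are embedded by PCA of the
unit-variance-scaled feature matrix and the ratio of average between-group to
average within-group squared distances in the variance-weighted PC space is
expressed in decibels,

    SNR = 10 * log10( (sum_between / n_between_pairs)
                      / (sum_within / n_within_pairs) )

with squared differences summed over the first ``n_pcs`` components, each
weighted by its variance-explained fraction ``W_p``.  For a balanced design of
m groups with n replicates the pair-count prefactor reduces to the familiar
``m*C(n,2) / (C(m,2)*n*n)``.

Four alternative formulations are provided for comparison: full-feature-space
Euclidean distance, per-feature median Euclidean distance, one minus Pearson
correlation, and Euclidean distance in a seeded 2-D t-SNE embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .studydata import StudyDesign, summarize_design

__all__ = [
    "SNRResult",
    "LeaveOneOutResult",
    "SNR_METHODS",
    "snr_pca",
    "snr_variant",
    "snr_leave_one_out",
]

logger = logging.getLogger(__name__)

SNR_METHODS = (
    "OriAll_EucDist",
    "OriSingle_MedianEucDist",
    "OriAll_1-Cor",
    "ReducedDim_tSNE",
    "ReducedDim_PCA",
)

#: Display cap (dB) for batches with exactly zero within-group dispersion.
INFINITE_SNR_CAP_DB = 60.0


@dataclass
class SNRResult:
    snr_db: float
    method: str
    m: int
    n_per_group: dict[str, int]
    n_pcs: int | None = None
    weights: np.ndarray | None = None  # variance-explained fractions W_p
    coordinates: pd.DataFrame | None = None  # samples x PCs, for plotting
    infinite: bool = False
    degenerate: bool = False
    n_dropped_zero_variance: int = 0


@dataclass
class LeaveOneOutResult:
    snr_all_db: float
    table: pd.DataFrame  # columns: sample, snr11_db, delta_db
    diagnosis: str  # pass | random-failure | systematic-failure
    flagged_sample: str | None
    delta_db_threshold: float
    snr_cutoff: float


def _check_design(design: StudyDesign) -> None:
    if design.m < 2:
        raise ValueError("SNR undefined: need at least 2 groups")
    for group, n in design.n_per_group().items():
        if n < 2:
            raise ValueError(
                f"noise undefined: group {group!r} has a single replicate"
            )


def _scale_features(matrix: pd.DataFrame, scale: bool) -> tuple[np.ndarray, int]:
    """Center (and optionally unit-variance scale) genes across samples.

    Zero-variance features carry no information and would divide by zero under
    scaling; they are dropped with a logged count.
    """
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance features before PCA", n_dropped)
    X = X[keep]
    X = X - X.mean(axis=1, keepdims=True)
    if scale:
        X = X / sd[keep][:, None]
    return X.T, n_dropped  # samples x features


def _pair_masks(design: StudyDesign, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Condensed-form boolean masks of within- and between-group sample pairs."""
    groups = design.group_of().loc[samples].to_numpy()
    n = len(samples)
    same = np.array(
        [groups[i] == groups[j] for i in range(n) for j in range(i + 1, n)]
    )
    return same, ~same


def snr_pca(
    matrix: pd.DataFrame,
    design: StudyDesign,
    n_pcs: int = 2,
    scale: bool = True,
) -> SNRResult:
    """PCA-weighted SNR of a gene x sample matrix (log or ratio values).

    Features are centered and, when ``scale`` is on, divided by their standard
    deviation (univariance scaling) before PCA.  ``W_p`` is the fraction of
    total variance explained by PC p; a common rescaling of all weights leaves
    the ratio unchanged.
    """
    _check_design(design)
    samples = design.samples
    matrix = matrix[samples]
    X, n_dropped = _scale_features(matrix, scale)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features with nonzero variance")

    # PCA via SVD of the feature-centered data matrix (samples x features).
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    ev = S**2 / (X.shape[0] - 1)
    total = ev.sum()
    n_pcs_eff = min(n_pcs, len(S))
    weights = ev[:n_pcs_eff] / total
    scores = U[:, :n_pcs_eff] * S[:n_pcs_eff]

    summary = summarize_design(design)
    # Weighted squared distances in PC space, condensed pair order.
    sq = pdist(scores * np.sqrt(weights), metric="sqeuclidean")
    within_mask, between_mask = _pair_masks(design, samples)
    sum_within = sq[within_mask].sum()
    sum_between = sq[between_mask].sum()

    coords = pd.DataFrame(
        scores, index=samples, columns=[f"PC{p+1}" for p in range(n_pcs_eff)]
    )
    base = dict(
        method="ReducedDim_PCA",
        m=summary.m,
        n_per_group=summary.n_per_group,
        n_pcs=n_pcs_eff,
        weights=weights,
        coordinates=coords,
        n_dropped_zero_variance=n_dropped,
    )
    if sum_within <= 1e-12 * max(sum_between, 1.0):
        return SNRResult(snr_db=INFINITE_SNR_CAP_DB, infinite=True, **base)
    ratio = (sum_between / summary.between_pairs) / (sum_within / summary.within_pairs)
    return SNRResult(snr_db=10 * np.log10(ratio), **base)


def snr_variant(
    matrix: pd.DataFrame,
    design: StudyDesign,
    method: str,
    seed: int | None = None,
    n_pcs: int = 2,
    scale: bool = True,
) -> SNRResult:
    """SNR under one of the five distance formulations.

    The non-PCA variants define signal as the mean pairwise distance between
    samples of different groups and noise as the mean within-group distance,
    with SNR = 10*log10(signal/noise).  Original-space variants use the matrix
    as given (no scaling); the t-SNE variant scales features like the PCA
    variant and requires a seed.
    """
    if method not in SNR_METHODS:
        raise ValueError(f"unknown SNR method {method!r}; choose one of {SNR_METHODS}")
    if method == "ReducedDim_PCA":
        return snr_pca(matrix, design, n_pcs=n_pcs, scale=scale)
    _check_design(design)
    samples = design.samples
    X = matrix[samples].to_numpy(dtype=float).T  # samples x features

    if method == "OriAll_EucDist":
        dist = pdist(X, metric="euclidean")
    elif method == "OriSingle_MedianEucDist":
        # per-feature |difference| summarized by the median across features
        n = len(samples)
        dist = np.array(
            [
                np.median(np.abs(X[i] - X[j]))
                for i in range(n)
                for j in range(i + 1, n)
            ]
        )
    elif method == "OriAll_1-Cor":
        dist = pdist(X, metric="correlation")  # 1 - Pearson r
    else:  # ReducedDim_tSNE
        if seed is None:
            raise ValueError("ReducedDim_tSNE requires a seed")
        from sklearn.manifold import TSNE

        Xs, _ = _scale_features(matrix[samples], scale=True)
        n = Xs.shape[0]
        perplexity = min(10.0, (n - 1) / 3)
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
        ).fit_transform(Xs)
        dist = pdist(emb, metric="euclidean")

    within_mask, between_mask = _pair_masks(design, samples)
    noise = dist[within_mask].mean()
    signal = dist[between_mask].mean()
    summary = summarize_design(design)
    base = dict(method=method, m=summary.m, n_per_group=summary.n_per_group)
    eps = 1e-12
    if signal < eps and noise < eps:
        return SNRResult(snr_db=0.0, degenerate=True, **base)
    if noise < eps:
        return SNRResult(snr_db=INFINITE_SNR_CAP_DB, infinite=True, **base)
    return SNRResult(snr_db=10 * np.log10(signal / noise), **base)


def snr_leave_one_out(
    matrix: pd.DataFrame,
    design: StudyDesign,
    delta_db: float = 6.0,
    snr_cutoff: float = 12.0,
    n_pcs: int = 2,
    scale: bool = True,
) -> LeaveOneOutResult:
    """Leave-one-out SNR diagnosis of a batch.

    Recomputes the PCA SNR with each sample excluded in turn ("SNR11" in the
    standard 12-library batch).  If excluding some sample raises the SNR by
    more than ``delta_db`` (default 6 dB) the batch's quality problem is
    attributed to that replicate (random failure); if the full-batch SNR is
    below ``snr_cutoff`` and no single exclusion helps, the failure is deemed
    systematic.
    """
    for group, n in design.n_per_group().items():
        if n < 3:
            raise ValueError(
                f"leave-one-out needs >= 3 replicates per group; "
                f"group {group!r} has {n}"
            )
    full = snr_pca(matrix, design, n_pcs=n_pcs, scale=scale)
    rows = []
    for sample in design.samples:
        keep = [s for s in design.samples if s != sample]
        sub_design = design.subset(keep)
        res = snr_pca(matrix[keep], sub_design, n_pcs=n_pcs, scale=scale)
        rows.append(
            {"sample": sample, "snr11_db": res.snr_db, "delta_db": res.snr_db - full.snr_db}
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["delta_db"].idxmax()]
    if best["delta_db"] > delta_db:
        diagnosis, flagged = "random-failure", str(best["sample"])
    elif full.snr_db < snr_cutoff:
        diagnosis, flagged = "systematic-failure", None
    else:
        diagnosis, flagged = "pass", None
    return LeaveOneOutResult(
        snr_all_db=full.snr_db,
        table=table,
        diagnosis=diagnosis,
        flagged_sample=flagged,
        delta_db_threshold=delta_db,
        snr_cutoff=snr_cutoff,
    )
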