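"""Log transformation, detectability filtering and ratio-based profiling.

Ratio-based ("relative-scale") expression subtracts, per gene and per batch,
the mean log2 abundance of designated denominator replicates from every
sample's log2 abundance.  Under a gene-wise additive batch shift in log space
this cancels the shift exactly, which is the property that makes multi-batch
integration at the ratio level possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .studydata import ExpressionStudy, StudyDesign

__all__ = [
    "log_transform",
    "DetectabilityMask",
    "detectability_mask",
    "consensus_detectable",
    "RatioMatrix",
    "ratio_transform",
]

logger = logging.getLogger(__name__)

#: Offset added to abundances before log2 so zeros stay finite.
DEFAULT_LOG_OFFSET = 0.01


def log_transform(study: ExpressionStudy | pd.DataFrame, offset: float = DEFAULT_LOG_OFFSET) -> pd.DataFrame:
    """log2(value + offset) for every cell of the abundance matrix.

    A small positive ``offset`` (default 0.01) keeps zero abundances finite;
    a zero FPKM maps to log2(0.01) ~ -6.64.
    """
    if offset <= 0:
        raise ValueError(f"offset must be positive, got {offset}")
    values = study.values if isinstance(study, ExpressionStudy) else study
    out = np.log2(values + offset)
    out.attrs["log_offset"] = offset
    return out


@dataclass
class DetectabilityMask:
    """Boolean gene x (group, batch) detectability calls.

    A gene is detectable in a (group, batch) cell when at least
    ``min_replicates`` replicates have ``>= min_reads`` mapped reads.
    """

    mask: pd.DataFrame  # genes x MultiIndex[(group, batch)]
    min_reads: int
    min_replicates: int

    def detected(self, group: str, batch: str) -> pd.Series:
        return self.mask[(group, batch)]


def detectability_mask(
    study: ExpressionStudy,
    min_reads: int = 3,
    min_replicates: int = 2,
) -> DetectabilityMask:
    """Call genes detectable per (group, batch) from the raw-count layer."""
    if study.counts is None:
        raise ValueError(
            "detectability requires a counts layer; supply counts or use a "
            "values-threshold fallback"
        )
    design = study.design
    cols = {}
    for batch in design.batches:
        for group in design.groups:
            samples = design.samples_in(group=group, batch=batch)
            if not samples:
                continue
            if len(samples) < min_replicates:
                raise ValueError(
                    f"group {group!r} in batch {batch!r} has {len(samples)} replicates; "
                    f"detectability needs >= {min_replicates}"
                )
            hits = (study.counts[samples] >= min_reads).sum(axis=1)
            cols[(group, batch)] = hits >= min_replicates
    mask = pd.DataFrame(cols)
    mask.columns = pd.MultiIndex.from_tuples(mask.columns, names=["group", "batch"])
    return DetectabilityMask(mask=mask, min_reads=min_reads, min_replicates=min_replicates)


def consensus_detectable(
    masks: Sequence[DetectabilityMask],
    group: str,
    require_all: bool = True,
    min_batches: int | None = None,
) -> pd.Index:
    """Genes detectable in ``group`` across batches, by consensus.

    With ``require_all`` (the default) a gene must be detected in the group in
    every batch that carries the group; otherwise ``min_batches`` batches
    suffice.
    """
    if not masks:
        raise ValueError("empty batch list")
    per_batch: list[pd.Series] = []
    for m in masks:
        cols = [c for c in m.mask.columns if c[0] == group]
        if not cols:
            logger.warning("group %r absent from a batch mask; batch skipped", group)
            continue
        for c in cols:
            per_batch.append(m.mask[c])
    if not per_batch:
        raise ValueError(f"group {group!r} absent from every batch")
    stacked = pd.concat(per_batch, axis=1).fillna(False)
    hits = stacked.sum(axis=1)
    if require_all:
        keep = hits == stacked.shape[1]
    else:
        if min_batches is None:
            raise ValueError("min_batches required when require_all is off")
        keep = hits >= min_batches
    return stacked.index[keep]


@dataclass
class RatioMatrix:
    """Gene x sample log2 ratios relative to in-batch denominator replicates."""

    ratios: pd.DataFrame
    design: StudyDesign
    denominator_group: str
    denominator_samples: Mapping[str, list[str]]  # batch -> samples used
    log_offset: float | None = None

    @property
    def genes(self) -> list[str]:
        return self.ratios.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.ratios.columns.tolist()


def ratio_transform(
    log_matrix: pd.DataFrame,
    design: StudyDesign,
    denominator: str,
    replicate_subset: Sequence[int] | None = None,
) -> RatioMatrix:
    """Convert log2 profiles to relative-scale profiles within each batch.

    For each batch and gene, the mean log2 value of the denominator group's
    replicates (optionally a subset, selected by replicate index) is subtracted
    from every sample in that batch.  Denominator samples are transformed too,
    so their per-gene group mean maps to 0.
    """
    ratios = pd.DataFrame(
        np.empty(log_matrix.shape), index=log_matrix.index, columns=log_matrix.columns
    )
    denom_used: dict[str, list[str]] = {}
    for batch in design.batches:
        denom_rows = design.table[
            (design.table["batch"] == batch) & (design.table["group"] == denominator)
        ]
        if replicate_subset is not None:
            denom_rows = denom_rows[denom_rows["replicate"].isin(list(replicate_subset))]
        denom_samples = denom_rows["sample"].tolist()
        if not denom_samples:
            raise ValueError(
                f"denominator group {denominator!r} "
                f"(replicates {list(replicate_subset) if replicate_subset else 'all'}) "
                f"missing in batch {batch!r}"
            )
        if len(denom_samples) == 1:
            logger.info(
                "batch %r uses a single-replicate denominator (%s); "
                "ratio profiles will be less stable",
                batch,
                denom_samples[0],
            )
        denom_used[batch] = denom_samples
        batch_samples = design.samples_in(batch=batch)
        denom_mean = log_matrix[denom_samples].mean(axis=1)
        ratios[batch_samples] = log_matrix[batch_samples].sub(denom_mean, axis=0)
    return RatioMatrix(
        ratios=ratios,
        design=design,
        denominator_group=denominator,
        denominator_samples=denom_used,
        log_offset=log_matrix.attrs.get("log_offset"),
    )
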