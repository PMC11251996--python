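"""Two-group differential expression calling and cross-batch consensus voting.

A gene is called differentially expressed between two groups in a batch when
the two-sided t-test P value is below ``p_threshold`` (default 0.05) and the
fold change is at least ``fc_threshold`` (default 2, i.e. |log2FC| >= 1), with
the call direction given by the sign of the log2 fold change.  Consensus
voting across batches labels a gene a reference DEG when it is concordantly
called in more than ``min_batches`` batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .studydata import StudyDesign

__all__ = ["DEGTable", "ConfusionCounts", "call_degs", "consensus_degs"]

DEG_TESTS = ("student", "welch", "moderated")


@dataclass
class DEGTable:
    """Per-gene differential-expression calls for one ordered group pair."""

    table: pd.DataFrame  # index gene; columns log2fc, p_value, call, degenerate
    group_a: str
    group_b: str
    test: str
    p_threshold: float
    fc_threshold: float

    @property
    def pair(self) -> str:
        return f"{self.group_a}/{self.group_b}"

    def calls(self) -> pd.Series:
        return self.table["call"]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts of test calls against reference labels."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _moderated_t(
    diff: np.ndarray, s2: np.ndarray, df: int, n1: int, n2: int, prior_df: float
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes t with a pooled prior variance.

    The prior variance is the mean of the per-gene pooled variances and the
    posterior variance is the prior-df-weighted blend, a deliberately simple
    shrinkage in the spirit of moderated-t pipelines.
    """
    s2_prior = float(np.mean(s2))
    s2_post = (prior_df * s2_prior + df * s2) / (prior_df + df)
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2 * stats.t.sf(np.abs(t), df + prior_df)
    return t, p


def call_degs(
    log_matrix: pd.DataFrame,
    design: StudyDesign,
    group_a: str,
    group_b: str,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    test: str = "student",
    prior_df: float = 4.0,
    bh_correct: bool = False,
) -> DEGTable:
    """Call up/down/non-DE per gene between two groups on log2 values.

    The log2 fold change is mean(group_a) - mean(group_b).  ``test`` selects
    the pooled-variance Student t (default), Welch t, or a simple moderated t.
    Genes with zero variance in both groups cannot be tested and are reported
    with P = 1 and a degenerate flag.  ``bh_correct`` optionally applies a
    Benjamini-Hochberg adjustment before thresholding (off by default,
    matching the raw-P gate).
    """
    if test not in DEG_TESTS:
        raise ValueError(f"unknown test {test!r}; choose one of {DEG_TESTS}")
    a_samples = design.samples_in(group=group_a)
    b_samples = design.samples_in(group=group_b)
    for label, ss in ((group_a, a_samples), (group_b, b_samples)):
        if len(ss) < 2:
            raise ValueError(f"group {label!r} has {len(ss)} replicates; need >= 2")

    A = log_matrix[a_samples].to_numpy(dtype=float)
    B = log_matrix[b_samples].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    diff = mean_a - mean_b

    if test == "welch":
        se2 = var_a / n1 + var_b / n2
        degenerate = se2 == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(se2)
            df = se2**2 / (
                (var_a / n1) ** 2 / (n1 - 1) + (var_b / n2) ** 2 / (n2 - 1)
            )
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * var_a + (n2 - 1) * var_b) / df
        degenerate = s2 == 0
        if test == "student":
            se = np.sqrt(s2 * (1 / n1 + 1 / n2))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / se
            p = 2 * stats.t.sf(np.abs(t), df)
        else:  # moderated
            t, p = _moderated_t(diff, s2, df, n1, n2, prior_df)
            degenerate = np.zeros_like(degenerate)  # shrinkage rescues zero variance

    p = np.where(degenerate, 1.0, p)
    t = np.where(degenerate, np.nan, t)

    p_eff = p.copy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p_eff = multipletests(p, method="fdr_bh")[1]

    lfc_gate = np.log2(fc_threshold)
    call = np.full(len(diff), "non-DE", dtype=object)
    call[(p_eff < p_threshold) & (diff >= lfc_gate)] = "up"
    call[(p_eff < p_threshold) & (diff <= -lfc_gate)] = "down"

    table = pd.DataFrame(
        {
            "log2fc": diff,
            "t_stat": t,
            "p_value": p,
            "call": call,
            "degenerate": degenerate.astype(bool),
        },
        index=log_matrix.index,
    )
    return DEGTable(
        table=table,
        group_a=group_a,
        group_b=group_b,
        test=test,
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
    )


def consensus_degs(
    per_batch_tables: list[DEGTable],
    min_batches: int = 6,
) -> pd.DataFrame:
    """Vote per-batch DEG calls into consensus labels for one group pair.

    Returns a frame indexed by gene with columns ``n_up``, ``n_down`` and
    ``label``.  A gene is labeled ``up`` (``down``) when the matching vote
    count strictly exceeds ``min_batches``; genes exceeding the threshold in
    both directions are discordant and labeled ``excluded``; everything else
    is a ``non-DEG`` candidate.
    """
    if not per_batch_tables:
        raise ValueError("empty table list")
    pair = per_batch_tables[0].pair
    for t in per_batch_tables:
        if t.pair != pair:
            raise ValueError(
                f"tables cover different pairs: {pair!r} vs {t.pair!r}"
            )
    calls = pd.concat([t.calls() for t in per_batch_tables], axis=1)
    n_up = (calls == "up").sum(axis=1)
    n_down = (calls == "down").sum(axis=1)
    label = pd.Series("non-DEG", index=calls.index, dtype=object)
    label[n_up > min_batches] = "up"
    label[n_down > min_batches] = "down"
    discordant = (n_up > min_batches) & (n_down > min_batches)
    label[discordant] = "excluded"
    return pd.DataFrame({"n_up": n_up, "n_down": n_down, "label": label})
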