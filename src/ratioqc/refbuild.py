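"""Ratio-based reference-dataset construction with an uncertainty budget.

The workflow mirrors how certified reference values are assigned to a
multi-batch expression resource:

1. keep genes consensus-detectable in both groups of a pair across all
   high-quality batches;
2. summarize per-batch log2 ratios into a reference log2 fold change (the
   arithmetic mean of per-batch log2 ratios, i.e. the log of the geometric
   mean ratio), gated on batch-level differential-expression evidence and,
   when protocol labels exist, on protocol concordance;
3. assess material homogeneity (one-way unbalanced ANOVA of a replicated unit
   against single-measurement units) and long-term stability (per-gene slope
   test over storage time);
4. combine characterization, between-bottle and instability uncertainties into
   a combined uncertainty u_c = sqrt(u_char^2 + u_bb^2 + u_s^2) and an
   expanded uncertainty U = k * u_c (k = 2, ~95% confidence);
5. label high-confidence reference DEGs by cross-batch consensus voting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .degs import DEGTable, call_degs, consensus_degs
from .studydata import ExpressionStudy, REFERENCE_COLUMNS, ReferenceDataset
from .transform import consensus_detectable, detectability_mask, log_transform

__all__ = [
    "RefBuildResult",
    "build_reference_ratios",
    "homogeneity_test",
    "stability_test",
    "u_char_relative",
    "u_bb_absolute",
    "combine_uncertainty",
    "uncertainty_bundle",
    "apply_uncertainty",
]

logger = logging.getLogger(__name__)


@dataclass
class RefBuildResult:
    """Reference dataset plus the per-batch ratio samples behind each value."""

    reference: ReferenceDataset
    #: pair -> genes x batches frame of per-batch log2 ratios (characterization sample)
    characterization: dict[str, pd.DataFrame]
    #: pair -> per-batch DEG tables used in voting
    deg_tables: dict[str, list[DEGTable]]


def _pair_key(pair: tuple[str, str]) -> str:
    return f"{pair[0]}/{pair[1]}"


def _batch_protocol(study: ExpressionStudy) -> str | None:
    if "protocol" not in study.design.table.columns:
        return None
    protocols = study.design.table["protocol"].dropna().unique()
    return str(protocols[0]) if len(protocols) == 1 else None


def build_reference_ratios(
    batches: list[ExpressionStudy],
    pairs: list[tuple[str, str]],
    denominator: str,
    p_in_batches: int = 4,
    protocol_gate: bool = True,
    deg_min_batches: int = 6,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    detect_gate: bool = True,
    min_reads: int = 3,
    min_replicates: int = 2,
    log_offset: float = 0.01,
    test: str = "student",
) -> RefBuildResult:
    """Build per (gene, pair) reference log2 fold changes with vote counts.

    Per batch and pair, the log2 ratio of a gene is the mean log2 value of the
    numerator group minus that of the denominator-of-the-pair group (the
    common-denominator offset cancels in the difference).  A gene enters the
    reference for a pair when it is (a) consensus-detectable in both groups in
    every batch, (b) significant (two-sided P < ``p_threshold``) in at least
    ``p_in_batches`` batches, and (c) — when protocol labels exist and the
    gate is on — not significantly different between protocols (P > 0.05 or
    fold change strictly between 1/fc and fc).

    Uncertainty columns are NaN here; fill them with
    :func:`uncertainty_bundle` + :func:`apply_uncertainty`.
    """
    if len(batches) < 2:
        raise ValueError("need at least 2 batches to build a reference")
    for study in batches:
        for a, b in pairs:
            for g in (a, b):
                if g not in study.design.groups:
                    raise ValueError(
                        f"group {g!r} of pair {a}/{b} absent from batch "
                        f"{study.design.batches}"
                    )

    logs = [log_transform(s, offset=log_offset) for s in batches]
    masks = None
    if detect_gate:
        if any(s.counts is None for s in batches):
            raise ValueError(
                "detectability gate requires a counts layer in every batch; "
                "pass detect_gate=False to skip it"
            )
        masks = [
            detectability_mask(s, min_reads=min_reads, min_replicates=min_replicates)
            for s in batches
        ]
    protocols = [_batch_protocol(s) for s in batches]

    records: list[dict] = []
    characterization: dict[str, pd.DataFrame] = {}
    deg_tables_all: dict[str, list[DEGTable]] = {}
    for a, b in pairs:
        key = _pair_key((a, b))
        # (a) consensus detectability in both groups across all batches
        if masks is not None:
            det_a = consensus_detectable(masks, a, require_all=True)
            det_b = consensus_detectable(masks, b, require_all=True)
            genes = det_a.intersection(det_b)
        else:
            genes = logs[0].index
            for lm in logs[1:]:
                genes = genes.intersection(lm.index)
        genes = pd.Index(sorted(genes))
        if not len(genes):
            logger.warning("no detectable genes for pair %s", key)

        # per-batch log2 ratios and DEG tables
        ratio_cols = {}
        tables: list[DEGTable] = []
        for study, lm in zip(batches, logs):
            batch_label = study.design.batches[0]
            table = call_degs(
                lm.loc[genes],
                study.design,
                a,
                b,
                p_threshold=p_threshold,
                fc_threshold=fc_threshold,
                test=test,
            )
            tables.append(table)
            ratio_cols[batch_label] = table.table["log2fc"]
        char = pd.DataFrame(ratio_cols)
        deg_tables_all[key] = tables

        # (b) significance in >= p_in_batches batches
        p_hits = pd.concat(
            [t.table["p_value"] < p_threshold for t in tables], axis=1
        ).sum(axis=1)
        keep = p_hits >= p_in_batches

        # (c) protocol concordance gate
        if protocol_gate and len(set(p for p in protocols if p is not None)) >= 2:
            keep &= _protocol_concordant(char, protocols, fc_threshold)

        kept_genes = genes[keep.loc[genes]]
        char = char.loc[kept_genes]
        characterization[key] = char

        votes = consensus_degs(tables, min_batches=deg_min_batches).loc[kept_genes]
        label = votes["label"].replace({"excluded": "unassessed"})
        n_disc = int((votes["label"] == "excluded").sum())
        if n_disc:
            logger.info("pair %s: %d discordant genes left unassessed", key, n_disc)

        for gene in kept_genes:
            records.append(
                {
                    "gene": gene,
                    "pair": key,
                    "log2fc_ref": float(char.loc[gene].mean()),
                    "n_batches": int(char.loc[gene].notna().sum()),
                    "n_up": int(votes.at[gene, "n_up"]),
                    "n_down": int(votes.at[gene, "n_down"]),
                    "u_char": np.nan,
                    "u_bb": np.nan,
                    "u_s": np.nan,
                    "u_c": np.nan,
                    "k": 2.0,
                    "U": np.nan,
                    "deg_label": label.loc[gene],
                }
            )
    if not records:
        logger.warning("no genes passed the reference gates; reference is empty")
        frame = pd.DataFrame(columns=list(REFERENCE_COLUMNS))
    else:
        frame = pd.DataFrame(records)
    return RefBuildResult(
        reference=ReferenceDataset(frame),
        characterization=characterization,
        deg_tables=deg_tables_all,
    )


def _protocol_concordant(
    char: pd.DataFrame, protocols: list[str | None], fc_threshold: float
) -> pd.Series:
    """Keep genes whose per-batch ratios agree across library protocols.

    A gene is removed when the two protocol groups differ with two-sided
    P < 0.05 AND |mean difference| >= log2(fc_threshold); i.e. it is kept when
    P > 0.05 OR the fold change stays strictly inside (1/fc, fc).
    """
    labels = pd.Series(protocols, index=char.columns)
    uniq = [p for p in labels.dropna().unique()]
    if len(uniq) != 2:
        logger.warning("protocol gate needs exactly 2 protocols, found %s; skipped", uniq)
        return pd.Series(True, index=char.index)
    ga = char.loc[:, labels == uniq[0]].to_numpy(dtype=float)
    gb = char.loc[:, labels == uniq[1]].to_numpy(dtype=float)
    if ga.shape[1] < 2 or gb.shape[1] < 2:
        logger.warning("protocol gate needs >= 2 batches per protocol; skipped")
        return pd.Series(True, index=char.index)
    t, p = stats.ttest_ind(ga, gb, axis=1)
    diff = ga.mean(axis=1) - gb.mean(axis=1)
    lfc = np.log2(fc_threshold)
    removed = (p < 0.05) & (np.abs(diff) >= lfc)
    return pd.Series(~removed, index=char.index)


# ---------------------------------------------------------------------------
# Homogeneity
# ---------------------------------------------------------------------------

def homogeneity_test(
    matrix: pd.DataFrame,
    units: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene between-unit homogeneity ANOVA on an unbalanced design.

    The design has exactly one replicated unit (within-unit arm, giving the
    within-unit variance s2^2 with r-1 df) and several units measured once
    each (between-unit arm).  The between-arm variance v_b is the sample
    variance of the single measurements; F = v_b / s2^2 is referred to an
    F(u-1, r-1) distribution two-sidedly, P values are BH-adjusted across
    genes, and a gene passes when the adjusted P exceeds ``alpha``.  The
    between-unit variance component is s1^2 = max(v_b - s2^2, 0).

    Parameters
    ----------
    matrix:
        Gene x sample values (typically ratio-based log2 profiles).
    units:
        Unit label per sample (index = sample ids).
    """
    units = units.loc[matrix.columns]
    counts = units.value_counts()
    replicated = counts[counts >= 2].index.tolist()
    singles = counts[counts == 1].index.tolist()
    if len(replicated) != 1:
        raise ValueError(
            f"homogeneity design needs exactly one replicated unit, found {replicated}"
        )
    if len(singles) < 2:
        raise ValueError("homogeneity design needs >= 2 single-measurement units")

    within_samples = units.index[units == replicated[0]]
    single_samples = units.index[units.isin(singles)]
    W = matrix[within_samples].to_numpy(dtype=float)
    S = matrix[single_samples].to_numpy(dtype=float)
    r, u = W.shape[1], S.shape[1]

    s2_sq = W.var(axis=1, ddof=1)
    v_b = S.var(axis=1, ddof=1)
    degenerate = s2_sq == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = v_b / s2_sq
    df1, df2 = u - 1, r - 1
    p_raw = np.where(
        degenerate,
        np.nan,
        np.minimum(
            1.0,
            2
            * np.minimum(
                stats.f.sf(f_stat, df1, df2), stats.f.cdf(f_stat, df1, df2)
            ),
        ),
    )
    p_adj = np.full_like(p_raw, np.nan)
    ok = ~degenerate
    if ok.any():
        p_adj[ok] = multipletests(p_raw[ok], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "s1_sq": np.maximum(v_b - s2_sq, 0.0),
            "s2_sq": s2_sq,
            "v_between": v_b,
            "df_s2": df2,
            "f_stat": f_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "degenerate": degenerate,
        },
        index=matrix.index,
    )
    out["passed"] = ok & (out["p_adj"] > alpha)
    return out


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

def stability_test(
    matrix: pd.DataFrame,
    timepoints: pd.Series,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-gene long-term stability via the slope of value vs. storage time.

    Ordinary least squares of each gene's series on the timepoints (months);
    a gene is stable when |b1| < s(b1) * t_crit where t_crit is the two-sided
    critical value at ``confidence`` with n-2 df.  s(b1) also feeds the
    instability uncertainty u_s = t_horizon * s(b1).
    """
    x = timepoints.loc[matrix.columns].to_numpy(dtype=float)
    n = len(x)
    if len(np.unique(x)) < 3:
        raise ValueError("stability regression needs >= 3 distinct timepoints")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero variance in timepoints")
    Y = matrix.to_numpy(dtype=float)
    xc = x - x.mean()
    b1 = (Y * xc).sum(axis=1) / sxx
    b0 = Y.mean(axis=1) - b1 * x.mean()
    resid = Y - (b0[:, None] + b1[:, None] * x[None, :])
    sse = (resid**2).sum(axis=1)
    se_b1 = np.sqrt(sse / ((n - 2) * sxx))
    t_crit = stats.t.ppf(0.5 + confidence / 2, n - 2)
    # a perfectly constant series (b1 = 0, s(b1) = 0) is stable by definition;
    # an exact deterministic drift (s(b1) = 0, b1 != 0) fails
    passed = np.where(se_b1 == 0, b1 == 0, np.abs(b1) < se_b1 * t_crit)
    return pd.DataFrame(
        {
            "slope": b1,
            "intercept": b0,
            "se_slope": se_b1,
            "t_crit": t_crit,
            "passed": passed,
        },
        index=matrix.index,
    )


# ---------------------------------------------------------------------------
# Uncertainty budget
# ---------------------------------------------------------------------------

def u_char_relative(x: np.ndarray) -> float:
    """Relative characterization uncertainty: SEM of the per-batch ratios / |mean|."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError("characterization needs >= 2 measurements")
    xbar = x.mean()
    sem = math.sqrt(((x - xbar) ** 2).sum() / ((n - 1) * n))
    return sem / abs(xbar)


def u_bb_absolute(s1_sq: float, s2_sq: float, df_s2: float, n_bb: int) -> tuple[float, str]:
    """Between-bottle uncertainty on the measurement scale.

    When the between-unit component exceeds the within-unit variance
    (s1^2 > s2^2) the inhomogeneity is directly quantifiable as
    sqrt((s1^2 - s2^2) / n); otherwise the detection limit of the design,
    sqrt(s2^2 / n) * (2 / df)^(1/4), is used.  Ties resolve to the
    detection-limit branch.  Returns (value, branch).
    """
    if n_bb < 2:
        raise ValueError("n_bb must be >= 2")
    if s1_sq > s2_sq:
        return math.sqrt((s1_sq - s2_sq) / n_bb), "excess"
    return math.sqrt(s2_sq / n_bb) * (2.0 / df_s2) ** 0.25, "detection-limit"


def combine_uncertainty(
    u_char: float, u_bb: float, u_s: float, k: float = 2.0
) -> tuple[float, float]:
    """Combined and expanded uncertainty: u_c = sqrt(sum of squares), U = k*u_c."""
    u_c = math.sqrt(u_char**2 + u_bb**2 + u_s**2)
    return u_c, k * u_c


def uncertainty_bundle(
    char: pd.DataFrame,
    hom: pd.DataFrame | None = None,
    stab: pd.DataFrame | None = None,
    t_horizon: float | None = None,
    k: float = 2.0,
    n_bb: int | None = None,
    relative: bool = True,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Per-gene uncertainty budget for one group pair.

    Parameters
    ----------
    char:
        Genes x batches frame of per-batch log2 ratios (the characterization
        sample); the reference value is its row mean.
    hom, stab:
        Outputs of :func:`homogeneity_test` / :func:`stability_test` aligned
        on gene; omit either to drop that term (treated as 0).
    t_horizon:
        Shelf-life horizon in months multiplying the slope standard error;
        defaults to the maximum observed timepoint recorded in ``stab.attrs``
        if present, else required when ``stab`` is given.
    n_bb:
        Number of between-unit measurements (required with ``hom``).
    relative:
        Normalize u_bb and u_s by |reference value| before combination so all
        three terms share the relative scale of u_char (default); with
        ``relative=False`` all three terms stay on the measurement scale.
    epsilon:
        Records with |reference value| <= epsilon cannot carry a relative
        uncertainty and are flagged unquantifiable (NaN fields).
    """
    if hom is not None and n_bb is None:
        raise ValueError("n_bb (number of between-unit measurements) required with hom")
    if stab is not None and t_horizon is None:
        raise ValueError("t_horizon (months) required with stab")
    rows = []
    for gene in char.index:
        x = char.loc[gene].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if len(x) < 2:
            raise ValueError(f"gene {gene!r}: characterization needs >= 2 batches")
        xbar = x.mean()
        if abs(xbar) <= epsilon:
            rows.append(
                dict(gene=gene, u_char=np.nan, u_bb=np.nan, u_s=np.nan,
                     u_c=np.nan, U=np.nan, k=k, branch=None, unquantifiable=True)
            )
            continue
        uc_rel = u_char_relative(x)
        u_char_term = uc_rel if relative else uc_rel * abs(xbar)

        branch = None
        u_bb_term = 0.0
        if hom is not None and gene in hom.index and not bool(hom.at[gene, "degenerate"]):
            u_bb_abs, branch = u_bb_absolute(
                float(hom.at[gene, "s1_sq"]),
                float(hom.at[gene, "s2_sq"]),
                float(hom.at[gene, "df_s2"]),
                n_bb,
            )
            u_bb_term = u_bb_abs / abs(xbar) if relative else u_bb_abs

        u_s_term = 0.0
        if stab is not None and gene in stab.index:
            u_s_abs = t_horizon * float(stab.at[gene, "se_slope"])
            u_s_term = u_s_abs / abs(xbar) if relative else u_s_abs

        u_c, U = combine_uncertainty(u_char_term, u_bb_term, u_s_term, k=k)
        rows.append(
            dict(gene=gene, u_char=u_char_term, u_bb=u_bb_term, u_s=u_s_term,
                 u_c=u_c, U=U, k=k, branch=branch, unquantifiable=False)
        )
    return pd.DataFrame(rows).set_index("gene")


def apply_uncertainty(
    result: RefBuildResult, bundles: dict[str, pd.DataFrame]
) -> ReferenceDataset:
    """Write per-pair uncertainty bundles into the reference records."""
    records = result.reference.records.copy()
    for pair, bundle in bundles.items():
        mask = records["pair"] == pair
        genes = records.loc[mask, "gene"]
        for col in ("u_char", "u_bb", "u_s", "u_c", "k", "U"):
            records.loc[mask, col] = bundle[col].reindex(genes).to_numpy()
    return ReferenceDataset(records)
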