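"""Reference-dependent concordance metrics, cutoffs and QC report assembly.

Given a ratio-based reference dataset, a test batch is scored by:

* RC — Pearson correlation between the test dataset's per-gene log2 ratios for
  a group pair and the reference fold changes;
* RMSE — root mean square difference of the same two vectors;
* MCC — Matthews correlation coefficient of the test DEG calls against
  reference DEG / non-DEG labels;
* total score — geometric mean of the (clipped) SNR and RC.

Cutoffs follow the mean +/- sample-s.d. convention over a corpus of batches
(lower bounds for SNR/RC/MCC, upper bound for RMSE).  The cutoffs published
for the original 21-batch multi-laboratory corpus (SNR 12, RC 0.89, RMSE 0.38,
MCC 0.54) ship as documented defaults.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .degs import ConfusionCounts, DEGTable, call_degs
from .refbuild import RefBuildResult, build_reference_ratios
from .snr import LeaveOneOutResult, SNRResult, snr_leave_one_out, snr_pca
from .studydata import ExpressionStudy, ReferenceDataset, StudyDesign
from .transform import log_transform, ratio_transform

__all__ = [
    "DEFAULT_CUTOFFS",
    "MCCResult",
    "QCReport",
    "CrossValidationResult",
    "pair_ratios",
    "relative_correlation",
    "rmse_vs_reference",
    "mcc_vs_reference",
    "total_score",
    "reference_overhead",
    "derive_cutoffs",
    "cross_validate_reference",
    "evaluate_subset_designs",
    "qc_report",
]

logger = logging.getLogger(__name__)

#: Published defaults derived from the original 21-batch corpus (documented
#: defaults, not recomputed here).
DEFAULT_CUTOFFS: dict[str, float] = {"snr": 12.0, "rc": 0.89, "rmse": 0.38, "mcc": 0.54}

EVALUABLE_LABELS = ("up", "down", "non-DEG")


def pair_ratios(
    log_matrix: pd.DataFrame, design: StudyDesign, group_a: str, group_b: str
) -> pd.Series:
    """Per-gene log2 fold change between group means (replicate means first)."""
    a = design.samples_in(group=group_a)
    b = design.samples_in(group=group_b)
    if not a or not b:
        raise ValueError(f"groups {group_a!r}/{group_b!r} not both present")
    return log_matrix[a].mean(axis=1) - log_matrix[b].mean(axis=1)


def _aligned(test_ratios: pd.Series, ref: ReferenceDataset, pair: str) -> pd.DataFrame:
    ref_vals = ref.for_pair(pair)["log2fc_ref"]
    common = test_ratios.index.intersection(ref_vals.index)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} genes shared between test and reference for {pair!r}; "
            "need >= 3"
        )
    return pd.DataFrame({"test": test_ratios.loc[common], "ref": ref_vals.loc[common]})

def relative_correlation(
    test_ratios: pd.Series, ref: ReferenceDataset, pair: str
) -> tuple[float, int]:
    """RC: Pearson correlation of test vs reference log2 ratios over shared genes."""
    frame = _aligned(test_ratios, ref, pair)
    if frame["test"].std(ddof=0) == 0 or frame["ref"].std(ddof=0) == 0:
        raise ValueError("degenerate: zero variance in test or reference ratios")
    r, _ = stats.pearsonr(frame["test"], frame["ref"])
    return float(r), len(frame)


def rmse_vs_reference(
    test_ratios: pd.Series, ref: ReferenceDataset, pair: str
) -> tuple[float, int]:
    """Root mean square difference of test vs reference log2 ratios."""
    frame = _aligned(test_ratios, ref, pair)
    diff = frame["test"] - frame["ref"]
    return float(np.sqrt((diff**2).mean())), len(frame)


@dataclass(frozen=True)
class MCCResult:
    mcc: float
    counts: ConfusionCounts
    degenerate: bool = False


def _mcc_from_counts(c: ConfusionCounts) -> tuple[float, bool]:
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0, True
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom), False


def mcc_vs_reference(
    test_degs: DEGTable,
    ref: ReferenceDataset,
    pair: str | None = None,
    direction_aware: bool = True,
) -> MCCResult:
    """MCC of test DEG calls against reference DEG / non-DEG labels.

    Evaluation is restricted to reference genes labeled up, down or non-DEG
    (unassessed genes are ignored).  With ``direction_aware`` (default) a test
    call on a reference DEG counts as a true positive only with the matching
    sign; a direction mismatch counts as a false positive and a false negative
    simultaneously.  MCC is defined as 0 (flagged degenerate) when any
    marginal of the confusion table is empty.
    """
    pair = pair or test_degs.pair
    labels = ref.deg_labels(pair)
    labels = labels[labels.isin(EVALUABLE_LABELS)]
    if not (labels == "non-DEG").any():
        raise ValueError(f"reference has no non-DEG genes for pair {pair!r}")
    calls = test_degs.calls()
    common = labels.index.intersection(calls.index)
    labels, calls = labels.loc[common], calls.loc[common]

    tp = tn = fp = fn = 0
    for lab, call in zip(labels, calls):
        if lab == "non-DEG":
            if call == "non-DE":
                tn += 1
            else:
                fp += 1
        else:  # reference DEG
            if call == "non-DE":
                fn += 1
            elif call == lab or not direction_aware:
                tp += 1
            else:  # direction mismatch
                fp += 1
                fn += 1
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    mcc, degenerate = _mcc_from_counts(counts)
    return MCCResult(mcc=mcc, counts=counts, degenerate=degenerate)


def reference_overhead(n_reference: int, batch_size: int) -> float:
    """Fraction of a batch's study capacity spent on reference profiles.

    With ``n_reference`` reference libraries in a batch of ``batch_size``
    libraries, the cost overhead relative to the remaining study libraries is
    n_reference / (batch_size - n_reference); e.g. 4 reference profiles per
    96-library batch cost 4/92 ~ 4.3%.
    """
    if not 0 < n_reference < batch_size:
        raise ValueError("need 0 < n_reference < batch_size")
    return n_reference / (batch_size - n_reference)


def total_score(snr_db: float, rc: float) -> tuple[float, bool]:
    """Geometric mean of SNR (dB) and RC, clipping negatives to 0.

    Returns (score, clipped); the geometric mean of negative quantities is
    undefined, so negative inputs contribute 0 and raise the clip flag.
    """
    clipped = snr_db < 0 or rc < 0
    return math.sqrt(max(snr_db, 0.0) * max(rc, 0.0)), clipped


def derive_cutoffs(
    values: list[float] | np.ndarray, direction: str = "lower-bound"
) -> float:
    """Mean - s.d. (lower-bound metrics) or mean + s.d. (upper-bound, RMSE)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("cutoff derivation needs >= 2 values")
    if direction not in ("lower-bound", "upper-bound"):
        raise ValueError("direction must be 'lower-bound' or 'upper-bound'")
    sd = values.std(ddof=1)
    return float(values.mean() - sd) if direction == "lower-bound" else float(values.mean() + sd)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    table: pd.DataFrame  # round, batch, role, rc, rmse, mcc
    train_validation_correlation: dict[str, float]
    cutoffs: dict[str, float]


def _batch_metrics(
    study: ExpressionStudy,
    ref: ReferenceDataset,
    pairs: list[tuple[str, str]],
    log_offset: float = 0.01,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> dict[str, float]:
    """Mean RC/RMSE/MCC over the reference pairs for one batch."""
    lm = log_transform(study, offset=log_offset)
    rcs, rmses, mccs = [], [], []
    for a, b in pairs:
        key = f"{a}/{b}"
        ratios = pair_ratios(lm, study.design, a, b)
        rc, _ = relative_correlation(ratios, ref, key)
        rmse, _ = rmse_vs_reference(ratios, ref, key)
        table = call_degs(
            lm, study.design, a, b, p_threshold=p_threshold, fc_threshold=fc_threshold
        )
        mccs.append(mcc_vs_reference(table, ref, key).mcc)
        rcs.append(rc)
        rmses.append(rmse)
    return {
        "rc": float(np.mean(rcs)),
        "rmse": float(np.mean(rmses)),
        "mcc": float(np.mean(mccs)),
    }


def _scaled_gate(base: int, base_total: int, train_size: int) -> int:
    """Scale a batch-count gate proportionally, rounding up, floor 2."""
    return max(2, math.ceil(train_size * base / base_total))


def cross_validate_reference(
    batches: list[ExpressionStudy],
    pairs: list[tuple[str, str]],
    denominator: str,
    n_rounds: int = 30,
    train_size: int = 13,
    seed: int | None = None,
    p_in_batches_base: tuple[int, int] = (4, 13),
    deg_min_batches_base: tuple[int, int] = (6, 13),
    **ref_kwargs,
) -> CrossValidationResult:
    """Train references on random batch subsets; score every batch per round.

    Each round samples ``train_size`` batches without replacement, builds a
    reference from them (batch-count-dependent gates scaled proportionally,
    rounded up, floor 2), and computes RC/RMSE/MCC for all batches.  Rows are
    labeled train/validation; cutoffs come from the validation values, and a
    per-batch train-vs-validation correlation summarizes split independence.
    """
    if seed is None:
        raise ValueError("seed is mandatory for cross-validation")
    if train_size >= len(batches):
        raise ValueError(
            f"train_size {train_size} must be < number of batches {len(batches)}"
        )
    rng = np.random.default_rng(seed)
    p_in = _scaled_gate(p_in_batches_base[0], p_in_batches_base[1], train_size)
    deg_min = _scaled_gate(deg_min_batches_base[0], deg_min_batches_base[1], train_size)
    labels = [s.design.batches[0] for s in batches]

    rows = []
    for rnd in range(n_rounds):
        train_idx = rng.choice(len(batches), size=train_size, replace=False)
        train_set = set(train_idx.tolist())
        result = build_reference_ratios(
            [batches[i] for i in sorted(train_set)],
            pairs,
            denominator,
            p_in_batches=p_in,
            deg_min_batches=deg_min,
            **ref_kwargs,
        )
        for i, study in enumerate(batches):
            try:
                metrics = _batch_metrics(study, result.reference, pairs)
            except (ValueError, KeyError) as exc:
                logger.warning("round %d batch %s skipped: %s", rnd, labels[i], exc)
                continue
            rows.append(
                {
                    "round": rnd,
                    "batch": labels[i],
                    "role": "train" if i in train_set else "validation",
                    **metrics,
                }
            )
    table = pd.DataFrame(rows)

    corr: dict[str, float] = {}
    for metric in ("rc", "rmse", "mcc"):
        per_batch = table.pivot_table(
            index="batch", columns="role", values=metric, aggfunc="mean"
        )
        per_batch = per_batch.dropna()
        if len(per_batch) >= 3 and {"train", "validation"} <= set(per_batch.columns):
            corr[metric] = float(
                stats.pearsonr(per_batch["train"], per_batch["validation"])[0]
            )
        else:
            corr[metric] = float("nan")

    val = table[table["role"] == "validation"]
    cutoffs = {
        "rc": derive_cutoffs(val["rc"].to_numpy(), "lower-bound"),
        "rmse": derive_cutoffs(val["rmse"].to_numpy(), "upper-bound"),
        "mcc": derive_cutoffs(val["mcc"].to_numpy(), "lower-bound"),
    }
    return CrossValidationResult(
        table=table, train_validation_correlation=corr, cutoffs=cutoffs
    )


# ---------------------------------------------------------------------------
# Subset-design enumeration
# ---------------------------------------------------------------------------

def evaluate_subset_designs(
    study: ExpressionStudy,
    groups_range: list[int],
    reps_range: list[int],
    mode: str = "snr",
    ref: ReferenceDataset | None = None,
    denominator: str | None = None,
    log_offset: float = 0.01,
    max_combinations: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Metric distributions over enumerated (groups x replicates) sub-designs.

    For each (G, R) in ``groups_range x reps_range`` all subsets of G groups
    are enumerated.  ``mode``:

    * ``"snr"`` — PCA SNR of the sub-design (G >= 2, R >= 2 required); all
      per-group R-replicate sample subsets are enumerated (single batch);
    * ``"rc"`` — mean RC against ``ref`` over the pairs (g, denominator) with
      g in the subset (denominator must be in the subset); enumeration as
      for ``"snr"``;
    * ``"ratio-denominator"`` — PCA SNR of ratio profiles of the (possibly
      multi-batch) design, using the chosen groups with R replicate *indices*
      per group as the in-batch denominator pool (R >= 1); replicate indices
      apply uniformly across batches, matching a physical vial layout.

    ``max_combinations`` randomly subsamples the enumeration (seeded
    reservoir sampling; the enumeration stays lazy).
    """
    if mode not in ("snr", "rc", "ratio-denominator"):
        raise ValueError("mode must be snr, rc or ratio-denominator")
    design = study.design
    lm = log_transform(study, offset=log_offset)
    groups = design.groups
    rows = []
    rng = np.random.default_rng(seed)
    for G in groups_range:
        if G > len(groups):
            raise ValueError(f"requested {G} groups, design has {len(groups)}")
        if mode == "snr" and G < 2:
            raise ValueError("SNR needs >= 2 groups")
        for R in reps_range:
            combos = _enumerate_subsets(design, G, R, mode, denominator)
            if max_combinations is not None:
                combos = _reservoir(combos, max_combinations, rng)
            for chosen_groups, pick in combos:
                value = _subset_metric(
                    study, lm, chosen_groups, pick, mode, ref, denominator
                )
                rows.append(
                    {
                        "G": G,
                        "R": R,
                        "design": f"G{G}R{R}",
                        "groups": ",".join(chosen_groups),
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def _reservoir(iterable, k, rng):
    """Uniform k-subsample of an iterable without materializing it."""
    sample = []
    for i, item in enumerate(iterable):
        if i < k:
            sample.append(item)
        else:
            j = rng.integers(0, i + 1)
            if j < k:
                sample[j] = item
    return sample


def _enumerate_subsets(design, G, R, mode, denominator):
    """Yield (chosen_groups, pick): pick is a sample list (snr/rc modes) or
    a tuple of replicate indices (ratio-denominator mode)."""
    groups = design.groups
    if mode == "ratio-denominator":
        rep_indices = sorted(design.table["replicate"].unique())
        for chosen in itertools.combinations(groups, G):
            for reps in itertools.combinations(rep_indices, R):
                yield chosen, reps
        return
    for chosen in itertools.combinations(groups, G):
        if mode == "rc" and denominator not in chosen:
            continue
        per_group_choices = []
        ok = True
        for g in chosen:
            samples_g = design.samples_in(group=g)
            if len(samples_g) < R:
                ok = False
                break
            per_group_choices.append(list(itertools.combinations(samples_g, R)))
        if not ok:
            continue
        for pick in itertools.product(*per_group_choices):
            yield chosen, [s for sub in pick for s in sub]


def _subset_metric(study, lm, chosen_groups, pick, mode, ref, denominator):
    design = study.design
    if mode == "snr":
        sub = design.subset(pick)
        return snr_pca(lm[pick], sub).snr_db
    if mode == "rc":
        if ref is None or denominator is None:
            raise ValueError("mode='rc' requires ref and denominator")
        sub = design.subset(pick)
        rcs = []
        for g in sub.groups:
            if g == denominator:
                continue
            key = f"{g}/{denominator}"
            if key not in ref.pairs:
                continue
            ratios = pair_ratios(lm[pick], sub, g, denominator)
            rcs.append(relative_correlation(ratios, ref, key)[0])
        return float(np.mean(rcs)) if rcs else float("nan")
    # ratio-denominator: chosen groups x replicate indices form the pool
    rep_set = set(pick)
    ratios = lm.copy()
    for batch in design.batches:
        batch_samples = design.samples_in(batch=batch)
        denom_rows = design.table[
            (design.table["batch"] == batch)
            & design.table["group"].isin(chosen_groups)
            & design.table["replicate"].isin(rep_set)
        ]
        denom = denom_rows["sample"].tolist()
        if not denom:
            return float("nan")
        ratios[batch_samples] = lm[batch_samples].sub(lm[denom].mean(axis=1), axis=0)
    return snr_pca(ratios, design).snr_db


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-batch QC metric bundle with pass/fail flags and diagnosis."""

    batch: str
    snr: SNRResult
    leave_one_out: LeaveOneOutResult | None
    reference_metrics: pd.DataFrame | None  # per pair: rc, rmse, mcc, n_genes
    total: float | None
    total_clipped: bool
    cutoffs: dict[str, float]
    flags: dict[str, bool | None]
    final_flag: bool
    diagnosis: str

    def to_dict(self) -> dict:
        out = {
            "batch": self.batch,
            "snr_db": self.snr.snr_db,
            "snr_infinite": self.snr.infinite,
            "diagnosis": self.diagnosis,
            "cutoffs": self.cutoffs,
            "flags": self.flags,
            "final_flag": "pass" if self.final_flag else "fail",
            "total_score": self.total,
            "total_clipped": self.total_clipped,
        }
        if self.reference_metrics is not None:
            out["reference_metrics"] = self.reference_metrics.to_dict(orient="index")
        else:
            out["reference_metrics"] = "unavailable"
        if self.leave_one_out is not None:
            out["leave_one_out"] = self.leave_one_out.table.to_dict(orient="records")
            out["flagged_sample"] = self.leave_one_out.flagged_sample
        return out


def qc_report(
    study: ExpressionStudy,
    ref: ReferenceDataset | None = None,
    cutoffs: dict[str, float] | None = None,
    log_offset: float = 0.01,
    loo: bool = True,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> QCReport:
    """Assemble the QC report for one batch.

    Computes the PCA SNR (plus leave-one-out diagnosis when every group has at
    least 3 replicates) and, when a reference dataset is supplied, RC, RMSE and
    MCC per reference pair and the total score.  Each metric is flagged against
    its cutoff; the final flag fails if any computed metric fails.
    """
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    design = study.design
    batch = design.batches[0] if len(design.batches) == 1 else ",".join(design.batches)
    lm = log_transform(study, offset=log_offset)
    snr_res = snr_pca(lm, design)

    loo_res = None
    diagnosis = "pass" if snr_res.snr_db >= cutoffs["snr"] else "systematic-failure"
    if loo and all(n >= 3 for n in design.n_per_group().values()):
        loo_res = snr_leave_one_out(lm, design, snr_cutoff=cutoffs["snr"])
        diagnosis = loo_res.diagnosis

    flags: dict[str, bool | None] = {"snr": bool(snr_res.snr_db >= cutoffs["snr"])}
    ref_frame = None
    total = None
    clipped = False
    if ref is not None:
        rows = {}
        for pair in ref.pairs:
            a, b = pair.split("/")
            if a not in design.groups or b not in design.groups:
                continue
            ratios = pair_ratios(lm, design, a, b)
            rc, n_genes = relative_correlation(ratios, ref, pair)
            rmse, _ = rmse_vs_reference(ratios, ref, pair)
            table = call_degs(
                lm, design, a, b, p_threshold=p_threshold, fc_threshold=fc_threshold
            )
            mcc = mcc_vs_reference(table, ref, pair).mcc
            rows[pair] = {"rc": rc, "rmse": rmse, "mcc": mcc, "n_genes": n_genes}
        if rows:
            ref_frame = pd.DataFrame.from_dict(rows, orient="index")
            rc_mean = float(ref_frame["rc"].mean())
            flags["rc"] = bool(rc_mean >= cutoffs["rc"])
            flags["rmse"] = bool(ref_frame["rmse"].mean() <= cutoffs["rmse"])
            flags["mcc"] = bool(ref_frame["mcc"].mean() >= cutoffs["mcc"])
            total, clipped = total_score(snr_res.snr_db, rc_mean)
    else:
        flags.update({"rc": None, "rmse": None, "mcc": None})

    final = all(v for v in flags.values() if v is not None)
    return QCReport(
        batch=batch,
        snr=snr_res,
        leave_one_out=loo_res,
        reference_metrics=ref_frame,
        total=total,
        total_clipped=clipped,
        cutoffs=cutoffs,
        flags=flags,
        final_flag=final,
        diagnosis=diagnosis,
    )
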