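import math

import numpy as np
import pandas as pd
import pytest

from ratioqc import (
    ExpressionStudy,
    ReferenceDataset,
    SimulationConfig,
    build_reference_ratios,
    call_degs,
    cross_validate_reference,
    derive_cutoffs,
    evaluate_subset_designs,
    inject_outlier,
    log_transform,
    mcc_vs_reference,
    pair_ratios,
    qc_report,
    relative_correlation,
    rmse_vs_reference,
    simulate_study,
    snr_pca,
    total_score,
)

from conftest import make_design

PAIRS = [("D5", "D6"), ("F7", "D6"), ("M8", "D6")]


def ref_from_values(values: pd.Series, labels: pd.Series | None = None, pair="D5/D6"):
    n = len(values)
    if labels is None:
        labels = pd.Series("non-DEG", index=values.index)
    return ReferenceDataset(
        pd.DataFrame(
            {
                "gene": values.index,
                "pair": pair,
                "log2fc_ref": values.to_numpy(),
                "n_batches": 13,
                "n_up": 0,
                "n_down": 0,
                "u_char": 0.01,
                "u_bb": 0.0,
                "u_s": 0.0,
                "u_c": 0.01,
                "k": 2.0,
                "U": 0.02,
                "deg_label": labels.to_numpy(),
            }
        )
    )


@pytest.fixture(scope="session")
def sim_reference(multibatch_study):
    """Reference over all consensus-detectable genes of the 8-batch study."""
    result = build_reference_ratios(
        multibatch_study.batches, PAIRS, "D6", p_in_batches=0, deg_min_batches=4
    )
    return result.reference


# -- RC / RMSE -------------------------------------------------------------

def test_rc_trivial_and_sign():
    rng = np.random.default_rng(0)
    vals = pd.Series(rng.normal(0, 1, 50), index=[f"g{i}" for i in range(50)])
    ref = ref_from_values(vals)
    rc, n = relative_correlation(vals, ref, "D5/D6")
    assert rc == pytest.approx(1.0) and n == 50
    rc_neg, _ = relative_correlation(-vals, ref, "D5/D6")
    assert rc_neg == pytest.approx(-1.0)


def test_rc_noise_attenuation():
    """i.i.d. noise sigma=0.5 on unit-s.d. reference attenuates RC to ~0.894."""
    rng = np.random.default_rng(1)
    vals = pd.Series(rng.normal(0, 1, 1000), index=[f"g{i}" for i in range(1000)])
    ref = ref_from_values(vals)
    noisy = vals + rng.normal(0, 0.5, 1000)
    rc, _ = relative_correlation(noisy, ref, "D5/D6")
    assert rc == pytest.approx(1 / math.sqrt(1.25), abs=0.02)


def test_rc_requires_overlap_and_variance():
    vals = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    ref = ref_from_values(vals)
    with pytest.raises(ValueError, match="shared"):
        relative_correlation(vals.iloc[:2], ref, "D5/D6")
    flat = ref_from_values(pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"]))
    with pytest.raises(ValueError, match="degenerate"):
        relative_correlation(vals, flat, "D5/D6")


def test_rmse_arithmetic():
    vals = pd.Series([0.0, 0.0, 0.0], index=["a", "b", "c"])
    ref = ref_from_values(pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]))
    rmse, _ = rmse_vs_reference(vals, ref, "D5/D6")
    assert rmse == pytest.approx(math.sqrt(14 / 3), abs=1e-12)
    identical, _ = rmse_vs_reference(
        pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]), ref, "D5/D6"
    )
    assert identical == 0.0
    shifted, _ = rmse_vs_reference(
        pd.Series([1.7, 2.7, 3.7], index=["a", "b", "c"]), ref, "D5/D6"
    )
    assert shifted == pytest.approx(0.7, abs=1e-12)


# -- MCC -------------------------------------------------------------------

def _deg_table(calls: pd.Series) -> "DEGTable":
    design = make_design(("D5", "D6"), reps=3)
    lm = pd.DataFrame(np.ones((len(calls), 6)), index=calls.index,
                      columns=design.samples)
    table = call_degs(lm, design, "D5", "D6")
    table.table["call"] = calls
    return table


def brute_force_confusion(labels, calls, direction_aware=True):
    tp = tn = fp = fn = 0
    for g in labels.index:
        lab, call = labels[g], calls[g]
        if lab == "non-DEG":
            tn += call == "non-DE"
            fp += call != "non-DE"
        else:
            if call == "non-DE":
                fn += 1
            elif call == lab or not direction_aware:
                tp += 1
            else:
                fp += 1
                fn += 1
    return tp, tn, fp, fn


def test_mcc_perfect_and_inverted():
    genes = [f"g{i}" for i in range(8)]
    labels = pd.Series(["up"] * 2 + ["down"] * 2 + ["non-DEG"] * 4, index=genes)
    ref = ref_from_values(pd.Series(1.0, index=genes), labels)
    perfect = labels.map({"up": "up", "down": "down", "non-DEG": "non-DE"})
    assert mcc_vs_reference(_deg_table(perfect), ref, "D5/D6").mcc == pytest.approx(1.0)
    inverted = labels.map({"up": "non-DE", "down": "non-DE", "non-DEG": "up"})
    assert mcc_vs_reference(_deg_table(inverted), ref, "D5/D6").mcc == pytest.approx(-1.0)


def test_mcc_arithmetic_example():
    """TP=3, TN=4, FP=1, FN=2 -> (12-2)/sqrt(4*5*5*6) ~ 0.4082."""
    genes = [f"g{i}" for i in range(10)]
    labels = pd.Series(["up"] * 5 + ["non-DEG"] * 5, index=genes)
    calls = pd.Series(
        ["up", "up", "up", "non-DE", "non-DE", "up", "non-DE", "non-DE", "non-DE", "non-DE"],
        index=genes,
    )
    ref = ref_from_values(pd.Series(1.0, index=genes), labels)
    res = mcc_vs_reference(_deg_table(calls), ref, "D5/D6")
    assert (res.counts.tp, res.counts.tn, res.counts.fp, res.counts.fn) == (3, 4, 1, 2)
    assert res.mcc == pytest.approx(10 / math.sqrt(600), abs=1e-12)


def test_mcc_matches_brute_force_contingency():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(40)]
    for trial in range(25):
        labels = pd.Series(rng.choice(["up", "down", "non-DEG"], 40, p=[0.2, 0.2, 0.6]),
                           index=genes)
        calls = pd.Series(rng.choice(["up", "down", "non-DE"], 40, p=[0.2, 0.2, 0.6]),
                          index=genes)
        if not (labels == "non-DEG").any():
            continue
        ref = ref_from_values(pd.Series(1.0, index=genes), labels)
        res = mcc_vs_reference(_deg_table(calls), ref, "D5/D6")
        tp, tn, fp, fn = brute_force_confusion(labels, calls)
        assert (res.counts.tp, res.counts.tn, res.counts.fp, res.counts.fn) == (tp, tn, fp, fn)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
        assert res.mcc == pytest.approx(expected, abs=1e-12)
        # counts cover every evaluated gene (mismatches double-counted)
        mismatches = sum(
            1 for g in genes
            if labels[g] in ("up", "down") and calls[g] in ("up", "down")
            and calls[g] != labels[g]
        )
        assert res.counts.total == len(genes) + mismatches


def test_mcc_requires_non_degs():
    genes = ["a", "b", "c"]
    labels = pd.Series(["up", "up", "down"], index=genes)
    ref = ref_from_values(pd.Series(1.0, index=genes), labels)
    with pytest.raises(ValueError, match="non-DEG"):
        mcc_vs_reference(_deg_table(pd.Series("up", index=genes)), ref, "D5/D6")


# -- total score & cutoffs -------------------------------------------------

@pytest.mark.parametrize(
    "snr, rc, expected, clipped",
    [(16.0, 1.0, 4.0, False), (0.0, 0.9, 0.0, False), (-3.0, 0.9, 0.0, True)],
)
def test_total_score(snr, rc, expected, clipped):
    score, flag = total_score(snr, rc)
    assert score == pytest.approx(expected)
    assert flag is clipped


def test_derive_cutoffs():
    assert derive_cutoffs([10, 12, 14], "lower-bound") == pytest.approx(10.0)
    assert derive_cutoffs([0.3, 0.3, 0.3], "upper-bound") == pytest.approx(0.3)
    with pytest.raises(ValueError, match=">= 2"):
        derive_cutoffs([1.0], "lower-bound")


# -- cross-validation ------------------------------------------------------

@pytest.fixture(scope="module")
def graded_batches(multibatch_study):
    """The 8-batch study with a per-batch quality gradient (extra noise)."""
    rng = np.random.default_rng(99)
    out = []
    for b, extra in zip(multibatch_study.batches, np.linspace(0.0, 0.8, 8)):
        vals = b.values * 2 ** rng.normal(0, extra, size=b.values.shape)
        out.append(ExpressionStudy(vals, b.design, b.counts))
    return out


def test_cross_validation_split_independence(graded_batches):
    """Metrics of a batch agree whether it trained the reference or not."""
    cv = cross_validate_reference(
        graded_batches, PAIRS, "D6", n_rounds=10, train_size=5, seed=3,
        detect_gate=False,
    )
    assert cv.train_validation_correlation["rc"] > 0.9
    assert set(cv.table["role"]) == {"train", "validation"}
    # cutoffs exist and are ordered sensibly
    assert cv.cutoffs["rc"] <= 1.0
    assert cv.cutoffs["rmse"] > 0.0


def test_cross_validation_seeded_determinism_and_errors(graded_batches):
    kwargs = dict(n_rounds=2, train_size=5, seed=3, detect_gate=False)
    a = cross_validate_reference(graded_batches, PAIRS, "D6", **kwargs)
    b = cross_validate_reference(graded_batches, PAIRS, "D6", **kwargs)
    pd.testing.assert_frame_equal(a.table, b.table)
    with pytest.raises(ValueError, match="train_size"):
        cross_validate_reference(
            graded_batches, PAIRS, "D6", n_rounds=1, train_size=8, seed=3
        )
    with pytest.raises(ValueError, match="seed"):
        cross_validate_reference(graded_batches, PAIRS, "D6", train_size=5)


# -- subset designs --------------------------------------------------------

def test_subset_design_counts_and_identity(quartet_batch):
    tab = evaluate_subset_designs(quartet_batch, [2], [2], mode="snr")
    assert len(tab) == 54  # C(4,2) * C(3,2)^2
    full = evaluate_subset_designs(quartet_batch, [4], [3], mode="snr")
    assert len(full) == 1
    lm = log_transform(quartet_batch)
    assert full["value"].iloc[0] == pytest.approx(
        snr_pca(lm, quartet_batch.design).snr_db
    )


def test_more_groups_raise_subset_snr(quartet_batch):
    tab = evaluate_subset_designs(quartet_batch, [2, 3], [2], mode="snr")
    med = tab.groupby("design")["value"].median()
    assert med["G3R2"] > med["G2R2"]


def test_subset_snr_rejects_single_group(quartet_batch):
    with pytest.raises(ValueError, match="2 groups"):
        evaluate_subset_designs(quartet_batch, [1], [2], mode="snr")


def test_denominator_pool_snr_grows_with_replicates(multibatch_study):
    pooled = multibatch_study.pooled()
    tab = evaluate_subset_designs(pooled, [1], [1, 3], mode="ratio-denominator")
    med = tab.groupby("design")["value"].median()
    assert med["G1R3"] > med["G1R1"]


# -- report ----------------------------------------------------------------

def test_clean_batch_report_passes(multibatch_study, sim_reference):
    rep = qc_report(multibatch_study.batches[0], ref=sim_reference)
    assert rep.flags == {"snr": True, "rc": True, "rmse": True, "mcc": True}
    assert rep.final_flag
    assert rep.diagnosis == "pass"
    assert rep.total is not None and rep.total > 0


def test_outlier_batch_report_fails_with_diagnosis(sim_reference):
    study = simulate_study(SimulationConfig(n_genes=300, seed=303))
    target = study.batches[0].samples[2]
    spiked = inject_outlier(study, target, severity=12).batches[0]
    rep = qc_report(spiked, ref=None)
    assert rep.diagnosis == "random-failure"
    assert rep.leave_one_out.flagged_sample == target


def test_report_without_reference_marks_unavailable(quartet_batch):
    rep = qc_report(quartet_batch)
    assert rep.reference_metrics is None
    assert rep.flags["rc"] is None
    payload = rep.to_dict()
    assert payload["reference_metrics"] == "unavailable"


def test_depleted_transcripts_split_snr_from_reference_metrics(
    multibatch_study, sim_reference
):
    """A batch with a depleted gene subset keeps a high SNR but loses RC.

    Emulates a customized library kit removing a set of transcripts: group
    separation survives, yet ratio profiles disagree with the reference.
    """
    clean = multibatch_study.batches[0]
    ref_genes = sim_reference.for_pair("D5/D6").index
    depleted_vals = clean.values.copy()
    # deplete a third of the reference genes to (near) zero in every sample
    targets = ref_genes[: len(ref_genes) // 3]
    depleted_vals.loc[targets] = 0.0
    depleted = ExpressionStudy(depleted_vals, clean.design, clean.counts)

    rep_clean = qc_report(clean, ref=sim_reference)
    rep_depl = qc_report(depleted, ref=sim_reference)
    assert rep_depl.snr.snr_db > 12.0  # separation survives
    assert (
        rep_depl.reference_metrics["rc"].mean()
        < rep_clean.reference_metrics["rc"].mean() - 0.1
    )
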