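import math

import numpy as np
import pandas as pd
import pytest

from ratioqc import (
    SimulationConfig,
    build_reference_ratios,
    combine_uncertainty,
    homogeneity_test,
    simulate_study,
    stability_test,
    u_bb_absolute,
    u_char_relative,
    uncertainty_bundle,
)


PAIRS = [("D5", "D6"), ("F7", "D6"), ("M8", "D6")]


# -- reference construction ------------------------------------------------

def test_reference_recovers_planted_fold_changes(multibatch_study):
    """Mean of per-batch log2 ratios recovers planted effects (8 batches)."""
    result = build_reference_ratios(
        multibatch_study.batches, PAIRS, "D6", p_in_batches=3, deg_min_batches=4
    )
    for pair in ("D5/D6", "F7/D6", "M8/D6"):
        rp = result.reference.for_pair(pair)
        truth = multibatch_study.truth[pair]["true_log2fc"].loc[rp.index]
        err = rp["log2fc_ref"] - truth
        assert abs(err.mean()) < 0.05
        assert np.sqrt((err**2).mean()) < 0.15


def test_thirteen_batch_reference_pins_planted_degs():
    """With 13 batches, >= 95% of planted DEGs are recovered within +-0.1."""
    study = simulate_study(SimulationConfig(n_genes=500, n_batches=13, seed=88))
    result = build_reference_ratios(study.batches, PAIRS, "D6", p_in_batches=4)
    errors = []
    for pair in ("D5/D6", "F7/D6", "M8/D6"):
        rp = result.reference.for_pair(pair)
        truth = study.truth[pair]["true_log2fc"].loc[rp.index]
        planted = truth[truth.abs() >= 1.0]
        errors.append((rp.loc[planted.index, "log2fc_ref"] - planted).abs())
    errors = pd.concat(errors)
    assert len(errors) > 50
    assert (errors <= 0.1).mean() >= 0.95


def test_reference_batch_order_invariant(multibatch_study):
    fwd = build_reference_ratios(
        multibatch_study.batches, [("D5", "D6")], "D6", p_in_batches=3
    )
    rev = build_reference_ratios(
        multibatch_study.batches[::-1], [("D5", "D6")], "D6", p_in_batches=3
    )
    pd.testing.assert_frame_equal(fwd.reference.records, rev.reference.records)


def test_constant_ratios_give_constant_reference():
    """A gene at log2 ratio 1.0 in every batch gets reference value 1.0."""
    study = simulate_study(SimulationConfig(n_genes=50, n_batches=5, seed=77))
    batches = []
    for b in study.batches:
        values = b.values.copy()
        a_cols = b.design.samples_in(group="D5")
        d_cols = b.design.samples_in(group="D6")
        # force gene 0 to exactly ratio 1: D5 = 2 * D6 mean in linear scale
        lm = np.log2(values + 0.01)
        target = lm[d_cols].mean(axis=1).iloc[0] + 1.0
        values.loc[values.index[0], a_cols] = 2.0**target - 0.01
        from ratioqc.studydata import ExpressionStudy

        batches.append(ExpressionStudy(values, b.design, b.counts))
    result = build_reference_ratios(
        batches, [("D5", "D6")], "D6", p_in_batches=0, detect_gate=False
    )
    gene0 = batches[0].genes[0]
    assert result.reference.for_pair("D5/D6").loc[gene0, "log2fc_ref"] == pytest.approx(
        1.0, abs=1e-9
    )


def test_missing_pair_group_rejected(multibatch_study):
    with pytest.raises(ValueError, match="absent"):
        build_reference_ratios(multibatch_study.batches, [("D5", "ZZ")], "D6")


# -- homogeneity -----------------------------------------------------------

def _homogeneity_frame(rng, n_genes, unit_sd=0.0, n_within=9, n_between=16):
    samples = [f"w{i}" for i in range(n_within)] + [f"u{i}" for i in range(n_between)]
    units = pd.Series(
        ["N1"] * n_within + [f"N{i+2}" for i in range(n_between)], index=samples
    )
    mat = rng.normal(0, 1, size=(n_genes, n_within + n_between))
    if unit_sd > 0:
        mat[:, n_within:] += rng.normal(0, unit_sd, size=(n_genes, n_between))
    return pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)], columns=samples), units


def test_homogeneity_null_calibration():
    """Raw type-I error ~5% and nearly all genes pass after BH on a null material."""
    rng = np.random.default_rng(12)
    mat, units = _homogeneity_frame(rng, 2000)
    res = homogeneity_test(mat, units)
    raw_rate = (res["p_raw"] < 0.05).mean()
    assert abs(raw_rate - 0.05) <= 0.02
    assert res["passed"].mean() >= 0.99


def test_homogeneity_power_on_inhomogeneous_material():
    """Unit effects at 3x replicate s.d.: >= 80% of genes fail."""
    rng = np.random.default_rng(13)
    mat, units = _homogeneity_frame(rng, 500, unit_sd=3.0)
    res = homogeneity_test(mat, units)
    assert (~res["passed"]).mean() >= 0.80


def test_homogeneity_degenerate_and_design_errors():
    rng = np.random.default_rng(14)
    mat, units = _homogeneity_frame(rng, 5)
    mat.iloc[0] = 1.0  # all measurements identical
    res = homogeneity_test(mat, units)
    assert res["degenerate"].iloc[0]
    assert np.isnan(res["p_adj"].iloc[0])
    with pytest.raises(ValueError, match="single-measurement"):
        homogeneity_test(mat, pd.Series("N1", index=mat.columns))
    two_replicated = pd.Series(
        ["N1"] * 9 + ["N2"] * 9 + [f"N{i+3}" for i in range(7)], index=mat.columns
    )
    with pytest.raises(ValueError, match="one replicated unit"):
        homogeneity_test(mat, two_replicated)


# -- stability -------------------------------------------------------------

def test_stability_trivial_cases():
    x = pd.Series(np.arange(10, dtype=float), index=[f"t{i}" for i in range(10)])
    const = pd.DataFrame([[2.0] * 10], index=["g1"], columns=x.index)
    res = stability_test(const, x)
    assert res["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert bool(res["passed"].iloc[0])

    x5 = pd.Series(np.arange(5, dtype=float), index=[f"t{i}" for i in range(5)])
    drift = pd.DataFrame([0.5 * x5.to_numpy()], index=["g1"], columns=x5.index)
    res2 = stability_test(drift, x5)
    assert res2["se_slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert not bool(res2["passed"].iloc[0])


def test_stability_null_pass_rate_matches_confidence():
    """Slope-0 genes pass at ~95% under the 95% two-sided slope criterion."""
    rng = np.random.default_rng(15)
    x = pd.Series(np.linspace(0, 26, 15), index=[f"t{i}" for i in range(15)])
    mat = pd.DataFrame(
        rng.normal(0, 0.3, size=(2000, 15)),
        index=[f"g{i}" for i in range(2000)], columns=x.index,
    )
    res = stability_test(mat, x)
    assert abs(res["passed"].mean() - 0.95) <= 0.02


def test_stability_requires_timepoint_spread():
    x = pd.Series([1.0, 1.0, 2.0], index=["a", "b", "c"])
    mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=x.index)
    with pytest.raises(ValueError, match="distinct timepoints"):
        stability_test(mat, x)


# -- uncertainty budget ----------------------------------------------------

def test_uncertainty_arithmetic_examples():
    # zero spread -> zero characterization uncertainty
    assert u_char_relative(np.full(13, 2.0)) == 0.0
    # between-bottle branches
    val, branch = u_bb_absolute(4.0, 1.0, 8, 16)
    assert val == pytest.approx(math.sqrt(3 / 16), abs=1e-12)
    assert branch == "excess"
    val2, branch2 = u_bb_absolute(1.0, 4.0, 8, 16)
    assert val2 == pytest.approx(math.sqrt(4 / 16) * (2 / 8) ** 0.25, abs=1e-12)
    assert branch2 == "detection-limit"
    # ties resolve to the detection-limit branch
    assert u_bb_absolute(2.0, 2.0, 8, 16)[1] == "detection-limit"
    # expansion
    u_c, U = combine_uncertainty(0.3, 0.4, 0.0, k=2.0)
    assert u_c == pytest.approx(0.5)
    assert U == pytest.approx(1.0)


def test_bundle_combination_and_flags():
    char = pd.DataFrame(
        {"b1": [2.0, 1e-9], "b2": [2.2, -1e-9], "b3": [1.8, 1e-9]},
        index=["g_ok", "g_zero"],
    )
    bundle = uncertainty_bundle(char, k=2.0)
    ok = bundle.loc["g_ok"]
    assert ok["U"] == pytest.approx(2.0 * ok["u_c"], abs=1e-15)
    assert ok["u_c"] ** 2 == pytest.approx(
        ok["u_char"] ** 2 + ok["u_bb"] ** 2 + ok["u_s"] ** 2, abs=1e-12
    )
    assert bundle.loc["g_zero", "unquantifiable"]
    assert np.isnan(bundle.loc["g_zero", "U"])


def test_bundle_with_hom_and_stab_terms():
    rng = np.random.default_rng(16)
    genes = [f"g{i}" for i in range(20)]
    char = pd.DataFrame(
        rng.normal(1.5, 0.1, size=(20, 13)), index=genes,
        columns=[f"b{i}" for i in range(13)],
    )
    mat, units = _homogeneity_frame(rng, 20)
    mat.index = genes
    hom = homogeneity_test(mat, units)
    x = pd.Series(np.linspace(0, 26, 15), index=[f"t{i}" for i in range(15)])
    stab_mat = pd.DataFrame(rng.normal(1.5, 0.2, size=(20, 15)), index=genes,
                            columns=x.index)
    stab = stability_test(stab_mat, x)
    bundle = uncertainty_bundle(char, hom=hom, stab=stab, t_horizon=26.0, n_bb=16)
    resid = bundle["u_c"] ** 2 - (
        bundle["u_char"] ** 2 + bundle["u_bb"] ** 2 + bundle["u_s"] ** 2
    )
    assert resid.abs().max() < 1e-12
    assert (bundle["U"] == 2.0 * bundle["u_c"]).all()
    assert bundle["branch"].isin(["excess", "detection-limit"]).all()


def test_well_behaved_reference_has_tight_expanded_uncertainty(multibatch_study):
    """Most genes of a clean simulated reference carry U < 30%."""
    result = build_reference_ratios(
        multibatch_study.batches, [("D5", "D6")], "D6", p_in_batches=3
    )
    char = result.characterization["D5/D6"]
    strong = char[char.mean(axis=1).abs() >= 1.0]
    bundle = uncertainty_bundle(strong, k=2.0)
    quantified = bundle[~bundle["unquantifiable"]]
    assert (quantified["U"] < 0.30).mean() >= 0.80
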