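"""Metric suite, threshold sweeps, mutation-type matrices, RSA analysis."""

import numpy as np
import pytest

from ddgformer.evaluate import (classify_ddg, metric_suite,
                                mutation_type_matrix,
                                relative_solvent_accessibility, rsa_analysis,
                                threshold_sweep)
from ddgformer._tables import AA_ORDER, HYDROPHOBIC_AAS, POLAR_AAS


# -- three-way classification -----------------------------------------------

@pytest.mark.parametrize("ddg, label", [
    (-0.6, "stabilizing"),
    (-0.5, "neutral"),        # boundary values are neutral
    (0.5, "neutral"),
    (0.0, "neutral"),
    (0.51, "destabilizing"),
    (3.0, "destabilizing"),
])
def test_classify_ddg_boundaries(ddg, label):
    assert classify_ddg(ddg) == label


def test_classify_rejects_nonfinite():
    with pytest.raises(ValueError):
        classify_ddg(float("nan"))


# -- metric suite ------------------------------------------------------------

def test_perfect_predictions():
    true = np.array([-1.2, 0.3, 2.0, -0.4, 1.1])
    rep = metric_suite(true, true)
    assert rep.pearson == pytest.approx(1.0)
    assert rep.rmse == 0.0
    assert rep.precision == 1.0 and rep.recall == 1.0 and rep.auroc == 1.0


def test_anticorrelated_predictions():
    true = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    rep = metric_suite(-true, true)
    assert rep.pearson == pytest.approx(-1.0)


def _metric_oracle(pred, true, threshold=0.0):
    """Independent closed-form recomputation of every metric."""
    n = len(pred)
    pm, tm = pred.mean(), true.mean()
    pearson = (((pred - pm) * (true - tm)).sum()
               / np.sqrt(((pred - pm) ** 2).sum() * ((true - tm) ** 2).sum()))
    rp = np.argsort(np.argsort(pred)).astype(float)
    rt = np.argsort(np.argsort(true)).astype(float)
    spearman = (((rp - rp.mean()) * (rt - rt.mean())).sum()
                / np.sqrt(((rp - rp.mean()) ** 2).sum()
                          * ((rt - rt.mean()) ** 2).sum()))
    rmse = np.sqrt(((pred - true) ** 2).mean())
    y = true < threshold
    yhat = pred < threshold
    tp = int((y & yhat).sum()); fp = int((~y & yhat).sum())
    fn = int((y & ~yhat).sum()); tn = int((~y & ~yhat).sum())
    mcc = ((tp * tn - fp * fn)
           / np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))))
    # AUROC by pairwise comparison of scores (-pred), ties count half
    pos, neg = -pred[y], -pred[~y]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    auroc = wins / (len(pos) * len(neg))
    return pearson, spearman, rmse, mcc, auroc, tp / (tp + fp), tp / (tp + fn)


def test_metric_suite_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(6, 60))
        true = rng.normal(0, 1.5, n)
        pred = true + rng.normal(0, 1.0, n)
        if (true < 0).all() or (true >= 0).all():
            continue
        rep = metric_suite(pred, true)
        pearson, spearman, rmse, mcc, auroc, prec, rec = _metric_oracle(pred,
                                                                        true)
        assert rep.pearson == pytest.approx(pearson, abs=1e-9)
        assert rep.spearman == pytest.approx(spearman, abs=1e-9)
        assert rep.rmse == pytest.approx(rmse, abs=1e-9)
        assert rep.mcc == pytest.approx(mcc, abs=1e-9)
        assert rep.auroc == pytest.approx(auroc, abs=1e-9)
        assert rep.precision == pytest.approx(prec, abs=1e-9)
        assert rep.recall == pytest.approx(rec, abs=1e-9)


def test_single_class_reports_undefined_not_zero():
    true = np.array([1.0, 2.0, 0.5])
    rep = metric_suite(np.array([1.1, 1.9, 0.4]), true)
    assert rep.auroc is None and rep.mcc is None


def test_metric_suite_input_validation():
    with pytest.raises(ValueError):
        metric_suite([1.0], [1.0])


# -- threshold sweep ----------------------------------------------------------

def test_sweep_empty_selection_reports_nan_with_zero_count():
    sweep = threshold_sweep(np.array([1.0, 2.0]), np.array([0.0, 0.0]),
                            [-1.0, 0.0])
    assert (sweep.n_selected == 0).all()
    assert sweep.frac_stabilizing.isna().all()


def test_sweep_calibrated_predictions_are_pure_at_minus_half():
    true = np.array([-2.0, -1.0, -0.6, 0.0, 1.0, 2.0])
    sweep = threshold_sweep(true, true, [-0.5])
    assert sweep.frac_stabilizing.iloc[0] == 1.0
    assert sweep.recall_of_stabilizing.iloc[0] == 1.0


def test_sweep_matches_filter_and_count_oracle():
    rng = np.random.default_rng(1)
    pred = rng.normal(0, 1.5, 200)
    true = rng.normal(0, 1.5, 200)
    taus = [-2.0, -1.0, -0.5, 0.0, 0.5]
    sweep = threshold_sweep(pred, true, taus)
    for row, tau in zip(sweep.itertuples(), taus):
        sel = [t for p, t in zip(pred, true) if p < tau]
        assert row.n_selected == len(sel)
        if sel:
            stab = sum(t < -0.5 for t in sel) / len(sel)
            neut = sum(abs(t) <= 0.5 for t in sel) / len(sel)
            dest = sum(t > 0.5 for t in sel) / len(sel)
            assert row.frac_stabilizing == pytest.approx(stab)
            assert row.frac_neutral == pytest.approx(neut)
            assert row.frac_destabilizing == pytest.approx(dest)
            assert (row.frac_stabilizing + row.frac_neutral
                    + row.frac_destabilizing) == pytest.approx(1.0)


# -- mutation-type matrix -----------------------------------------------------

def test_balanced_tp_set_has_uniform_cells():
    pairs = [(a, b) for a in AA_ORDER for b in AA_ORDER if a != b]
    m = mutation_type_matrix(pairs)
    assert m.coverage == 1.0
    assert np.allclose(m.fractions()[~np.eye(20, dtype=bool)], 1 / 380)
    assert (1 / 380) * 100 == pytest.approx(0.26, abs=0.01)


def test_matrix_diagonal_zero_and_total():
    pairs = [("A", "V")] * 3 + [("L", "R")] * 2
    m = mutation_type_matrix(pairs)
    assert np.all(np.diag(m.counts) == 0)
    assert m.total == 5
    assert m.coverage == pytest.approx(2 / 380)


def test_matrix_coverage_of_ten_types():
    pairs = list(zip("ACDEFGHIKL", "VVVVVVVVVV"))
    assert mutation_type_matrix(pairs).coverage == pytest.approx(10 / 380)


def test_matrix_rejects_bad_codes():
    with pytest.raises(ValueError):
        mutation_type_matrix([("A", "B")])
    with pytest.raises(ValueError):
        mutation_type_matrix([("A", "A")])


# -- RSA analysis --------------------------------------------------------------

def test_rsa_definition_and_cap():
    assert relative_solvent_accessibility(0.0, "A") == 0.0
    assert relative_solvent_accessibility(64.5, "A") == pytest.approx(0.5)
    assert relative_solvent_accessibility(500.0, "A") == 1.0   # capped


def test_polar_hydrophobic_partition_is_the_seventeen_listed():
    assert POLAR_AAS == frozenset("STNQDERKHY")
    assert HYDROPHOBIC_AAS == frozenset("LMIVFWA")
    assert not (POLAR_AAS & HYDROPHOBIC_AAS)
    assert set(AA_ORDER) - POLAR_AAS - HYDROPHOBIC_AAS == {"G", "C", "P"}


def test_rsa_analysis_bins_and_class_exclusion():
    pred = np.array([-1.0, -1.0, 1.0, -1.0])
    true = np.array([-1.0, 1.0, 1.0, -1.0])
    wt = ["S", "L", "G", "A"]             # G excluded from both classes
    rsa = [0.02, 0.3, 0.3, 0.9]
    table = rsa_analysis(pred, true, wt, rsa)
    assert set(table.aa_class) == {"polar", "hydrophobic"}
    assert table.n.sum() == 3             # the glycine row counts nowhere
    polar_first = table[(table.aa_class == "polar") & (table.rsa_lo == 0.0)]
    assert polar_first.n.iloc[0] == 1
    assert polar_first.precision.iloc[0] == 1.0
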