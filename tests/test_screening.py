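"""Screening: death rates, hit calling, dose-response, fold change, t-tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rtevolve import (
    DoseResponseModel,
    PlateParams,
    ViabilityPlate,
    call_hits,
    compare_populations,
    death_rate,
    fold_change,
    generate_viability_plate,
    holm_adjust,
    screening_scenario,
    sensitization_scenario,
)


def test_death_rate_arithmetic():
    assert death_rate(1.0, 1.0) == 0.0
    assert death_rate(0.0, 1.0) == 1.0
    # the >80% regime that disqualifies over-strong screening concentrations
    assert death_rate(0.2, 1.0) == pytest.approx(0.8)
    assert death_rate(1.2, 1.0) == 0.0  # clamped
    with pytest.raises(ValueError):
        death_rate(0.5, 0.0)


@given(st.floats(0.0, 2.0), st.floats(0.0, 2.0), st.floats(0.1, 2.0))
def test_death_rate_antitone_in_signal(r1, r2, zero):
    lo, hi = sorted((r1, r2))
    assert death_rate(hi, zero) <= death_rate(lo, zero)


def test_plate_requires_zero_concentration():
    df = pd.DataFrame({
        "clone_id": ["a", "a"], "experiment_id": ["e1", "e1"],
        "concentration_nM": [10.0, 35.0], "readout": [0.5, 0.3],
    })
    with pytest.raises(ValueError, match="0-concentration"):
        ViabilityPlate(df)


def test_noiseless_fold_one_plate_is_degenerate_flat():
    """noise 0, sensitizer fold 1: every library clone's column is identical."""
    params = PlateParams(noise_sd=0.0, sensitizer_fold=1.0,
                         sensitizers=frozenset({"c1"}))
    plate = generate_viability_plate(
        ["c1", "c2", "c3"], [0.0, 10.0, 35.0, 70.0], params, seed=5,
        n_experiments=2, control_ids=None)
    wide = plate.data.pivot_table(index="concentration_nM", columns="clone_id",
                                  values="readout", aggfunc="mean")
    assert np.allclose(wide.values, wide.values[:, [0]])


def test_hit_calling_no_exceedance_means_no_hits():
    # clones strictly below both controls at the screening concentration
    params = PlateParams(noise_sd=0.0)
    plate = generate_viability_plate(["c1", "c2"], [0.0, 10.0, 35.0, 70.0],
                                     params, seed=9)
    hits = call_hits(plate)
    assert hits["hit"].sum() == 0
    assert (hits["n_exceed"] == 0).all()


def test_single_experiment_exceedance_is_a_hit():
    """Death above both controls in exactly 1 of 3 experiments flags a hit."""
    rows = []
    for exp in ("e1", "e2", "e3"):
        beat = exp == "e2"
        for cid, v10 in (("untransduced", 0.9), ("wt-dCK", 0.8),
                         ("clone", 0.5 if beat else 0.95)):
            rows += [(cid, exp, 0.0, 1.0), (cid, exp, 10.0, v10)]
    plate = ViabilityPlate(pd.DataFrame(
        rows, columns=["clone_id", "experiment_id", "concentration_nM", "readout"]))
    hits = call_hits(plate)
    row = hits.set_index("clone_id").loc["clone"]
    assert row["n_exceed"] == 1 and bool(row["hit"])
    strict = call_hits(plate, min_experiments=2).set_index("clone_id").loc["clone"]
    assert not bool(strict["hit"])


def test_hit_calling_requires_controls_everywhere():
    rows = [("untransduced", "e1", 0.0, 1.0), ("untransduced", "e1", 10.0, 0.9),
            ("clone", "e1", 0.0, 1.0), ("clone", "e1", 10.0, 0.5)]
    plate = ViabilityPlate(pd.DataFrame(
        rows, columns=["clone_id", "experiment_id", "concentration_nM", "readout"]))
    with pytest.raises(ValueError, match="control"):
        call_hits(plate)


def test_hit_calling_invariant_under_row_shuffles(screen_scenario):
    plate, _ = screen_scenario
    shuffled = ViabilityPlate(plate.data.sample(frac=1.0, random_state=3))
    a = call_hits(plate)
    b = call_hits(shuffled)
    pd.testing.assert_frame_equal(a, b)


def test_screen_recovers_implanted_sensitizers(screen_scenario):
    """76 clones, 6 implants, default noise: sensitivity 6/6, <=2 false calls."""
    plate, implanted = screen_scenario
    hits = call_hits(plate)
    called = set(hits.loc[hits["hit"], "clone_id"])
    assert set(implanted) <= called
    assert len(called - set(implanted)) <= 2


# -- dose-response ----------------------------------------------------------

def test_noiseless_ic50_recovery():
    conc = np.concatenate([[0.0], np.geomspace(7.5, 750.0, 8)])
    true = 0.05 + 0.95 / (1 + (conc / 75.0) ** 1.5)
    res = DoseResponseModel(conc, true).fit()
    assert res.converged
    assert res.ic50 == pytest.approx(75.0, rel=1e-3)
    assert res.hill == pytest.approx(1.5, rel=1e-2)
    assert res.bottom <= res.top


def test_flat_viability_flagged_not_silent():
    res = DoseResponseModel([0.0, 1.0, 10.0, 100.0, 1000.0], [1.0] * 5).fit()
    assert not res.converged
    assert np.isnan(res.ic50)


def test_model_input_validation():
    with pytest.raises(ValueError, match="4 distinct"):
        DoseResponseModel([0.0, 1.0, 10.0], [1, 1, 1])
    with pytest.raises(ValueError, match="0-concentration"):
        DoseResponseModel([1.0, 10.0, 100.0, 1000.0], [1, 1, 1, 1])
    with pytest.raises(ValueError, match="plate error"):
        DoseResponseModel([0.0, 1.0, 10.0, 100.0], [1.0, 1.0, 1.6, 0.5])


def test_noiseless_fold_change_recovery():
    """Generator panel: 60x vs the wt transgene, 300x vs untransduced."""
    plate = sensitization_scenario(seed=5)
    fits = {cid: DoseResponseModel.from_plate(plate, cid).fit()
            for cid in plate.clone_ids}
    assert all(f.converged for f in fits.values())
    assert fits["sensitizer"].ic50 == pytest.approx(75.0, rel=1e-3)
    fc_wt = fold_change(fits["wt-dCK"], fits["sensitizer"], seed=1)
    fc_un = fold_change(fits["untransduced"], fits["sensitizer"], seed=2)
    assert fc_wt.ratio == pytest.approx(60.0, rel=0.01)
    assert fc_un.ratio == pytest.approx(300.0, rel=0.01)
    # bootstrap interval contains the point estimate
    assert fc_wt.ci_low <= fc_wt.ratio <= fc_wt.ci_high


def test_fold_change_identical_fits_is_one():
    plate = sensitization_scenario(seed=6)
    fit = DoseResponseModel.from_plate(plate, "wt-dCK").fit()
    fc = fold_change(fit, fit, seed=3, n_boot=50)
    assert fc.ratio == 1.0


def test_fold_change_rejects_unconverged():
    flat = DoseResponseModel([0.0, 1.0, 10.0, 100.0], [1.0] * 4).fit()
    plate = sensitization_scenario(seed=6)
    ok = DoseResponseModel.from_plate(plate, "wt-dCK").fit()
    with pytest.raises(ValueError, match="converge"):
        fold_change(ok, flat, seed=1)


def test_ic50_recovery_under_noise():
    """sd 0.05 noise on viability: median |relative error| <= 10% over 100 fits."""
    rng = np.random.default_rng(123)
    conc = np.concatenate([[0.0], np.geomspace(7.5, 750.0, 8)])
    truth = 0.05 + 0.95 / (1 + (conc / 75.0) ** 1.5)
    errors = []
    for _ in range(100):
        v = np.clip(truth + rng.normal(0, 0.05, conc.size), 0.0, 1.5)
        res = DoseResponseModel(conc, v).fit(n_starts=6)
        if res.converged:
            errors.append(abs(res.ic50 - 75.0) / 75.0)
    assert len(errors) >= 90
    assert np.median(errors) <= 0.10


def test_absolute_ic50_complements_relative():
    conc = np.concatenate([[0.0], np.geomspace(1.0, 1e4, 10)])
    v = 1.0 / (1 + (conc / 100.0) ** 2.0)  # top 1, bottom 0: both IC50s agree
    res = DoseResponseModel(conc, v).fit()
    assert res.absolute_ic50() == pytest.approx(100.0, rel=1e-3)


# -- population comparison --------------------------------------------------

def test_welch_test_textbook_case():
    res = compare_populations([0.1, 0.2, 0.15], [0.8, 0.9, 0.85])
    # hand computation: t = 0.7 / sqrt(2 * 0.0025 / 3)
    assert abs(res.statistic) == pytest.approx(0.7 / np.sqrt(2 * 0.0025 / 3), rel=1e-6)
    assert res.pvalue < 1e-3


def test_welch_test_degenerate_conventions():
    assert compare_populations([0.5, 0.5], [0.5, 0.5]) == (0.0, 1.0)
    ident = compare_populations([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
    assert ident.statistic == 0.0 and ident.pvalue == 1.0
    with pytest.raises(ValueError):
        compare_populations([0.5], [0.4, 0.6])


def test_paper_scale_separation_is_highly_significant():
    """9 vs 9 populations at a 50%- vs 90%-viability separation: p < 1e-4."""
    rng = np.random.default_rng(4)
    sensitized = np.clip(rng.normal(0.50, 0.05, 9), 0, 1.5)
    wildtype = np.clip(rng.normal(0.90, 0.05, 9), 0, 1.5)
    assert compare_populations(sensitized, wildtype).pvalue < 1e-4


def test_holm_adjustment_monotone():
    p = [0.001, 0.02, 0.04, 0.5]
    adj = holm_adjust(p)
    assert (adj >= np.asarray(p)).all()
    assert (np.sort(adj) == adj[np.argsort(p)]).all()
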