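import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popgate.gating import (
    _mannwhitney_z,
    drift_control,
    gating_permutation_test,
    gating_ratio,
    label_populations,
    selectivity_regression,
)
from popgate.recordings import (
    EffectSizes,
    NeuronSpec,
    RecordingSet,
    generate_recording,
    sample_neurons,
)


def test_mannwhitney_matches_scipy(rng):
    rates = rng.poisson(5, size=(8, 60)).astype(float)
    mask = rng.random(60) < 0.5
    z, p = _mannwhitney_z(rates, mask)
    for i in range(8):
        ref = stats.mannwhitneyu(
            rates[i, mask], rates[i, ~mask], alternative="two-sided",
            method="asymptotic",
        )
        assert p[i] == pytest.approx(ref.pvalue, rel=1e-10)


def test_label_recovery_on_planted_populations(a1_recording):
    rec, specs = a1_recording
    labels = label_populations(rec)
    truth = np.array([s.pop for s in specs])
    assert np.mean(labels.labels == truth) >= 0.85


def test_labels_use_sign_of_rate_difference(a1_recording):
    rec, specs = a1_recording
    labels = label_populations(rec)
    pre = rec.rates(rec.pre_window)
    in_a = (rec.meta["context"] == "A").to_numpy()
    for pop in ("A", "B"):
        m = labels.mask(pop)
        diff = pre[m][:, in_a].mean(axis=1) - pre[m][:, ~in_a].mean(axis=1)
        # preferred context = lower firing there
        assert np.all(diff < 0) if pop == "A" else np.all(diff > 0)


def test_null_generator_respects_fdr(null_recording):
    rec, _ = null_recording
    labels = label_populations(rec, alpha=0.05)
    assert np.mean(labels.labels != "0") <= 0.05


def _hand_made_recording(sep_pref, sep_nonpref):
    """Two neurons with exactly controlled go/no-go cell means.

    Counts are deterministic so the gating ratio is a hand computation:
    the output axis is the normalised overall go-minus-no-go difference,
    and the ratio is (separation along it in context A) over (context B).
    """
    from popgate.recordings import _trial_table

    meta = _trial_table(4, 2)
    counts = np.zeros((2, len(meta), 25), dtype=int)
    go = (meta["response"] != 0).to_numpy()
    in_a = (meta["context"] == "A").to_numpy()
    # neuron 0 carries the whole separation; neuron 1 is flat
    counts[0, go & in_a, 20:] = sep_pref
    counts[0, go & ~in_a, 20:] = sep_nonpref
    return RecordingSet(counts=counts, meta=meta)


def test_gating_ratio_hand_computed():
    """Separations 3.0 (preferred) vs 1.5 (other context) give ratio 2."""
    rec = _hand_made_recording(3, 1)  # counts per bin: rates 60 vs 20 Hz
    table = pd.DataFrame({"label": ["A", "A"], "z": [0, 0], "p": [0, 0],
                          "p_adj": [0, 0], "testable": [True, True]})
    from popgate.gating import PopulationLabels

    labels = PopulationLabels(table=table, alpha=0.05)
    res = gating_ratio(rec, labels, "A")
    assert res.ratio == pytest.approx(3.0)  # 60 Hz vs 20 Hz separation
    rec2 = _hand_made_recording(3, 0)
    with pytest.warns(UserWarning, match="infinite"):
        res2 = gating_ratio(rec2, labels, "A")
    assert np.isinf(res2.ratio)


def test_gating_ratio_symmetric_construction_is_one():
    rec = _hand_made_recording(2, 2)
    from popgate.gating import PopulationLabels

    table = pd.DataFrame({"label": ["A", "A"], "z": [0, 0], "p": [0, 0],
                          "p_adj": [0, 0], "testable": [True, True]})
    res = gating_ratio(rec, PopulationLabels(table=table, alpha=0.05), "A")
    assert res.ratio == pytest.approx(1.0)


def test_permutation_test_contract():
    rec = _hand_made_recording(2, 1)
    with pytest.raises(ValueError, match="n_perm"):
        gating_permutation_test(rec, "A", n_perm=0, seed=0)


def test_planted_gating_significant_pop0_not(a1_recording):
    rec, _ = a1_recording
    for pop, expect_sig in (("A", True), ("B", True), ("0", False)):
        res = gating_permutation_test(rec, pop, n_perm=200, seed=1)
        if expect_sig:
            assert res.p_value < 0.05
        else:
            assert res.p_value > 0.05


def test_permutation_p_uniform_under_null():
    """Null-generator p-values are approximately uniform."""
    eff = EffectSizes(ctx_mod_mean=0.0, ctx_mod_sd=0.0, sensory_sd_hz=0.0,
                      gate_sd_hz=0.0)
    ps = []
    for i in range(20):
        specs = sample_neurons(40, effects=eff, seed=100 + i)
        rec = generate_recording(specs, 12, seed=200 + i)
        res = gating_permutation_test(rec, "0", n_perm=79, seed=300 + i)
        ps.append(res.p_value)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01
    assert np.mean(np.array(ps) > 0.25) > 0.5


def test_selectivity_regression_planted_classes():
    base = dict(baseline_hz=20.0, ctx_mod=0.0, w_loc=0.0, w_pitch=0.0,
                gate_hz=0.0, pop="0")
    specs = [
        NeuronSpec(**{**base, "w_loc": 8.0}),  # pure location
        NeuronSpec(**{**base, "w_loc": 8.0, "pop": "A", "ctx_mod": -0.5}),  # mixed
        NeuronSpec(**base),  # null
    ]
    rec = generate_recording(specs, 60, seed=2)
    table = selectivity_regression(rec)
    assert table.loc[0, "class"] == "pure" and table.loc[0, "p_location"] < 0.05
    assert table.loc[1, "class"] == "mixed"
    assert table.loc[1, "p_location"] < 0.05 and table.loc[1, "p_context"] < 0.05


def test_selectivity_false_positive_rate_on_null_neurons():
    base = dict(baseline_hz=15.0, ctx_mod=0.0, w_loc=0.0, w_pitch=0.0,
                gate_hz=0.0, pop="0")
    specs = [NeuronSpec(**base) for _ in range(100)]
    rec = generate_recording(specs, 30, seed=3)
    table = selectivity_regression(rec)
    for nm in ("location", "pitch", "decision", "context"):
        assert (table[f"p_{nm}"] < 0.05).mean() <= 0.11  # ~5% nominal


def test_most_planted_neurons_are_mixed_selective(a1_recording):
    rec, _ = a1_recording
    table = selectivity_regression(rec)
    assert (table["class"] == "mixed").mean() > 0.3


def test_drift_control_flags_planted_drift():
    base = dict(baseline_hz=15.0, ctx_mod=0.0, w_loc=0.0, w_pitch=0.0,
                gate_hz=0.0, pop="0")
    specs = [
        NeuronSpec(**base, drift_hz_per_block=3.0),  # drift, no context effect
        NeuronSpec(**{**base, "ctx_mod": -0.5, "pop": "A"}),  # identity effect
        NeuronSpec(**{**base, "baseline_hz": 0.0}),  # constant (silent)
    ]
    rec = generate_recording(specs, 40, seed=4, n_blocks=8)
    rep = drift_control(rec)
    assert bool(rep.loc[0, "drift_flag"])
    assert not bool(rep.loc[1, "drift_flag"]) and rep.loc[1, "p_identity"] < 0.05
    assert not bool(rep.loc[2, "testable"])


def test_windows_are_structurally_separate(a1_recording):
    """Labelling reads only pre-stimulus bins; ratios only stimulus bins."""
    rec, _ = a1_recording
    labels = label_populations(rec)
    tampered = RecordingSet(
        counts=rec.counts.copy(), meta=rec.meta, n_pre_bins=rec.n_pre_bins,
        n_stim_bins=rec.n_stim_bins,
    )
    tampered.counts[:, :, tampered.stim_window] = 0  # destroy stimulus epoch
    labels2 = label_populations(tampered)
    assert np.array_equal(labels.labels, labels2.labels)
    tampered2 = RecordingSet(
        counts=rec.counts.copy(), meta=rec.meta, n_pre_bins=rec.n_pre_bins,
        n_stim_bins=rec.n_stim_bins,
    )
    tampered2.counts[:, :, tampered2.pre_window] = 0  # destroy pre-stimulus
    r1 = gating_ratio(rec, labels, "A").ratio
    r2 = gating_ratio(tampered2, labels, "A").ratio
    assert r1 == pytest.approx(r2)
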