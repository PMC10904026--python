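"""Training/testing protocol: rate estimation, trials, ISI, test battery."""

import numpy as np
import pytest

import braincat as bc
from braincat import network as net
from braincat import protocol as proto


def _rate_oracle(train, tau):
    """Independent closed form of the Euler recursion."""
    n = len(train)
    return sum((1 / tau) * (1 - 1 / tau) ** (n - 1 - k) * train[k]
               for k in range(n))


@pytest.mark.parametrize("train", [
    [0] * 30,
    [1] * 30,
    [1] + [0] * 29,
    [0, 1, 0, 1, 1, 0] * 5,
])
@pytest.mark.parametrize("tau", [5.0, 30.0])
def test_estimate_rate_matches_recursion_oracle(train, tau):
    assert bc.estimate_rate(train, tau) == pytest.approx(
        _rate_oracle(train, tau), abs=1e-12)


def test_estimate_rate_special_values():
    assert bc.estimate_rate([0] * 30, 5.0) == 0.0
    full = bc.estimate_rate([1] * 30, 5.0)
    assert 0 < full < 1
    assert full == pytest.approx(1 - (1 - 1 / 5) ** 30, abs=1e-12)
    # a single early spike decays by (1 - 1/tau) per step
    one = bc.estimate_rate([1, 0, 0], 5.0)
    assert one == pytest.approx((1 / 5) * (1 - 1 / 5) ** 2, abs=1e-12)
    with pytest.raises(ValueError):
        bc.estimate_rate([1], 0.0)


def test_condition_table():
    assert proto.CONDITIONS["NoS"].trials_per_instance == 2000
    assert proto.CONDITIONS["CT"].trials_per_instance == 2000
    assert proto.CONDITIONS["PN"].trials_per_instance == 2000
    assert proto.CONDITIONS["CT_1x"].trials_per_instance == 1000
    assert proto.CONDITIONS["PN_3x"].trials_per_instance == 3000
    assert proto.CONDITIONS["NoS_1x"].trials_per_instance == 1000
    assert proto.CONDITIONS["NoS_3x"].trials_per_instance == 3000
    assert proto.MAIN_DESIGN == ("NoS", "CT", "PN")
    assert len(proto.CONTROL_DESIGN) == 4


def test_trial_spec_symbol_pairing(battery2):
    ct = proto.make_trial_spec(battery2, 0, proto.CONDITIONS["CT"])
    assert set(ct.inputs) == {"V1", "M1_L", "A1", "M1_i"}
    assert ct.inputs["A1"] == battery2.ct_words[0].cells("A1")
    # all trained instances of a category share the CT word form
    ct2 = proto.make_trial_spec(battery2, 1, proto.CONDITIONS["CT"])
    assert ct2.inputs["A1"] == ct.inputs["A1"]

    pn = proto.make_trial_spec(battery2, 0, proto.CONDITIONS["PN"])
    assert pn.inputs["A1"] == battery2.pn_words[0].cells("A1")
    pn2 = proto.make_trial_spec(battery2, 1, proto.CONDITIONS["PN"])
    assert pn2.inputs["A1"] != pn.inputs["A1"]

    nos = proto.make_trial_spec(battery2, 0, proto.CONDITIONS["NoS"])
    assert set(nos.inputs) == {"V1", "M1_L"}
    assert not nos.has_word_form

    with pytest.raises(ValueError):
        proto.make_trial_spec(battery2, 3, proto.CONDITIONS["NoS"])  # novel


def test_isi_resets_state(model_a):
    st = net.NetworkState.zeros()
    st.Ve[:] = 0.5
    st.wG[:] = 50.0
    _, steps = proto.run_isi(model_a, st, seed=1)
    assert steps <= model_a.params.isi_cap
    assert st.Ve.max() == 0.0 and st.Vi.max() == 0.0
    assert st.wA.max() == 0.0 and st.wG.max() == 0.0
    # already-quiet network returns almost immediately
    _, steps2 = proto.run_isi(model_a, st, seed=2)
    assert steps2 <= 5


def test_training_bookkeeping(model_a, battery2):
    m = model_a.copy()
    log = bc.run_training(m, battery2, "CT", rng_seed=0, trial_scale=2 / 2000)
    assert log.trials == 2 * 6          # 2 epochs x 6 trained instances
    assert log.epochs == 2
    # each CT word form appears once per member instance per epoch
    assert sorted(log.word_form_trials.values()) == [6, 6]
    assert log.dw_effective == pytest.approx(m.params.delta_w * 1000)

    m2 = model_a.copy()
    log2 = bc.run_training(m2, battery2, "PN", rng_seed=0, trial_scale=2 / 2000)
    assert sorted(log2.word_form_trials.values()) == [2] * 6

    m3 = model_a.copy()
    log3 = bc.run_training(m3, battery2, "NoS", rng_seed=0, trial_scale=2 / 2000)
    assert log3.word_form_trials == {}


def test_test_battery_shape_determinism_and_weight_safety(model_a, battery2):
    m = model_a.copy()
    before = m.weight_checksum()
    r1 = bc.run_test_battery(m, battery2, rng_seed=9)
    r2 = bc.run_test_battery(m, battery2, rng_seed=9)
    assert m.weight_checksum() == before           # testing never learns
    assert len(r1) == battery2.n_instances
    assert r1[0].rates.shape == (12, 625)
    assert all(0 <= r.rates.min() and r.rates.max() <= 1 for r in r1)
    for a, b in zip(r1, r2):
        assert np.array_equal(a.rates, b.rates)    # same seed, same responses


def test_responses_identify_instances_not_noise(model_a, battery2):
    """Same instance under different noise streams stays far closer than
    different instances (reset correctness / position invariance)."""
    m = model_a.copy()
    r1 = bc.run_test_battery(m, battery2, rng_seed=1)
    r2 = bc.run_test_battery(m, battery2, rng_seed=2)
    same = np.linalg.norm(r1[0].rates - r2[0].rates)
    diff = np.linalg.norm(r1[0].rates - r1[1].rates)
    assert same < diff


def test_cue_ignites_trained_circuits_only(model_a, battery2):
    """After training, a V1-only cue spreads to higher areas; untrained, not."""
    trained = model_a.copy()
    bc.run_training(trained, battery2, "NoS", rng_seed=3, trial_scale=60 / 2000)

    def extras_spikes(model):
        st = net.NetworkState.zeros()
        stim = net.stim_mask_from({"V1": battery2.instance(0).cells("V1")})
        amp = net.noise_amplitudes(model.params, "test")
        total = np.zeros(12, dtype=np.int64)
        for t in range(30):
            _, _, sp = net.run_network(model, st, 1,
                                       stim_mask=stim if t < 2 else None,
                                       noise_e_area=amp, tau_favg=5.0,
                                       seed=500 + t)
            total += sp
        from braincat.architecture import AREA_INDEX
        return sum(total[AREA_INDEX[a]] for a in ("TO", "AT"))

    assert extras_spikes(trained) > 3 * max(extras_spikes(model_a), 1)


def test_run_study_layout(battery2):
    study = bc.run_study([5], battery2, design="main", trial_scale=2 / 2000,
                         keep_models=True)
    assert study.conditions == ("NoS", "CT", "PN")
    assert study.n_instantiations == 1
    assert len(study.responses[0]) == 3
    assert len(study.responses[0][0]) == battery2.n_instances
    assert set(study.models) == {(0, "NoS"), (0, "CT"), (0, "PN")}
    for model in study.models.values():
        assert model.w.min() >= 0 and model.w.max() <= model.params.w_max + 1e-12


def test_control_design_word_form_balance(model_a, battery2):
    """CT_1x and PN_3x equalize presentations per word form (3000 at full
    scale); the per-symbol trial counts scale with the compressed schedule."""
    m = model_a.copy()
    log_ct = bc.run_training(m, battery2, "CT_1x", rng_seed=1,
                             trial_scale=2 / 1000)
    # each CT symbol: 3 member instances x epochs
    assert all(v == 3 * log_ct.epochs for v in log_ct.word_form_trials.values())

    m2 = model_a.copy()
    log_pn = bc.run_training(m2, battery2, "PN_3x", rng_seed=1,
                             trial_scale=2 / 3000)
    assert all(v == log_pn.epochs for v in log_pn.word_form_trials.values())
    # at full scale both designs give 3000 trials per word form
    assert proto.CONDITIONS["CT_1x"].trials_per_instance * 3 == 3000
    assert proto.CONDITIONS["PN_3x"].trials_per_instance == 3000
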