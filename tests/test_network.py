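"""Cell dynamics, initialization, plasticity rule, activity regulation."""

import numpy as np
import pytest

import braincat as bc
from braincat import network as net
from braincat.architecture import AREA_INDEX


def test_initialization_is_deterministic_and_weak():
    m1 = bc.initialize_model(rng_seed=5)
    m2 = bc.initialize_model(rng_seed=5)
    assert np.array_equal(m1.w, m2.w)
    assert np.array_equal(m1.csc_rows, m2.csc_rows)
    m3 = bc.initialize_model(rng_seed=6)
    assert not np.array_equal(m1.w, m3.w)
    # initially weak: mean weight far below the learned ceiling
    assert 0 < m1.w.mean() < m1.params.w_max / 3
    assert m1.w.min() >= 0


def test_no_autapses(model_a):
    col = model_a.csc_col_index()
    assert not np.any(col == model_a.csc_rows)


def test_in_degree_near_target(model_a):
    indeg = np.diff(model_a.csr_indptr)
    p = model_a.params
    # V1 receives from 2 areas, PB from 6; within-area links add ~50 more
    v1 = indeg[AREA_INDEX["V1"] * 625:(AREA_INDEX["V1"] + 1) * 625].mean()
    pb = indeg[AREA_INDEX["PB"] * 625:(AREA_INDEX["PB"] + 1) * 625].mean()
    assert v1 == pytest.approx(p.within_indegree + 2 * p.between_indegree, rel=0.2)
    assert pb == pytest.approx(p.within_indegree + 6 * p.between_indegree, rel=0.2)


def test_quiescent_fixed_point(model_a, quiet_params):
    """No input and no noise: the zero state is a fixed point."""
    m = model_a.copy()
    m.params = quiet_params
    st = net.NetworkState.zeros()
    net.run_network(m, st, 10, noise_e_area=np.zeros(12), seed=0)
    assert st.Ve.max() == 0.0
    assert st.phi.sum() == 0
    assert st.wA.max() == st.wE.max() == st.wG.max() == 0.0


def test_subthreshold_drive_follows_exponential_approach(model_a):
    """Constant subthreshold drive: V follows the discretized exponential."""
    m = model_a.copy()
    m.params = bc.ModelParams(noise_amp=0.0, stim_strength=0.1)  # below thresh
    st = net.NetworkState.zeros()
    stim = np.zeros(net.N_E)
    cell = AREA_INDEX["V1"] * 625 + 40
    stim[cell] = 1.0
    tau = m.params.tau_e
    trace = []
    for _ in range(12):
        net.run_network(m, st, 1, stim_mask=stim, noise_e_area=np.zeros(12), seed=0)
        trace.append(st.Ve[cell])
    expected = [0.1 * (1 - (1 - 1 / tau) ** (t + 1)) for t in range(12)]
    assert np.allclose(trace, expected, atol=1e-12)
    assert st.phi.sum() == 0  # never crossed threshold


def test_adaptation_interrupts_sustained_firing(model_a):
    """Suprathreshold drive: adaptation (alpha=8) forces pauses in the train."""
    m = model_a.copy()
    m.params = bc.ModelParams(noise_amp=0.0, stim_strength=1.0)
    st = net.NetworkState.zeros()
    stim = np.zeros(net.N_E)
    cell = AREA_INDEX["V1"] * 625 + 300
    stim[cell] = 1.0
    spikes = []
    for _ in range(60):
        net.run_network(m, st, 1, stim_mask=stim, noise_e_area=np.zeros(12), seed=0)
        spikes.append(int(st.phi[cell]))
    assert sum(spikes) >= 3           # it does fire
    assert 0 in spikes[spikes.index(1):]  # and pauses after firing began
    # long-run duty is adaptation-limited well below 100%
    assert sum(spikes) / len(spikes) < 0.6


def _single_synapse_setup(model):
    """Pick one synapse and return (model copy, slot, pre, post)."""
    m = model.copy()
    slot = 0
    post = int(m.csc_rows[slot])
    pre = int(m.csc_col_index()[slot])
    return m, slot, pre, post


@pytest.mark.parametrize("pre_rate,post_pot,w0,expected", [
    (0.06, 0.20, 0.01, 0.0108),    # LTP: pre eligible, post above theta_plus
    (0.06, 0.145, 0.01, 0.0092),   # LTD: post inside [theta_minus, theta_plus)
    (0.01, 0.20, 0.01, 0.01),      # ineligible presynaptic cell: no change
    (0.06, 0.10, 0.01, 0.01),      # post below theta_minus: no change
])
def test_hebbian_rule_arithmetic(model_a, pre_rate, post_pot, w0, expected):
    m, slot, pre, post = _single_synapse_setup(model_a)
    m.w[:] = 0.5
    m.w[slot] = w0
    rates = np.zeros(net.N_E)
    pots = np.zeros(net.N_E)
    rates[pre] = pre_rate
    pots[post] = post_pot
    net.hebbian_update(m, rates, pots)
    assert m.w[slot] == pytest.approx(expected, abs=1e-12)


def test_hebbian_update_matches_bruteforce_oracle(model_a):
    """Vectorized rule equals an independent per-synapse double loop."""
    m = model_a.copy()
    rng = np.random.default_rng(0)
    rates = rng.uniform(0, 0.2, net.N_E)
    pots = rng.uniform(0, 0.3, net.N_E)
    p = m.params
    col = m.csc_col_index()
    # oracle on a contiguous slice of synapses
    sl = slice(0, 5000)
    expected = m.w[sl].copy()
    for k in range(sl.stop):
        if rates[col[k]] >= p.theta_pre:
            v = pots[m.csc_rows[k]]
            if v >= p.theta_plus:
                expected[k] = min(expected[k] + p.delta_w, p.w_max)
            elif v >= p.theta_minus:
                expected[k] = max(expected[k] - p.delta_w, 0.0)
    net.hebbian_update(m, rates, pots)
    assert np.allclose(m.w[sl], expected, atol=1e-15)


def test_weights_stay_bounded_under_plasticity(model_a, battery2):
    m = model_a.copy()
    spec_inputs = {a: battery2.instance(0).cells(a) for a in ("V1", "M1_L")}
    stim = net.stim_mask_from(spec_inputs)
    amps = net.noise_amplitudes(m.params, "train", stimulated_areas=list(spec_inputs))
    st = net.NetworkState.zeros()
    for k in range(6):
        net.run_network(m, st, 16, stim_mask=stim, noise_e_area=amps,
                        plastic=True, dw=0.5, seed=k)
    assert m.w.min() >= 0.0
    assert m.w.max() <= m.params.w_max + 1e-12


def test_global_activity_measure(model_a):
    st = net.NetworkState.zeros()
    assert bc.global_activity(model_a, st, "V1") == 0.0
    st.wG[AREA_INDEX["V1"]] = 100.0
    p = model_a.params
    assert bc.global_activity(model_a, st, "V1") == pytest.approx(
        p.k1 * p.kG * 100.0)
    # decays below the reset threshold with no input
    m = model_a.copy()
    m.params = bc.ModelParams(noise_amp=0.0)
    st.wG[:] = 100.0
    net.run_network(m, st, 60, noise_e_area=np.zeros(12), seed=0)
    assert all(bc.global_activity(m, st, a) < 0.18 for a in bc.AREA_NAMES)


def test_noise_amplitudes_by_phase():
    p = bc.ModelParams()
    amp = net.noise_amplitudes(p, "train", stimulated_areas=("V1", "M1_L"))
    for name in ("V1", "M1_L"):
        assert amp[AREA_INDEX[name]] == p.noise_amp
    for name in ("A1", "M1_i", "TO", "AT"):
        assert amp[AREA_INDEX[name]] == p.noise_amp * p.extra_noise_factor
    assert np.all(net.noise_amplitudes(p, "test") == p.noise_amp)
    assert np.all(net.noise_amplitudes(p, "isi") == p.noise_amp)
    with pytest.raises(ValueError):
        net.noise_amplitudes(p, "bogus")


def test_noise_seeded_repeatability(model_a, battery2):
    m = model_a.copy()
    stim = net.stim_mask_from({a: battery2.instance(0).cells(a)
                               for a in ("V1", "M1_L")})
    outs = []
    for _ in range(2):
        st = net.NetworkState.zeros()
        _, _, spikes = net.run_network(m, st, 20, stim_mask=stim, seed=123)
        outs.append((spikes.copy(), st.Ve.copy()))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])


def test_model_save_load_roundtrip(model_a, tmp_path):
    path = tmp_path / "model.npz"
    model_a.save(path)
    m2 = net.NetworkModel.load(path)
    assert np.array_equal(model_a.w, m2.w)
    assert np.array_equal(model_a.csc_indptr, m2.csc_indptr)
    assert m2.params.w_max == model_a.params.w_max
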