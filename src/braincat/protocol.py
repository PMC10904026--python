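"""Training and testing protocol.

Training presents each trained instance's grounding pattern to V1/M1_L for 16
steps with plasticity on — alone (NoS), together with its category's word
form (CT), or with its own proper name (PN) in A1/M1_i. Consecutive trials
are separated by a noise-only interstimulus interval that ends once every
area's slow activity measure has returned below baseline (thresh), after
which the whole state is zeroed, so trial order carries no information.

Testing is symbol-free: each of the 60 instances (trained and novel) drives
V1/M1_L for 2 steps with its pure grounding pattern, the network then runs
freely for 28 more steps, and the response is the per-cell firing-rate
estimate (tau_favg = 5) at step 30.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import network as net
from .architecture import AREA_NAMES, AREA_INDEX
from .params import ModelParams
from .patterns import StimulusSet, GroundingPattern

logger = logging.getLogger(__name__)

TRIAL_STEPS = 16
TEST_STIM_STEPS = 2
TEST_TOTAL_STEPS = 30

GROUNDING_AREAS = ("V1", "M1_L")
WORDFORM_AREAS = ("A1", "M1_i")


class RunawayActivityError(RuntimeError):
    """Raised when area activity stays above the runaway ceiling too long."""


@dataclass(frozen=True)
class Condition:
    label: str
    trials_per_instance: int
    symbol_pairing: str   # "none" | "category-term" | "proper-name"


CONDITIONS: dict[str, Condition] = {
    "NoS": Condition("NoS", 2000, "none"),
    "CT": Condition("CT", 2000, "category-term"),
    "PN": Condition("PN", 2000, "proper-name"),
    "NoS_1x": Condition("NoS_1x", 1000, "none"),
    "NoS_3x": Condition("NoS_3x", 3000, "none"),
    "CT_1x": Condition("CT_1x", 1000, "category-term"),
    "PN_3x": Condition("PN_3x", 3000, "proper-name"),
}
MAIN_DESIGN = ("NoS", "CT", "PN")
CONTROL_DESIGN = ("NoS_1x", "NoS_3x", "CT_1x", "PN_3x")


@dataclass(frozen=True)
class TrialSpec:
    """One training trial: which cells are driven in which areas for 16 steps."""

    instance_id: int
    inputs: dict[str, frozenset[int]]   # area -> cells
    duration: int = TRIAL_STEPS

    @property
    def has_word_form(self) -> bool:
        return any(a in self.inputs for a in WORDFORM_AREAS)


@dataclass
class TestResponse:
    instance_id: int
    rates: np.ndarray   # (n_areas, 625) rate estimates at the last recorded step

    def area_rates(self, area: str) -> np.ndarray:
        return self.rates[AREA_INDEX[area]]


@dataclass
class TrainingLog:
    condition: str
    trials_per_instance: int
    dw_effective: float
    epochs: int = 0
    trials: int = 0
    weight_change_l1: list = field(default_factory=list)   # per epoch
    spikes_per_area: np.ndarray | None = None              # totals over training
    isi_steps: list = field(default_factory=list)          # per epoch mean
    isi_cap_hits: int = 0
    word_form_trials: dict = field(default_factory=dict)   # symbol_id -> trial count


def make_trial_spec(stimuli: StimulusSet, instance_id: int, condition: Condition) -> TrialSpec:
    g = stimuli.instance(instance_id)
    if not g.trained:
        raise ValueError(f"instance {instance_id} is novel; only trained instances are presented")
    inputs: dict[str, frozenset[int]] = {a: g.cells(a) for a in GROUNDING_AREAS}
    if condition.symbol_pairing == "category-term":
        w = stimuli.ct_words[g.category_id]
        for a in WORDFORM_AREAS:
            inputs[a] = w.cells(a)
    elif condition.symbol_pairing == "proper-name":
        w = stimuli.pn_words[instance_id]
        for a in WORDFORM_AREAS:
            inputs[a] = w.cells(a)
    elif condition.symbol_pairing != "none":
        raise ValueError(f"unknown symbol pairing {condition.symbol_pairing!r}")
    return TrialSpec(instance_id=instance_id, inputs=inputs)


def estimate_rate(spike_train, tau_favg: float) -> float:
    """Firing-rate estimate: forward-Euler solution of tau*dw/dt = -w + phi.

    Starts from w(0) = 0 and returns the value after the last sample.
    """
    if tau_favg <= 0:
        raise ValueError("tau_favg must be > 0")
    w = 0.0
    inv = 1.0 / tau_favg
    for phi in spike_train:
        w += inv * (-w + float(phi))
    return w


def run_isi(model: net.NetworkModel, state: net.NetworkState,
            seed: int = -1) -> tuple[net.NetworkState, int]:
    """Noise-only waiting interval, then hard zero of the whole state.

    Runs until the slow activity measure k1*kG*wG has fallen below the
    baseline threshold in all areas (cap isi_cap steps), then zeroes all
    membrane potentials and auxiliary variables. Plasticity is off.
    """
    p = model.params
    amp = net.noise_amplitudes(p, "isi")
    steps, _, _ = net.run_network(
        model, state, p.isi_cap, noise_e_area=amp,
        tau_favg=p.tau_favg_train, plastic=False,
        stop_below=p.thresh, seed=seed,
    )
    if steps >= p.isi_cap:
        logger.warning("ISI cap (%d steps) reached; forcing reset", p.isi_cap)
    state.reset()
    return state, steps


def run_training(model: net.NetworkModel, stimuli: StimulusSet,
                 condition: Condition | str, rng_seed: int,
                 trial_scale: float = 1.0) -> TrainingLog:
    """Train a model in place under one condition; returns the training log.

    trial_scale compresses the schedule: trials_per_instance is multiplied by
    trial_scale and the learning rate divided by it, conserving the cumulative
    plasticity budget (see docs/methods.md). trial_scale=1 reproduces the full
    design with the nominal learning rate.
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    p = model.params
    n_epochs = max(1, round(condition.trials_per_instance * trial_scale))
    dw_eff = p.delta_w / trial_scale
    trained = stimuli.trained_instances()
    specs = {g.instance_id: make_trial_spec(stimuli, g.instance_id, condition)
             for g in trained}
    masks = {i: net.stim_mask_from(s.inputs) for i, s in specs.items()}
    stim_areas = {i: tuple(s.inputs) for i, s in specs.items()}
    amps = {i: net.noise_amplitudes(p, "train", stimulated_areas=stim_areas[i])
            for i in specs}

    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0x7EA1]))
    log = TrainingLog(condition=condition.label,
                      trials_per_instance=n_epochs,
                      dw_effective=dw_eff)
    log.spikes_per_area = np.zeros(len(AREA_NAMES), dtype=np.int64)
    instance_ids = np.array(sorted(specs))
    state = net.NetworkState.zeros()
    state.reset()
    runaway_state = np.zeros(1, dtype=np.int64)

    for _epoch in range(n_epochs):
        order = rng.permutation(instance_ids)
        w_before = model.w.copy()
        isi_epoch = []
        for inst in order:
            kseed = int(rng.integers(2**31))
            _, runaway, spikes = net.run_network(
                model, state, TRIAL_STEPS,
                stim_mask=masks[inst], noise_e_area=amps[inst],
                tau_favg=p.tau_favg_train, plastic=True, dw=dw_eff,
                seed=kseed, runaway_state=runaway_state,
            )
            log.spikes_per_area += spikes
            if runaway:
                raise RunawayActivityError(
                    f"area activity above ceiling for >100 consecutive steps "
                    f"(condition {condition.label}, instance {inst})")
            _, isi_steps = run_isi(model, state, seed=int(rng.integers(2**31)))
            if isi_steps >= p.isi_cap:
                log.isi_cap_hits += 1
            isi_epoch.append(isi_steps)
            log.trials += 1
            if specs[inst].has_word_form:
                wfp = (stimuli.ct_words[stimuli.instance(inst).category_id]
                       if condition.symbol_pairing == "category-term"
                       else stimuli.pn_words[inst])
                log.word_form_trials[wfp.symbol_id] = \
                    log.word_form_trials.get(wfp.symbol_id, 0) + 1
        log.weight_change_l1.append(float(np.abs(model.w - w_before).sum()))
        log.isi_steps.append(float(np.mean(isi_epoch)))
        log.epochs += 1
    return log


def run_test_battery(model: net.NetworkModel, stimuli: StimulusSet,
                     rng_seed: int = 0) -> list[TestResponse]:
    """Symbol-free test of all instances (trained + novel); plasticity off.

    Each trial: full reset, 2 steps of pure grounding stimulation of V1/M1_L,
    28 free-running steps, response read from the tau_favg=5 rate estimate at
    step 30, then an interstimulus reset.
    """
    p = model.params
    amp = net.noise_amplitudes(p, "test")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0x7E57]))
    state = net.NetworkState.zeros()
    out: list[TestResponse] = []
    for g in sorted(stimuli.grounding, key=lambda x: x.instance_id):
        state.reset()
        stim = net.stim_mask_from({a: g.cells(a) for a in GROUNDING_AREAS})
        net.run_network(model, state, TEST_STIM_STEPS, stim_mask=stim,
                        noise_e_area=amp, tau_favg=p.tau_favg_test,
                        plastic=False, seed=int(rng.integers(2**31)))
        net.run_network(model, state, TEST_TOTAL_STEPS - TEST_STIM_STEPS,
                        noise_e_area=amp, tau_favg=p.tau_favg_test,
                        plastic=False, seed=int(rng.integers(2**31)))
        rates = state.wE.reshape(len(AREA_NAMES), -1).copy()
        out.append(TestResponse(instance_id=g.instance_id, rates=rates))
        run_isi(model, state, seed=int(rng.integers(2**31)))
    return out


@dataclass
class StudyResult:
    """Trained models' test responses for every (instantiation, condition)."""

    design: str
    conditions: tuple[str, ...]
    seeds: tuple[int, ...]
    stimuli: StimulusSet
    # responses[i][c] -> list[TestResponse] for instantiation i, condition c
    responses: list[list[list[TestResponse]]]
    logs: dict = field(default_factory=dict)    # (inst_idx, label) -> TrainingLog
    models: dict = field(default_factory=dict)  # (inst_idx, label) -> NetworkModel (if kept)

    @property
    def n_instantiations(self) -> int:
        return len(self.responses)


def run_study(seeds, stimuli: StimulusSet, params: ModelParams | None = None,
              design: str = "main", trial_scale: float = 1.0,
              keep_models: bool = False,
              progress: bool = False) -> StudyResult:
    """Run the whole within-subject study.

    Each instantiation (one entry of `seeds`) is initialized once and cloned
    into every condition of the design before training, so conditions share
    identical initial weights within an instantiation.
    """
    params = params or ModelParams()
    labels = MAIN_DESIGN if design == "main" else CONTROL_DESIGN
    result = StudyResult(design=design, conditions=tuple(labels),
                         seeds=tuple(int(s) for s in seeds),
                         stimuli=stimuli, responses=[])
    for i, seed in enumerate(result.seeds):
        base = net.initialize_model(params=params, rng_seed=seed,
                                    instantiation_id=i)
        per_cond: list[list[TestResponse]] = []
        for c, label in enumerate(labels):
            model = base.copy()
            cond_seed = int(np.random.SeedSequence([seed, c, 1]).generate_state(1)[0] % 2**31)
            test_seed = int(np.random.SeedSequence([seed, c, 2]).generate_state(1)[0] % 2**31)
            log = run_training(model, stimuli, label, cond_seed,
                               trial_scale=trial_scale)
            result.logs[(i, label)] = log
            per_cond.append(run_test_battery(model, stimuli, rng_seed=test_seed))
            if keep_models:
                result.models[(i, label)] = model
            if progress:
                print(f"[braincat] instantiation {i} condition {label}: "
                      f"{log.trials} trials done", flush=True)
        result.responses.append(per_cond)
    return result
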