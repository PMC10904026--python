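"""Network model: initialization, state, single-step dynamics, plasticity.

A model instantiation holds one sparse excitatory weight matrix over the
concatenated e-cell population of the 12 areas (within-area and between-area
synapses together), the fixed inhibitory machinery (one i-cell per cortical
column, non-plastic), and the parameter set. Learning changes weights, never
topology; the sparsity masks are frozen at initialization.

Within-area e->e links are drawn inside a square neighbourhood with a
Gaussian distance falloff; between-area links use a topographic Gaussian
kernel between corresponding grid positions of the two linked areas. Both
kernels are rescaled so the expected in-degree of an interior cell matches
the configured target. No autapses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .architecture import AREA_NAMES, AREA_INDEX, PRIMARY_AREAS, build_architecture, ConnectivityGraph, AreaSpec
from .params import ModelParams

GRID = 25
N_PER_AREA = GRID * GRID
N_AREAS = len(AREA_NAMES)
N_E = N_AREAS * N_PER_AREA


@dataclass
class NetworkModel:
    instantiation_id: int
    init_seed: int
    params: ModelParams
    # CSC storage (column = presynaptic cell) + CSR view into the same data
    csc_indptr: np.ndarray
    csc_rows: np.ndarray
    w: np.ndarray
    csr_indptr: np.ndarray
    csr_cols: np.ndarray
    csr_perm: np.ndarray
    _csc_col: np.ndarray | None = field(default=None, repr=False)

    @property
    def nnz(self) -> int:
        return self.w.shape[0]

    def csc_col_index(self) -> np.ndarray:
        """Presynaptic (column) index of every CSC data slot."""
        if self._csc_col is None:
            self._csc_col = np.repeat(
                np.arange(N_E, dtype=np.int32), np.diff(self.csc_indptr)
            )
        return self._csc_col

    def copy(self) -> "NetworkModel":
        return replace(
            self,
            params=replace(self.params),
            w=self.w.copy(),
            _csc_col=None,
        )

    def weight_checksum(self) -> float:
        return float(self.w.sum())

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            csc_indptr=self.csc_indptr, csc_rows=self.csc_rows, w=self.w,
            csr_indptr=self.csr_indptr, csr_cols=self.csr_cols,
            csr_perm=self.csr_perm,
            meta=np.frombuffer(json.dumps({
                "instantiation_id": self.instantiation_id,
                "init_seed": self.init_seed,
                "params": self.params.__dict__,
            }).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "NetworkModel":
        z = np.load(path)
        meta = json.loads(bytes(z["meta"]).decode())
        return cls(
            instantiation_id=meta["instantiation_id"],
            init_seed=meta["init_seed"],
            params=ModelParams(**meta["params"]),
            csc_indptr=z["csc_indptr"], csc_rows=z["csc_rows"], w=z["w"],
            csr_indptr=z["csr_indptr"], csr_cols=z["csr_cols"],
            csr_perm=z["csr_perm"],
        )


@dataclass
class NetworkState:
    Ve: np.ndarray    # e-cell membrane potentials
    De: np.ndarray    # e-cell dendritic potentials (excitatory drive, no inhibition)
    phi: np.ndarray   # e-cell binary outputs
    wA: np.ndarray    # adaptation variables
    wE: np.ndarray    # rate estimates
    Vi: np.ndarray    # i-cell potentials
    Oi: np.ndarray    # i-cell graded outputs
    wG: np.ndarray    # per-area slow global-inhibition variables

    @classmethod
    def zeros(cls) -> "NetworkState":
        return cls(
            Ve=np.zeros(N_E), De=np.zeros(N_E), phi=np.zeros(N_E, dtype=np.uint8),
            wA=np.zeros(N_E), wE=np.zeros(N_E),
            Vi=np.zeros(N_E), Oi=np.zeros(N_E), wG=np.zeros(N_AREAS),
        )

    def reset(self) -> None:
        """Hard reset: zero all potentials and auxiliary variables."""
        self.Ve[:] = 0.0
        self.De[:] = 0.0
        self.phi[:] = 0
        self.wA[:] = 0.0
        self.wE[:] = 0.0
        self.Vi[:] = 0.0
        self.Oi[:] = 0.0
        self.wG[:] = 0.0


def _kernel_probs(radius: int, sigma: float, target: float,
                  include_center: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offsets (dr, dc) and connection probabilities scaled to the in-degree target."""
    drs, dcs, d2s = [], [], []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if not include_center and dr == 0 and dc == 0:
                continue
            drs.append(dr)
            dcs.append(dc)
            d2s.append(dr * dr + dc * dc)
    drs = np.array(drs)
    dcs = np.array(dcs)
    g = np.exp(-np.array(d2s, dtype=float) / (2.0 * sigma * sigma))
    p = g * (target / g.sum())
    # renormalize mass lost to the p<=1 cap (iteratively, a couple of passes)
    for _ in range(8):
        over = p > 1.0
        if not over.any():
            break
        excess = (p[over] - 1.0).sum()
        p[over] = 1.0
        room = ~over
        if p[room].sum() <= 0:
            break
        p[room] *= 1.0 + excess / p[room].sum()
    return drs, dcs, np.clip(p, 0.0, 1.0)


def _draw_projection(rng: np.random.Generator, src_area: int, dst_area: int,
                     drs, dcs, probs,
                     src_list: list, dst_list: list) -> None:
    rr, cc = np.meshgrid(np.arange(GRID), np.arange(GRID), indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    src_base = src_area * N_PER_AREA
    dst_base = dst_area * N_PER_AREA
    for dr, dc, p in zip(drs, dcs, probs):
        r2 = rr + dr
        c2 = cc + dc
        valid = (r2 >= 0) & (r2 < GRID) & (c2 >= 0) & (c2 < GRID)
        idx = np.flatnonzero(valid)
        hit = idx[rng.random(idx.size) < p]
        if hit.size:
            src_list.append(src_base + hit)
            dst_list.append(dst_base + (r2[hit] * GRID + c2[hit]))


def initialize_model(
    architecture: tuple[list[AreaSpec], ConnectivityGraph] | None = None,
    params: ModelParams | None = None,
    rng_seed: int = 0,
    instantiation_id: int = 0,
) -> NetworkModel:
    """Randomize all synaptic links and their (initially weak) weights.

    The same seed always yields an identical model.
    """
    if architecture is None:
        architecture = build_architecture()
    _, graph = architecture
    params = params or ModelParams()
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0xA11]))

    src_list: list[np.ndarray] = []
    dst_list: list[np.ndarray] = []

    drs_w, dcs_w, p_w = _kernel_probs(params.within_radius, params.within_sigma,
                                      params.within_indegree, include_center=False)
    for a in range(N_AREAS):
        _draw_projection(rng, a, a, drs_w, dcs_w, p_w, src_list, dst_list)

    radius_b = int(np.ceil(3.0 * params.between_sigma))
    drs_b, dcs_b, p_b = _kernel_probs(radius_b, params.between_sigma,
                                      params.between_indegree, include_center=True)
    for a_name, b_name in graph.directed_pairs():
        _draw_projection(rng, AREA_INDEX[a_name], AREA_INDEX[b_name],
                         drs_b, dcs_b, p_b, src_list, dst_list)

    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    nnz = src.size
    order = np.arange(nnz, dtype=np.int64)
    csc = sp.csc_matrix((order.astype(np.float64), (dst, src)), shape=(N_E, N_E))
    csc.sort_indices()
    slot_of = csc.data.astype(np.int64)            # original draw order of each CSC slot
    csr = sp.csc_matrix((np.arange(csc.nnz, dtype=np.float64),
                         csc.indices, csc.indptr), shape=(N_E, N_E)).tocsr()
    csr.sort_indices()
    perm = csr.data.astype(np.int64)               # CSR slot -> CSC data slot

    weights_by_draw = rng.uniform(0.0, params.w_init_max, nnz)
    w = weights_by_draw[slot_of]

    return NetworkModel(
        instantiation_id=int(instantiation_id),
        init_seed=int(rng_seed),
        params=params,
        csc_indptr=csc.indptr.astype(np.int64),
        csc_rows=csc.indices.astype(np.int32),
        w=w,
        csr_indptr=csr.indptr.astype(np.int64),
        csr_cols=csr.indices.astype(np.int32),
        csr_perm=perm,
    )


def stim_mask_from(external_input: Mapping[str, Iterable[int]] | None) -> np.ndarray:
    """Map {area name -> cell indices} to a global 0/1 drive mask."""
    mask = np.zeros(N_E)
    if external_input:
        for area, cells in external_input.items():
            base = AREA_INDEX[area] * N_PER_AREA
            for c in cells:
                mask[base + int(c)] = 1.0
    return mask


def noise_amplitudes(params: ModelParams, noise_mode: str,
                     stimulated_areas: Iterable[str] = ()) -> np.ndarray:
    """Per-area e-cell noise amplitude for a given phase.

    Baseline white noise is always on. During training, every area that
    receives no pattern gets the stronger uncorrelated noise standing in for
    activity unrelated to instances or symbols.
    """
    amp = np.full(N_AREAS, params.noise_amp)
    if noise_mode in ("train-stimulated", "train-unstimulated", "train"):
        stimulated = set(stimulated_areas)
        for name in AREA_NAMES:
            if name not in stimulated:
                amp[AREA_INDEX[name]] = params.noise_amp * params.extra_noise_factor
    elif noise_mode in ("test", "isi"):
        pass
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    return amp


def run_network(model: NetworkModel, state: NetworkState, n_steps: int, *,
                stim_mask: np.ndarray | None = None,
                noise_e_area: np.ndarray | None = None,
                tau_favg: float | None = None,
                plastic: bool = False,
                dw: float | None = None,
                stop_below: float = 0.0,
                seed: int = -1,
                runaway_state: np.ndarray | None = None) -> tuple[int, bool, np.ndarray]:
    """Advance the state in place; returns (steps_taken, runaway, per-area spikes)."""
    p = model.params
    pv = _kernels.pack_params(p, p.tau_favg_train if tau_favg is None else tau_favg)
    if noise_e_area is None:
        noise_e_area = np.full(N_AREAS, p.noise_amp)
    if stim_mask is None:
        stim = np.zeros(N_E)
        stim_on = False
    else:
        stim = stim_mask
        stim_on = bool(stim_mask.any())
    spikes = np.zeros(N_AREAS, dtype=np.int64)
    if runaway_state is None:
        runaway_state = np.zeros(1, dtype=np.int64)
    steps, runaway = _kernels.run_steps(
        int(n_steps), int(seed),
        state.Ve, state.De, state.phi, state.wA, state.wE, state.Vi, state.Oi, state.wG,
        model.csc_indptr, model.csc_rows, model.w,
        model.csr_indptr, model.csr_cols, model.csr_perm,
        N_AREAS,
        stim, stim_on,
        np.asarray(noise_e_area, dtype=float),
        pv,
        bool(plastic), p.delta_w if dw is None else float(dw),
        p.plasticity_gate == "somatic",
        float(stop_below),
        spikes, runaway_state,
    )
    return steps, bool(runaway), spikes


def step(model: NetworkModel, state: NetworkState,
         external_input: Mapping[str, Iterable[int]] | None = None,
         noise_mode: str = "test",
         *, plastic: bool = False, tau_favg: float | None = None,
         seed: int = -1) -> NetworkState:
    """One synchronous update of the whole network (in place; state returned)."""
    stim = stim_mask_from(external_input) if external_input else None
    amp = noise_amplitudes(model.params, noise_mode,
                           stimulated_areas=list(external_input) if external_input else ())
    if tau_favg is None:
        tau_favg = (model.params.tau_favg_test if noise_mode in ("test", "isi")
                    else model.params.tau_favg_train)
    run_network(model, state, 1, stim_mask=stim, noise_e_area=amp,
                tau_favg=tau_favg, plastic=plastic, seed=seed)
    return state


def hebbian_update(model: NetworkModel, pre_rate: np.ndarray,
                   post_potential: np.ndarray) -> None:
    """Apply one LTP/LTD sweep to all existing synapses (reference path).

    For every synapse whose presynaptic output activity (rate estimate)
    reaches theta_pre: potentiate by delta_w if the postsynaptic (dendritic)
    potential is >= theta_plus, depress by delta_w if it lies in
    [theta_minus, theta_plus).
    Weights are clamped to [0, w_max]. The training loop applies the identical
    rule inside the compiled kernel; this vectorized version is the module's
    reference implementation for single sweeps.
    """
    p = model.params
    col = model.csc_col_index()
    eligible = pre_rate[col] >= p.theta_pre
    post = post_potential[model.csc_rows]
    pot = eligible & (post >= p.theta_plus)
    dep = eligible & (post >= p.theta_minus) & (post < p.theta_plus)
    model.w[pot] += p.delta_w
    model.w[dep] -= p.delta_w
    np.clip(model.w, 0.0, p.w_max, out=model.w)


def global_activity(model: NetworkModel, state: NetworkState, area: str) -> float:
    """Aggregate area activity used for the interstimulus reset criterion.

    The slow global-inhibition variable wG low-passes the area's total e-cell
    output with tau_fglob; scaled into membrane-input units (k1*kG*wG) it is
    compared against the baseline threshold 0.18.
    """
    return float(model.params.k1 * model.params.kG * state.wG[AREA_INDEX[area]])
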