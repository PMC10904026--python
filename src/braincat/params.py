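"""Model parameters.

The named neural/learning constants (time constants, thresholds, learning
rate) are the study conditions and should normally be left at their defaults.
The implementation block below them (connectivity kernels, gains, noise and
drive amplitudes, weight ceiling) fixes scalings the model family leaves to
the implementer; see docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class ModelParams:
    # --- membrane / rate dynamics ---
    tau_e: float = 2.5          # e-cell leak time constant (steps)
    tau_i: float = 5.0          # i-cell leak time constant (steps)
    k1: float = 0.01            # total-input rescaling factor
    kG: float = 0.80            # global (area-level) inhibition strength
    thresh: float = 0.18        # spiking threshold
    alpha: float = 8.0          # adaptation strength
    tau_adapt: float = 10.0     # adaptation time constant
    tau_favg_train: float = 30.0  # firing-rate estimate time constant (training)
    tau_favg_test: float = 5.0    # firing-rate estimate time constant (testing)
    tau_fglob: float = 12.0     # global-inhibition low-pass time constant

    # --- Hebbian plasticity (LTP/LTD) ---
    theta_plus: float = 0.15    # postsynaptic potential threshold for LTP
    theta_minus: float = 0.14   # lower edge of the LTD potential band
    theta_pre: float = 0.05     # presynaptic output activity required for any change
    delta_w: float = 0.0008     # learning rate (weight increment)

    # --- implementation: connectivity ---
    within_radius: int = 4      # square neighbourhood half-width for within-area links
    within_indegree: float = 50.0   # expected within-area e->e in-degree
    within_sigma: float = 2.5       # Gaussian distance falloff (within-area)
    between_indegree: float = 100.0  # expected in-degree per afferent area
    between_sigma: float = 3.0      # topographic kernel width (between-area)
    inhib_pool: int = 5         # i-cell pooling window (inhib_pool x inhib_pool)

    # --- implementation: gains, noise, drive ---
    w_ie: float = 600.0         # i->e inhibitory weight (per column)
    g_glob: float = 2.5         # gain of the slow global-inhibition drive
    ff_inhib: float = 3.0       # fast feed-forward inhibition per area spike
    tau_ff: float = 3.0         # time constant of the fast inhibition low-pass
    plasticity_gate: str = "dendritic"  # potential gating LTP/LTD: dendritic | somatic
    w_ei: float = 0.15          # e->i pooling gain
    w_max: float = 8.0          # excitatory weight ceiling
    w_init_max: float = 2.0     # initial weights ~ U(0, w_init_max)
    noise_amp: float = 0.30     # baseline membrane noise, uniform in +-noise_amp/2
    extra_noise_factor: float = 2.0  # extra noise in unstimulated areas (training)
    stim_strength: float = 4e6      # external drive; its slow decay is the stimulus echo
    isi_cap: int = 1000         # hard cap on interstimulus-interval steps
    runaway_frac: float = 0.6   # per-area firing fraction treated as runaway

    def validate(self) -> None:
        for name in ("tau_e", "tau_i", "tau_adapt", "tau_favg_train",
                     "tau_favg_test", "tau_fglob"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.theta_minus < self.theta_plus:
            raise ValueError("theta_minus must be < theta_plus")
        if self.delta_w <= 0:
            raise ValueError("delta_w must be > 0")
        if self.w_max <= 0 or self.w_init_max < 0:
            raise ValueError("weight bounds must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        p = cls(**raw)
        p.validate()
        return p
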