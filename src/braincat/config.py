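"""Run configuration and presets."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .params import ModelParams


@dataclass
class RunConfig:
    """End-to-end run description.

    The full presets reproduce the study design (12 instantiations, 10
    categories, 2000/1000/3000 trials per instance depending on condition);
    the reduced preset compresses the schedule for desk-scale runs while
    conserving the cumulative plasticity budget (trial_scale < 1 divides the
    learning rate by the same factor — see docs/methods.md).
    """

    design: str = "main"            # "main" | "control"
    seed: int = 0
    n_instantiations: int = 12
    n_categories: int = 10
    trial_scale: float = 1.0
    out_dir: str | None = None
    make_heatmaps: bool = False
    progress: bool = False
    params: ModelParams = field(default_factory=ModelParams)

    def validate(self) -> None:
        if self.design not in ("main", "control"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_instantiations < 1 or self.n_categories < 1:
            raise ValueError("n_instantiations and n_categories must be >= 1")
        if not (0 < self.trial_scale <= 1):
            raise ValueError("trial_scale must be in (0, 1]")
        self.params.validate()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = ModelParams(**raw.pop("params", {}))
        cfg = cls(params=params, **raw)
        cfg.validate()
        return cfg


def full_main(seed: int = 0) -> RunConfig:
    return RunConfig(design="main", seed=seed)


def full_control(seed: int = 0) -> RunConfig:
    return RunConfig(design="control", seed=seed)


def reduced(seed: int = 0, design: str = "main") -> RunConfig:
    """Desk-scale preset: 3 instantiations, 3 categories, 250 trials/instance."""
    return RunConfig(design=design, seed=seed, n_instantiations=3,
                     n_categories=3, trial_scale=0.125)


PRESETS = {"full-main": full_main, "full-control": full_control,
           "reduced": reduced}
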