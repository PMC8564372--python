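"""Run configuration: one YAML/JSON document drives the whole pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from rarobust.simulate import SimulationConfig


@dataclass
class RunConfig:
    """All knobs of a pipeline run.

    Thresholds follow the analysis conventions: minimum normalized
    count 5, BH q <= 0.05, two-fold threshold for the t0-referenced
    patterns and 1.3-fold for the control-referenced COMPACT patterns.
    """

    outdir: str = "run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_count: float = 5.0
    pseudocount: float = 1.0
    q_threshold: float = 0.05
    fold_t0: float = 2.0
    fold_control: float = 1.3
    smoother_df: int = 5
    curve_tol: float = 1e-4
    curve_max_iter: int = 50
    seed: int | None = None  # overrides simulation.seed when set
    verbose: bool = False

    def __post_init__(self) -> None:
        for name in ("min_count", "pseudocount", "q_threshold", "fold_t0", "fold_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fold_t0 <= 1 or self.fold_control <= 1:
            raise ValueError("fold thresholds are linear fold changes > 1")
        if self.seed is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=int(self.seed))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        if isinstance(sim, dict):
            if "class_proportions" in sim:
                sim["class_proportions"] = dict(sim["class_proportions"])
            for key in ("times_h", "treatments", "tradeoff_u"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if isinstance(sim.get("recovery_halftime_h"), list):
                sim["recovery_halftime_h"] = tuple(sim["recovery_halftime_h"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        sim = data["simulation"]
        for key in ("times_h", "treatments", "tradeoff_u"):
            if sim.get(key) is not None:
                sim[key] = list(sim[key])
        if isinstance(sim.get("recovery_halftime_h"), tuple):
            sim["recovery_halftime_h"] = list(sim["recovery_halftime_h"])
        return data

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
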