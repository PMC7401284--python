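"""Run configuration: every analysis decision surfaced as a named key.

All paper-gap choices of the analysis (ratio convention, food-counting
unit, test-positivity directions, outcome cutoff grids, recall-completeness
filter, tie rules implied by the strict/non-strict comparisons) are plain
config keys with their defaults stated here, so an alternative reading of
the protocol is one config change away.  Configs round-trip through YAML.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from fpmiron.composition import CutoffTable, RatioMode
from fpmiron.diagnostics import DEFAULT_DIRECTIONS, Direction, OutcomeCutoffGrid, default_grids
from fpmiron.recalls import CountingMode
from fpmiron.simulate import SimulationConfig


class GridSpec(BaseModel):
    start: float
    stop: float
    step: float = Field(gt=0)


class RunConfig(BaseModel):
    """Serializable configuration for the simulate/score/compare pipeline."""

    composition_path: str = "composition.csv"
    recalls_path: str = "recalls.csv"
    hematology_path: str = "hematology.csv"
    out_dir: str = "fpmiron_out"

    iron_cutoff: float = 0.35
    ascorbic_cutoff: float = 24.0
    phytate_cutoff: float = 50.0
    ratio_cutoff: float = 1.0
    ratio_mode: RatioMode = "molar"
    counting_mode: CountingMode = "instances"
    required_days: int = Field(default=3, ge=1)
    directions: dict[str, Direction] = Field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    grids: dict[str, GridSpec] = Field(
        default_factory=lambda: {
            name: GridSpec(start=g.start, stop=g.stop, step=g.step)
            for name, g in default_grids().items()
        }
    )
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    def cutoff_table(self) -> CutoffTable:
        return CutoffTable(
            iron_cutoff=self.iron_cutoff,
            ascorbic_cutoff=self.ascorbic_cutoff,
            phytate_cutoff=self.phytate_cutoff,
            ratio_cutoff=self.ratio_cutoff,
            ratio_mode=self.ratio_mode,
        )

    def outcome_grids(self) -> dict[str, OutcomeCutoffGrid]:
        return {
            name: OutcomeCutoffGrid(name, g.start, g.stop, g.step)
            for name, g in self.grids.items()
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
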