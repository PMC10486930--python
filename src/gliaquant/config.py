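"""Run configuration: every analysis constant lives here exactly once."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml

#: 19-gene qPCR panel: 8 phagocytosis, 2 mitophagy, 4 A1 and 5 A2
#: reactivity markers.
DEFAULT_GENE_PANEL = [
    # phagocytosis
    "Abca1", "Abca7", "Dock1", "Gulp1", "Lamp1", "Lgals3", "Megf10", "Mfge8",
    # mitophagy
    "Pink1", "Park2",
    # A1 reactivity
    "Fbln5", "H2-T23", "Psmb8", "Srgn",
    # A2 reactivity
    "Clcf1", "Emp1", "Ptx3", "Stat3", "Tgm1",
]


@dataclass
class RunConfig:
    # imaging / enclosure
    green_threshold: int = 100          # strict > on the 8-bit green channel
    red_threshold: Union[int, str] = "otsu"
    connectivity: int = 26
    median_filter: bool = True          # 3x3 per-slice median on binary red
    min_component_voxels: int = 0
    voxel_size_um: float = 0.4
    category_bins: tuple[int, int, int] = (0, 5, 20)
    # single-cell qPCR
    ct_ceiling: float = 40.0
    ct_cutoff: float = 32.0
    qc_mode: str = "both"
    gene_panel: list[str] = field(default_factory=lambda: list(DEFAULT_GENE_PANEL))
    # statistics
    alpha: float = 0.05
    # synthetic demo cohort sizes
    n_stacks_per_group: int = 3
    stack_shape: tuple[int, int, int] = (64, 64, 64)
    astrocytes_per_stack: int = 2
    cells_per_group: tuple[int, int] = (33, 39)
    reactive_fraction: float = 0.5      # reactive mixture in the treated group
    spiked_fold_change: float = 8.0
    spiked_genes: tuple[str, ...] = ("Gulp1", "Lgals3")
    eyes_per_group: int = 6
    fields_per_retina: int = 8
    field_area_mm2: float = 0.1
    rgc_density: float = 3000.0          # nuclei per mm^2, control retinas
    rgc_loss_fraction: float = 0.15
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        # YAML has no tuple type; restore the declared shapes
        for name in ("category_bins", "stack_shape", "cells_per_group",
                     "spiked_genes"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg
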