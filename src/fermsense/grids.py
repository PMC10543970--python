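"""Packaged reference selection grids.

Three engine × hidden-node RMSE/R² tables — one per soft-sensor task
(batch biomass, fed-batch biomass, growth rate) — shipped as CSV so the
model-selection logic has a fixed test surface independent of training
stochasticity.
"""

from __future__ import annotations

from importlib import resources

from .ann import FitGrid

__all__ = ["reference_grid", "REFERENCE_GRIDS"]

REFERENCE_GRIDS = ("batch_biomass", "fedbatch_biomass", "growth_rate")


def reference_grid(task: str) -> FitGrid:
    """Load the packaged reference grid for one task."""
    if task not in REFERENCE_GRIDS:
        raise ValueError(f"unknown task {task!r}; choose from {REFERENCE_GRIDS}")
    ref = resources.files("fermsense") / "data" / f"refgrid_{task}.csv"
    with resources.as_file(ref) as path:
        return FitGrid.from_csv(path)
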