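"""Packaged parameter presets.

``table2`` is the standard two-network configuration used for the
(F_GO, F_MO) regime sweeps: N = M = 100, all fixed couplings at 0.025,
mean periods of 200 s (glycolysis/glucose) and 100 s (OXPHOS/oxygen),
modulation periods ten times slower and modulation amplitudes a third of
the mean frequency.  ``table4`` is the time-varying HeLa scenario (see
:mod:`kuramet.hela`).  ``desk`` is a scaled-down sweep preset
(N = M = 20, 3,000 s runs, 10 x 10 grid) sized for interactive work and
for the packaged verification suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .model import ModelConfig
from .integrate import SimulationSpec

__all__ = ["table2_config", "single_oscillator_config", "desk_preset", "standard_protocol"]


def table2_config(seed: int = 0, **overrides) -> ModelConfig:
    """The standard two-network configuration (its values are the
    :class:`~kuramet.model.ModelConfig` defaults)."""
    return replace(ModelConfig(seed=seed), **overrides)


def single_oscillator_config(seed: int = 0, **overrides) -> ModelConfig:
    """N = M = 1, K = 0: the two-oscillator ancestor model."""
    return replace(ModelConfig(N=1, M=1, K_GO=0.0, K_MO=0.0, seed=seed), **overrides)


def standard_protocol(seed: int = 0) -> SimulationSpec:
    """10,000 s run, 0.1 s sampling, first 5,000 s discarded."""
    return SimulationSpec(seed=seed)


def desk_preset(seed: int = 0):
    """Scaled-down sweep: (config, simulation spec, grid spec)."""
    from .sweep import GridSpec  # local import to avoid a cycle

    config = table2_config(seed=seed, N=20, M=20)
    sim = SimulationSpec(t_total=3_000.0, t_transient=1_500.0, seed=seed)
    grid = GridSpec(step=0.03, allow_any_size=True)  # 10 x 10 over [0, 0.27]
    return config, sim, grid
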