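"""Regime map over a grid of inter-network coupling strengths.

Each cell of the (F_GO, F_MO) grid runs one full simulation at the base
configuration with the cell's couplings substituted, discards the
transient, classifies the six synchronization modes and records the
taxonomy colour.  Cells are seeded individually (base seed + cell
index), so the map is reproducible and independent of worker count and
evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .integrate import SimulationSpec, discard_transient, integrate
from .model import ModelConfig
from .syncmetrics import RegimeLabel, classify_regime

__all__ = ["GridSpec", "RegimeMap", "grid_values", "run_sweep"]


@dataclass(frozen=True)
class GridSpec:
    """Arithmetic grid of coupling values, by default 50 steps of 0.006.

    With ``include_zero`` the grid is {step*k : k = 0..n-1} (zero-coupling
    corner on the grid, maximum one step short of f_max); without it,
    {step*k : k = 1..n}.  A grid whose size differs from 50 requires
    ``allow_any_size``.
    """

    f_min: float = 0.0
    f_max: float = 0.3
    step: float = 0.006
    include_zero: bool = True
    allow_any_size: bool = False

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.f_max <= self.f_min:
            raise ValueError("need f_max > f_min")
        if self.size != 50 and not self.allow_any_size:
            raise ValueError(
                f"grid size {self.size} != 50; pass allow_any_size=True to override"
            )

    @property
    def size(self) -> int:
        return int(round((self.f_max - self.f_min) / self.step))


def grid_values(spec: GridSpec) -> np.ndarray:
    """Ordered coupling values of one grid axis."""
    n = spec.size
    ks = np.arange(0, n) if spec.include_zero else np.arange(1, n + 1)
    return spec.f_min + spec.step * ks


@dataclass
class RegimeMap:
    """Classified regimes over the (F_GO, F_MO) grid.

    ``cells[i][j]`` is the verdict at F_GO = f_go_values[i],
    F_MO = f_mo_values[j] (None where the cell's solver failed; the
    failure message is kept in ``errors``).
    """

    grid: GridSpec
    f_go_values: np.ndarray
    f_mo_values: np.ndarray
    cells: list  # list[list[Optional[RegimeLabel]]]
    seeds: np.ndarray  # (n_go, n_mo) int
    errors: dict = field(default_factory=dict)  # (i, j) -> message

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, f_go in enumerate(self.f_go_values):
            for j, f_mo in enumerate(self.f_mo_values):
                label = self.cells[i][j]
                row = {"F_GO": f_go, "F_MO": f_mo, "seed": int(self.seeds[i, j])}
                if label is None:
                    row.update(
                        go_g="error", go_net="error", go_mo="error",
                        mo_go="error", mo_net="error", mo_o="error", color="error",
                    )
                else:
                    row.update(label.to_dict())
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / "regime_map.csv", index=False)
        manifest = {
            "grid": {
                "f_min": self.grid.f_min,
                "f_max": self.grid.f_max,
                "step": self.grid.step,
                "include_zero": self.grid.include_zero,
                "allow_any_size": self.grid.allow_any_size,
            },
            "errors": {f"{i},{j}": msg for (i, j), msg in self.errors.items()},
        }
        (directory / "regime_map.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "RegimeMap":
        directory = Path(directory)
        manifest = json.loads((directory / "regime_map.json").read_text())
        grid = GridSpec(**manifest["grid"])
        df = pd.read_csv(directory / "regime_map.csv")
        f_go = np.sort(df["F_GO"].unique())
        f_mo = np.sort(df["F_MO"].unique())
        cells = [[None] * len(f_mo) for _ in f_go]
        seeds = np.zeros((len(f_go), len(f_mo)), dtype=int)
        for _, row in df.iterrows():
            i = int(np.argmin(np.abs(f_go - row["F_GO"])))
            j = int(np.argmin(np.abs(f_mo - row["F_MO"])))
            seeds[i, j] = int(row["seed"])
            if row["color"] != "error":
                cells[i][j] = RegimeLabel.from_dict(row.to_dict())
        errors = {
            tuple(int(x) for x in k.split(",")): v
            for k, v in manifest.get("errors", {}).items()
        }
        return cls(grid=grid, f_go_values=f_go, f_mo_values=f_mo,
                   cells=cells, seeds=seeds, errors=errors)

    def plot(self, path: Union[str, Path]) -> None:
        """Render the map as a coloured grid (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.patches import Patch

        palette = {
            "red": "#d62728", "orange": "#ff7f0e", "yellow": "#e6d800",
            "blue": "#1f77b4", "dark blue": "#003366", "light blue": "#87cefa",
            "purple": "#9467bd", "green": "#2ca02c", "cyan": "#17becf",
            "unlisted": "#bbbbbb", "error": "#000000",
        }
        n_go, n_mo = len(self.f_go_values), len(self.f_mo_values)
        img = np.zeros((n_mo, n_go, 3))
        seen = set()
        for i in range(n_go):
            for j in range(n_mo):
                label = self.cells[i][j]
                color = "error" if label is None else label.color
                seen.add(color)
                img[j, i] = matplotlib.colors.to_rgb(palette[color])
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.imshow(img, origin="lower", aspect="auto",
                  extent=[self.f_go_values[0], self.f_go_values[-1],
                          self.f_mo_values[0], self.f_mo_values[-1]])
        ax.set_xlabel("F_GO (rad/s)")
        ax.set_ylabel("F_MO (rad/s)")
        ax.legend(handles=[Patch(color=palette[c], label=c) for c in sorted(seen)],
                  loc="center left", bbox_to_anchor=(1.02, 0.5), fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _run_cell(base: ModelConfig, spec: SimulationSpec, f_go: float, f_mo: float, seed: int):
    config = replace(base, F_GO=float(f_go), F_MO=float(f_mo), seed=int(seed))
    try:
        series = integrate(config, spec)
        analysed = discard_transient(series, spec.t_transient)
        return classify_regime(analysed), None
    except Exception as exc:  # noqa: BLE001 - per-cell failures must not kill the sweep
        return None, f"{type(exc).__name__}: {exc}"


def run_sweep(
    grid: GridSpec,
    base: ModelConfig,
    spec: SimulationSpec,
    workers: int = 1,
) -> RegimeMap:
    """Classify every (F_GO, F_MO) cell of the grid.

    Per-cell seeds are ``base.seed + flat cell index``, so results do not
    depend on ``workers`` or on evaluation order.
    """
    f_go = grid_values(grid)
    f_mo = grid_values(grid)
    n_go, n_mo = len(f_go), len(f_mo)
    seeds = base.seed + np.arange(n_go * n_mo).reshape(n_go, n_mo)

    tasks = [
        (i, j, delayed(_run_cell)(base, spec, f_go[i], f_mo[j], seeds[i, j]))
        for i in range(n_go)
        for j in range(n_mo)
    ]
    results = Parallel(n_jobs=workers)(t[2] for t in tasks)

    cells = [[None] * n_mo for _ in range(n_go)]
    errors = {}
    for (i, j, _), (label, err) in zip(tasks, results):
        cells[i][j] = label
        if err is not None:
            errors[(i, j)] = err
    return RegimeMap(grid=grid, f_go_values=f_go, f_mo_values=f_mo,
                     cells=cells, seeds=seeds, errors=errors)
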