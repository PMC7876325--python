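"""Labeled synthetic phase series with known synchronization ground truth.

These generators build phase-difference and network-phase series whose
correct verdict is known by construction, so every statistic and the
regime classifier can be tested without integrating the full model:

* ``locked`` — constant difference plus small bounded jitter
  (coherence > 0.99, bounded): permanent.
* ``slipping`` — locked with a handful of discrete 2*pi slips inserted:
  coherent (a 2*pi step leaves the unit phasor unchanged) but unbounded:
  intermittent.
* ``drifting`` — constant detuning spanning many full cycles: the unit
  phasor averages out, coherence ~ 0: none.
* ``ordered_network`` — fixed circular spread sigma_c around a common
  drift, r = exp(-sigma_c^2/2)-ish and constant in time: permanent.
* ``disordered_network`` — phases redrawn uniformly each sample,
  r ~ 1/sqrt(n): disordered.
* ``intermittent_network`` — alternating low/high spread blocks:
  r_mean > 0.5 with r_range > 0.2: intermittent.

Each generator verifies its intended label with the same brute-force
statistics the classifier uses (an honest label, not an assumed one) and
retries with a fresh draw a bounded number of times if a random draw
lands outside its class.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .syncmetrics import (
    COHERENCE_THRESHOLD,
    NetworkLabel,
    PairLabel,
    R_MEAN_THRESHOLD,
    R_RANGE_THRESHOLD,
    is_bounded,
    order_parameter_series,
    phase_coherence,
)

__all__ = ["FixtureKind", "FixtureSpec", "make_pair_fixture", "make_network_fixture"]

_MAX_RETRIES = 8


class FixtureKind(str, enum.Enum):
    locked = "locked"
    drifting = "drifting"
    slipping = "slipping"
    ordered_network = "ordered_network"
    disordered_network = "disordered_network"
    intermittent_network = "intermittent_network"


_PAIR_KINDS = {FixtureKind.locked, FixtureKind.drifting, FixtureKind.slipping}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one labeled series; generation is seed-deterministic."""

    kind: FixtureKind
    duration: float = 5_000.0
    sample_interval: float = 0.1
    seed: int = 0
    omega: float = 2 * np.pi / 200  # common carrier frequency, rad/s
    jitter: float = 0.05            # locked-pair jitter amplitude, rad
    detuning: float = 0.05          # drifting-pair frequency offset, rad/s
    n_slips: int = 1                # slipping-pair 2*pi slip count
    spread: float = 0.3             # ordered-network circular spread, rad
    spread_hi: float = 1.5          # intermittent-network high spread, rad
    alternation_period: float = 250.0  # intermittent-network block length, s
    n_oscillators: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", FixtureKind(self.kind))
        if self.duration <= 0 or self.sample_interval <= 0:
            raise ValueError("duration and sample_interval must be > 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.sample_interval))
        return np.arange(n + 1) * self.sample_interval


def _bounded_jitter(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Small bounded wander: clipped random-walk increments plus a slow sine.

    Clipping (not noise integration) guarantees the boundedness label by
    construction.
    """
    walk = np.clip(np.cumsum(rng.uniform(-1.0, 1.0, n)) * amplitude * 0.02,
                   -amplitude, amplitude)
    phase0 = rng.uniform(0, 2 * np.pi)
    slow = amplitude * np.sin(2 * np.pi * np.arange(n) / max(n / 3, 2) + phase0)
    return walk + slow


def make_pair_fixture(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray, PairLabel]:
    """(series_a, series_b, expected_label) for a pair kind."""
    if spec.kind not in _PAIR_KINDS:
        raise ValueError(f"{spec.kind.value} is not a pair kind")
    t = spec.times
    rng = np.random.default_rng(spec.seed)

    for attempt in range(_MAX_RETRIES):
        base = spec.omega * t
        offset = rng.uniform(0, 2 * np.pi)
        if spec.kind is FixtureKind.locked:
            delta = offset + _bounded_jitter(rng, t.size, spec.jitter)
            expected = PairLabel.permanent
            ok = phase_coherence(delta) > 0.99 and is_bounded(delta)
        elif spec.kind is FixtureKind.drifting:
            cycles = spec.detuning * spec.duration / (2 * np.pi)
            if cycles < 10:
                raise ValueError(
                    f"drift covers only {cycles:.1f} cycles; need >= 10 for an honest label"
                )
            delta = offset + spec.detuning * t
            expected = PairLabel.none
            ok = phase_coherence(delta) < 0.1
        else:  # slipping
            delta = offset + _bounded_jitter(rng, t.size, spec.jitter)
            # place slips away from the window edges
            slip_times = rng.uniform(0.2 * spec.duration, 0.8 * spec.duration, spec.n_slips)
            for ts in slip_times:
                delta = delta + 2 * np.pi * (t >= ts)
            expected = PairLabel.intermittent
            ok = phase_coherence(delta) > COHERENCE_THRESHOLD and not is_bounded(delta)
        if ok:
            return base + delta, base, expected
    raise RuntimeError(
        f"could not generate a valid {spec.kind.value} fixture in {_MAX_RETRIES} tries"
    )


def make_network_fixture(spec: FixtureSpec) -> tuple[np.ndarray, NetworkLabel]:
    """((T, n) phase matrix, expected_label) for a network kind."""
    if spec.kind in _PAIR_KINDS:
        raise ValueError(f"{spec.kind.value} is not a network kind")
    t = spec.times
    rng = np.random.default_rng(spec.seed)
    n = spec.n_oscillators

    for attempt in range(_MAX_RETRIES):
        carrier = (spec.omega * t)[:, None]
        if spec.kind is FixtureKind.ordered_network:
            delta = rng.normal(0.0, spec.spread, n)[None, :]
            theta = carrier + delta
            r = order_parameter_series(theta)
            expected = NetworkLabel.permanent
            ok = r.mean() > R_MEAN_THRESHOLD and (r.max() - r.min()) < R_RANGE_THRESHOLD
        elif spec.kind is FixtureKind.disordered_network:
            theta = rng.uniform(0, 2 * np.pi, (t.size, n))
            r = order_parameter_series(theta)
            expected = NetworkLabel.disordered
            ok = r.mean() <= R_MEAN_THRESHOLD
        else:  # intermittent_network
            lo = rng.normal(0.0, spec.spread, n)
            hi = rng.normal(0.0, spec.spread_hi, n)
            block = ((t // spec.alternation_period).astype(int) % 2).astype(bool)
            theta = carrier + np.where(block[:, None], hi[None, :], lo[None, :])
            r = order_parameter_series(theta)
            expected = NetworkLabel.intermittent
            ok = r.mean() > R_MEAN_THRESHOLD and (r.max() - r.min()) >= R_RANGE_THRESHOLD
        if ok:
            return theta, expected
    raise RuntimeError(
        f"could not generate a valid {spec.kind.value} fixture in {_MAX_RETRIES} tries"
    )


def save_fixture(spec: FixtureSpec, path: Union[str, Path]) -> None:
    """Write a fixture in the PhaseSeries columnar format with a JSON sidecar."""
    path = Path(path)
    t = spec.times
    if spec.kind in _PAIR_KINDS:
        a, b, label = make_pair_fixture(spec)
        data = np.column_stack([t, a, b])
        header = "time,theta_a,theta_b"
    else:
        theta, label = make_network_fixture(spec)
        data = np.column_stack([t, theta])
        header = ",".join(["time"] + [f"theta_{i}" for i in range(1, theta.shape[1] + 1)])
    np.savetxt(path, data, delimiter=",", header=header, comments="")
    sidecar = {"kind": spec.kind.value, "seed": spec.seed, "expected_label": label.value}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
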