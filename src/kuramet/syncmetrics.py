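"""Finite-time synchronization statistics and regime classification.

Two oscillators are judged on two statistics over the analysis window:

* phase coherence — the modulus of the time-averaged unit phasor of
  their phase difference, ``sqrt(<cos d>^2 + <sin d>^2)``.  A constant
  difference gives 1; steady drift through many cycles gives ~0.
  Non-autonomous frequency modulation keeps even locked pairs below 1,
  so the operating threshold is 0.9 rather than ~1.
* boundedness — whether the difference stays inside one 2*pi band for
  the whole window.  Coherent but unbounded pairs exhibit episodic
  2*pi slips: intermittent synchronization, a finite-time phenomenon
  that asymptotic averaging would misread as no synchronization.

A network is synchronized when its time-averaged Kuramoto order
parameter exceeds 0.5 (more ordered than disordered), permanently so
when the parameter varies by less than 0.2 over the window.

A run is summarised by six modes — glycolysis-glucose, glycolysis
network, glycolysis-to-OXPHOS mean field, OXPHOS-to-glycolysis mean
field, OXPHOS network, OXPHOS-oxygen — and mapped to the colour code of
the published regime taxonomy where the combination is listed.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .integrate import PhaseSeries

__all__ = [
    "PairLabel",
    "NetworkLabel",
    "Mode",
    "PairVerdict",
    "NetworkVerdict",
    "RegimeLabel",
    "COHERENCE_THRESHOLD",
    "R_MEAN_THRESHOLD",
    "R_RANGE_THRESHOLD",
    "phase_coherence",
    "is_bounded",
    "classify_pair",
    "classify_network",
    "order_parameter_series",
    "mean_field_phase",
    "pair_series",
    "classify_regime",
    "modified_order",
    "regime_color",
]

COHERENCE_THRESHOLD = 0.9
R_MEAN_THRESHOLD = 0.5
R_RANGE_THRESHOLD = 0.2


class PairLabel(str, enum.Enum):
    none = "none"
    intermittent = "intermittent"
    permanent = "permanent"


class NetworkLabel(str, enum.Enum):
    disordered = "disordered"
    intermittent = "intermittent"
    permanent = "permanent"


class Mode(str, enum.Enum):
    """The six synchronization modes of the two-network model."""

    go_g = "go_g"      # glycolysis oscillators to their glucose drivers
    go_net = "go_net"  # glycolysis network internal order
    go_mo = "go_mo"    # glycolysis oscillators to the OXPHOS mean field
    mo_go = "mo_go"    # OXPHOS oscillators to the glycolysis mean field
    mo_net = "mo_net"  # OXPHOS network internal order
    mo_o = "mo_o"      # OXPHOS oscillators to their oxygen drivers


_PAIR_MODES = (Mode.go_g, Mode.mo_o, Mode.go_mo, Mode.mo_go)
_WEAKNESS = {PairLabel.none: 0, PairLabel.intermittent: 1, PairLabel.permanent: 2}


@dataclass(frozen=True)
class PairVerdict:
    coherence: float
    bounded: bool
    label: PairLabel


@dataclass(frozen=True)
class NetworkVerdict:
    r_mean: float
    r_range: float
    label: NetworkLabel


@dataclass(frozen=True)
class RegimeLabel:
    go_g: PairLabel
    go_net: NetworkLabel
    go_mo: PairLabel
    mo_go: PairLabel
    mo_net: NetworkLabel
    mo_o: PairLabel

    @property
    def color(self) -> str:
        return regime_color(self)

    def to_dict(self) -> dict:
        return {
            "go_g": self.go_g.value,
            "go_net": self.go_net.value,
            "go_mo": self.go_mo.value,
            "mo_go": self.mo_go.value,
            "mo_net": self.mo_net.value,
            "mo_o": self.mo_o.value,
            "color": self.color,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegimeLabel":
        return cls(
            go_g=PairLabel(d["go_g"]),
            go_net=NetworkLabel(d["go_net"]),
            go_mo=PairLabel(d["go_mo"]),
            mo_go=PairLabel(d["mo_go"]),
            mo_net=NetworkLabel(d["mo_net"]),
            mo_o=PairLabel(d["mo_o"]),
        )


# colour taxonomy of the network-model regimes:
# (go_g, go_net, go_mo, mo_go, mo_net, mo_o) -> colour
_P, _I, _N = PairLabel.permanent, PairLabel.intermittent, PairLabel.none
_NP, _NI = NetworkLabel.permanent, NetworkLabel.intermittent
_COLOR_TABLE = {
    (_P, _NP, _N, _N, _NP, _P): "red",
    (_N, _NP, _N, _N, _NP, _P): "orange",
    (_N, _NP, _P, _P, _NP, _P): "light blue",
    (_P, _NP, _N, _N, _NP, _N): "yellow",
    (_P, _NP, _P, _P, _NP, _N): "blue",
    (_N, _NP, _N, _N, _NP, _N): "purple",
    (_N, _NP, _N, _N, _NI, _N): "green",
    (_N, _NI, _N, _N, _NP, _N): "cyan",
    (_N, _NP, _P, _P, _NP, _N): "dark blue",
}


def regime_color(label: RegimeLabel) -> str:
    """Colour of the published taxonomy, or "unlisted" for other combinations."""
    key = (label.go_g, label.go_net, label.go_mo, label.mo_go, label.mo_net, label.mo_o)
    return _COLOR_TABLE.get(key, "unlisted")


# ---------------------------------------------------------------------------
# pair statistics


def phase_coherence(delta: np.ndarray) -> float:
    """Modulus of the time-averaged unit phasor of a phase difference."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("phase_coherence needs a non-empty series")
    return float(np.hypot(np.cos(delta).mean(), np.sin(delta).mean()))


def is_bounded(delta: np.ndarray) -> bool:
    """True iff the difference stays within one 2*pi band: max - min < 2*pi."""
    delta = np.asarray(delta, dtype=float)
    return bool(delta.max() - delta.min() < 2 * np.pi)


def _pair_verdict(delta: np.ndarray) -> PairVerdict:
    coh = phase_coherence(delta)
    bounded = is_bounded(delta)
    if coh > COHERENCE_THRESHOLD:
        label = PairLabel.permanent if bounded else PairLabel.intermittent
    else:
        label = PairLabel.none
    return PairVerdict(coherence=coh, bounded=bounded, label=label)


def classify_pair(a: np.ndarray, b: np.ndarray) -> PairVerdict:
    """Verdict on the synchronization of two unwrapped phase series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"series length mismatch: {a.shape} vs {b.shape}")
    return _pair_verdict(a - b)


def classify_network(r_series: np.ndarray) -> NetworkVerdict:
    """Verdict on a network from its order-parameter time series."""
    r = np.asarray(r_series, dtype=float)
    if r.size == 0:
        raise ValueError("classify_network needs a non-empty series")
    r_mean = float(r.mean())
    r_range = float(r.max() - r.min())
    if r_mean <= R_MEAN_THRESHOLD:
        label = NetworkLabel.disordered
    elif r_range < R_RANGE_THRESHOLD:
        label = NetworkLabel.permanent
    else:
        label = NetworkLabel.intermittent
    return NetworkVerdict(r_mean=r_mean, r_range=r_range, label=label)


# ---------------------------------------------------------------------------
# series extraction


def order_parameter_series(theta: np.ndarray) -> np.ndarray:
    """r(t) of a (T, n) matrix of unwrapped phases."""
    z = np.exp(1j * np.asarray(theta, dtype=float)).mean(axis=1)
    return np.abs(z)


def mean_field_phase(theta: np.ndarray, r_floor: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """(r(t), Psi(t)) of a network, with Psi unwrapped over time.

    The argument of the mean field is undefined where r ~ 0; such samples
    carry the previous Psi forward before unwrapping.
    """
    z = np.exp(1j * np.asarray(theta, dtype=float)).mean(axis=1)
    r = np.abs(z)
    psi = np.angle(z)
    bad = r < r_floor
    if bad.any():
        for t in np.nonzero(bad)[0]:
            psi[t] = psi[t - 1] if t > 0 else 0.0
    return r, np.unwrap(psi)


def pair_series(series: PhaseSeries, mode: Mode) -> np.ndarray:
    """Phase-difference series for a driver or inter-network mode.

    Returns a (T, n_pairs) array: one column per oscillator.  Driver
    modes difference each network oscillator against its own driver;
    inter-network modes difference each oscillator against the other
    network's unwrapped mean-field phase.
    """
    mode = Mode(mode)
    if mode is Mode.go_g:
        return series.theta_GO - series.theta_G
    if mode is Mode.mo_o:
        return series.theta_MO - series.theta_O
    if mode is Mode.go_mo:
        _, psi_mo = mean_field_phase(series.theta_MO)
        return series.theta_GO - psi_mo[:, None]
    if mode is Mode.mo_go:
        _, psi_go = mean_field_phase(series.theta_GO)
        return series.theta_MO - psi_go[:, None]
    raise ValueError(f"mode {mode.value} is network-internal; use classify_network")


def _majority_pair_label(deltas: np.ndarray) -> PairLabel:
    """Majority vote over per-oscillator verdicts, ties broken weaker."""
    labels = [_pair_verdict(deltas[:, k]).label for k in range(deltas.shape[1])]
    counts = {lab: labels.count(lab) for lab in set(labels)}
    best = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == best]
    return min(tied, key=lambda lab: _WEAKNESS[lab])


def classify_regime(series: PhaseSeries) -> RegimeLabel:
    """Six-mode regime classification of a transient-free run."""
    window = series.times[-1] - series.times[0]
    slowest = max(
        2 * np.pi / series.config.freq_GO.omega_mean,
        2 * np.pi / series.config.freq_MO.omega_mean,
    )
    if window < 10 * slowest:
        warnings.warn(
            f"analysis window {window:.0f} s covers fewer than 10 oscillation "
            "periods; classification may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    return RegimeLabel(
        go_g=_majority_pair_label(pair_series(series, Mode.go_g)),
        go_net=classify_network(order_parameter_series(series.theta_GO)).label,
        go_mo=_majority_pair_label(pair_series(series, Mode.go_mo)),
        mo_go=_majority_pair_label(pair_series(series, Mode.mo_go)),
        mo_net=classify_network(order_parameter_series(series.theta_MO)).label,
        mo_o=_majority_pair_label(pair_series(series, Mode.mo_o)),
    )


def modified_order(series: PhaseSeries) -> np.ndarray:
    """Two-network order parameter s(t) = |sum_GO e^(i th) + sum_MO e^(i th)| / (N+M).

    Treats both ATP-producing networks as one population; s is both a
    coherence measure and a proxy for the amplitude of the joint mean
    field, comparable to a single-cell NADH fluorescence trace.
    """
    zGO = np.exp(1j * series.theta_GO).sum(axis=1)
    zMO = np.exp(1j * series.theta_MO).sum(axis=1)
    return np.abs(zGO + zMO) / (series.N + series.M)


def verdicts_to_json(series: PhaseSeries) -> str:
    """Full JSON report of a run: six labels, colour, per-mode statistics."""
    regime = classify_regime(series)
    report = regime.to_dict()
    for mode in _PAIR_MODES:
        deltas = pair_series(series, mode)
        report[f"{mode.value}_coherence"] = [
            phase_coherence(deltas[:, k]) for k in range(deltas.shape[1])
        ]
    for name, theta in (("go_net", series.theta_GO), ("mo_net", series.theta_MO)):
        v = classify_network(order_parameter_series(theta))
        report[f"{name}_r_mean"] = v.r_mean
        report[f"{name}_r_range"] = v.r_range
    return json.dumps(report, indent=2)
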