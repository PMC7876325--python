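"""Two-network non-autonomous Kuramoto model of cell energy metabolism.

Glycolysis (GO) and oxidative phosphorylation (MO) are each represented by
an all-to-all network of Kuramoto phase oscillators arranged on a ring,
with coupling weights that fall off with ring distance.  Each network is
driven element-wise by a supply oscillator population (glucose G, oxygen O)
and by the mean field of the other network.  Every oscillator's natural
frequency is modulated deterministically in time,

    omega_Xi(t) = omega_X + A_X * sin(omega_Xm * t + t_i),

with a fixed random offset ``t_i`` per oscillator so that the population
shares one mean frequency and one modulation cycle but is spread across
modulation phases.

The governing phase velocities are::

    dtheta_G_i  = omega_G_i(t)
    dtheta_O_i  = omega_O_i(t)
    dtheta_GO_i = omega_GO_i(t) + (K_GO/N) * sum_j W_ij sin(theta_GO_j - theta_GO_i)
                  - eps_G * sin(theta_GO_i - theta_G_i)
                  + F_GO * r_MO * sin(Psi_MO - theta_GO_i)
    dtheta_MO_i = omega_MO_i(t) + (K_MO/M) * sum_j W_ij sin(theta_MO_j - theta_MO_i)
                  - eps_O * sin(theta_MO_i - theta_O_i)
                  -+ F_MO * r_GO * sin(Psi_GO - theta_MO_i)

where (r_X, Psi_X) is the Kuramoto order parameter of network X.  Both
mean-field terms are attractive by default (``mo_go_attractive=True``),
the convention under which strong inter-network coupling produces mutual
synchronization of the two networks; ``mo_go_attractive=False`` selects
the repulsive sign on the MO term instead, which drives the OXPHOS
network away from the glycolysis mean field and disorders both networks
at strong coupling.  With N = M = 1 and K = 0 the model reduces to the
two-oscillator ancestor model, optionally with additive white frequency
noise.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import yaml

from .schedule import CouplingValue, Schedule, evaluate_coupling

__all__ = [
    "FrequencyParams",
    "PhaseOffsets",
    "OffsetSet",
    "KernelKind",
    "WeightKernel",
    "ModelConfig",
    "PhaseState",
    "ring_distance",
    "weight",
    "sample_offsets",
    "instantaneous_frequency",
    "order_parameter",
    "PhaseModel",
    "rhs",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FrequencyParams:
    """Parameters of one element's time-varying natural frequency.

    omega_mean : rad/s
        Mean natural frequency omega_X around which the modulation runs.
    mod_amplitude : rad/s
        Amplitude A_X of the sinusoidal frequency modulation.
    mod_frequency : rad/s
        Angular frequency omega_Xm of the modulation.
    """

    omega_mean: float
    mod_amplitude: float = 0.0
    mod_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_mean <= 0:
            raise ValueError("omega_mean must be > 0")
        if self.mod_amplitude < 0:
            raise ValueError("mod_amplitude must be >= 0")
        if self.mod_amplitude > 0 and self.mod_frequency <= 0:
            raise ValueError("mod_frequency must be > 0 when mod_amplitude > 0")


@dataclass(frozen=True)
class PhaseOffsets:
    """Fixed per-oscillator offsets t_i of the frequency modulation."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OffsetSet:
    """Offsets for all four elements: glucose, oxygen, glycolysis, OXPHOS."""

    g: PhaseOffsets
    o: PhaseOffsets
    go: PhaseOffsets
    mo: PhaseOffsets

    def to_dict(self) -> dict:
        return {k: getattr(self, k).values.tolist() for k in ("g", "o", "go", "mo")}

    @classmethod
    def from_dict(cls, d: dict) -> "OffsetSet":
        return cls(**{k: PhaseOffsets(np.asarray(v)) for k, v in d.items()})


class KernelKind(str, enum.Enum):
    """Functional form of the ring-distance coupling weight.

    The default ``harmonic_decay`` (base/d) falls off with ring distance,
    realising diffusion-limited molecular exchange: nearest neighbours
    couple most strongly, opposite points on the ring most weakly.
    ``uniform`` reproduces the unweighted all-to-all network.  The other
    two readings of the weighting expression are provided for comparison.
    """

    harmonic_decay = "harmonic_decay"  # W / d
    power_decay = "power_decay"        # W ** d
    linear_growth = "linear_growth"    # W * d
    uniform = "uniform"                # W for every pair


@dataclass(frozen=True)
class WeightKernel:
    kind: KernelKind = KernelKind.harmonic_decay
    base: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", KernelKind(self.kind))
        if self.base <= 0:
            raise ValueError("kernel base W must be > 0")

    def weight_of_distance(self, d: np.ndarray) -> np.ndarray:
        """Weight as a function of ring distance; d = 0 (self) maps to 0."""
        d = np.asarray(d, dtype=float)
        with np.errstate(divide="ignore"):
            if self.kind is KernelKind.harmonic_decay:
                w = np.where(d > 0, self.base / np.maximum(d, 1e-300), 0.0)
            elif self.kind is KernelKind.power_decay:
                w = np.where(d > 0, self.base ** d, 0.0)
            elif self.kind is KernelKind.linear_growth:
                w = self.base * d
            else:  # uniform
                w = np.where(d > 0, self.base, 0.0)
        return w

    def matrix(self, n: int) -> np.ndarray:
        """Full symmetric weight matrix W_ij for an n-ring."""
        return self.weight_of_distance(_ring_distance_matrix(n))


@dataclass
class ModelConfig:
    """All structural and coupling parameters of the two-network model.

    Couplings are angular rates (rad/s); ``eps_G``, ``eps_O``, ``F_GO`` and
    ``F_MO`` may be scalars or :class:`~kuramet.schedule.Schedule` objects
    evaluated at integration time.  ``noise_sigma`` scales optional additive
    white frequency noise (rad/s^(1/2)); it requires the fixed-step
    integrator.  ``seed`` drives the modulation offsets and the initial
    phases.
    """

    N: int = 100
    M: int = 100
    K_GO: float = 0.025
    K_MO: float = 0.025
    eps_G: CouplingValue = 0.025
    eps_O: CouplingValue = 0.025
    F_GO: CouplingValue = 0.0
    F_MO: CouplingValue = 0.0
    kernel: WeightKernel = field(default_factory=WeightKernel)
    freq_G: FrequencyParams = field(
        default_factory=lambda: FrequencyParams(2 * np.pi / 200, 2 * np.pi / 600, 2 * np.pi / 2000)
    )
    freq_O: FrequencyParams = field(
        default_factory=lambda: FrequencyParams(2 * np.pi / 100, 2 * np.pi / 300, 2 * np.pi / 1000)
    )
    freq_GO: FrequencyParams = field(
        default_factory=lambda: FrequencyParams(2 * np.pi / 200, 2 * np.pi / 600, 2 * np.pi / 2000)
    )
    freq_MO: FrequencyParams = field(
        default_factory=lambda: FrequencyParams(2 * np.pi / 100, 2 * np.pi / 300, 2 * np.pi / 1000)
    )
    noise_sigma: float = 0.0
    seed: int = 0
    mo_go_attractive: bool = True
    offset_mode: str = "time_shift"
    random_driver_phases: bool = False

    def __post_init__(self) -> None:
        if self.N < 1 or self.M < 1:
            raise ValueError("N and M must be >= 1")
        for name in ("K_GO", "K_MO"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("eps_G", "eps_O", "F_GO", "F_MO"):
            v = getattr(self, name)
            if not isinstance(v, Schedule) and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.offset_mode not in ("time_shift", "time", "phase"):
            raise ValueError("offset_mode must be 'time_shift', 'time' or 'phase'")

    @property
    def n_oscillators(self) -> int:
        return 2 * self.N + 2 * self.M

    def with_couplings(self, **kwargs: CouplingValue) -> "ModelConfig":
        return replace(self, **kwargs)

    # -- serialization (keys follow the field's conventional symbols) -------

    def to_dict(self) -> dict:
        def coupling(v: CouplingValue):
            return v.to_dict() if isinstance(v, Schedule) else float(v)

        return {
            "N": self.N,
            "M": self.M,
            "K_GO": self.K_GO,
            "K_MO": self.K_MO,
            "eps_G": coupling(self.eps_G),
            "eps_O": coupling(self.eps_O),
            "F_GO": coupling(self.F_GO),
            "F_MO": coupling(self.F_MO),
            "W": self.kernel.base,
            "kernel": self.kernel.kind.value,
            "omega_G": self.freq_G.omega_mean,
            "A_G": self.freq_G.mod_amplitude,
            "omega_Gm": self.freq_G.mod_frequency,
            "omega_O": self.freq_O.omega_mean,
            "A_O": self.freq_O.mod_amplitude,
            "omega_Om": self.freq_O.mod_frequency,
            "omega_GO": self.freq_GO.omega_mean,
            "A_GO": self.freq_GO.mod_amplitude,
            "omega_GOm": self.freq_GO.mod_frequency,
            "omega_MO": self.freq_MO.omega_mean,
            "A_MO": self.freq_MO.mod_amplitude,
            "omega_MOm": self.freq_MO.mod_frequency,
            "sigma": self.noise_sigma,
            "seed": self.seed,
            "mo_go_attractive": self.mo_go_attractive,
            "offset_mode": self.offset_mode,
            "random_driver_phases": self.random_driver_phases,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        def coupling(v):
            return Schedule.from_dict(v) if isinstance(v, dict) else float(v)

        def freq(x: str) -> FrequencyParams:
            return FrequencyParams(d[f"omega_{x}"], d.get(f"A_{x}", 0.0), d.get(f"omega_{x}m", 0.0))

        return cls(
            N=int(d["N"]),
            M=int(d["M"]),
            K_GO=float(d["K_GO"]),
            K_MO=float(d["K_MO"]),
            eps_G=coupling(d["eps_G"]),
            eps_O=coupling(d["eps_O"]),
            F_GO=coupling(d["F_GO"]),
            F_MO=coupling(d["F_MO"]),
            kernel=WeightKernel(KernelKind(d.get("kernel", "harmonic_decay")), float(d.get("W", 1.0))),
            freq_G=freq("G"),
            freq_O=freq("O"),
            freq_GO=freq("GO"),
            freq_MO=freq("MO"),
            noise_sigma=float(d.get("sigma", 0.0)),
            seed=int(d.get("seed", 0)),
            mo_go_attractive=bool(d.get("mo_go_attractive", True)),
            offset_mode=str(d.get("offset_mode", "time_shift")),
            random_driver_phases=bool(d.get("random_driver_phases", False)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class PhaseState:
    """Unwrapped phases of all 2N + 2M oscillators at one instant.

    Phases are never reduced modulo 2*pi, so differences over time remain
    meaningful for boundedness tests.
    """

    theta_G: np.ndarray
    theta_O: np.ndarray
    theta_GO: np.ndarray
    theta_MO: np.ndarray

    def pack(self) -> np.ndarray:
        return np.concatenate([self.theta_G, self.theta_O, self.theta_GO, self.theta_MO])

    @classmethod
    def unpack(cls, y: np.ndarray, N: int, M: int) -> "PhaseState":
        y = np.asarray(y, dtype=float)
        if y.size != 2 * N + 2 * M:
            raise ValueError(f"state size {y.size} != 2N+2M = {2 * N + 2 * M}")
        return cls(
            theta_G=y[:N],
            theta_O=y[N : N + M],
            theta_GO=y[N + M : 2 * N + M],
            theta_MO=y[2 * N + M :],
        )


# ---------------------------------------------------------------------------
# ring geometry and weights


def ring_distance(i: int, j: int, N: int) -> int:
    """Index separation of oscillators i and j on the N-ring (1-based).

    min(|i - j|, N - |i - j|): identical to the two-branch definition of
    the weighting function (|i - j| on the near branch, |j - N - i| or
    |j + N - i| on the wrapped branch) for even ring sizes, and its
    symmetric completion for odd ones, where the printed branch bounds
    fall between integers.  Symmetric in (i, j); 0 only for i == j.
    """
    if not (1 <= i <= N and 1 <= j <= N):
        raise ValueError(f"indices must be in [1, {N}], got i={i}, j={j}")
    d = abs(i - j)
    return min(d, N - d)


def _ring_distance_matrix(n: int) -> np.ndarray:
    idx = np.arange(1, n + 1)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n - d)


def weight(i: int, j: int, N: int, kernel: WeightKernel) -> float:
    """Coupling weight W_ij between ring positions i and j (1-based)."""
    return float(kernel.weight_of_distance(np.array(ring_distance(i, j, N))))


# ---------------------------------------------------------------------------
# non-autonomous frequencies


def sample_offsets(
    params: FrequencyParams,
    count: int,
    rng: np.random.Generator,
    mode: str = "time",
) -> PhaseOffsets:
    """Draw per-oscillator modulation offsets t_i (stored as phase addends).

    The perturbation t_i spreads the oscillators of one element across the
    modulation cycle while leaving them one mean frequency and one
    deterministic modulation.  Three readings of the sampled range are
    supported:

    * ``"time"`` — draw t_i uniformly from [0, 1/omega_m] seconds and add
      it directly inside the sine, ``sin(omega_m*t + t_i)``.  Since
      1/omega_m >> 2*pi at the standard parameters, this covers the whole
      modulation cycle (many times over).
    * ``"time_shift"`` (integration default) — read t_i as a time shift,
      ``sin(omega_m*(t + t_i))``, equivalent to a phase addend
      omega_m*t_i uniform on [0, 1] rad.  The population then spans under
      1 rad of modulation phase: frequencies are distributed but the
      element stays nearly modulation-synchronous.
    * ``"phase"`` — phase addend uniform on [0, 2*pi): full-cycle
      coverage by construction.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if params.mod_amplitude == 0:
        return PhaseOffsets(np.zeros(count))
    if params.mod_frequency <= 0:
        raise ValueError("mod_frequency must be > 0 to sample offsets")
    if mode == "time":
        hi = 1.0 / params.mod_frequency
    elif mode == "time_shift":
        hi = 1.0  # omega_m * (1/omega_m) rad
    elif mode == "phase":
        hi = 2 * np.pi
    else:
        raise ValueError("mode must be 'time_shift', 'time' or 'phase'")
    return PhaseOffsets(rng.uniform(0.0, hi, size=count))


def instantaneous_frequency(
    t: float, params: FrequencyParams, offset: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """omega(t) = omega + A*sin(omega_m*t + t_i); bounded in [omega-A, omega+A]."""
    if params.mod_amplitude == 0:
        if np.ndim(offset) == 0:
            return params.omega_mean
        return np.full(np.shape(offset), params.omega_mean)
    return params.omega_mean + params.mod_amplitude * np.sin(
        params.mod_frequency * t + np.asarray(offset)
    )


# ---------------------------------------------------------------------------
# order parameter


def order_parameter(phases: np.ndarray) -> tuple[float, float]:
    """Kuramoto order parameter (r, Psi) of a phase population.

    r is the modulus of the mean unit phasor (1 = totally ordered,
    ~0 = disordered); Psi its argument.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("order_parameter needs at least one phase")
    z = np.exp(1j * phases).mean()
    return float(np.abs(z)), float(np.angle(z))


# ---------------------------------------------------------------------------
# right-hand side


class PhaseModel:
    """Precomputed evaluator of the governing phase velocities.

    Builds the weight matrices and (if not supplied) the modulation
    offsets once, then evaluates the packed right-hand side
    ``dy = f(t, y)`` with O(N^2) vectorised work per call.
    """

    def __init__(self, config: ModelConfig, offsets: Optional[OffsetSet] = None):
        self.config = config
        self.W_GO = config.kernel.matrix(config.N)
        self.W_MO = config.kernel.matrix(config.M)
        if offsets is None:
            rng = np.random.default_rng(config.seed)
            offsets = OffsetSet(
                g=sample_offsets(config.freq_G, config.N, rng, config.offset_mode),
                o=sample_offsets(config.freq_O, config.M, rng, config.offset_mode),
                go=sample_offsets(config.freq_GO, config.N, rng, config.offset_mode),
                mo=sample_offsets(config.freq_MO, config.M, rng, config.offset_mode),
            )
        self.offsets = offsets
        for name, off, count in (
            ("g", offsets.g, config.N),
            ("o", offsets.o, config.M),
            ("go", offsets.go, config.N),
            ("mo", offsets.mo, config.M),
        ):
            if len(off) != count:
                raise ValueError(f"offsets.{name} has length {len(off)}, expected {count}")

    def initial_phases(self, rng: np.random.Generator) -> np.ndarray:
        """Initial phases: network oscillators uniform on [0, 2*pi).

        The supply drivers start from a common zero phase (they are pure
        rotators, so their ensemble keeps whatever coherence it starts
        with); ``random_driver_phases=True`` randomizes them too.
        """
        cfg = self.config
        y0 = rng.uniform(0.0, 2 * np.pi, size=cfg.n_oscillators)
        if not cfg.random_driver_phases:
            y0[: cfg.N + cfg.M] = 0.0
        return y0

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        cfg = self.config
        N, M = cfg.N, cfg.M
        thG = y[:N]
        thO = y[N : N + M]
        thGO = y[N + M : 2 * N + M]
        thMO = y[2 * N + M :]

        wG = instantaneous_frequency(t, cfg.freq_G, self.offsets.g.values)
        wO = instantaneous_frequency(t, cfg.freq_O, self.offsets.o.values)
        wGO = instantaneous_frequency(t, cfg.freq_GO, self.offsets.go.values)
        wMO = instantaneous_frequency(t, cfg.freq_MO, self.offsets.mo.values)

        eps_G = evaluate_coupling(cfg.eps_G, t)
        eps_O = evaluate_coupling(cfg.eps_O, t)
        F_GO = evaluate_coupling(cfg.F_GO, t)
        F_MO = evaluate_coupling(cfg.F_MO, t)

        sGO, cGO = np.sin(thGO), np.cos(thGO)
        sMO, cMO = np.sin(thMO), np.cos(thMO)

        # sum_j W_ij sin(th_j - th_i) = cos(th_i)*(W@sin th) - sin(th_i)*(W@cos th)
        net_GO = (cfg.K_GO / N) * (cGO * (self.W_GO @ sGO) - sGO * (self.W_GO @ cGO))
        net_MO = (cfg.K_MO / M) * (cMO * (self.W_MO @ sMO) - sMO * (self.W_MO @ cMO))

        drv_GO = eps_G * np.sin(thGO - thG)
        drv_MO = eps_O * np.sin(thMO - thO)

        # mean fields: r*sin(Psi - th_i) = Im(z)*cos(th_i) - Re(z)*sin(th_i)
        zGO_re, zGO_im = cGO.mean(), sGO.mean()
        zMO_re, zMO_im = cMO.mean(), sMO.mean()
        mf_GO = F_GO * (zMO_im * cGO - zMO_re * sGO)
        mf_MO = F_MO * (zGO_im * cMO - zGO_re * sMO)
        mo_sign = 1.0 if cfg.mo_go_attractive else -1.0

        dy = np.empty_like(y)
        dy[:N] = wG
        dy[N : N + M] = wO
        dy[N + M : 2 * N + M] = wGO + net_GO - drv_GO + mf_GO
        dy[2 * N + M :] = wMO + net_MO - drv_MO + mo_sign * mf_MO
        return dy


def rhs(t: float, state: PhaseState, config: ModelConfig, offsets: OffsetSet) -> PhaseState:
    """Phase velocities (rad/s) of every oscillator at time t."""
    model = PhaseModel(config, offsets)
    dy = model(t, state.pack())
    return PhaseState.unpack(dy, config.N, config.M)
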