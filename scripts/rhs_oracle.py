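"""Independent double-loop transcription of the governing phase equations.

Used by acceptance.py as an oracle against the package's vectorised
right-hand side; deliberately written index-by-index from the model
definition, sharing no code with kuramet.model.PhaseModel.
"""

from __future__ import annotations

import numpy as np

from kuramet import ModelConfig, OffsetSet, PhaseState, order_parameter, sample_offsets, weight
from kuramet.schedule import evaluate_coupling


def naive_rhs(t: float, state: PhaseState, cfg: ModelConfig, off: OffsetSet) -> PhaseState:
    N, M = cfg.N, cfg.M

    def omega(fp, t_i):
        return fp.omega_mean + fp.mod_amplitude * np.sin(fp.mod_frequency * t + t_i)

    dG = np.array([omega(cfg.freq_G, off.g.values[i]) for i in range(N)])
    dO = np.array([omega(cfg.freq_O, off.o.values[i]) for i in range(M)])

    eps_G = evaluate_coupling(cfg.eps_G, t)
    eps_O = evaluate_coupling(cfg.eps_O, t)
    F_GO = evaluate_coupling(cfg.F_GO, t)
    F_MO = evaluate_coupling(cfg.F_MO, t)

    r_GO, psi_GO = order_parameter(state.theta_GO)
    r_MO, psi_MO = order_parameter(state.theta_MO)

    dGO = np.zeros(N)
    for i in range(N):
        acc = 0.0
        for j in range(N):
            acc += weight(i + 1, j + 1, N, cfg.kernel) * np.sin(
                state.theta_GO[j] - state.theta_GO[i]
            )
        dGO[i] = (
            omega(cfg.freq_GO, off.go.values[i])
            + cfg.K_GO / N * acc
            - eps_G * np.sin(state.theta_GO[i] - state.theta_G[i])
            + F_GO * r_MO * np.sin(psi_MO - state.theta_GO[i])
        )

    sign = 1.0 if cfg.mo_go_attractive else -1.0
    dMO = np.zeros(M)
    for i in range(M):
        acc = 0.0
        for j in range(M):
            acc += weight(i + 1, j + 1, M, cfg.kernel) * np.sin(
                state.theta_MO[j] - state.theta_MO[i]
            )
        dMO[i] = (
            omega(cfg.freq_MO, off.mo.values[i])
            - eps_O * np.sin(state.theta_MO[i] - state.theta_O[i])
            + cfg.K_MO / M * acc
            + sign * F_MO * r_GO * np.sin(psi_GO - state.theta_MO[i])
        )
    return PhaseState(dG, dO, dGO, dMO)


def random_setup(N: int, M: int, seed: int):
    cfg = ModelConfig(N=N, M=M, F_GO=0.11, F_MO=0.07, seed=seed)
    rng = np.random.default_rng(seed)
    off = OffsetSet(
        g=sample_offsets(cfg.freq_G, N, rng, cfg.offset_mode),
        o=sample_offsets(cfg.freq_O, M, rng, cfg.offset_mode),
        go=sample_offsets(cfg.freq_GO, N, rng, cfg.offset_mode),
        mo=sample_offsets(cfg.freq_MO, M, rng, cfg.offset_mode),
    )
    state = PhaseState.unpack(rng.uniform(-10, 10, 2 * N + 2 * M), N, M)
    return cfg, off, state
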