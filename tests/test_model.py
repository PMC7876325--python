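"""Unit tests for the ring geometry, frequencies and governing equations."""

import numpy as np
import pytest
from scipy.integrate import quad

from kuramet import (
    FrequencyParams,
    KernelKind,
    ModelConfig,
    OffsetSet,
    PhaseModel,
    PhaseOffsets,
    PhaseState,
    WeightKernel,
    instantaneous_frequency,
    order_parameter,
    rhs,
    ring_distance,
    sample_offsets,
    weight,
)
from kuramet.model import _ring_distance_matrix
from kuramet.schedule import evaluate_coupling


# ---------------------------------------------------------------------------
# ring distance and weights


@pytest.mark.parametrize(
    "i,j,N,expected",
    [
        (1, 2, 100, 1),     # near branch |i-j|
        (1, 100, 100, 1),   # wrapped branch |j-N-i|
        (7, 7, 100, 0),     # identity
        (1, 51, 100, 50),   # antipode
        (2, 51, 100, 49),
        (60, 9, 100, 49),   # i > N/2 wrapped branch |j+N-i|
    ],
)
def test_ring_distance_examples(i, j, N, expected):
    assert ring_distance(i, j, N) == expected


def test_ring_distance_symmetric_and_bounded_all_small_rings():
    """W_ij = W_ji for every ring size up to 200, exhaustively."""
    for n in range(1, 201):
        d = _ring_distance_matrix(n)
        assert (d == d.T).all()
        assert d.max() <= int(np.ceil(n / 2))
        assert (np.diag(d) == 0).all()
        assert (d[~np.eye(n, dtype=bool)] > 0).all()


def test_ring_distance_matrix_matches_scalar():
    for n in (5, 6, 10, 13):
        d = _ring_distance_matrix(n)
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                assert d[i - 1, j - 1] == ring_distance(i, j, n)


def test_ring_distance_rejects_bad_indices():
    with pytest.raises(ValueError):
        ring_distance(0, 1, 10)
    with pytest.raises(ValueError):
        ring_distance(1, 11, 10)


def test_harmonic_weights():
    k = WeightKernel(KernelKind.harmonic_decay, 1.0)
    assert weight(1, 2, 100, k) == 1.0
    assert weight(1, 3, 100, k) == 0.5
    assert weight(5, 5, 100, k) == 0.0


def test_uniform_kernel_reproduces_unweighted_network():
    k = WeightKernel(KernelKind.uniform, 1.0)
    W = k.matrix(10)
    assert (np.diag(W) == 0).all()
    assert (W[~np.eye(10, dtype=bool)] == 1.0).all()


def test_kernel_kinds_at_distance():
    d = np.array([0, 1, 2, 3])
    np.testing.assert_allclose(
        WeightKernel(KernelKind.harmonic_decay, 2.0).weight_of_distance(d), [0, 2, 1, 2 / 3]
    )
    np.testing.assert_allclose(
        WeightKernel(KernelKind.power_decay, 0.5).weight_of_distance(d), [0, 0.5, 0.25, 0.125]
    )
    np.testing.assert_allclose(
        WeightKernel(KernelKind.linear_growth, 2.0).weight_of_distance(d), [0, 2, 4, 6]
    )


def test_harmonic_weight_nonincreasing_in_distance():
    k = WeightKernel(KernelKind.harmonic_decay, 1.0)
    for n in (6, 17, 50):
        d = _ring_distance_matrix(n)
        w = k.matrix(n)
        i = 0
        order = np.argsort(d[i])
        off = order[1:]  # skip self
        assert (np.diff(w[i][off]) <= 1e-15).all()


# ---------------------------------------------------------------------------
# offsets and frequencies


def test_sample_offsets_bounds_and_determinism():
    params = FrequencyParams(0.1, 0.01, 2 * np.pi / 2000)
    r1 = sample_offsets(params, 100, np.random.default_rng(5), mode="time")
    r2 = sample_offsets(params, 100, np.random.default_rng(5), mode="time")
    assert (r1.values >= 0).all() and (r1.values <= 2000 / (2 * np.pi) + 1e-12).all()
    np.testing.assert_array_equal(r1.values, r2.values)

    ts = sample_offsets(params, 100, np.random.default_rng(5), mode="time_shift")
    assert (ts.values >= 0).all() and (ts.values <= 1.0).all()
    ph = sample_offsets(params, 100, np.random.default_rng(5), mode="phase")
    assert (ph.values <= 2 * np.pi).all()


def test_sample_offsets_zero_amplitude_gives_zeros():
    off = sample_offsets(FrequencyParams(0.1), 7, np.random.default_rng(0))
    assert (off.values == 0).all()


def test_frequency_params_validation():
    with pytest.raises(ValueError):
        FrequencyParams(0.0)
    with pytest.raises(ValueError):
        FrequencyParams(0.1, mod_amplitude=0.01, mod_frequency=0.0)
    with pytest.raises(ValueError):
        FrequencyParams(0.1, mod_amplitude=-0.01, mod_frequency=0.1)


def test_instantaneous_frequency_bounds_and_mean():
    p = FrequencyParams(0.1, 0.02, 2 * np.pi / 500)
    t = np.linspace(0, 5000, 2001)
    w = p.omega_mean + p.mod_amplitude * np.sin(p.mod_frequency * t + 0.3)
    np.testing.assert_allclose(instantaneous_frequency(t[0], p, 0.3), w[0])
    # extremum of the sine
    t_star = (np.pi / 2 - 0.3) / p.mod_frequency
    assert instantaneous_frequency(t_star, p, 0.3) == pytest.approx(0.12)
    # time-average over one modulation period equals the mean frequency
    period = 2 * np.pi / p.mod_frequency
    avg, _ = quad(lambda t: instantaneous_frequency(t, p, 0.3), 0, period)
    assert avg / period == pytest.approx(p.omega_mean, abs=1e-12)
    # zero amplitude: constant
    assert instantaneous_frequency(123.0, FrequencyParams(0.1), 5.0) == 0.1


# ---------------------------------------------------------------------------
# order parameter


def test_order_parameter_identities():
    r, _ = order_parameter(np.full(50, 1.3))
    assert r == pytest.approx(1.0)
    n = 16
    r, _ = order_parameter(2 * np.pi * np.arange(n) / n)
    assert r == pytest.approx(0.0, abs=1e-12)
    r, psi = order_parameter(np.array([0.0, np.pi / 2]))
    assert r == pytest.approx(np.sqrt(2) / 2)
    assert psi == pytest.approx(np.pi / 4)
    with pytest.raises(ValueError):
        order_parameter(np.array([]))


def test_order_parameter_shift_invariance(rng):
    phases = rng.uniform(0, 2 * np.pi, 100)
    r1, _ = order_parameter(phases)
    r2, _ = order_parameter(phases + 1.7)
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_order_parameter_wrapped_normal_limit(rng):
    """r of a wrapped-normal sample converges to exp(-sigma^2/2)."""
    n = 10_000
    for sigma in (0.3, 0.8, 1.5):
        phases = rng.normal(0.0, sigma, n)
        r, _ = order_parameter(phases)
        expected = np.exp(-sigma**2 / 2)
        se = np.sqrt((1 - expected**2) / (2 * n))  # conservative phasor s.e.
        assert abs(r - expected) < 3 * max(se, 1e-3)


# ---------------------------------------------------------------------------
# right-hand side


def _naive_rhs(t, state: PhaseState, cfg: ModelConfig, off: OffsetSet) -> PhaseState:
    """Independent double-loop transcription of the governing equations."""
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
        s = 0.0
        for j in range(N):
            s += weight(i + 1, j + 1, N, cfg.kernel) * np.sin(
                state.theta_GO[j] - state.theta_GO[i]
            )
        dGO[i] = (
            omega(cfg.freq_GO, off.go.values[i])
            + cfg.K_GO / N * s
            - eps_G * np.sin(state.theta_GO[i] - state.theta_G[i])
            + F_GO * r_MO * np.sin(psi_MO - state.theta_GO[i])
        )
    sign = 1.0 if cfg.mo_go_attractive else -1.0
    dMO = np.zeros(M)
    for i in range(M):
        s = 0.0
        for j in range(M):
            s += weight(i + 1, j + 1, M, cfg.kernel) * np.sin(
                state.theta_MO[j] - state.theta_MO[i]
            )
        dMO[i] = (
            omega(cfg.freq_MO, off.mo.values[i])
            + cfg.K_MO / M * s
            - eps_O * np.sin(state.theta_MO[i] - state.theta_O[i])
            + sign * F_MO * r_GO * np.sin(psi_GO - state.theta_MO[i])
        )
    return PhaseState(dG, dO, dGO, dMO)


def _random_setup(N, M, seed, **kwargs):
    cfg = ModelConfig(N=N, M=M, F_GO=0.11, F_MO=0.07, seed=seed, **kwargs)
    rng = np.random.default_rng(seed)
    off = OffsetSet(
        g=sample_offsets(cfg.freq_G, N, rng, cfg.offset_mode),
        o=sample_offsets(cfg.freq_O, M, rng, cfg.offset_mode),
        go=sample_offsets(cfg.freq_GO, N, rng, cfg.offset_mode),
        mo=sample_offsets(cfg.freq_MO, M, rng, cfg.offset_mode),
    )
    state = PhaseState.unpack(rng.uniform(-10, 10, 2 * N + 2 * M), N, M)
    return cfg, off, state


@pytest.mark.parametrize("N,M", [(1, 1), (2, 3), (5, 5), (4, 2)])
@pytest.mark.parametrize("attractive", [True, False])
def test_rhs_matches_naive_double_loop(N, M, attractive):
    """Vectorised RHS agrees with the independent transcription to 1e-12."""
    for seed in range(3):
        cfg, off, state = _random_setup(N, M, seed, mo_go_attractive=attractive)
        fast = rhs(0.0, state, cfg, off).pack()
        slow = _naive_rhs(0.0, state, cfg, off).pack()
        np.testing.assert_allclose(fast, slow, atol=1e-12, rtol=0)
        fast = rhs(77.7, state, cfg, off).pack()
        slow = _naive_rhs(77.7, state, cfg, off).pack()
        np.testing.assert_allclose(fast, slow, atol=1e-12, rtol=0)


def test_rhs_zero_couplings_returns_mean_frequencies():
    cfg = ModelConfig(
        N=3, M=2, K_GO=0, K_MO=0, eps_G=0, eps_O=0, F_GO=0, F_MO=0,
        freq_G=FrequencyParams(0.1), freq_O=FrequencyParams(0.2),
        freq_GO=FrequencyParams(0.3), freq_MO=FrequencyParams(0.4),
    )
    off = OffsetSet(*(PhaseOffsets(np.zeros(k)) for k in (3, 2, 3, 2)))
    state = PhaseState.unpack(np.linspace(-3, 3, 10), 3, 2)
    v = rhs(5.0, state, cfg, off)
    np.testing.assert_allclose(v.theta_G, 0.1)
    np.testing.assert_allclose(v.theta_O, 0.2)
    np.testing.assert_allclose(v.theta_GO, 0.3)
    np.testing.assert_allclose(v.theta_MO, 0.4)


def test_rhs_translation_invariance():
    """A common phase shift leaves every coupling term unchanged."""
    cfg, off, state = _random_setup(4, 3, 9)
    v1 = rhs(3.0, state, cfg, off).pack()
    shifted = PhaseState.unpack(state.pack() + 2.345, 4, 3)
    v2 = rhs(3.0, shifted, cfg, off).pack()
    np.testing.assert_allclose(v1, v2, atol=1e-12)


@pytest.mark.parametrize("n", [6, 10])
def test_rhs_ring_symmetry_under_cyclic_relabeling(n):
    """Cyclically shifting oscillator labels permutes the RHS identically."""
    cfg, off, state = _random_setup(n, n, 21)
    roll = lambda a, k: np.roll(a, k)
    for k in (1, 3):
        state_r = PhaseState(
            roll(state.theta_G, k), roll(state.theta_O, k),
            roll(state.theta_GO, k), roll(state.theta_MO, k),
        )
        off_r = OffsetSet(
            PhaseOffsets(roll(off.g.values, k)), PhaseOffsets(roll(off.o.values, k)),
            PhaseOffsets(roll(off.go.values, k)), PhaseOffsets(roll(off.mo.values, k)),
        )
        v = rhs(11.0, state, cfg, off)
        v_r = rhs(11.0, state_r, cfg, off_r)
        np.testing.assert_allclose(roll(v.theta_GO, k), v_r.theta_GO, atol=1e-12)
        np.testing.assert_allclose(roll(v.theta_MO, k), v_r.theta_MO, atol=1e-12)


def test_rhs_single_pair_reduces_to_ancestor_model():
    """N = M = 1, K = 0: velocities match the two-oscillator equations."""
    cfg = ModelConfig(
        N=1, M=1, K_GO=0, K_MO=0, eps_G=0.1, eps_O=0.2, F_GO=0.3, F_MO=0.4,
        freq_G=FrequencyParams(1.0), freq_O=FrequencyParams(2.0),
        freq_GO=FrequencyParams(3.0), freq_MO=FrequencyParams(4.0),
        mo_go_attractive=True,
    )
    off = OffsetSet(*(PhaseOffsets(np.zeros(1)) for _ in range(4)))
    th = {"G": 0.3, "O": -0.8, "GO": 1.1, "MO": 2.9}
    state = PhaseState(*[np.array([th[k]]) for k in ("G", "O", "GO", "MO")])
    v = rhs(0.0, state, cfg, off)
    # with a single oscillator the mean field is the oscillator itself (r = 1)
    assert v.theta_GO[0] == pytest.approx(
        3.0 - 0.1 * np.sin(th["GO"] - th["G"]) + 0.3 * np.sin(th["MO"] - th["GO"])
    )
    assert v.theta_MO[0] == pytest.approx(
        4.0 - 0.2 * np.sin(th["MO"] - th["O"]) + 0.4 * np.sin(th["GO"] - th["MO"])
    )


def test_rhs_dimension_mismatch_raises(tiny_config):
    model = PhaseModel(tiny_config)
    with pytest.raises(ValueError):
        PhaseState.unpack(np.zeros(7), tiny_config.N, tiny_config.M)
    bad = OffsetSet(*(PhaseOffsets(np.zeros(9)) for _ in range(4)))
    with pytest.raises(ValueError):
        PhaseModel(tiny_config, bad)


# ---------------------------------------------------------------------------
# config plumbing


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(N=0)
    with pytest.raises(ValueError):
        ModelConfig(K_GO=-0.1)
    with pytest.raises(ValueError):
        ModelConfig(noise_sigma=-1.0)


def test_config_yaml_round_trip(tiny_config):
    restored = ModelConfig.from_yaml(tiny_config.to_yaml())
    assert restored == tiny_config
    restored = ModelConfig.from_json(tiny_config.to_json())
    assert restored == tiny_config


def test_config_round_trip_with_schedules():
    from kuramet import HelaSpec, hela_config

    cfg = hela_config(HelaSpec(seed=3))
    restored = ModelConfig.from_yaml(cfg.to_yaml())
    assert restored == cfg
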