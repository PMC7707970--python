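"""First-passage statistics: Monte Carlo, backward-FPK survival, NMFPT."""

import numpy as np
import pytest

from fhnswitch import (
    CouplingSpec,
    FNParams,
    InitEnsemble,
    NMFPTConfig,
    PassageProblem,
    SimConfig,
    StableNoiseSpec,
    build_ring_lattice,
    mfpt_from_survival,
    mfpt_monte_carlo,
    nmfpt_estimate,
    nmfpt_surface,
    survival_backward_fpk,
)
from fhnswitch.passage import SurvivalGrid
from fhnswitch.synthetic import RingNetwork


def test_absorbed_at_start_gives_zero(params_bistable):
    prob = PassageProblem(
        params_bistable, StableNoiseSpec(gamma=0.3), start=(1.5, 2.0), u_high=1.0
    )
    est = mfpt_monte_carlo(prob, SimConfig(dt=0.01, t_end=1.0), n_paths=10)
    assert est.mean == 0.0 and est.censored == 0


def test_mfpt_matches_double_well_quadrature_oracle():
    """Effectively-1D double well: MC exit time vs the exact double integral.

    With a ~ 0 the recovery variable stays at 0 and u follows the gradient
    SDE du = -V'(u) dt + sqrt(D) dW with V = -u^2/2 + u^4/12 and D = 2 gamma^2.
    The exit time from the left well (-sqrt(3)) to u = 1 has the closed
    quadrature form (2/D) int_x0^1 exp(2V(y)/D) int_-inf^y exp(-2V(z)/D) dz dy.
    """
    gamma = 0.6
    D = 2 * gamma**2
    p = FNParams(a=1e-9, b=1.0, c=1.0, e=1.0)
    x0, theta = -np.sqrt(3.0), 1.0

    V = lambda u: -(u**2) / 2.0 + u**4 / 12.0
    z = np.linspace(-6.0, theta, 4001)
    inner = np.concatenate(
        [[0.0], np.cumsum(0.5 * np.diff(z) * (np.exp(-2 * V(z) / D)[1:] + np.exp(-2 * V(z) / D)[:-1]))]
    )
    y_mask = z >= x0
    integrand = np.exp(2 * V(z[y_mask]) / D) * inner[y_mask]
    oracle = (2.0 / D) * np.trapezoid(integrand, z[y_mask])

    prob = PassageProblem(p, StableNoiseSpec(gamma=gamma), start=(x0, 0.0), u_high=theta)
    # dt small enough that discrete threshold monitoring does not bias the exit
    est = mfpt_monte_carlo(prob, SimConfig(dt=0.002, t_end=800.0, seed=17), n_paths=400)
    assert est.censored == 0
    assert abs(est.mean - oracle) < 3 * est.sem


def test_mfpt_decreases_with_noise(params_bistable, eq_low):
    cfg = SimConfig(dt=0.01, t_end=300.0, seed=4)
    means = []
    for g in (0.3, 0.4):
        prob = PassageProblem(params_bistable, StableNoiseSpec(gamma=g), tuple(eq_low))
        means.append(mfpt_monte_carlo(prob, cfg, n_paths=200).mean)
    assert means[0] > means[1]


def test_sem_shrinks_like_inverse_sqrt_n(params_bistable, eq_low):
    cfg = SimConfig(dt=0.01, t_end=300.0, seed=9)
    prob = PassageProblem(params_bistable, StableNoiseSpec(gamma=0.4), tuple(eq_low))
    s_small = mfpt_monte_carlo(prob, cfg, n_paths=150).sem
    s_big = mfpt_monte_carlo(prob, SimConfig(dt=0.01, t_end=300.0, seed=10), n_paths=600).sem
    assert 1.4 < s_small / s_big < 2.9  # expect ~2 = sqrt(600/150)


@pytest.fixture(scope="module")
def survival_solution(params_bistable, eq_low):
    prob = PassageProblem(
        params_bistable,
        StableNoiseSpec(gamma=0.4),
        start=tuple(eq_low),
        u_high=1.0,
        domain=(-3.2, 1.0, -4.4, 2.4),
    )
    grid = survival_backward_fpk(prob, n_u=81, n_v=81, t_max=100.0, dt0=0.02, dt_late=0.25)
    return prob, grid


def test_survival_bounds_and_monotone_decay(survival_solution):
    """Discrete maximum principle and pointwise decay of G."""
    _, grid = survival_solution
    assert grid.G.min() >= 0.0 and grid.G.max() <= 1.0
    interior = grid.G[0][:-1, :]
    assert np.all(interior == 1.0)  # initial condition inside R
    assert np.all(grid.G[0][-1, :] == 0.0)  # absorbing boundary
    assert np.all(np.diff(grid.G, axis=0) <= 1e-9)


def test_mfpt_field_zero_on_absorbing_boundary(survival_solution):
    _, grid = survival_solution
    fld = mfpt_from_survival(grid)
    assert np.all(fld.values[-1, :] == 0.0)
    assert fld.values.max() > 0.0


def test_mfpt_from_survival_exponential_fixture():
    """Synthetic G = exp(-t/tau0) integrates to tau0; G = 0 gives T = 0."""
    tau0 = 3.0
    u = np.linspace(-1.0, 1.0, 5)
    v = np.linspace(-1.0, 1.0, 5)
    t = np.linspace(0.0, 10 * tau0, 1201)
    G = np.exp(-t / tau0)[:, None, None] * np.ones((1, 5, 5))
    G[:, -1, :] = 0.0
    grid = SurvivalGrid(u_grid=u, v_grid=v, times=t, G=G, absorbing_edge="u_max")
    fld = mfpt_from_survival(grid, tail_tol=1.0)
    assert fld.values[0, 0] == pytest.approx(tau0, rel=1e-3)

    grid0 = SurvivalGrid(u_grid=u, v_grid=v, times=t, G=np.zeros_like(G), absorbing_edge="u_max")
    fld0 = mfpt_from_survival(grid0)
    assert np.all(fld0.values == 0.0)


def test_mfpt_from_survival_raises_without_decay():
    u = np.linspace(-1.0, 1.0, 4)
    t = np.linspace(0.0, 1.0, 10)
    G = np.ones((10, 4, 4))
    grid = SurvivalGrid(u_grid=u, v_grid=u, times=t, G=G, absorbing_edge="u_max")
    with pytest.raises(RuntimeError, match="not decayed"):
        mfpt_from_survival(grid, tail_tol=0.05, extrapolate=False)


def test_pde_grid_refinement_stability(params_bistable, eq_low):
    """Refining the grid changes T(start) by < 5% on the benchmark problem."""
    prob = PassageProblem(
        params_bistable,
        StableNoiseSpec(gamma=0.3),
        start=tuple(eq_low),
        u_high=1.0,
        domain=(-3.2, 1.0, -4.4, 2.4),
    )
    vals = []
    for n in (101, 141):
        grid = survival_backward_fpk(prob, n_u=n, n_v=n, t_max=400.0, dt0=0.02, dt_late=0.25)
        vals.append(mfpt_from_survival(grid).at(*eq_low))
    assert abs(vals[1] - vals[0]) / vals[1] < 0.05


def test_no_diffusion_no_escape(params_bistable, eq_low):
    """D_u = eps = 0 from inside the attracting basin: G stays ~1 at the start."""
    prob = PassageProblem(
        params_bistable,
        StableNoiseSpec(gamma=0.3),
        start=tuple(eq_low),
        u_high=1.0,
        domain=(-3.2, 1.0, -4.4, 2.4),
    )
    grid = survival_backward_fpk(
        prob, n_u=61, n_v=61, t_max=20.0, D_u=0.0, eps=0.0, dt0=0.05, dt_late=0.5
    )
    assert grid.interp(*eq_low) > 0.99


# ---------------------------------------------------------------------------
# NMFPT
# ---------------------------------------------------------------------------


def _singleton_network():
    return RingNetwork(
        n_nodes=1, k_neighbors=0, adjacency=np.zeros((1, 1)), laplacian=np.zeros((1, 1)),
        clustering=0.0,
    )


def test_nmfpt_zero_at_start_beyond_threshold(params_bistable):
    net = _singleton_network()
    ens = InitEnsemble(mode="custom", states=np.array([[-2.5, 0.0]]))
    res = nmfpt_estimate(
        params_bistable, net, CouplingSpec(0, 0), StableNoiseSpec(gamma=0.3), ens,
        SimConfig(dt=0.01, t_end=5.0, seed=0), NMFPTConfig(n_reps=4),
    )
    # start below u_low in the low basin: exit needs the far threshold, not tau=0
    assert res.pooled_mean > 0.0


def test_nmfpt_single_node_matches_single_unit_mfpt(params_bistable, eq_low):
    """A 1-node network NMFPT equals the single-unit MFPT estimate (3 sem)."""
    noise = StableNoiseSpec(gamma=0.4)
    net = _singleton_network()
    ens = InitEnsemble(mode="custom", states=np.array([eq_low], dtype=float))
    res = nmfpt_estimate(
        params_bistable, net, CouplingSpec(0, 0), noise, ens,
        SimConfig(dt=0.01, t_end=200.0, seed=3), NMFPTConfig(n_reps=200),
    )
    prob = PassageProblem(params_bistable, noise, tuple(eq_low), u_high=1.0)
    est = mfpt_monte_carlo(prob, SimConfig(dt=0.01, t_end=200.0, seed=4), n_paths=200)
    tol = 3 * np.hypot(res.pooled_sem, est.sem)
    assert abs(res.pooled_mean - est.mean) < tol


def test_nmfpt_uncoupled_network_matches_independent_units(params_bistable):
    """With d1 = d2 = 0 the network statistic is the average of single units."""
    noise = StableNoiseSpec(gamma=0.4)
    net = build_ring_lattice(20, 2)
    res = nmfpt_estimate(
        params_bistable, net, CouplingSpec(0.0, 0.0), noise, "random_basin",
        SimConfig(dt=0.01, t_end=200.0, seed=11), NMFPTConfig(n_reps=20),
    )
    eq_low = (-np.sqrt(2.0), -np.sqrt(2.0) * 2 / 1.5)
    prob = PassageProblem(params_bistable, noise, eq_low, u_high=1.0)
    est = mfpt_monte_carlo(prob, SimConfig(dt=0.01, t_end=200.0, seed=12), n_paths=400)
    tol = 3 * np.hypot(res.pooled_sem, est.sem)
    assert res.n_censored == 0
    assert abs(res.pooled_mean - est.mean) < tol


def test_nmfpt_all_censored_flagged(params_bistable):
    net = build_ring_lattice(10, 2)
    res = nmfpt_estimate(
        params_bistable, net, CouplingSpec(0.1, 0.1), StableNoiseSpec(gamma=0.01),
        "random_basin", SimConfig(dt=0.01, t_end=2.0, seed=0), NMFPTConfig(n_reps=3),
    )
    assert res.all_censored
    assert res.pooled_mean == pytest.approx(2.0)
    assert np.isnan(res.observed_mean)


def test_nmfpt_surface_single_cell_reduces_to_estimate(params_bistable):
    cfg = SimConfig(dt=0.01, t_end=50.0, seed=21)
    nmcfg = NMFPTConfig(n_reps=10)
    df = nmfpt_surface(
        params_bistable, k_list=[14], gamma_list=[0.5], n_nodes=30,
        coupling=CouplingSpec(0.1, 0.1), cfg=cfg, nmcfg=nmcfg,
    )
    net = build_ring_lattice(30, 14)
    res = nmfpt_estimate(
        params_bistable, net, CouplingSpec(0.1, 0.1), StableNoiseSpec(gamma=0.5),
        "random_basin", cfg, nmcfg,
    )
    assert df.shape[0] == 1
    assert df.nmfpt[0] == res.pooled_mean
    assert df.cc[0] == pytest.approx(net.clustering)


def test_nmfpt_rep_doubling_is_consistent(params_bistable):
    """Doubling realizations moves the estimate by a few pooled sems at most."""
    cfg = SimConfig(dt=0.01, t_end=60.0, seed=8)
    net = build_ring_lattice(30, 2)
    res_a = nmfpt_estimate(
        params_bistable, net, CouplingSpec(0.1, 0.1), StableNoiseSpec(gamma=0.5),
        "random_basin", cfg, NMFPTConfig(n_reps=10),
    )
    res_b = nmfpt_estimate(
        params_bistable, net, CouplingSpec(0.1, 0.1), StableNoiseSpec(gamma=0.5),
        "random_basin", cfg, NMFPTConfig(n_reps=20),
    )
    assert abs(res_a.pooled_mean - res_b.pooled_mean) < 3 * np.hypot(
        res_a.pooled_sem, res_b.pooled_sem
    )


def test_conditional_nmfpt_peaks_at_intermediate_noise(params_bistable):
    """On the uncoupled-like k=2 ring the crossing-conditioned mean first rises
    with noise (slow bulk exits enter the observation window) then falls."""
    df = nmfpt_surface(
        params_bistable, k_list=[2], gamma_list=[0.1, 0.2, 0.5, 0.9], n_nodes=100,
        cfg=SimConfig(dt=0.01, t_end=100.0, seed=5), nmcfg=NMFPTConfig(n_reps=50),
    )
    obs = df.nmfpt_observed.to_numpy()
    assert obs[1] > obs[0]
    assert obs[1] > obs[2] > obs[3]
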