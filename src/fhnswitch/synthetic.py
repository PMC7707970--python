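"""Synthetic inputs: stable-noise realizations, ring lattices, initial ensembles.

This module generates every input the pipeline consumes:

* **alpha-stable noise.**  The driver xi(t) is an alpha-stable process with
  characteristic exponent ``alpha`` in (0, 2], skewness ``beta`` in [-1, 1],
  scale ``gamma > 0`` and location ``delta`` (the standard 1-parameterization;
  ``alpha = 2`` is Gaussian noise with variance ``2 gamma^2`` per unit time).
  Sampling uses the Chambers-Mallows-Stuck transform, which is exact and
  needs no rejection step.  Euler-Maruyama increments over a step ``dt`` are
  self-similar: scale ``gamma dt^(1/alpha)`` and location ``delta dt``.

* **Ring lattices.**  K-nearest-neighbour coupled rings: node i is adjacent
  to i±1, ..., i±K/2 (mod N).  Their average local clustering coefficient is
  0 for K = 2 and ``3 (K-2) / (4 (K-1))`` for even K >= 4, so the coefficient
  is selected by choosing K (K = 14, 20, 36 give cc = 0.6923, 0.7105, 0.7286
  to 4 decimals at N = 100).

* **Initial ensembles.**  Per-node initial conditions placed at the stable
  equilibria of a bistable parameter set, uniformly or at random per node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .model import FNParams, find_equilibria

__all__ = [
    "StableNoiseSpec",
    "RingNetwork",
    "InitEnsemble",
    "stable_characteristic_function",
    "sample_stable_standard",
    "sample_stable_increments",
    "build_ring_lattice",
    "ring_clustering_closed_form",
    "clustering_coefficient",
    "graph_laplacian",
    "draw_initial_conditions",
    "write_edge_list",
    "write_adjacency_csv",
    "write_run_manifest",
]


@dataclass(frozen=True)
class StableNoiseSpec:
    """Parameters (alpha, beta, gamma, delta) of the stable noise law.

    The derived diffusion label ``d = gamma**alpha`` is the noise strength the
    sweeps are indexed by; it is always recomputed from gamma and alpha.
    """

    alpha: float = 2.0
    beta: float = 0.0
    gamma: float = 0.1
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 2.0):
            raise ValueError(f"alpha must be in (0, 2], got {self.alpha!r}")
        if not (-1.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [-1, 1], got {self.beta!r}")
        if not (self.gamma > 0.0):
            raise ValueError(f"gamma must be > 0, got {self.gamma!r}")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")

    @property
    def d(self) -> float:
        """Noise-strength label d = gamma**alpha."""
        return self.gamma**self.alpha

    @property
    def diffusion_u(self) -> float:
        """Diffusion constant of the simulated process (variance per unit time).

        For alpha = 2 the stable law with scale gamma has variance 2 gamma^2,
        so the Fokker-Planck diffusion entry consistent with the simulation is
        2 gamma^2 (not the label d = gamma^2).  Undefined (inf) for alpha < 2.
        """
        if self.alpha == 2.0:
            return 2.0 * self.gamma**2
        return float("inf")


def stable_characteristic_function(spec: StableNoiseSpec, t) -> np.ndarray | complex:
    """Characteristic function E[exp(i t X)] of the stable law (1-param form).

    For alpha != 1:
        exp(-gamma^alpha |t|^alpha [1 - i beta sign(t) tan(pi alpha / 2)] + i delta t)
    For alpha = 1:
        exp(-gamma |t| [1 + i beta sign(t) (2/pi) ln|t|] + i delta t)
    """
    t_arr = np.asarray(t, dtype=float)
    a, b, g, d = spec.alpha, spec.beta, spec.gamma, spec.delta
    at = np.abs(t_arr)
    sgn = np.sign(t_arr)
    if a != 1.0:
        expo = -(g**a) * at**a * (1.0 - 1j * b * sgn * np.tan(np.pi * a / 2.0)) + 1j * d * t_arr
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            logt = np.where(at > 0, np.log(np.where(at > 0, at, 1.0)), 0.0)
        expo = -g * at * (1.0 + 1j * b * sgn * (2.0 / np.pi) * logt) + 1j * d * t_arr
    out = np.exp(expo)
    return out if out.shape else complex(out)


def sample_stable_standard(alpha: float, beta: float, size, rng: np.random.Generator) -> np.ndarray:
    """Standard stable variates S(alpha, beta; scale 1, location 0) via CMS.

    Chambers-Mallows-Stuck transform: with U ~ Uniform(-pi/2, pi/2) and
    W ~ Exp(1) independent, an exact stable variate is produced with no
    rejection.  At alpha = 2 this reduces to 2 sin(U) sqrt(W) ~ N(0, 2).
    """
    u = rng.uniform(-np.pi / 2.0, np.pi / 2.0, size=size)
    w = rng.standard_exponential(size=size)
    if alpha != 1.0:
        tb = beta * np.tan(np.pi * alpha / 2.0)
        b0 = np.arctan(tb) / alpha
        s0 = (1.0 + tb * tb) ** (1.0 / (2.0 * alpha))
        x = (
            s0
            * np.sin(alpha * (u + b0))
            / np.cos(u) ** (1.0 / alpha)
            * (np.cos(u - alpha * (u + b0)) / w) ** ((1.0 - alpha) / alpha)
        )
    else:
        hp = np.pi / 2.0
        x = (1.0 / hp) * (
            (hp + beta * u) * np.tan(u)
            - beta * np.log((hp * w * np.cos(u)) / (hp + beta * u))
        )
    return x


def sample_stable_increments(
    spec: StableNoiseSpec,
    n: int,
    dt: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """n iid stable increments for an Euler-Maruyama step of length dt.

    Self-similar scaling: scale gamma * dt**(1/alpha), location delta * dt.
    Deterministic for a given integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = sample_stable_standard(spec.alpha, spec.beta, n, rng)
    scale = spec.gamma * dt ** (1.0 / spec.alpha)
    loc = spec.delta * dt
    if spec.alpha == 1.0 and spec.beta != 0.0:
        # 1-parameterization shift so that gamma*X + delta*dt keeps the CF form
        loc = loc + (2.0 / np.pi) * spec.beta * scale * np.log(scale)
    return scale * x + loc


# ---------------------------------------------------------------------------
# Ring lattices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingNetwork:
    """K-nearest-neighbour coupled ring: adjacency, Laplacian, clustering.

    The Laplacian is ``L = A - diag(degree)`` (negative semidefinite, zero row
    sums), so the coupling term ``Sum_j L_ij x_j`` is diffusive and vanishes
    on uniform states.
    """

    n_nodes: int
    k_neighbors: int
    adjacency: np.ndarray
    laplacian: np.ndarray
    clustering: float

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape mismatch")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")


def ring_clustering_closed_form(k: int) -> float:
    """Closed-form average clustering of a K-nearest-neighbour ring (even K)."""
    if k < 4:
        return 0.0
    return 3.0 * (k - 2) / (4.0 * (k - 1))


def build_ring_lattice(n_nodes: int, k_neighbors: int) -> RingNetwork:
    """Ring of n nodes, each adjacent to its k nearest neighbours (k even)."""
    n, k = int(n_nodes), int(k_neighbors)
    if k % 2 != 0:
        raise ValueError(f"k_neighbors must be even, got {k}")
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    g = nx.watts_strogatz_graph(n, k, p=0.0)  # p=0: the unrewired ring lattice
    adj = nx.to_numpy_array(g, nodelist=range(n), dtype=float)
    lap = adj - np.diag(adj.sum(axis=1))
    cc = float(nx.average_clustering(g))
    return RingNetwork(n_nodes=n, k_neighbors=k, adjacency=adj, laplacian=lap, clustering=cc)


def clustering_coefficient(net: RingNetwork) -> float:
    """Average local clustering coefficient, recomputed by triangle counting."""
    g = nx.from_numpy_array(net.adjacency)
    return float(nx.average_clustering(g))


def graph_laplacian(net: RingNetwork) -> np.ndarray:
    """L = adjacency - degree diagonal (rows sum to zero, eigenvalues <= 0)."""
    return net.adjacency - np.diag(net.adjacency.sum(axis=1))


# ---------------------------------------------------------------------------
# Initial-condition ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InitEnsemble:
    """Per-node initial (u, v) states with provenance (mode, seed)."""

    mode: str
    states: np.ndarray  # (n_nodes, 2)
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.states.shape[0]


def draw_initial_conditions(
    mode: str,
    params: FNParams,
    n_nodes: int,
    seed: int = 0,
    custom_states: np.ndarray | None = None,
) -> InitEnsemble:
    """Initial ensemble in one of the modes all_low / all_high / random_basin / custom.

    Basin modes place each node exactly at a stable equilibrium of a bistable
    parameter set; ``random_basin`` assigns nodes to the low/high basin
    independently with probability 1/2 (seeded).
    """
    if mode == "custom":
        if custom_states is None:
            raise ValueError("custom mode requires custom_states")
        states = np.asarray(custom_states, dtype=float).reshape(n_nodes, 2)
        return InitEnsemble(mode=mode, states=states, seed=None)
    eq = find_equilibria(params)
    if eq.regime != "bistable":
        raise ValueError(f"basin mode {mode!r} requires bistable params, regime is {eq.regime!r}")
    low, high = eq.stable_points[0], eq.stable_points[-1]
    if mode == "all_low":
        states = np.tile(np.array(low, dtype=float), (n_nodes, 1))
    elif mode == "all_high":
        states = np.tile(np.array(high, dtype=float), (n_nodes, 1))
    elif mode == "random_basin":
        rng = np.random.default_rng(seed)
        pick_high = rng.random(n_nodes) < 0.5
        states = np.where(
            pick_high[:, None], np.array(high, dtype=float), np.array(low, dtype=float)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return InitEnsemble(mode=mode, states=states, seed=int(seed))


# ---------------------------------------------------------------------------
# Text exports
# ---------------------------------------------------------------------------


def write_edge_list(net: RingNetwork, path) -> None:
    """Write the network as a two-column, 0-based edge list."""
    iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            fh.write(f"{i} {j}\n")


def write_adjacency_csv(net: RingNetwork, path) -> None:
    """Write the dense adjacency matrix as CSV (integers)."""
    np.savetxt(path, net.adjacency.astype(int), fmt="%d", delimiter=",")


def write_run_manifest(path, **entries) -> None:
    """Record noise specs, seeds and other run metadata as JSON."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    Path(path).write_text(json.dumps(entries, indent=2, default=_default) + "\n")
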