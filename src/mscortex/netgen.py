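"""Multi-scale connectome construction.

The network is organized on two scales.  Microscale: each cortical region is
a small-world graph of ``m`` neurons, obtained by rewiring a regular ring
lattice (Watts–Strogatz).  Macroscale: regions sit on a square lattice and
every ordered pair of neurons in *different* regions is connected
independently with probability

    P(i, j) = rho * exp(-[(x_i - x_j)^2 + (y_i - y_j)^2] / (2 sigma^2)),

an exponential-distance rule evaluated at the two regions' lattice
coordinates.  ``rho`` sets the overall inter-regional density and ``sigma``
the spatial scale over which connections occur.

Strengths follow a synaptic-scaling rule: a within-region edge has strength
1/m; an inter-regional edge into neuron i has strength 1/N_in(i), where
N_in(i) is the *total* (local + inter-regional) in-degree of i.  Absent
pairs have strength zero.  ``A[i, k]`` is the strength of the edge k -> i,
so row i of ``A`` lists the incoming connections of neuron i.

The macroscale matrix ``R`` sums neuron-level strengths over regional
blocks: R_ik = sum_{x in Y_i} sum_{y in Y_k} A_xy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "RegionLayout",
    "SmallWorldParams",
    "InterRegionParams",
    "Connectome",
    "MacroConnectome",
    "build_region_lattice",
    "ring_degree",
    "build_small_world",
    "connection_probability",
    "region_probability_matrix",
    "sample_inter_regional_edges",
    "assemble_connectome",
    "build_connectome",
    "macroscale_matrix",
    "write_connectome",
    "read_connectome",
    "write_macro_csv",
    "read_macro_csv",
]


@dataclass(frozen=True)
class RegionLayout:
    """Lattice coordinates and neuron-to-region membership.

    Regions are indexed left-to-right, top-down on a unit-spaced
    ``grid_side x grid_side`` grid (x rightward, y downward).  Neuron
    indices are contiguous blocks: region g owns ``[g*m, (g+1)*m)``.
    """

    z: int
    m: int
    coords: np.ndarray  # (z, 2) float, columns (x, y)
    membership: np.ndarray  # (n,) int

    @property
    def n(self) -> int:
        return self.z * self.m

    @property
    def grid_side(self) -> int:
        return math.isqrt(self.z)

    def neurons_of(self, g: int) -> slice:
        """Index slice of the neurons belonging to region ``g``."""
        return slice(g * self.m, (g + 1) * self.m)


@dataclass(frozen=True)
class SmallWorldParams:
    """Within-region (microscale) graph parameters.

    c : local connection density (fraction of ordered pairs), default 0.1.
    p : Watts–Strogatz rewiring probability, default 0.1.
    """

    c: float = 0.1
    p: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"local density c must lie in (0, 1); got {self.c}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"rewiring probability p must lie in [0, 1]; got {self.p}")


@dataclass(frozen=True)
class InterRegionParams:
    """Exponential-distance-rule parameters: density scale rho, spatial scale sigma."""

    rho: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1]; got {self.rho}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive; got {self.sigma}")


@dataclass(frozen=True)
class Connectome:
    """Full neuron-level strength matrix with provenance.

    ``A[i, k]`` is the strength of the directed edge k -> i (zero when no
    edge exists); ``N_in[i]`` is the total in-degree of neuron i.
    """

    A: np.ndarray  # (n, n) float64
    N_in: np.ndarray  # (n,) int
    layout: RegionLayout
    sw_params: SmallWorldParams | None = None
    ir_params: InterRegionParams | None = None
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.layout.n


@dataclass(frozen=True)
class MacroConnectome:
    """Region-by-region matrix of summed connection strengths.

    ``scale_mode`` is ``"raw"`` (plain block sums of A) or ``"per_neuron"``
    (block sums divided by m).
    """

    R: np.ndarray  # (z, z)
    scale_mode: str
    layout: RegionLayout | None = None

    @property
    def z(self) -> int:
        return self.R.shape[0]


def build_region_lattice(z: int, m: int) -> RegionLayout:
    """Place ``z`` regions of ``m`` neurons each on a square lattice.

    ``z`` must be a perfect square.  Coordinates are unit spaced with the
    origin at the top-left corner; region g sits at
    ``(g % side, g // side)``.
    """
    if z < 1 or m < 1:
        raise ValueError("z and m must be positive integers")
    side = math.isqrt(z)
    if side * side != z:
        raise ValueError(
            f"region count z must be a perfect square (square lattice); got z={z}"
        )
    g = np.arange(z)
    coords = np.column_stack([g % side, g // side]).astype(float)
    membership = np.repeat(g, m)
    return RegionLayout(z=z, m=m, coords=coords, membership=membership)


def ring_degree(m: int, c: float) -> int:
    """Ring-lattice neighbor count: c*(m-1) rounded to the nearest even integer."""
    k = 2 * round(c * (m - 1) / 2.0)
    if k < 2:
        raise ValueError(
            f"c*(m-1) = {c * (m - 1):.3g} rounds below 2; "
            "the ring lattice needs at least one neighbor per side"
        )
    if k >= m:
        raise ValueError(f"ring degree {k} must be smaller than m={m}")
    return k


def build_small_world(
    m: int, params: SmallWorldParams, rng: np.random.Generator
) -> np.ndarray:
    """Directed 0/1 adjacency of one region's small-world graph.

    The graph is built undirected (ring lattice of ``ring_degree(m, c)``
    neighbors, each edge rewired with probability p, edge count conserved)
    and expanded to reciprocal directed edges.  Entry ``[i, k] = 1`` means
    k -> i.
    """
    k = ring_degree(m, params.c)
    g = nx.watts_strogatz_graph(m, k, params.p, seed=rng)
    adj = nx.to_numpy_array(g, nodelist=range(m), dtype=np.uint8)
    return adj


def connection_probability(
    coord_i: np.ndarray, coord_j: np.ndarray, params: InterRegionParams
) -> float:
    """Exponential-distance-rule probability for one pair of region coordinates."""
    ci = np.asarray(coord_i, dtype=float)
    cj = np.asarray(coord_j, dtype=float)
    if not (np.all(np.isfinite(ci)) and np.all(np.isfinite(cj))):
        raise ValueError("coordinates must be finite")
    d2 = float(np.sum((ci - cj) ** 2))
    return params.rho * math.exp(-d2 / (2.0 * params.sigma**2))


def region_probability_matrix(
    layout: RegionLayout, params: InterRegionParams
) -> np.ndarray:
    """(z, z) matrix of pairwise connection probabilities; diagonal zeroed.

    Within-region connectivity is governed by the small-world graph, never
    by the distance rule, hence the zero diagonal.
    """
    diff = layout.coords[:, None, :] - layout.coords[None, :, :]
    d2 = np.sum(diff**2, axis=-1)
    p = params.rho * np.exp(-d2 / (2.0 * params.sigma**2))
    np.fill_diagonal(p, 0.0)
    return p


def sample_inter_regional_edges(
    layout: RegionLayout, params: InterRegionParams, rng: np.random.Generator
) -> np.ndarray:
    """Sample directed inter-regional neuron pairs independently.

    Each ordered cross-region pair (k -> i) is included with the
    distance-rule probability of the two regions.  Returns an (E, 2) int
    array with columns (i, k) = (target, source); no within-region pairs.
    """
    n = layout.n
    p_region = region_probability_matrix(layout, params)
    p_neuron = p_region[layout.membership][:, layout.membership]
    mask = rng.random((n, n)) < p_neuron
    return np.argwhere(mask)


def assemble_connectome(
    local_adjacencies: list[np.ndarray],
    inter_edges: np.ndarray,
    layout: RegionLayout,
    *,
    sw_params: SmallWorldParams | None = None,
    ir_params: InterRegionParams | None = None,
    seed: int | None = None,
) -> Connectome:
    """Combine local blocks and inter-regional edges into a strength matrix.

    Within-region strengths are 1/m; inter-regional strengths into neuron i
    are 1/N_in(i) with N_in(i) the total in-degree (local plus
    inter-regional) of i.
    """
    z, m, n = layout.z, layout.m, layout.n
    if len(local_adjacencies) != z:
        raise ValueError(f"expected {z} local adjacency blocks, got {len(local_adjacencies)}")
    inter_edges = np.asarray(inter_edges, dtype=np.int64).reshape(-1, 2)

    adj = np.zeros((n, n), dtype=bool)
    for g, block in enumerate(local_adjacencies):
        if block.shape != (m, m):
            raise ValueError(f"local adjacency of region {g} must be {m}x{m}")
        sl = layout.neurons_of(g)
        adj[sl, sl] = block.astype(bool)
    if np.any(adj.diagonal()):
        raise ValueError("local adjacencies must not contain self-loops")

    if inter_edges.size:
        tgt, src = inter_edges[:, 0], inter_edges[:, 1]
        if np.any(layout.membership[tgt] == layout.membership[src]):
            raise ValueError("inter-regional edges must connect different regions")
        inter_mask = np.zeros((n, n), dtype=bool)
        inter_mask[tgt, src] = True
    else:
        inter_mask = np.zeros((n, n), dtype=bool)

    n_in = adj.sum(axis=1) + inter_mask.sum(axis=1)
    # Any neuron holding an inter-regional in-link has N_in >= 1 by construction.
    assert np.all(n_in[inter_mask.any(axis=1)] > 0)

    A = np.zeros((n, n), dtype=np.float64)
    A[adj] = 1.0 / m
    if inter_edges.size:
        rows = np.nonzero(inter_mask)
        A[rows] = 1.0 / n_in[rows[0]]
    return Connectome(
        A=A,
        N_in=n_in.astype(np.int64),
        layout=layout,
        sw_params=sw_params,
        ir_params=ir_params,
        seed=seed,
    )


def build_connectome(
    z: int,
    m: int,
    sw_params: SmallWorldParams,
    ir_params: InterRegionParams,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> Connectome:
    """Full pipeline: lattice, per-region small worlds, distance-rule edges, strengths."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layout = build_region_lattice(z, m)
    local = [build_small_world(m, sw_params, rng) for _ in range(z)]
    inter = sample_inter_regional_edges(layout, ir_params, rng)
    stored_seed = seed if isinstance(seed, int) else None
    return assemble_connectome(
        local, inter, layout, sw_params=sw_params, ir_params=ir_params, seed=stored_seed
    )


def macroscale_matrix(conn: Connectome, scale_mode: str = "per_neuron") -> MacroConnectome:
    """Region-level matrix R_ik = sum of A over the (i, k) regional block.

    The diagonal (within-region block sums) is kept.  ``per_neuron`` mode
    divides the raw block sums by m, which is the default input to
    structural complexity (raw entries would violate its weak-coupling
    premise).
    """
    if scale_mode not in ("raw", "per_neuron"):
        raise ValueError(f"scale_mode must be 'raw' or 'per_neuron'; got {scale_mode!r}")
    z, m = conn.layout.z, conn.layout.m
    R = conn.A.reshape(z, m, z, m).sum(axis=(1, 3))
    if scale_mode == "per_neuron":
        R = R / m
    return MacroConnectome(R=R, scale_mode=scale_mode, layout=conn.layout)


# ---------------------------------------------------------------------------
# External interfaces: Matrix Market + sidecar JSON, dense CSV for R


def write_connectome(conn: Connectome, path: str | Path) -> None:
    """Write A as Matrix Market coordinate (real general) plus a JSON sidecar."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(conn.A))
    sidecar = {
        "z": conn.layout.z,
        "m": conn.layout.m,
        "coords": conn.layout.coords.tolist(),
        "sw_params": None
        if conn.sw_params is None
        else {"c": conn.sw_params.c, "p": conn.sw_params.p},
        "ir_params": None
        if conn.ir_params is None
        else {"rho": conn.ir_params.rho, "sigma": conn.ir_params.sigma},
        "seed": conn.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_connectome(path: str | Path) -> Connectome:
    """Read a connectome written by :func:`write_connectome`."""
    path = Path(path)
    raw = scipy.io.mmread(str(path))
    A = np.asarray(raw.toarray() if scipy.sparse.issparse(raw) else raw, dtype=np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    layout = build_region_lattice(meta["z"], meta["m"])
    sw = None if meta["sw_params"] is None else SmallWorldParams(**meta["sw_params"])
    ir = None if meta["ir_params"] is None else InterRegionParams(**meta["ir_params"])
    n_in = (A != 0).sum(axis=1).astype(np.int64)
    return Connectome(
        A=A, N_in=n_in, layout=layout, sw_params=sw, ir_params=ir, seed=meta["seed"]
    )


def write_macro_csv(macro: MacroConnectome, path: str | Path) -> None:
    labels = [f"g{i}" for i in range(macro.z)]
    pd.DataFrame(macro.R, index=labels, columns=labels).to_csv(path)


def read_macro_csv(path: str | Path, scale_mode: str = "raw") -> MacroConnectome:
    df = pd.read_csv(path, index_col=0)
    return MacroConnectome(R=df.to_numpy(dtype=float), scale_mode=scale_mode)
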