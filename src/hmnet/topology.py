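"""Hierarchical modular network construction and connectivity analytics.

Networks are built by recursive split-and-rewire: starting from a directed
Erdos-Renyi graph of ``N`` neurons with connection probability ``eps``, each
module is randomly split into two equal halves, and every connection that
becomes intermodular is, with probability ``Rex`` (excitatory presynaptic
neuron) or ``Rin`` (inhibitory), redirected to a random target inside the
presynaptic neuron's own module.  After ``H`` elevations the network has
``2**H`` equal modules; with ``Rin = 1`` every inhibitory connection is
strictly intramodular while excitation remains partly long-range.

The expected intramodular in-degree obeys the recursion

    n_in(0)   = N*eps
    n_in(h+1) = n_in(h)*(1 - R)/2 + N*eps*R

with limit ``2*N*R*eps/(R + 1)`` as ``h`` grows, and the intermodular
in-degree is ``n_out(h) = N*eps - n_in(h)``.  The intramodular density is
``eps_in = 2**h * n_in / N`` and grows with ``h`` because modules shrink
while ``n_in`` saturates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "TopologyConfig",
    "NetworkTopology",
    "ConnectivityPrediction",
    "build_base_random",
    "elevate_hierarchy",
    "build_hierarchy",
    "expected_n_in",
    "measure_connectivity",
    "save_topology",
    "load_topology",
]

@dataclass(frozen=True)
class TopologyConfig:
    """Parameters of the split-and-rewire construction.

    n_neurons : network size N (must be divisible by 2**hierarchy_level)
    connectivity : Erdos-Renyi connection probability eps
    hierarchy_level : number of recursive split-and-rewire steps H
    rewire_exc, rewire_inh : rewiring probabilities Rex, Rin
    exc_fraction : fraction of excitatory neurons (4:1 ratio -> 0.8)
    seed : RNG seed; identical seed + config gives a byte-identical edge list
    allow_multi_edges : permit parallel edges when rewiring.  The default
        keeps the graph simple, which caps the intramodular density at 1 and
        makes rewiring saturate once modules fill up; multigraph mode keeps
        the analytic intramodular in-degree attainable at every level (the
        analytic density 2**H * n_in / N exceeds 1 at high H, which only a
        multigraph realises) and is what the dynamics sweeps use.
    """

    n_neurons: int
    connectivity: float
    hierarchy_level: int = 0
    rewire_exc: float = 0.9
    rewire_inh: float = 1.0
    exc_fraction: float = 0.8
    seed: int = 0
    allow_multi_edges: bool = False

    def __post_init__(self) -> None:
        if self.n_neurons <= 1:
            raise ValueError(f"n_neurons must be > 1, got {self.n_neurons}")
        for name in ("connectivity", "rewire_exc", "rewire_inh", "exc_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.hierarchy_level < 0:
            raise ValueError("hierarchy_level must be >= 0")
        if self.n_neurons % (2 ** self.hierarchy_level):
            raise ValueError(
                f"n_neurons={self.n_neurons} not divisible by "
                f"2**H={2 ** self.hierarchy_level}"
            )
    @property
    def n_exc(self) -> int:
        # rounded: a 4:1 ratio is never exact for power-of-two N
        return round(self.exc_fraction * self.n_neurons)


@dataclass
class NetworkTopology:
    """Directed signed network with a per-level module assignment.

    Edges are stored as parallel ``pre``/``post`` arrays; the sign of every
    edge is set by its presynaptic neuron: ids ``< config.n_exc`` are
    excitatory, the rest inhibitory.  ``module_of`` maps each neuron to a
    module index in ``[0, 2**level)``; module indices follow the binary-split
    genealogy (children of module ``m`` are ``2m`` and ``2m+1``), so
    consecutive indices are topologically close and ``module_order`` is the
    ring ordering used for adjacent-module statistics.
    """

    pre: np.ndarray
    post: np.ndarray
    module_of: np.ndarray
    level: int
    config: TopologyConfig
    n_unrewired: int = 0

    @property
    def n_neurons(self) -> int:
        return self.config.n_neurons

    @property
    def n_modules(self) -> int:
        return 2 ** self.level

    @property
    def module_order(self) -> np.ndarray:
        return np.arange(self.n_modules)

    @property
    def module_size(self) -> int:
        return self.n_neurons // self.n_modules

    @property
    def is_excitatory_edge(self) -> np.ndarray:
        """Boolean mask over edges: True where the presynaptic neuron is excitatory."""
        return self.pre < self.config.n_exc

    @property
    def n_edges(self) -> int:
        return self.pre.size

    def module_members(self) -> np.ndarray:
        """(n_modules, module_size) array of neuron ids per module, sorted."""
        order = np.argsort(self.module_of, kind="stable")
        return order.reshape(self.n_modules, self.module_size)

    def validate(self) -> None:
        if np.any(self.pre == self.post):
            raise ValueError("self-edges present")
        sizes = np.bincount(self.module_of, minlength=self.n_modules)
        if not np.all(sizes == self.module_size):
            raise ValueError("unequal module sizes")


@dataclass(frozen=True)
class ConnectivityPrediction:
    """Expected/measured per-neuron connectivity split by module membership.

    n_in : intramodular in-connections per neuron
    n_out : intermodular in-connections per neuron
    eps_in : intramodular connection density, 2**H * n_in / N
    n_in_limit : large-H asymptote 2*N*R*eps/(R + 1)
    """

    n_in: float
    n_out: float
    eps_in: float
    n_in_limit: float


def _decode_pairs(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    # code = i*(n-1) + jj with jj in [0, n-1); j skips the diagonal
    pre = codes // (n - 1)
    jj = codes % (n - 1)
    post = jj + (jj >= pre)
    return pre, post


def build_base_random(config: TopologyConfig) -> NetworkTopology:
    """Directed G(N, eps) graph: each ordered pair (i, j), i != j, is an edge
    independently with probability eps.  Single module, level 0."""
    n, eps = config.n_neurons, config.connectivity
    rng = np.random.default_rng(config.seed)
    n_pairs = n * (n - 1)
    if eps == 1.0:
        codes = np.arange(n_pairs, dtype=np.int64)
    elif eps == 0.0:
        codes = np.empty(0, dtype=np.int64)
    else:
        # geometric-gap sampler: walks the ordered pair space with
        # Geometric(eps) skips, which includes each pair independently with
        # probability eps in O(edges) time
        chunks = []
        pos = -1
        est = int(n_pairs * eps * 1.05) + 64
        while pos < n_pairs:
            gaps = rng.geometric(eps, size=est)
            hits = pos + np.cumsum(gaps)
            chunks.append(hits)
            pos = int(hits[-1])
            est = max(64, int((n_pairs - pos) * eps * 1.2) + 64)
        codes = np.concatenate(chunks)
        codes = codes[codes < n_pairs]
    pre, post = _decode_pairs(codes, n)
    return NetworkTopology(
        pre=pre.astype(np.int64),
        post=post.astype(np.int64),
        module_of=np.zeros(n, dtype=np.int64),
        level=0,
        config=config,
    )


def elevate_hierarchy(
    topology: NetworkTopology, rng: np.random.Generator | None = None
) -> NetworkTopology:
    """One split-and-rewire step: level H -> H + 1.

    Every module is randomly split into two equal halves (children 2m and
    2m+1 of module m).  Each edge that is intermodular after the split is,
    with probability Rex/Rin by presynaptic sign, redirected to a uniformly
    chosen free target in the presynaptic neuron's module (no self-edges, no
    duplicate edges).  Total edge count and every edge's sign are conserved.

    When a presynaptic neuron's module row is full (high intramodular
    density), the affected edges keep their original intermodular target and
    are counted in ``n_unrewired`` — the rewiring saturates gracefully
    instead of failing, since dense modules cannot absorb more edges.
    """
    cfg = topology.config
    n = topology.n_neurons
    if topology.module_size % 2:
        raise ValueError("module size is odd; cannot split equally")
    if rng is None:
        rng = np.random.default_rng((cfg.seed, topology.level + 1))

    # step 1: random equal split of every module
    new_module_of = np.empty(n, dtype=np.int64)
    members = topology.module_members()
    half = topology.module_size // 2
    for m in range(topology.n_modules):
        perm = rng.permutation(members[m])
        new_module_of[perm[:half]] = 2 * m
        new_module_of[perm[half:]] = 2 * m + 1

    pre, post = topology.pre, topology.post
    inter = new_module_of[pre] != new_module_of[post]
    p_rewire = np.where(topology.is_excitatory_edge, cfg.rewire_exc, cfg.rewire_inh)
    do_rewire = inter & (rng.random(pre.size) < p_rewire)

    new_post = post.copy()
    n_unrewired = 0
    idx = np.flatnonzero(do_rewire)
    if idx.size and cfg.allow_multi_edges:
        # parallel edges allowed: draw targets with replacement, only
        # excluding self-edges
        msize = half
        order = np.argsort(new_module_of, kind="stable")
        member_table = order.reshape(2 * topology.n_modules, msize)
        pending = idx
        while pending.size:
            k = member_table[
                new_module_of[pre[pending]],
                rng.integers(0, msize, size=pending.size),
            ]
            ok = k != pre[pending]
            new_post[pending[ok]] = k[ok]
            pending = pending[~ok]
    elif idx.size:
        msize = half
        order = np.argsort(new_module_of, kind="stable")
        member_table = order.reshape(2 * topology.n_modules, msize)

        # per presynaptic neuron, the rewired edges need distinct free target
        # slots inside its module: sample them without replacement, which has
        # the same distribution as redrawing uniformly until the edge is free
        by_pre = idx[np.argsort(pre[idx], kind="stable")]
        pre_sorted = pre[by_pre]
        starts = np.flatnonzero(np.diff(pre_sorted, prepend=-1))
        bounds = np.append(starts, by_pre.size)

        # existing intramodular targets per pre among edges that stay put
        keep = ~do_rewire
        same = keep & (new_module_of[pre] == new_module_of[post])
        intra_idx = np.flatnonzero(same)
        intra_idx = intra_idx[np.argsort(pre[intra_idx], kind="stable")]
        intra_pre = pre[intra_idx]
        intra_post = post[intra_idx]

        for s, e in zip(bounds[:-1], bounds[1:]):
            p = pre_sorted[s]
            edges = by_pre[s:e]
            members = member_table[new_module_of[p]]
            lo = np.searchsorted(intra_pre, p)
            hi = np.searchsorted(intra_pre, p, side="right")
            taken = intra_post[lo:hi]
            free = members[~np.isin(members, taken)]
            free = free[free != p]
            k = min(edges.size, free.size)
            if k:
                chosen = rng.choice(free, size=k, replace=False)
                sel = rng.permutation(edges)[:k] if k < edges.size else edges
                new_post[sel] = chosen
            # saturation: module too dense to absorb the rest; those edges
            # keep their original (intermodular) targets, which is safe
            # because intermodular codes stay unique
            n_unrewired += edges.size - k

    out = NetworkTopology(
        pre=pre.copy(),
        post=new_post,
        module_of=new_module_of,
        level=topology.level + 1,
        config=cfg,
        n_unrewired=topology.n_unrewired + n_unrewired,
    )
    return out


def build_hierarchy(config: TopologyConfig) -> NetworkTopology:
    """Base random network elevated ``config.hierarchy_level`` times.

    All randomness (base graph, splits, rewiring) derives from ``config.seed``.
    """
    topo = build_base_random(config)
    rng = np.random.default_rng((config.seed, 0xE1E7A7E))
    for _ in range(config.hierarchy_level):
        topo = elevate_hierarchy(topo, rng=rng)
    return topo


def expected_n_in(
    config: TopologyConfig, level: int, rewire: float | None = None
) -> ConnectivityPrediction:
    """Analytic per-neuron connectivity at a hierarchical level.

    Uses the single-R recursion ``n_in(h+1) = n_in(h)*(1-R)/2 + N*eps*R``
    with ``n_in(0) = N*eps``; ``rewire`` defaults to ``config.rewire_exc``
    (when Rex != Rin the prediction applies to the excitatory subgraph).
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    r = config.rewire_exc if rewire is None else rewire
    n_eps = config.n_neurons * config.connectivity
    n_in = n_eps
    for _ in range(level):
        n_in = n_in * (1.0 - r) / 2.0 + n_eps * r
    limit = 2.0 * config.n_neurons * r * config.connectivity / (r + 1.0)
    return ConnectivityPrediction(
        n_in=n_in,
        n_out=n_eps - n_in,
        eps_in=(2 ** level) * n_in / config.n_neurons,
        n_in_limit=limit,
    )


def measure_connectivity(
    topology: NetworkTopology, subgraph: str = "all"
) -> ConnectivityPrediction:
    """Empirical mean intra-/inter-module in-degree and intramodular density.

    subgraph : "all" | "exc" | "inh" — restrict to edges of one sign
    (useful when comparing against the single-R analytic prediction on
    networks built with Rex != Rin).
    """
    pre, post = topology.pre, topology.post
    if subgraph == "exc":
        mask = topology.is_excitatory_edge
        pre, post = pre[mask], post[mask]
    elif subgraph == "inh":
        mask = ~topology.is_excitatory_edge
        pre, post = pre[mask], post[mask]
    elif subgraph != "all":
        raise ValueError(f"unknown subgraph {subgraph!r}")
    intra = topology.module_of[pre] == topology.module_of[post]
    n = topology.n_neurons
    n_in = float(np.count_nonzero(intra)) / n
    n_out = float(np.count_nonzero(~intra)) / n
    return ConnectivityPrediction(
        n_in=n_in,
        n_out=n_out,
        eps_in=topology.n_modules * n_in / n,
        n_in_limit=float("nan"),
    )


# ---------------------------------------------------------------------------
# text round-trip: headered edge list + JSON sidecar

def save_topology(topology: NetworkTopology, out_dir: str | Path) -> Path:
    """Write ``edges.tsv`` (pre, post, sign) and ``topology.json`` sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sign = np.where(topology.is_excitatory_edge, "exc", "inh")
    with open(out / "edges.tsv", "w") as fh:
        fh.write("pre\tpost\tsign\n")
        for p, q, s in zip(topology.pre, topology.post, sign):
            fh.write(f"{p}\t{q}\t{s}\n")
    meta = {
        "config": asdict(topology.config),
        "level": topology.level,
        "module_of": topology.module_of.tolist(),
        "module_order": topology.module_order.tolist(),
        "n_unrewired": topology.n_unrewired,
    }
    (out / "topology.json").write_text(json.dumps(meta))
    return out


def load_topology(in_dir: str | Path) -> NetworkTopology:
    src = Path(in_dir)
    meta = json.loads((src / "topology.json").read_text())
    body = (src / "edges.tsv").read_text().splitlines()[1:]
    if body:
        data = np.loadtxt(body, dtype=str, ndmin=2)
        pre = data[:, 0].astype(np.int64)
        post = data[:, 1].astype(np.int64)
    else:
        pre = np.empty(0, np.int64)
        post = np.empty(0, np.int64)
    return NetworkTopology(
        pre=pre,
        post=post,
        module_of=np.asarray(meta["module_of"], dtype=np.int64),
        level=int(meta["level"]),
        config=TopologyConfig(**meta["config"]),
        n_unrewired=int(meta.get("n_unrewired", 0)),
    )
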