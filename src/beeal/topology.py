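"""Random antennal-lobe connectivity.

The network is organised in glomeruli, each housing a fixed number of
uniglomerular projection neurons (PNs) and inhibitory local neurons (iLNs).
PNs are purely postsynaptic; iLNs provide the only synapses in the model
(GABAergic lateral inhibition).  Each iLN inhibits every glomerulus
independently with probability ``p_connect``, including its home glomerulus.
When an iLN inhibits a foreign glomerulus it contacts all of its neurons;
when it inhibits its home glomerulus it contacts only the other sibling
iLNs, never its home PNs or itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

PN = 0
ILN = 1

__all__ = [
    "PN",
    "ILN",
    "LayoutSpec",
    "Connectome",
    "TopologyStats",
    "build_topology",
    "topology_stats",
    "no_inhibition_probability",
]


@dataclass(frozen=True)
class LayoutSpec:
    """Layout of the antennal-lobe network.

    Defaults give the standard 20-glomerulus network: 3 PNs + 5 iLNs per
    glomerulus (160 neurons), 25% connection probability per
    (iLN, glomerulus) pair.
    """

    n_glomeruli: int = 20
    pns_per_glomerulus: int = 3
    ilns_per_glomerulus: int = 5
    p_connect: float = 0.25
    include_home: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glomeruli < 1 or self.pns_per_glomerulus < 1 or self.ilns_per_glomerulus < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("p_connect must lie in [0, 1]")

    @property
    def neurons_per_glomerulus(self) -> int:
        return self.pns_per_glomerulus + self.ilns_per_glomerulus

    @property
    def n_neurons(self) -> int:
        return self.n_glomeruli * self.neurons_per_glomerulus


@dataclass
class Connectome:
    """Realised wiring of one random antennal lobe.

    Neurons are numbered ``0 .. n-1`` grouped by glomerulus, PNs before
    iLNs within a glomerulus.  ``edges`` is the set of ordered
    (presynaptic iLN, postsynaptic neuron) pairs; ``glomerular_targets``
    maps each iLN to the set of glomeruli it inhibits.
    """

    spec: LayoutSpec
    role: np.ndarray            # (n,) int, PN or ILN
    home_glomerulus: np.ndarray  # (n,) int
    edges: set[tuple[int, int]]
    glomerular_targets: dict[int, set[int]]

    @property
    def neuron_count(self) -> int:
        return self.role.size

    def iln_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == ILN)

    def pn_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == PN)

    def glomerulus_members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.home_glomerulus == g)

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 matrix, rows postsynaptic, columns presynaptic."""
        n = self.neuron_count
        a = np.zeros((n, n), dtype=np.int8)
        for pre, post in self.edges:
            a[post, pre] = 1
        return a

    def validate(self) -> None:
        """Audit the structural wiring rules; raise AssertionError on breach."""
        spec = self.spec
        for pre, post in self.edges:
            assert pre != post, "self-edge"
            assert self.role[pre] == ILN, "presynaptic endpoint is not an iLN"
            if self.home_glomerulus[pre] == self.home_glomerulus[post]:
                assert self.role[post] == ILN, "home-glomerulus edge onto a PN"
        for k, targets in self.glomerular_targets.items():
            home = int(self.home_glomerulus[k])
            for g in targets:
                members = self.glomerulus_members(g)
                if g == home:
                    expected = {int(i) for i in members
                                if self.role[i] == ILN and i != k}
                    assert len(expected) == spec.ilns_per_glomerulus - 1
                else:
                    expected = {int(i) for i in members}
                got = {post for pre, post in self.edges
                       if pre == k and self.home_glomerulus[post] == g}
                assert got == expected, f"all-or-none rule broken for iLN {k} -> glomerulus {g}"

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "spec": asdict(self.spec),
            "edges": sorted(map(list, self.edges)),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Connectome":
        doc = json.loads(text)
        spec = LayoutSpec(**doc["spec"])
        c = _empty_connectome(spec)
        c.edges = {(int(a), int(b)) for a, b in doc["edges"]}
        for pre, post in c.edges:
            c.glomerular_targets.setdefault(pre, set()).add(int(c.home_glomerulus[post]))
        return c

    def save_matrix(self, path: str) -> None:
        """Dense 0/1 matrix as delimited text (rows postsynaptic)."""
        np.savetxt(path, self.adjacency(), fmt="%d", delimiter="\t")


@dataclass
class TopologyStats:
    mean_glomeruli_per_iln: float
    mean_incoming_ilns_per_glomerulus: float
    frac_unconnected_ordered_pairs: float
    incoming_iln_count_histogram: dict[int, float] = field(default_factory=dict)


def _empty_connectome(spec: LayoutSpec) -> Connectome:
    per = spec.neurons_per_glomerulus
    role = np.zeros(spec.n_neurons, dtype=np.int64)
    home = np.repeat(np.arange(spec.n_glomeruli), per)
    for g in range(spec.n_glomeruli):
        role[g * per + spec.pns_per_glomerulus: (g + 1) * per] = ILN
    return Connectome(spec=spec, role=role, home_glomerulus=home,
                      edges=set(), glomerular_targets={})


def build_topology(spec: LayoutSpec) -> Connectome:
    """Draw one random connectome.

    One independent Bernoulli(``p_connect``) draw per (iLN, glomerulus)
    pair — including the home glomerulus when ``include_home`` — then each
    successful draw is expanded to edges under the all-or-none rule.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    c = _empty_connectome(spec)
    ilns = c.iln_indices()
    draws = rng.random((ilns.size, spec.n_glomeruli)) < spec.p_connect
    for row, k in enumerate(ilns):
        k = int(k)
        home = int(c.home_glomerulus[k])
        targets: set[int] = set()
        for g in range(spec.n_glomeruli):
            if not draws[row, g]:
                continue
            if g == home:
                if not spec.include_home:
                    continue
                posts = [int(i) for i in c.glomerulus_members(g)
                         if c.role[i] == ILN and i != k]
            else:
                posts = [int(i) for i in c.glomerulus_members(g)]
            if not posts:   # home glomerulus with no sibling iLNs: no edges
                continue
            targets.add(g)
            for post in posts:
                c.edges.add((k, post))
        if targets:
            c.glomerular_targets[k] = targets
    return c


def topology_stats(c: Connectome) -> TopologyStats:
    """Summary statistics of one connectome, computed from its edge set."""
    spec = c.spec
    ilns = c.iln_indices()
    glom_per_iln = np.array(
        [len(c.glomerular_targets.get(int(k), ())) for k in ilns], dtype=float)

    # distinct iLNs feeding each glomerulus
    incoming: dict[int, set[int]] = {g: set() for g in range(spec.n_glomeruli)}
    for pre, post in c.edges:
        incoming[int(c.home_glomerulus[post])].add(pre)
    mean_incoming = float(np.mean([len(s) for s in incoming.values()]))

    # ordered pairs of distinct glomeruli: how many iLNs of the source
    # inhibit the target glomerulus
    counts = []
    for gs in range(spec.n_glomeruli):
        source_ilns = [int(i) for i in c.glomerulus_members(gs) if c.role[i] == ILN]
        for gt in range(spec.n_glomeruli):
            if gt == gs:
                continue
            counts.append(sum(gt in c.glomerular_targets.get(k, ()) for k in source_ilns))
    counts = np.asarray(counts)
    hist = {int(v): float(np.mean(counts == v))
            for v in range(spec.ilns_per_glomerulus + 1)}
    return TopologyStats(
        mean_glomeruli_per_iln=float(glom_per_iln.mean()),
        mean_incoming_ilns_per_glomerulus=mean_incoming,
        frac_unconnected_ordered_pairs=float(np.mean(counts == 0)),
        incoming_iln_count_histogram=hist,
    )


def monte_carlo_stats(spec: LayoutSpec, n_topologies: int, seed: int = 0) -> TopologyStats:
    """Mean :class:`TopologyStats` over many random topologies.

    Uses the fact that, under the all-or-none expansion with at least two
    iLNs per glomerulus, every successful (iLN, glomerulus) Bernoulli draw
    contributes exactly one distinct target glomerulus to that iLN and one
    distinct incoming iLN to that glomerulus, so the statistics are exact
    functions of the draw matrix (equivalence with the explicit edge-set
    path is covered by tests).
    """
    if spec.ilns_per_glomerulus < 2 and spec.include_home:
        raise ValueError("vectorized path requires >= 2 iLNs per glomerulus")
    rng = np.random.default_rng(seed)
    G, L = spec.n_glomeruli, spec.ilns_per_glomerulus
    n_iln = G * L
    glom_sum = 0.0
    incoming_sum = 0.0
    pair_counts = np.zeros(L + 1, dtype=np.int64)
    chunk = max(1, min(n_topologies, 2000))
    done = 0
    off_diag = ~np.eye(G, dtype=bool)
    while done < n_topologies:
        t = min(chunk, n_topologies - done)
        draws = rng.random((t, n_iln, G)) < spec.p_connect
        if not spec.include_home:
            home = np.repeat(np.arange(G), L)
            draws[:, np.arange(n_iln), home] = False
        glom_sum += draws.sum(axis=2).mean(axis=1).sum()
        incoming_sum += draws.sum(axis=1).mean(axis=1).sum()
        # (topology, source glomerulus, target glomerulus) iLN counts
        counts = draws.reshape(t, G, L, G).sum(axis=2)[:, off_diag]
        pair_counts += np.bincount(counts.ravel(), minlength=L + 1)
        done += t
    hist = pair_counts / pair_counts.sum()
    return TopologyStats(
        mean_glomeruli_per_iln=glom_sum / n_topologies,
        mean_incoming_ilns_per_glomerulus=incoming_sum / n_topologies,
        frac_unconnected_ordered_pairs=float(hist[0]),
        incoming_iln_count_histogram={i: float(f) for i, f in enumerate(hist)},
    )


def no_inhibition_probability(p: float, n_iln: int) -> float:
    """Probability that a glomerulus receives no inhibition from another
    glomerulus housing ``n_iln`` iLNs: (1 - p)**n_iln."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_iln < 0:
        raise ValueError("n_iln must be >= 0")
    return (1.0 - p) ** n_iln
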