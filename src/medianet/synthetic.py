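"""Deterministic fixtures, random generators and brute-force oracles.

Everything here exists so the indices can be tested without any external
database: a small canonical "toy" interaction network with two disease
proteins whose every effect value is known in closed form, an Erdős–Rényi
generator with planted disease labels, and brute-force re-implementations of
the effect and betweenness indices by explicit enumeration (independent of
the matrix-power and Brandes-style code paths they cross-check).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

from .disease import DiseaseAnnotation
from .network import InteractionNetwork, write_edge_list

__all__ = [
    "ToyFixture",
    "toy_fixture",
    "random_disease_network",
    "brute_force_effect",
    "brute_force_betweenness",
    "write_demo_files",
]

# combinatorial guard: large enough to admit the 13-node toy fixture
_GUARD_N = 13
_GUARD_STEPS = 5


@dataclass
class ToyFixture:
    """The canonical 13-node demonstration network with known effect values.

    Two disease proteins: "red" (disease X, degree 3) and "black" (disease Y,
    degree 7). Their common neighbors "green" (degree 2) and "yellow"
    (degree 5) mediate all two-step effects between them; the "blue" nodes
    neighbor only one disease protein each and mediate nothing; the "white"
    nodes hang off yellow and are not interacting partners of any disease
    protein. ``expected`` maps descriptive keys to the exact index values.
    """

    network: InteractionNetwork
    annotation: DiseaseAnnotation
    expected: dict[str, float]


def toy_fixture() -> ToyFixture:
    """Build the toy fixture; deterministic, 13 nodes / 13 edges."""
    edges = [
        ("red", "green"),
        ("red", "yellow"),
        ("red", "blue1"),
        ("black", "green"),
        ("black", "yellow"),
        ("black", "blue2"),
        ("black", "blue3"),
        ("black", "blue4"),
        ("black", "blue5"),
        ("black", "blue6"),
        ("yellow", "white1"),
        ("yellow", "white2"),
        ("yellow", "white3"),
    ]
    net = InteractionNetwork.from_edges(edges, name="toy")
    ann = DiseaseAnnotation.from_pairs([("red", "X"), ("black", "Y")])
    expected = {
        "one_step_red_to_green": float(Fraction(1, 2)),
        "one_step_green_to_black": float(Fraction(1, 7)),
        "pathway_red_green_black": float(Fraction(1, 14)),
        "pathway_red_yellow_black": float(Fraction(1, 35)),
        "two_step_red_to_black": float(Fraction(1, 10)),
        "two_step_black_to_red": float(Fraction(7, 30)),
        "mutual_dependence_red_black": float(Fraction(1, 3)),
        "mediator_m2_yellow": float(Fraction(2, 21)),   # 1/15 + 1/35 = 0.095
        "mediator_m2_green": float(Fraction(5, 21)),    # 1/14 + 1/6 = 0.238
    }
    return ToyFixture(network=net, annotation=ann, expected=expected)


def random_disease_network(
    n_nodes: int,
    edge_prob: float,
    labels: list[str],
    dp_per_label: int,
    seed: int,
) -> tuple[InteractionNetwork, DiseaseAnnotation]:
    """Erdős–Rényi graph with disease labels planted on disjoint node subsets.

    Node ids are "P000".."P{n-1:03d}". Fully reproducible: a single integer
    seed drives one numpy Generator stream for both the edge draws and the
    label assignment.
    """
    if not (0 < edge_prob <= 1):
        raise ValueError("edge_prob must be in (0, 1]")
    if dp_per_label * len(labels) > n_nodes:
        raise ValueError("more disease proteins requested than nodes available")
    rng = np.random.default_rng(seed)
    node_ids = [f"P{k:03d}" for k in range(n_nodes)]
    edges = []
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((node_ids[a], node_ids[b]))
    net = InteractionNetwork.from_edges(
        edges, nodes=node_ids, name=f"er_n{n_nodes}_p{edge_prob}_s{seed}"
    )
    picks = rng.choice(n_nodes, size=dp_per_label * len(labels), replace=False)
    pairs = []
    for li, label in enumerate(labels):
        for p in picks[li * dp_per_label : (li + 1) * dp_per_label]:
            pairs.append((node_ids[int(p)], label))
    return net, DiseaseAnnotation.from_pairs(pairs)


def brute_force_effect(
    net: InteractionNetwork, source: str, receiver: str, n: int
) -> float:
    """n-step effect of *source* on *receiver* by explicit walk enumeration.

    Recursively enumerates every walk of exactly n steps from the source and
    multiplies 1/D over the successive receivers, summing across walks.
    Independent of the matrix-power implementation by construction. Guarded
    to n <= 5 and N <= 13.
    """
    if n > _GUARD_STEPS or net.n_nodes > _GUARD_N:
        raise ValueError("brute-force guard exceeded (n <= 5, N <= 13)")
    if n < 1:
        raise ValueError("step count n must be >= 1")
    net._require(source, receiver)

    total = Fraction(0)

    def walk(current: str, strength: Fraction, remaining: int) -> None:
        nonlocal total
        if remaining == 0:
            if current == receiver:
                total += strength
            return
        for nb in net.neighbors(current):
            walk(nb, strength * Fraction(1, net.degree(nb)), remaining - 1)

    walk(source, Fraction(1), n)
    return float(total)


def _bfs_distances(net: InteractionNetwork, start: str) -> dict[str, int]:
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in net.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _geodesics(net: InteractionNetwork, j: str, k: str) -> list[list[str]]:
    """All shortest paths j..k by DFS over distance-decreasing edges."""
    dist_to_k = _bfs_distances(net, k)
    if j not in dist_to_k:
        return []
    paths: list[list[str]] = []

    def extend(path: list[str]) -> None:
        u = path[-1]
        if u == k:
            paths.append(list(path))
            return
        for v in net.neighbors(u):
            if dist_to_k.get(v, -1) == dist_to_k[u] - 1:
                path.append(v)
                extend(path)
                path.pop()

    extend([j])
    return paths


def brute_force_betweenness(net: InteractionNetwork, i: str) -> float:
    """Betweenness of *i* by explicit enumeration of every geodesic.

    For each unordered pair {j, k} of other nodes, lists all shortest paths
    (own BFS + depth-first expansion, no library centrality code) and adds
    the fraction passing through i. Guarded to N <= 13.
    """
    if net.n_nodes > _GUARD_N:
        raise ValueError("brute-force guard exceeded (N <= 13)")
    net._require(i)
    others = [v for v in net.nodes if v != i]
    total = Fraction(0)
    for a in range(len(others)):
        for b in range(a + 1, len(others)):
            paths = _geodesics(net, others[a], others[b])
            if not paths:
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            total += Fraction(through, len(paths))
    return float(total)


def write_demo_files(outdir: str | Path) -> None:
    """Write the toy edge list, annotation and expected-value TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    toy = toy_fixture()
    write_edge_list(toy.network, outdir / "toy_edges.tsv")
    with open(outdir / "toy_annotation.tsv", "w") as fh:
        for protein in sorted(toy.annotation.labels):
            for label in sorted(toy.annotation.labels[protein]):
                fh.write(f"{protein}\t{label}\n")
    with open(outdir / "toy_expected.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        for key, value in toy.expected.items():
            fh.write(f"{key}\t{value!r}\n")
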