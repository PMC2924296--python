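"""Walk-based indirect-effect indices on an interaction network.

The model: an effect spreads from a node to each of its neighbors, and a
node receiving effects divides its attention equally among its D neighbors.
The one-step effect of node j on node i is therefore

    a1_ij = 1 / D_i   if {i, j} is an edge, else 0.

NOTE the direction convention: ``a_ij`` is the effect OF source j ON
receiver i, and its magnitude is set by the RECEIVER's degree. The effect
matrix is receiver-row indexed (rows are receivers, columns sources) and is
row-stochastic for every node with at least one neighbor. The transpose is
a common bug; every public function in this module takes explicit
``source=`` / ``receiver=`` roles.

Effects along a walk are multiplicative and across walks additive, so the
n-step effect matrix is simply the n-th power of the one-step matrix. The
diagonal of a power is generally nonzero (a walk can return to its origin);
diagonal entries are retained in the matrix but excluded from every "effects
on other nodes" aggregate (topological importance TI^n, set-level effects
A^n, mutual dependence).

Derived indices:

* ``topological_importance`` — TI^n_j, the summed effect of j on all other
  nodes.
* ``set_effect`` — A^n between two node sets (how strongly one disease's
  proteins influence another's).
* ``mediator_contribution`` — M^2_k(i, j), the two-directional two-step
  effect between i and j carried by the specific common neighbor k; summed
  over all cross-set pairs it ranks mediator proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import InteractionNetwork

__all__ = [
    "EffectMatrix",
    "DiseasePairEffect",
    "MediatorTable",
    "one_step_effect",
    "pathway_effect",
    "effect_matrix",
    "mutual_dependence",
    "topological_importance",
    "set_effect",
    "mediator_contribution",
    "mediator_table",
]

# above this node count the matrix power runs on scipy.sparse CSR
_DENSE_LIMIT = 3000


@dataclass
class EffectMatrix:
    """n-step effect values a^n_ij, receiver-row indexed.

    ``values[i, j]`` is the effect of source ``nodes[j]`` on receiver
    ``nodes[i]`` through walks of exactly ``n`` steps.
    """

    nodes: list[str]
    n: int
    values: np.ndarray
    _pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._pos = {node: k for k, node in enumerate(self.nodes)}

    def loc(self, receiver: str, source: str) -> float:
        """Effect of *source* on *receiver*."""
        return float(self.values[self._pos[receiver], self._pos[source]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.nodes, columns=self.nodes)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="receiver\\source")


def one_step_effect(net: InteractionNetwork, source: str, receiver: str) -> float:
    """Direct effect of *source* on *receiver*: 1/D_receiver if adjacent."""
    net._require(source, receiver)
    if not net.has_edge(source, receiver):
        return 0.0
    return 1.0 / net.degree(receiver)


def pathway_effect(
    net: InteractionNetwork, source: str, mediator: str, receiver: str
) -> float:
    """Effect of *source* on *receiver* through the single two-step pathway
    source -> mediator -> receiver; zero unless the mediator is adjacent to
    both endpoints."""
    if len({source, mediator, receiver}) != 3:
        raise ValueError("source, mediator and receiver must be distinct")
    return one_step_effect(net, source, mediator) * one_step_effect(
        net, mediator, receiver
    )


def _one_step_matrix(net: InteractionNetwork, nodes: Sequence[str]) -> np.ndarray:
    import networkx as nx

    adj = nx.to_numpy_array(net.graph, nodelist=list(nodes), dtype=float)
    deg = adj.sum(axis=1)
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    return adj * inv[:, None]


def effect_matrix(net: InteractionNetwork, n: int = 2) -> EffectMatrix:
    """The n-step effect matrix a^n = (a^1)^n.

    Equivalent to summing, for each (receiver, source) pair, the product of
    one-step effects over every n-step walk from source to receiver. Dense
    numpy below ~3000 nodes, scipy.sparse above; results are identical.
    """
    if n < 1:
        raise ValueError("step count n must be >= 1")
    nodes = net.nodes
    if net.n_nodes <= _DENSE_LIMIT:
        a1 = _one_step_matrix(net, nodes)
        power = np.linalg.matrix_power(a1, n)
    else:
        a1 = sp.csr_matrix(_one_step_matrix_sparse(net, nodes))
        power = a1.copy()
        for _ in range(n - 1):
            power = power @ a1
        power = np.asarray(power.todense())
    return EffectMatrix(nodes=nodes, n=n, values=power)


def _one_step_matrix_sparse(net: InteractionNetwork, nodes: Sequence[str]) -> sp.csr_matrix:
    import networkx as nx

    adj = nx.to_scipy_sparse_array(net.graph, nodelist=list(nodes), format="csr", dtype=float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    return sp.diags(inv) @ adj


def mutual_dependence(net: InteractionNetwork, i: str, j: str, n: int = 2) -> float:
    """Summed two-directional n-step effect a^n_ij + a^n_ji between i and j."""
    if i == j:
        raise ValueError("mutual dependence requires two distinct nodes")
    m = effect_matrix(net, n)
    return m.loc(i, j) + m.loc(j, i)


def topological_importance(
    net: InteractionNetwork, j: str, n: int = 2, mode: str = "exact_n"
) -> float:
    """Topological importance TI^n_j of node j.

    mode="exact_n" (default): the sum of j's effects on all other nodes
    through walks of exactly n steps. mode="cumulative_mean": the mean over
    step lengths 1..n of those sums, the averaging variant used in the
    ecological TI literature.
    """
    net._require(j)
    if n < 1:
        raise ValueError("step count n must be >= 1")
    if mode not in ("exact_n", "cumulative_mean"):
        raise ValueError(f"unknown mode {mode!r}")

    def col_sum(m: EffectMatrix) -> float:
        col = m.values[:, m._pos[j]].copy()
        col[m._pos[j]] = 0.0
        return float(col.sum())

    if mode == "exact_n":
        return col_sum(effect_matrix(net, n))
    return sum(col_sum(effect_matrix(net, m)) for m in range(1, n + 1)) / n


@dataclass
class DiseasePairEffect:
    """Aggregate n-step effect A^n of one protein set on another.

    ``contributions`` has receivers as rows and sources as columns; its cell
    (i, j) is a^n_ij. Self-pairs (a protein present in both sets) are
    excluded. ``value`` is the sum of all cells.
    """

    source_label: str
    target_label: str
    n: int
    value: float
    contributions: pd.DataFrame

    @property
    def receivers(self) -> list[str]:
        return list(self.contributions.index)

    @property
    def sources(self) -> list[str]:
        return list(self.contributions.columns)


def set_effect(
    net: InteractionNetwork,
    sources: Iterable[str],
    receivers: Iterable[str],
    n: int = 2,
    source_label: str = "D1",
    target_label: str = "D2",
    symmetric: bool = False,
) -> DiseasePairEffect:
    """A^n of the *sources* set on the *receivers* set.

    A^n = sum over i in receivers, j in sources, i != j of a^n_ij. Zero iff
    no n-step walk links the sets. With ``symmetric=True`` the reverse-
    direction aggregate is added, giving A^n(D1;D2) + A^n(D2;D1).
    """
    src = sorted(set(sources))
    rec = sorted(set(receivers))
    if not src or not rec:
        raise ValueError("source and receiver sets must be non-empty")
    net._require(*src, *rec)
    m = effect_matrix(net, n)
    contrib = m.to_frame().loc[rec, src].copy()
    for shared in set(src) & set(rec):
        contrib.loc[shared, shared] = 0.0
    value = float(contrib.to_numpy().sum())
    if symmetric:
        rev = m.to_frame().loc[src, rec].copy()
        for shared in set(src) & set(rec):
            rev.loc[shared, shared] = 0.0
        value += float(rev.to_numpy().sum())
    return DiseasePairEffect(
        source_label=source_label,
        target_label=target_label,
        n=n,
        value=value,
        contributions=contrib,
    )


def mediator_contribution(
    net: InteractionNetwork, k: str, i: str, j: str
) -> float:
    """M^2_k(i, j): the two-step effect between i and j mediated by k,
    counted in both directions.

    Equals (1/D_k)(1/D_j) + (1/D_k)(1/D_i) when k is adjacent to both i and
    j, else 0.
    """
    if len({k, i, j}) != 3:
        raise ValueError("mediator and endpoints must be three distinct nodes")
    return pathway_effect(net, i, k, j) + pathway_effect(net, j, k, i)


@dataclass
class MediatorTable:
    """Per-pair mediator decomposition between two protein sets.

    ``records`` is a long-format frame with one row per
    (i in set1, j in set2, mediator k): columns i, j, k, m2. ``pair_effects``
    holds per-pair directed two-step strengths (columns a2_ij, a2_ji: effect
    of j on i and of i on j). ``totals`` maps each mediator to its grand
    total M^2_k(set1, set2) over all cross-set pairs.
    """

    label1: str
    label2: str
    set1: list[str]
    set2: list[str]
    records: pd.DataFrame
    pair_effects: pd.DataFrame
    totals: pd.Series

    def mediators(self) -> list[str]:
        return list(self.totals.index)

    def ids_matrix(self) -> pd.DataFrame:
        """Set2 x set1 matrix of comma-joined mediator ids (Table-1 style)."""
        mat = pd.DataFrame("", index=self.set2, columns=self.set1)
        for (i, j), grp in self.records.groupby(["i", "j"], sort=True):
            mat.loc[j, i] = ",".join(sorted(grp["k"]))
        return mat

    def strength_matrix(self) -> pd.DataFrame:
        """Set2 x set1 matrix of summed two-direction strengths (Table-2 style)."""
        mat = pd.DataFrame(0.0, index=self.set2, columns=self.set1)
        for _, row in self.pair_effects.iterrows():
            mat.loc[row["j"], row["i"]] = row["a2_ij"] + row["a2_ji"]
        return mat

    def write(self, outdir: str | Path, stem: str = "mediators") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ids_matrix().to_csv(outdir / f"{stem}_ids.tsv", sep="\t")
        self.strength_matrix().map(lambda v: float(f"{v:.4g}")).to_csv(
            outdir / f"{stem}_strength.tsv", sep="\t"
        )
        self.records.to_csv(outdir / f"{stem}_long.tsv", sep="\t", index=False)
        ranking = self.totals.rename("M2_total").to_frame()
        ranking["rank"] = (
            ranking["M2_total"].rank(method="min", ascending=False).astype(int)
        )
        ranking.sort_values(["rank", "M2_total"]).to_csv(
            outdir / f"{stem}_ranking.tsv", sep="\t", index_label="k"
        )


def mediator_table(
    net: InteractionNetwork,
    set1: Iterable[str],
    set2: Iterable[str],
    label1: str = "D1",
    label2: str = "D2",
) -> MediatorTable:
    """Decompose all cross-set two-step effects by mediator.

    For every ordered pair (i in set1, j in set2) the mediators are the
    common neighbors of i and j in *net* — any node may mediate, including a
    disease protein. Pairs where i == j (sets overlap) are skipped. The
    decomposition identity sum_k M^2_k(i, j) = a^2_ij + a^2_ji holds exactly
    because every two-step walk between distinct nodes passes through a
    common neighbor.
    """
    s1 = sorted(set(set1))
    s2 = sorted(set(set2))
    if not s1 or not s2:
        raise ValueError("both protein sets must be non-empty")
    net._require(*s1, *s2)
    rec_rows = []
    pair_rows = []
    for i in s1:
        ni = set(net.neighbors(i))
        for j in s2:
            if i == j:
                continue
            common = sorted((ni & set(net.neighbors(j))) - {i, j})
            a2_ij = 0.0  # effect of j on i
            a2_ji = 0.0
            for k in common:
                m2 = mediator_contribution(net, k, i, j)
                rec_rows.append({"i": i, "j": j, "k": k, "m2": m2})
                a2_ij += pathway_effect(net, j, k, i)
                a2_ji += pathway_effect(net, i, k, j)
            pair_rows.append({"i": i, "j": j, "a2_ij": a2_ij, "a2_ji": a2_ji})
    records = pd.DataFrame(rec_rows, columns=["i", "j", "k", "m2"])
    pair_effects = pd.DataFrame(pair_rows, columns=["i", "j", "a2_ij", "a2_ji"])
    if records.empty:
        totals = pd.Series(dtype=float, name="M2_total")
    else:
        totals = (
            records.groupby("k")["m2"]
            .sum()
            .sort_values(ascending=False)
            .rename("M2_total")
        )
        # deterministic order: strength descending, then id
        totals = totals.iloc[
            sorted(
                range(len(totals)),
                key=lambda p: (-totals.iloc[p], totals.index[p]),
            )
        ]
    return MediatorTable(
        label1=label1,
        label2=label2,
        set1=s1,
        set2=s2,
        records=records,
        pair_effects=pair_effects,
        totals=totals,
    )
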