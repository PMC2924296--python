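"""Disease annotations, node roles, and the DPIP / IP subnetworks.

Given a protein-protein interaction (PPI) network and a table of disease
annotations, nodes partition into three roles:

* DP (disease protein): carries at least one disease label. A protein with
  a label is always DP, never IP, regardless of its neighborhood.
* IP (interacting partner): unlabeled, but adjacent to at least one DP.
* other: unlabeled with no DP neighbor.

Two analysis subnetworks derive from this partition:

* DPIP — all DPs and IPs, keeping only edges with a DP endpoint (DP-DP and
  DP-IP interactions; no IP-IP edges).
* IP — the IPs alone, with the IP-IP edges from the PPI. The IP network is
  not a subgraph of the DPIP network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .network import InteractionNetwork, ParseError, _open_lines

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseAnnotation",
    "NodeRoles",
    "read_disease_annotation",
    "classify_nodes",
    "build_dpip",
    "build_ip",
    "disease_pair_linkage",
    "write_role_report",
]


@dataclass
class DiseaseAnnotation:
    """Mapping protein id -> set of disease labels (a protein may carry several)."""

    labels: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DiseaseAnnotation":
        mapping: dict[str, set[str]] = {}
        for protein, label in pairs:
            mapping.setdefault(protein, set()).add(label)
        return cls(labels=mapping)

    def labels_of(self, protein: str) -> set[str]:
        return set(self.labels.get(protein, set()))

    def proteins_with(self, label: str) -> set[str]:
        return {p for p, ls in self.labels.items() if label in ls}

    def all_labels(self) -> set[str]:
        out: set[str] = set()
        for ls in self.labels.values():
            out |= ls
        return out

    def is_disease_protein(self, protein: str) -> bool:
        return bool(self.labels.get(protein))

    def __len__(self) -> int:
        return len(self.labels)


def read_disease_annotation(source: str | Path | IO[str]) -> DiseaseAnnotation:
    """Read a two-column TSV (protein id, disease label) into an annotation.

    ``#`` comments are skipped, duplicate rows collapse. Blank ids or labels
    raise :class:`ParseError` with the line number; an empty file yields an
    empty annotation with a warning.
    """
    lines, label = _open_lines(source)
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"{label}: line {lineno}: expected protein id and disease label"
            )
        pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        logger.warning("%s: empty disease annotation", label)
    return DiseaseAnnotation.from_pairs(pairs)


@dataclass
class NodeRoles:
    """Role (DP / IP / other) per node, plus the label sets of DP nodes."""

    role: dict[str, str]
    dp_labels: dict[str, set[str]]

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, r in self.role.items() if r == role}

    @property
    def dps(self) -> set[str]:
        return self.nodes_with_role("DP")

    @property
    def ips(self) -> set[str]:
        return self.nodes_with_role("IP")


def classify_nodes(ppi: InteractionNetwork, ann: DiseaseAnnotation) -> NodeRoles:
    """Assign every PPI node a role per the DP/IP/other partition.

    Annotated proteins absent from the network are ignored with a warning.
    """
    missing = set(ann.labels) - set(ppi.nodes)
    if missing:
        logger.warning(
            "%d annotated protein(s) absent from network %s",
            len(missing),
            ppi.name,
        )
    role: dict[str, str] = {}
    dp_labels: dict[str, set[str]] = {}
    dps = {n for n in ppi.nodes if ann.is_disease_protein(n)}
    for n in ppi.nodes:
        if n in dps:
            role[n] = "DP"
            dp_labels[n] = ann.labels_of(n)
        elif any(nb in dps for nb in ppi.neighbors(n)):
            role[n] = "IP"
        else:
            role[n] = "other"
    return NodeRoles(role=role, dp_labels=dp_labels)


def build_dpip(ppi: InteractionNetwork, ann: DiseaseAnnotation) -> InteractionNetwork:
    """The DPIP subnetwork: DP and IP nodes; only DP-incident edges."""
    roles = classify_nodes(ppi, ann)
    dps = roles.dps
    if not dps:
        raise ValueError("cannot build DPIP network: no disease protein present")
    keep_nodes = dps | roles.ips
    edges = [
        (u, v) for u, v in ppi.edges if u in dps or v in dps
    ]
    return InteractionNetwork.from_edges(edges, nodes=keep_nodes, name=f"{ppi.name}:DPIP")


def build_ip(ppi: InteractionNetwork, ann: DiseaseAnnotation) -> InteractionNetwork:
    """The IP subnetwork: IP nodes and the IP-IP edges among them."""
    roles = classify_nodes(ppi, ann)
    ips = roles.ips
    if not ips:
        logger.warning("IP network of %s is empty", ppi.name)
    edges = [(u, v) for u, v in ppi.edges if u in ips and v in ips]
    return InteractionNetwork.from_edges(edges, nodes=ips, name=f"{ppi.name}:IP")


def disease_pair_linkage(
    ppi: InteractionNetwork, ann: DiseaseAnnotation
) -> pd.DataFrame:
    """Classify every unordered disease-label pair as direct / indirect / unlinked.

    "direct" if any PPI edge joins the two DP sets; otherwise "indirect" if
    any two-step path does (a common neighbor of members of both sets);
    otherwise "unlinked". Proteins annotated to both diseases are reported in
    a ``shared`` column and excluded from the path tests.
    """
    labels = sorted(ann.all_labels())
    if len(labels) < 2:
        raise ValueError("need at least two disease labels")
    rows = []
    for l1, l2 in combinations(labels, 2):
        s1 = {p for p in ann.proteins_with(l1) if p in ppi}
        s2 = {p for p in ann.proteins_with(l2) if p in ppi}
        shared = s1 & s2
        s1_only, s2_only = s1 - shared, s2 - shared
        direct = any(ppi.has_edge(a, b) for a in s1_only for b in s2_only)
        if direct:
            kind = "direct"
        else:
            indirect = any(
                set(ppi.neighbors(a)) & set(ppi.neighbors(b))
                for a in s1_only
                for b in s2_only
            )
            kind = "indirect" if indirect else "unlinked"
        rows.append(
            {
                "disease1": l1,
                "disease2": l2,
                "linkage": kind,
                "shared": ",".join(sorted(shared)),
            }
        )
    return pd.DataFrame(rows)


def write_role_report(
    roles: NodeRoles, path: str | Path
) -> None:
    """TSV: node, role, comma-joined labels (DP nodes only)."""
    rows = [
        {
            "node": n,
            "role": r,
            "labels": ",".join(sorted(roles.dp_labels.get(n, set()))),
        }
        for n, r in sorted(roles.role.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
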