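# medianet

Walk-based indirect effects and mediator proteins in protein–protein
interaction (PPI) networks.

Proteins whose mutations cause different diseases are often not directly
linked in the interactome, yet their diseases co-occur and interact. The
connection frequently runs through *mediator proteins*: non-disease proteins
that interact with disease proteins of both conditions. `medianet` is a
library (with a thin CLI) for quantifying those indirect relationships. It
is aimed at systems-biology researchers who have an undirected PPI edge list
and a disease-annotation table and want to know which proteins carry the
indirect cross-disease effects, and how strongly.

## The model

The network is undirected and unweighted. The **one-step effect** of node
*j* on an adjacent node *i* is

    a¹_ij = 1 / D_i

where *D_i* is the degree of the receiver — a node divides its attention
equally among its neighbors. Effects are **multiplicative along a walk and
additive across walks**, so the *n*-step effect matrix is the *n*-th power
of the one-step matrix, *a^n = (a¹)^n*, and every receiver row sums to 1.
From this follow the derived indices:

* **TI^n_j** (topological importance): Σ_{i≠j} a^n_ij, node *j*'s total
  effect on the rest of the network.
* **A^n_{D1;D2}**: the aggregate n-step effect of one disease-protein set on
  another; zero iff no n-step walk links them.
* **M²_k(i, j)** (mediator contribution): the two-step effect between *i*
  and *j* carried by the specific common neighbor *k*, in both directions:
  (1/D_k)(1/D_j) + (1/D_k)(1/D_i). Summed over all cross-disease pairs, M²
  ranks mediator proteins. The per-pair mediator values decompose the total:
  Σ_k M²_k(i,j) = a²_ij + a²_ji.

Alongside the effect indices, the package builds the disease-centric
subnetworks — **DPIP** (disease proteins plus interacting partners, with no
IP–IP edges) and the **IP network** (interacting partners only) — and
reports degree and betweenness centrality with the Freeman normalizations
nD = D/(N−1), nB = B/((N−1)(N−2)/2).

## Worked example

The built-in toy network has 13 nodes: disease proteins `red` (degree 3) and
`black` (degree 7), mediators `green` (degree 2) and `yellow` (degree 5).

```python
from medianet import toy_fixture, effect_matrix, mediator_contribution

net = toy_fixture().network
m2 = effect_matrix(net, n=2)
print(m2.loc("black", "red"))                               # 0.1
print(m2.loc("red", "black"))                               # 0.23333...
print(mediator_contribution(net, "green", "red", "black"))  # 0.23809...
print(mediator_contribution(net, "yellow", "red", "black")) # 0.09523...
```

Running `python examples/01_toy_walkthrough.py` prints:

```
red -> green  one-step effect : 0.5000
green -> black one-step effect: 0.1429
red -> green -> black pathway : 0.0714
red -> yellow -> black pathway: 0.0286
total two-step effect red -> black: 0.1000
total two-step effect black -> red: 0.2333
mutual dependence (both directions): 0.3333
mediator M2 through green : 0.238
mediator M2 through yellow: 0.095
```

Reading: red reaches black only through two-step walks. The green pathway
carries 1/14 ≈ 0.071 and the yellow pathway 1/35 ≈ 0.029, summing to the
0.100 total; in the reverse direction black's effect on red is 7/30 ≈ 0.233,
so the mutual dependence is 1/3. Green, despite having fewer neighbors than
yellow, is the stronger mediator (M² = 0.238 vs 0.095) because yellow's five
neighbors dilute everything routed through it — topological importance as a
mediator is not the same thing as being a hub.

The other examples cover subnetwork construction (`02`), centrality tables
(`03`), the full pipeline on a synthetic five-disease network (`04`), and
the M²-vs-functional-importance correlation helper (`05`).

## Command line

```
medianet demo --out demo/
medianet mediators --edges demo/toy_edges.tsv --annotation demo/toy_annotation.tsv \
    --set1 X --set2 Y --out results/
medianet centrality --edges demo/toy_edges.tsv --out results/
```

Subcommands: `networks`, `centrality`, `effects`, `mediators`, `influence`,
`correlate`, `demo`. Every run writes a `run_manifest.json`; outputs are
deterministic for fixed inputs.

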