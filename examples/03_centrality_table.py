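"""Degree and betweenness centrality with normalized values and ranks.

nD = D/(N-1) and nB = B/((N-1)(N-2)/2) lie in [0, 1], so they compare across
networks of different size; rank 1 is the most central node.
"""

from medianet import centrality_table, toy_fixture

net = toy_fixture().network
table = centrality_table(net)
print(table.round(4).sort_values("nD_rank").to_string())
print(
    "\nblack tops both indices: it has the most neighbors and sits on the"
    "\nmost shortest paths. The white leaves score zero betweenness."
)
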