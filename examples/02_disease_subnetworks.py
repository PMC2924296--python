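"""Classify node roles and build the DPIP and IP subnetworks of the toy PPI.

DPIP keeps disease proteins (DPs) plus their interacting partners (IPs) and
only the DP-incident edges; the IP network keeps the IPs and the IP-IP edges
the DPIP network discards.
"""

from medianet import (
    build_dpip,
    build_ip,
    classify_nodes,
    disease_pair_linkage,
    toy_fixture,
)

toy = toy_fixture()
roles = classify_nodes(toy.network, toy.annotation)

for role in ("DP", "IP", "other"):
    members = sorted(roles.nodes_with_role(role))
    print(f"{role:6s}: {', '.join(members)}")

dpip = build_dpip(toy.network, toy.annotation)
ip = build_ip(toy.network, toy.annotation)
print(f"\nDPIP network: {dpip.n_nodes} nodes / {dpip.n_edges} edges (no IP-IP links)")
print(f"IP network  : {ip.n_nodes} nodes / {ip.n_edges} edges")

print("\nhow are the two diseases linked?")
print(disease_pair_linkage(toy.network, toy.annotation).to_string(index=False))
# 'indirect': no edge joins the red and black disease proteins, but two-step
# paths through their shared neighbors do.
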