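"""Gene-gene signal network and hub ranking.

Induces the relation-table subgraph on the differential genes and ranks
hubs by connectivity (sum of connection strengths, Ki) and by Freeman
relative betweenness C'B in [0, 1].
"""

from cernanet.signalnet import build_signalnet, node_metrics, rank_hubs
from cernanet.synthetic_data import SimulationConfig, generate

bundle = generate(SimulationConfig(n_cohorts=1, n_mRNA=300, seed=3))
members = {f for f in bundle.truth.de_features if f.startswith("G")}

net = build_signalnet(bundle.relations, members)
metrics = node_metrics(net).sort_values("connectivity", ascending=False)
print(metrics.head(5).to_string(index=False))

top = rank_hubs(net, by="connectivity")[0]
print(f"\nnetwork: {len(net)} nodes ({len(net.dropped_isolated)} isolated members dropped)")
print(f"top hub by connectivity: {top} — the generator wires one planted DE gene "
      "as a high-degree regulator, and the ranking recovers it")
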