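"""Per-layer co-occurrence networks and Zi-Pi keystone classification.

For one soil layer: filter to abundant (>0.5%), prevalent (>50% of the
layer's samples) ASVs, correlate with Spearman, keep |rho| >= 0.8 and
BH q <= 0.001 edges, detect modules, and classify node roles by
within-module degree z-score (Zi) vs participation coefficient (Pi).
"""

from microdepth import (SimulationParams, build_cooccurrence_network,
                        compare_networks, detect_modules, network_metrics,
                        simulate_dataset, zi_pi)
from microdepth.network import topology_frame

table, metadata, *_ = simulate_dataset(
    SimulationParams(n_asvs=800, library_size=20_000, seed=9))

nets = {}
for layer in ("S", "M", "D"):
    net = build_cooccurrence_network(table, metadata, layer)
    nets[layer] = net
    modules, q = detect_modules(net, seed=0)
    m = network_metrics(net, modules, q)
    topo = topology_frame(zi_pi(net, modules))
    keystones = topo[topo["keystone"]]
    print(f"layer {layer}: {m.n_nodes} nodes, {m.n_edges} edges "
          f"({m.n_positive}+/{m.n_negative}-), modularity {m.modularity:.2f}, "
          f"{len(keystones)} keystone(s)")
    if len(keystones):
        print(keystones.round(2).to_string())

print("\nshared nodes:", compare_networks(nets))
# The three planted correlation modules reappear as network modules in
# every layer; keystones are the occasional connectors bridging them.
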