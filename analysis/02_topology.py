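"""Topological profile of the global network and its degree power law.

Computes per-node degree, clustering coefficient, topological coefficient
and neighborhood connectivity on the network written by 01_build_network
(regenerating it if absent), then fits f(x) = a * x**b to the degree
histogram on log-log scale.  Outputs under results/topology/.

Run from the repository root:  python analysis/02_topology.py [seed]
"""

import json
import sys
from dataclasses import replace
from pathlib import Path

from ffl_miner import network_io
from ffl_miner.network_io import assemble_tmgn, read_merged_edge_table, read_node_table
from ffl_miner.synthetic import TMGN_SCALE_CONFIG, generate_background_network, substream_seed
from ffl_miner.topology import compute_node_metrics, fit_degree_power_law


def load_or_build(seed: int):
    edge_path = Path("results/network/edges.tsv")
    if edge_path.exists():
        roles = read_node_table("results/network/nodes.tsv")
        net, _ = assemble_tmgn(
            read_merged_edge_table(edge_path), declared_roles=roles
        )
        return net
    cfg = replace(TMGN_SCALE_CONFIG, seed=substream_seed(seed, "global"))
    return generate_background_network(cfg)


def main(seed: int = 1) -> None:
    out = Path("results/topology")
    out.mkdir(parents=True, exist_ok=True)
    net = load_or_build(seed)

    profile = compute_node_metrics(net)
    fit = fit_degree_power_law(profile)
    profile.to_csv(out / "node_metrics.tsv", sep="\t")
    with open(out / "power_law_fit.json", "w") as fh:
        json.dump(
            {"a": fit.a, "b": fit.b, "r_squared": fit.r_squared}, fh, indent=2
        )

    hubs = profile.sort_values("degree", ascending=False).head(5)
    print(f"degree distribution fit: f(x) = {fit.a:.3f} * x^({fit.b:.3f}), "
          f"r^2 = {fit.r_squared:.3f}")
    print(f"mean degree {profile['degree'].mean():.2f}, "
          f"max degree {int(profile['degree'].max())}")
    print("top-degree hubs:")
    for node, row in hubs.iterrows():
        print(f"  {node}: degree {int(row['degree'])}, "
              f"clustering {row['clustering']:.3f}")
    print(f"tables written to {out}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
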