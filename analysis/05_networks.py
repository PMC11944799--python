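#!/usr/bin/env python
"""Per-crop co-occurrence networks and their topology summaries.

For each crop x kingdom: keep the top 80% of OTUs by mean relative
abundance, threshold the Spearman matrix at |r| > 0.60 and p < 0.05, and
compute the 17-metric topology summary; writes results/networks/.
"""

import json
from pathlib import Path

from rarecycle import NetworkConfig, build_network, prevalence_filter_top, spearman_matrix, topology_summary
from rarecycle.io_formats import read_nutrient_table, read_otu_table, write_network

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = DATA.parent / "networks"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    crop_labels = read_nutrient_table(DATA / "nutrients.csv").crop
    cfg = NetworkConfig()
    summaries = {}
    for kingdom in ("bacteria", "fungi"):
        table = read_otu_table(DATA / f"otu_{kingdom}.tsv", crop=crop_labels)
        summaries[kingdom] = {}
        for crop in sorted(table.crop.unique()):
            sub = table.subset_samples(table.crop.index[table.crop == crop])
            kept = prevalence_filter_top(sub, cfg.keep_fraction)
            r, p = spearman_matrix(kept)
            network = build_network(r, p, cfg)
            if network.n_edges == 0:
                summaries[kingdom][crop] = {"node_num": 0, "edge_num": 0}
                continue
            summary = topology_summary(network, seed=SEED)
            summaries[kingdom][crop] = summary.as_dict()
            write_network(network, OUT / f"network_{kingdom}_{crop}.graphml")
            print(f"{kingdom}/{crop}: N={summary.node_num} E={summary.edge_num} "
                  f"density={summary.density:.3f} Q={summary.modularity:.3f} "
                  f"robustness={summary.robustness:.3f}")
    (OUT / "topology.json").write_text(json.dumps(summaries, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
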