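#!/usr/bin/env python
"""Generate the interactome-scale synthetic dataset the analyses run on.

Produces an 886-protein, ~17,300-interaction network by preferential
attachment with a 30-node planted rich-club core (internal density 0.8),
literature-report frequencies elevated four-fold on hubs, and six drugs —
half targeting hubs (degree^2-biased), half uniform. Writes the edge list,
annotation and drug tables plus the planted ground truth.
"""

import argparse
import json
from pathlib import Path

from ppi_richclub import net_io, synthetic

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results/analysis/data"))
args = ap.parse_args()

spec = synthetic.SyntheticSpec(n_nodes=886, ba_m=20, core_size=30,
                               core_density=0.8, frequency_base=20.0,
                               hub_fold=4.0, n_drugs=6, targets_per_drug=120,
                               hub_bias=2.0, seed=args.seed)
data = synthetic.generate_dataset(spec)
G = data["graph"]

args.out.mkdir(parents=True, exist_ok=True)
net_io.write_edge_list(G, args.out / "edges.tsv")
with open(args.out / "annotations.tsv", "w") as fh:
    fh.write("accession\tfrequency\tlabels\n")
    for r in data["annotations"]:
        fh.write(f"{r.accession}\t{r.frequency}\t{';'.join(r.labels)}\n")
with open(args.out / "drug_targets.tsv", "w") as fh:
    fh.write("drug\ttarget_accession\n")
    for drug, targets in sorted(data["drug_targets"].items()):
        for t in sorted(targets):
            fh.write(f"{drug}\t{t}\n")
with open(args.out / "ground_truth.json", "w") as fh:
    json.dump(data["ground_truth"], fh, indent=2, sort_keys=True)
    fh.write("\n")

print(f"network: {G.number_of_nodes()} nodes, {G.number_of_edges()} edges")
print(f"planted core: {len(data['ground_truth']['planted_core'])} hubs "
      f"at internal density {spec.core_density}")
print(f"wrote edge list, annotations, drug targets and ground truth to {args.out}")
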