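#!/usr/bin/env python
"""Score drug-target enrichment in the network and in its rich club.

For each drug: a Fisher exact test of its targets against a 20,000-gene
universe (network-level enrichment) and against the network itself
(rich-club enrichment), plus a Welch comparison of target vs non-target
degrees. A drug that preferentially hits hubs should surface with a small
rich-club p and a higher mean target degree — here validated against the
generator's known hub-biased drugs.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ppi_richclub import enrichment, net_io

ap = argparse.ArgumentParser()
ap.add_argument("--background-size", type=int, default=20000)
ap.add_argument("--data", type=Path, default=Path("results/analysis/data"))
ap.add_argument("--out", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

G = net_io.read_edge_list(args.data / "edges.tsv")
drugs = net_io.read_drug_targets(args.data / "drug_targets.tsv")
call = json.loads((args.out / "richclub_call.json").read_text())
profile = pd.read_csv(args.out / "richclub_profile.tsv", sep="\t")
core_min_degree = call["core_range"][0] if call["core_range"] else None
core = ({v for v, d in G.degree() if d >= core_min_degree}
        if core_min_degree is not None else set())

rows = []
net_records = enrichment.drug_enrichment(drugs, set(G.nodes()),
                                         background=args.background_size)
rows += [vars(r) | {"foreground": "network"} for r in net_records]
in_net = net_io.in_network_targets(drugs, G)
rc_records = enrichment.drug_enrichment(in_net, core, background=set(G.nodes()))
rows += [vars(r) | {"foreground": "richclub"} for r in rc_records]
pd.DataFrame(rows).to_csv(args.out / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.6g")

deg_rows = []
for drug, targets in sorted(in_net.items()):
    mt, mn, p = enrichment.target_degree_comparison(G, targets)
    deg_rows.append((drug, mt, mn, p))
pd.DataFrame(deg_rows, columns=["drug", "target_mean_degree",
                                "nontarget_mean_degree", "welch_p"]).to_csv(
    args.out / "target_degree.tsv", sep="\t", index=False,
    float_format="%.6g")

print(f"rich-club foreground: {len(core)} proteins")
print("rich-club enrichment (smallest p first):")
for r in rc_records:
    share = r.a / (r.a + r.b) if (r.a + r.b) else 0.0
    print(f"  {r.set_name}: hits {r.a}/{r.a + r.b} of club ({share:.0%}), "
          f"OR = {r.odds_ratio:.2f}, p = {r.p_value:.3g}")
for drug, mt, mn, p in deg_rows:
    print(f"  {drug}: target mean degree {mt:.1f} vs {mn:.1f} "
          f"(Welch p = {p:.2g})")
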