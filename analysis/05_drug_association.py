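"""Drug curation screen and cumulative-hypergeometric miRNA-drug scoring.

Builds a 38-drug DrugBank-style fixture over the motif-scale gene panel,
applies the seven-flag curation screen, and scores every (CFMSN miRNA,
drug) target overlap with the upper-tail cumulative hypergeometric test
(drugs with < 2 targets excluded).  Writes results/drugs/.

Run from the repository root:  python analysis/05_drug_association.py [seed]
"""

import json
import sys
from pathlib import Path

from ffl_miner.drugs import (
    association_table,
    cumulative_hypergeometric,
    filter_drugs,
    mirna_drug_association,
)
from ffl_miner.network import Relation
from ffl_miner.study import build_drugs, build_motif_network


def main(seed: int = 1) -> None:
    out = Path("results/drugs")
    out.mkdir(parents=True, exist_ok=True)

    net, planted = build_motif_network(seed)
    records = build_drugs(net, seed)
    kept = filter_drugs(records)

    # miRNA target sets of the planted 3-node regulators, from the network
    planted_mirnas = {
        n for inst in planted[3] for n in inst.nodes if "miRNA" in net.roles[n]
    }
    targets = {}
    for s, t, rel in net.edges:
        if rel is Relation.MIRNA_REPRESSES_GENE and s in planted_mirnas:
            targets.setdefault(s, set()).add(t)

    genes = net.nodes_with_role("gene")
    results = mirna_drug_association(targets, records, universe=len(genes))
    sig = [r for r in results if r.is_significant]

    association_table(results).to_csv(out / "associations.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "n_drugs": len(records),
                "n_after_curation": len(kept),
                "n_pairs_tested": len(results),
                "n_significant_pairs": len(sig),
                "universe_size": len(genes),
                "worked_example_F(1|10,4,3)": cumulative_hypergeometric(1, 10, 4, 3),
            },
            fh,
            indent=2,
        )

    print(f"curation screen: {len(kept)}/{len(records)} drugs pass all seven flags")
    print(f"association test over {len(targets)} miRNA target sets x "
          f"{sum(1 for r in records if len(r.targets) >= 2)} multi-target drugs: "
          f"{len(sig)}/{len(results)} pairs significant at p<0.05 (upper tail)")
    print(f"worked check F(1|10,4,3) = {cumulative_hypergeometric(1, 10, 4, 3):.4f} "
          f"(= 80/120)")
    print(f"tables written to {out}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
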