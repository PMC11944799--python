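#!/usr/bin/env python
"""Partition OTUs into rare/intermediate/abundant and count crop overlap.

Reads results/data/, writes per-OTU class labels and per-crop presence
overlap (Venn/UpSet counts) under results/partition/.
"""

import json
from pathlib import Path

import pandas as pd

from rarecycle import classify_taxa, otu_overlap, phylum_aggregate
from rarecycle.io_formats import read_nutrient_table, read_otu_table

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = DATA.parent / "partition"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    crop = read_nutrient_table(DATA / "nutrients.csv").crop
    for kingdom in ("bacteria", "fungi"):
        table = read_otu_table(DATA / f"otu_{kingdom}.tsv", crop=crop)
        classes = classify_taxa(table)
        pd.DataFrame(
            {"mean_rel_abund": classes.mean_rel_abundance, "class": classes.labels}
        ).rename_axis("otu_id").to_csv(OUT / f"labels_{kingdom}.tsv", sep="\t")
        per_crop = {
            c: table.subset_samples(table.crop.index[table.crop == c])
            for c in sorted(table.crop.unique())
        }
        overlap = otu_overlap(per_crop)
        overlap_json = {
            "totals": overlap["totals"],
            "unique": overlap["unique"],
            "shared_all": overlap["shared_all"],
            "exclusive_intersections": {
                "+".join(combo): size
                for combo, size in overlap["exclusive_intersections"].items()
            },
        }
        (OUT / f"overlap_{kingdom}.json").write_text(
            json.dumps(overlap_json, indent=2, sort_keys=True)
        )
        _, top, pooled = phylum_aggregate(table)
        pooled.to_csv(OUT / f"phylum_fractions_{kingdom}.tsv", sep="\t")
        print(f"{kingdom}: classes {classes.counts}; "
              f"per-crop OTU totals {overlap['totals']}; top phyla {top[:3]}...")


if __name__ == "__main__":
    main()
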