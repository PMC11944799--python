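#!/usr/bin/env python
"""Soil multi-nutrient cycling index and crop comparisons.

Computes per-sample MNC, availability ratios, and per-crop means with
Duncan connected letters; writes results/mnc/.
"""

from pathlib import Path

from rarecycle import anova_duncan, availability_ratios, compute_mnc
from rarecycle.io_formats import read_nutrient_table

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = DATA.parent / "mnc"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    nutrients = read_nutrient_table(DATA / "nutrients.csv")
    result = compute_mnc(nutrients)
    frame = result.normalized.copy()
    frame["MNC"] = result.mnc
    frame["crop"] = nutrients.crop
    frame.to_csv(OUT / "mnc.tsv", sep="\t")
    ratios = availability_ratios(nutrients)
    ratios.to_csv(OUT / "availability_ratios.tsv", sep="\t")
    duncan = anova_duncan(result.mnc.to_numpy(), nutrients.crop.to_numpy())
    duncan.to_csv(OUT / "mnc_crop_means.tsv", sep="\t")
    print("per-crop MNC means with Duncan letters:")
    print(duncan.to_string(float_format="%.3f"))


if __name__ == "__main__":
    main()
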