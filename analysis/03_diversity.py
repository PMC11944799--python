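#!/usr/bin/env python
"""Alpha/beta diversity and crop-level statistics.

Computes richness/Shannon/Pielou, Bray-Curtis NMDS (stress), PERMANOVA by
crop, a Mantel test against the soil-chemistry distances, and
Kruskal-Wallis tests of the alpha indices; writes results/diversity/.
"""

import json
from pathlib import Path

import numpy as np

from rarecycle import alpha_diversity, bray_curtis, kruskal_wallis, mantel, nmds, permanova
from rarecycle.diversity import DistanceMatrix
from rarecycle.io_formats import read_nutrient_table, read_otu_table

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = DATA.parent / "diversity"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    nutrients = read_nutrient_table(DATA / "nutrients.csv")
    z = (nutrients.data - nutrients.data.mean()) / nutrients.data.std(ddof=0)
    env = DistanceMatrix(
        np.sqrt(((z.to_numpy()[:, None] - z.to_numpy()[None]) ** 2).sum(-1)),
        ids=list(z.index),
    )
    summary = {}
    for kingdom in ("bacteria", "fungi"):
        table = read_otu_table(DATA / f"otu_{kingdom}.tsv", crop=nutrients.crop)
        profile = alpha_diversity(table)
        profile.to_frame().to_csv(OUT / f"alpha_{kingdom}.tsv", sep="\t")
        dm = bray_curtis(table)
        coords, stress = nmds(dm, seed=SEED)
        coords.to_csv(OUT / f"nmds_{kingdom}.tsv", sep="\t")
        perm = permanova(dm, table.crop, seed=SEED)
        mant = mantel(dm, env, method="spearman", seed=SEED)
        kw = {
            name: kruskal_wallis(col.to_numpy(), table.crop.to_numpy()).as_dict()
            for name, col in profile.to_frame().items()
        }
        summary[kingdom] = {
            "nmds_stress": stress,
            "permanova": perm.as_dict(),
            "mantel_vs_soil_chemistry": mant.as_dict(),
            "kruskal_wallis_alpha": kw,
        }
        print(f"{kingdom}: NMDS stress {stress:.3f}; "
              f"PERMANOVA R2 {perm.effect:.3f} (p={perm.p_value:.3f}); "
              f"Mantel r {mant.statistic:.3f} (p={mant.p_value:.3f})")
    (OUT / "tests.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
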