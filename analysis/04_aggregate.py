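#!/usr/bin/env python
"""Aggregate solved sites into forest-type means.

Reduces the per-site summaries of 02_run_sites.py to means +- sample SD
per forest type (biomass by layer, total flux, trophic-function
percentages, spectrum slopes) and writes results/forest_type_means.csv.
Prints a compact biomass/flux table across the climate gradient.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"

ORDER = ["taiga", "mixed_broadleaved", "beech", "monsoon", "rainforest"]


def main() -> None:
    sites = pd.read_csv(ROOT / "site_summaries.csv").drop(columns=["site_id"])
    agg = sites.groupby("forest_type").agg(["mean", "std"])
    agg.columns = ["_".join(c) for c in agg.columns]
    agg = agg.reindex(ORDER).reset_index()
    agg.to_csv(ROOT / "forest_type_means.csv", index=False)

    print(f"{'forest type':<20}{'biomass g/m2':>16}{'flux mW/m2':>16}{'F:B':>8}")
    for _, r in agg.iterrows():
        print(
            f"{r['forest_type']:<20}"
            f"{r['total_biomass_g_m2_mean']:>9.1f} ± {r['total_biomass_g_m2_std']:<5.1f}"
            f"{r['total_flux_mW_m2_mean']:>9.1f} ± {r['total_flux_mW_m2_std']:<6.1f}"
            f"{r['fungivory_bacterivory_mean']:>6.2f}"
        )


if __name__ == "__main__":
    main()
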