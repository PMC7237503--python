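#!/usr/bin/env python
"""Raman tissue-map pipeline and group comparison of band ratios.

Runs the fixed pipeline (despike, baseline, crop 2800-3020, tissue mask,
60,000-count floor, 1-SD spectral QC, min-max + anchor scaling, band ratios)
on every simulated map, compares the lipid (2845/2935) and cholesterol
(2880/2935) ratios between conditions with a Mann-Whitney U test on per-map
means, and checks the recovered group difference against the planted 0.30.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ariomics import io
from ariomics.raman import compare_groups, run_map_pipeline

SIM = Path("results/sim")
OUT = Path("results/raman")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = pd.read_csv(SIM / "raman_truth.tsv", sep="\t")
    map_ids = sorted(truth["map_id"].unique())
    grouping = {m: ("CTL" if m.startswith("CTL") else "KO") for m in map_ids}

    results, reports = {}, {}
    for map_id in map_ids:
        rmap = io.read_raman_map(SIM / f"raman_{map_id}.tsv",
                                 SIM / f"raman_{map_id}_coords.tsv", map_id=map_id)
        results[map_id], reports[map_id] = run_map_pipeline(rmap)
    pd.DataFrame(reports).T.to_csv(OUT / "qc_report.tsv", sep="\t")

    qc = pd.DataFrame(reports).T
    print(f"{len(map_ids)} maps processed; per-map pixels retained: "
          f"{qc['retained'].min()}-{qc['retained'].max()} of {qc['n_input'].iloc[0]}")

    comp = compare_groups(results, grouping)
    comp.to_csv(OUT / "group_comparison.tsv", sep="\t", index=False)
    means = {m: r.mean["r_lipid"] for m, r in results.items()}
    ctl = np.mean([v for m, v in means.items() if grouping[m] == "CTL"])
    ko = np.mean([v for m, v in means.items() if grouping[m] == "KO"])
    planted = truth.dropna().groupby(truth["map_id"].map(grouping))[
        "true_ratio_lipid"].mean()
    row = comp.set_index("ratio").loc["r_lipid"]
    print(f"lipid ratio 2845/2935: CTL {ctl:.3f}, KO {ko:.3f} "
          f"(recovered delta {ko - ctl:.3f}, planted "
          f"{planted['KO'] - planted['CTL']:.3f})")
    print(f"Mann-Whitney on per-map means: U={row['U']:.0f}, p={row['p']:.4f}")
    row_c = comp.set_index("ratio").loc["r_chol"]
    print(f"cholesterol ratio 2880/2935: p={row_c['p']:.3f} (no difference planted)")


if __name__ == "__main__":
    main()
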