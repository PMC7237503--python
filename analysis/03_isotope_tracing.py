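#!/usr/bin/env python
"""Natural-abundance correction and labelling metrics for the tracing table.

Corrects the simulated palmitate isotopologue replicates (all-elements mode,
matching nominal-mass GC-MS of FAME derivatives), reports labelled fraction
and fractional enrichment per replicate, and compares the mean corrected MID
to the planted one.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ariomics import io
from ariomics.isotope import correct_mid, enrichment_metrics

SIM = Path("results/sim")
OUT = Path("results/tracing")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = io.read_isotopologues(SIM / "isotopologues.tsv")
    true_mid = np.loadtxt(SIM / "palmitate_true_mid.tsv")

    rows, mids = [], []
    for rec in records:
        x, total = correct_mid(rec, mode="all-elements")
        m = enrichment_metrics(x)
        mids.append(x)
        rows.append({"compound": rec.compound, "sample": rec.sample,
                     "total_signal": total,
                     "labelled_fraction": m["labelled_fraction"],
                     "fractional_enrichment": m["fractional_enrichment"],
                     **{f"M{i}": v for i, v in enumerate(x)}})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "corrected_mids.tsv", sep="\t", index=False)

    mean_mid = np.mean(mids, axis=0)
    l1 = np.abs(mean_mid - true_mid).sum()
    print(f"{len(records)} replicates corrected (C16, all-elements mode)")
    print(f"mean labelled fraction {table['labelled_fraction'].mean():.4f} "
          f"(planted {1 - true_mid[0]:.4f})")
    print(f"mean fractional enrichment {table['fractional_enrichment'].mean():.4f}")
    print(f"L1 distance of mean corrected MID from planted MID: {l1:.4f} "
          "(3% channel noise)")


if __name__ == "__main__":
    main()
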