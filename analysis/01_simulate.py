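#!/usr/bin/env python
"""Generate every synthetic input with planted ground truth.

Writes the two-format LFQ proteome, the 13C isotopologue table, the
control/knockout lipidome, the Raman tissue maps and the survival cohort
under results/sim/, together with the truth tables the later scripts score
against.
"""

from pathlib import Path

import numpy as np

from ariomics import io
from ariomics.isotope import parse_formula
from ariomics.synthetic import (
    SimDesign,
    gen_cohort,
    gen_lipidome,
    gen_proteome,
    gen_raman_map,
    gen_tracing_samples,
)

SEED = 20200519  # publication date of the study design being emulated
OUT = Path("results/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    design = SimDesign(seed=SEED)
    proteomes, prot_truth = gen_proteome(design)
    for fmt, mat in proteomes.items():
        io.write_omics_matrix(mat, OUT / f"proteome_{fmt}.tsv", OUT / f"design_{fmt}.tsv")
    prot_truth.to_csv(OUT / "proteome_truth.tsv", sep="\t")
    print(f"proteome: {design.n_features} features x {len(design.groups)} groups "
          f"x {len(design.formats)} formats, {int(prot_truth.is_signature.sum())} "
          "signature proteins planted")

    # palmitate from 13C-glucose: a partially labelled pool with strong M+16
    formula = parse_formula("C16H32O2")
    true_mid = np.zeros(17)
    true_mid[[0, 2, 14, 16]] = [0.35, 0.10, 0.15, 0.40]
    records = gen_tracing_samples(formula, true_mid, n_reps=4, noise_cv=0.03,
                                  seed=SEED + 1, mode="all-elements",
                                  compound="palmitate")
    io.write_isotopologues(records, OUT / "isotopologues.tsv")
    np.savetxt(OUT / "palmitate_true_mid.tsv", true_mid[None, :], delimiter="\t")
    print(f"tracing: {len(records)} palmitate replicates, true labelled "
          f"fraction {1 - true_mid[0]:.2f}")

    lipid_mat, species, lipid_truth = gen_lipidome(ko_effect=2.0, seed=SEED + 2)
    io.write_omics_matrix(lipid_mat, OUT / "lipidome.tsv", OUT / "lipidome_design.tsv")
    lipid_truth.to_csv(OUT / "lipidome_truth.tsv", sep="\t")
    n_high = int((lipid_truth.double_bonds > 2).sum())
    print(f"lipidome: {len(species)} species, {n_high} highly unsaturated "
          "(planted up in KO), rest planted down")

    study = gen_raman_map(nx=8, ny=8, group_delta=0.3, frac_background=0.2,
                          n_spikes=3, seed=SEED + 3, n_maps_per_group=6)
    for map_id, rmap in study.maps.items():
        io.write_raman_map(rmap, OUT / f"raman_{map_id}.tsv",
                           OUT / f"raman_{map_id}_coords.tsv")
    study.truth.to_csv(OUT / "raman_truth.tsv", sep="\t", index=False)
    study.spikes.to_csv(OUT / "raman_spikes.tsv", sep="\t", index=False)
    print(f"raman: {len(study.maps)} maps (6 per condition), planted lipid-band "
          "ratio difference 0.30, 20% background pixels, 3 cosmic spikes/map")

    cohort, cohort_truth = gen_cohort(n=300, hazard_ratio_per_group=(1.0, 1.4, 2.0),
                                      censor_rate=0.3, seed=SEED + 4)
    io.write_cohort(cohort, OUT / "cohort.tsv")
    cohort_truth.to_csv(OUT / "cohort_truth.tsv", sep="\t")
    print(f"cohort: {len(cohort)} patients, hazard ratios 1.0/1.4/2.0 across "
          "expression components, 30% censoring")


if __name__ == "__main__":
    main()
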