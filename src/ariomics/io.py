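"""Delimited-text readers/writers for every pipeline input and output.

Formats (all TSV):

* abundance matrix — features x samples, first column ``feature``;
* design table — columns sample, group, format, replicate;
* isotopologue long table — compound, formula, sample, isotopologue, intensity;
* Raman map — first column ``wavenumber``, one column per pixel (``px<i>``),
  plus a coordinate sidecar with columns pixel, x, y;
* cohort table — patient, expression, time, event.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diffsig import OmicsMatrix
from .isotope import IsotopologueRecord, parse_formula
from .raman import RamanMap
from .survival import CohortTable

__all__ = [
    "write_omics_matrix", "read_omics_matrix",
    "write_isotopologues", "read_isotopologues",
    "write_raman_map", "read_raman_map",
    "write_cohort", "read_cohort",
]


def write_omics_matrix(mat: OmicsMatrix, matrix_path, design_path) -> None:
    mat.values.rename_axis("feature").to_csv(matrix_path, sep="\t")
    mat.design.rename_axis("sample").to_csv(design_path, sep="\t")


def read_omics_matrix(matrix_path, design_path, reference: str) -> OmicsMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="feature")
    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    return OmicsMatrix(values, design, reference=reference)


def write_isotopologues(records: list[IsotopologueRecord], path) -> None:
    rows = [
        {
            "compound": r.compound,
            "formula": str(r.formula),
            "sample": r.sample,
            "isotopologue": i,
            "intensity": v,
        }
        for r in records
        for i, v in enumerate(r.raw)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_isotopologues(path) -> list[IsotopologueRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for (compound, formula, sample), grp in df.groupby(
        ["compound", "formula", "sample"], sort=False
    ):
        grp = grp.sort_values("isotopologue")
        records.append(
            IsotopologueRecord(
                compound=compound,
                formula=parse_formula(formula),
                sample=sample,
                raw=grp["intensity"].to_numpy(),
            )
        )
    return records


def write_raman_map(rmap: RamanMap, spectra_path, coords_path) -> None:
    df = pd.DataFrame(
        rmap.spectra.T,
        index=pd.Index(rmap.wavenumbers, name="wavenumber"),
        columns=[f"px{i}" for i in rmap.coords.index],
    )
    df.to_csv(spectra_path, sep="\t")
    rmap.coords.rename_axis("pixel").to_csv(coords_path, sep="\t")


def read_raman_map(spectra_path, coords_path, map_id: str = "map") -> RamanMap:
    df = pd.read_csv(spectra_path, sep="\t", index_col="wavenumber")
    coords = pd.read_csv(coords_path, sep="\t", index_col="pixel")
    return RamanMap(
        df.index.to_numpy(dtype=float), df.to_numpy().T, coords, map_id=map_id
    )


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.rename_axis("patient").to_csv(path, sep="\t")


def read_cohort(path) -> CohortTable:
    return CohortTable(pd.read_csv(path, sep="\t", index_col="patient"))
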