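"""Lipid shorthand parsing, saturation classes and heatmap matrices.

Lipid species are named ``"<CLASS> <carbons>:<double bonds>"`` (summed
shorthand, e.g. ``"PC 34:2"``) or in chain form ``"<CLASS> c1:d1/c2:d2[/...]"``
(e.g. ``"Cer d18:1/16:0"``; the sphingoid ``d``/``t`` hydroxyl prefix is
tolerated and chains are summed).  The saturation level of a species is its
total double-bond count; species with more than two double bonds count as
highly unsaturated, the rest (saturated, mono- or bi-unsaturated) as lowly
unsaturated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffsig import OmicsMatrix, differential_table, select_consistent

__all__ = [
    "LIPID_CLASSES",
    "LipidSpecies",
    "LipidParseError",
    "parse_lipid_name",
    "format_lipid_name",
    "classify_saturation",
    "fa_class_totals",
    "lipid_diff_matrix",
]

LIPID_CLASSES = (
    "Cer", "CL", "DG", "LysoPC", "PC", "PE", "PG", "PI", "PS", "SM", "TG", "BMP",
)


class LipidParseError(ValueError):
    """Lipid name outside the supported shorthand grammar."""


@dataclass(frozen=True)
class LipidSpecies:
    lipid_class: str
    carbons: int
    double_bonds: int
    raw_name: str

    def __post_init__(self):
        if self.lipid_class not in LIPID_CLASSES:
            raise LipidParseError(f"unsupported lipid class {self.lipid_class!r}")
        if self.carbons <= 0:
            raise LipidParseError(f"carbons must be positive in {self.raw_name!r}")
        if self.double_bonds < 0:
            raise LipidParseError(f"negative double bonds in {self.raw_name!r}")


_CHAIN = re.compile(r"^[dt]?(\d+):(\d+)$")


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into (class, total carbons, total DB)."""
    if not isinstance(name, str):
        raise LipidParseError(f"lipid name must be a string, got {name!r}")
    parts = name.strip().split(None, 1)
    if len(parts) != 2:
        raise LipidParseError(f"expected '<CLASS> <chains>' in {name!r}")
    cls, chains = parts
    if cls not in LIPID_CLASSES:
        raise LipidParseError(f"unknown lipid class {cls!r} in {name!r}")
    if chains.startswith(("O-", "P-")) or "O-" in chains or "P-" in chains:
        raise LipidParseError(
            f"ether/oxidised notation not supported: offending token {chains!r}"
        )
    carbons = 0
    double_bonds = 0
    for token in chains.split("/"):
        m = _CHAIN.match(token)
        if m is None:
            raise LipidParseError(f"malformed chain token {token!r} in {name!r}")
        carbons += int(m.group(1))
        double_bonds += int(m.group(2))
    return LipidSpecies(cls, carbons, double_bonds, name.strip())


def format_lipid_name(cls: str, carbons: int, double_bonds: int) -> str:
    return f"{cls} {carbons}:{double_bonds}"


def classify_saturation(sp: LipidSpecies) -> str:
    """``"high_unsat"`` for saturation level > 2, else ``"low_unsat"``."""
    return "high_unsat" if sp.double_bonds > 2 else "low_unsat"


def fa_class_totals(profile) -> dict:
    """Sum a fatty-acid profile into SFA / MUFA / PUFA pools.

    ``profile`` maps fatty acids named ``"<carbons>:<double bonds>"`` to
    non-negative concentrations (e.g. nmol per mg protein).  SFA = 0 double
    bonds, MUFA = 1, PUFA = >= 2 (per fatty acid).
    """
    totals = {"SFA_total": 0.0, "MUFA_total": 0.0, "PUFA_total": 0.0}
    items = profile.items() if hasattr(profile, "items") else profile
    for fa, conc in items:
        m = _CHAIN.match(fa.strip())
        if m is None:
            raise LipidParseError(f"malformed fatty acid {fa!r}")
        if conc < 0:
            raise ValueError(f"negative concentration for {fa!r}: {conc}")
        db = int(m.group(2))
        key = "SFA_total" if db == 0 else ("MUFA_total" if db == 1 else "PUFA_total")
        totals[key] += float(conc)
    return totals


def lipid_diff_matrix(
    mat: OmicsMatrix,
    species: list[LipidSpecies],
    mode: str = "logFC",
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    min_groups: int = 1,
    log_base: str = "e",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filtered heatmap matrix of significantly regulated lipids.

    Rows are retained by the same consistency rule as the protein panels
    (|log2FC| >= log2(fc_threshold) and p < p_threshold in at least
    ``min_groups`` group-vs-reference comparisons).  Values are per-comparison
    log fold changes (natural log by default, ``log_base="2"`` for log2) in
    ``"logFC"`` mode, or per-row z-scores across samples in ``"zscore"``
    mode.  Returns (matrix, annotation) with the annotation holding class,
    double bonds and saturation class; rows sorted by class then double
    bonds.
    """
    if mode not in ("logFC", "zscore"):
        raise ValueError(f"unsupported mode {mode!r}")
    if len(species) != len(mat.values.index):
        raise ValueError(
            f"species list ({len(species)}) does not align with the "
            f"{len(mat.values.index)} matrix rows"
        )
    for sp, row in zip(species, mat.values.index):
        if sp.raw_name != row:
            raise ValueError(f"row {row!r} does not match species {sp.raw_name!r}")
    res = differential_table(mat)
    retained = select_consistent(
        res,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        k_of_n=min_groups,
        require_sign=False,
    )
    by_name = {sp.raw_name: sp for sp in species}
    ann = pd.DataFrame(
        {
            "lipid_class": [by_name[f].lipid_class for f in retained],
            "double_bonds": [by_name[f].double_bonds for f in retained],
            "saturation": [classify_saturation(by_name[f]) for f in retained],
        },
        index=pd.Index(retained, name="feature"),
    ).sort_values(["lipid_class", "double_bonds"], kind="stable")
    order = list(ann.index)

    if mode == "logFC":
        wide = res.pivot_table(index="feature", columns=["format", "group"], values="log2fc")
        wide.columns = [f"{f}_{g}" if f != "default" else str(g) for f, g in wide.columns]
        matrix = wide.loc[order]
        if log_base == "e":
            matrix = matrix * math.log(2.0)
        elif log_base != "2":
            raise ValueError(f"unsupported log base {log_base!r}")
    else:
        vals = np.log2(mat.values.loc[order].to_numpy(dtype=float))
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        matrix = pd.DataFrame(
            (vals - mu) / sd, index=pd.Index(order, name="feature"), columns=mat.values.columns
        )
    return matrix, ann
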