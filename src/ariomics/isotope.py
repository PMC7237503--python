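"""Natural-abundance correction and labelling metrics for 13C tracing.

Isotopologue intensity vectors measured by MS mix the tracer signal with
heavy-isotope signal expected at natural abundance.  The measured raw vector
``y`` (length C+1 for a compound with C carbons) relates to the true mass
isotopomer distribution (MID) ``x`` through a correction matrix ``M`` whose
column ``j`` is the mass-shift distribution of a molecule carrying ``j``
tracer carbons.  Correction solves the non-negative least-squares problem
``min ||M x - y||`` and renormalises ``x`` to a probability vector.

Two modes are provided:

``"carbon-only"``
    Only 13C contributes mass shifts (high-resolution instruments where
    other isotopes are resolved from the tracer shifts).  ``M`` is lower
    triangular at full tracer purity.
``"all-elements"``
    The +1/+2 shift distributions of H, N, O, S and Si natural isotopes are
    convolved in (nominal-mass GC-MS of TMS/FAME derivatives).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import binom

__all__ = [
    "ElementalFormula",
    "AbundanceTable",
    "IsotopologueRecord",
    "FormulaError",
    "parse_formula",
    "correction_matrix",
    "correct_mid",
    "enrichment_metrics",
    "normalize_abundance",
]

SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "Si")


class FormulaError(ValueError):
    """Malformed or unsupported elemental formula."""


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts for the supported element set."""

    counts: dict

    def __post_init__(self):
        for el, n in self.counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise FormulaError(f"invalid count for {el}: {n!r}")

    def __getitem__(self, element: str) -> int:
        return int(self.counts.get(element, 0))

    @property
    def n_carbon(self) -> int:
        return self["C"]

    @property
    def n_atoms(self) -> int:
        return int(sum(self.counts.values()))

    def __str__(self) -> str:
        return "".join(
            f"{el}{self.counts[el]}" for el in SUPPORTED_ELEMENTS if self.counts.get(el)
        )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation-like formula string such as ``"C16H32O2"``."""
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"empty or non-string formula: {text!r}")
    text = text.strip()
    counts: dict = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)


# IUPAC isotope abundances; overridable via AbundanceTable fields.
_DEFAULT_ABUNDANCES = {
    "13C": 0.0107,
    "2H": 0.000115,
    "15N": 0.00364,
    "17O": 0.00038,
    "18O": 0.00205,
    "33S": 0.0075,
    "34S": 0.0425,
    "29Si": 0.0468,
    "30Si": 0.0310,
}


@dataclass(frozen=True)
class AbundanceTable:
    """Natural isotope abundances per element plus tracer purity.

    ``tracer_purity`` is the 13C fraction at nominally labelled positions
    (1.0 = ideal tracer; 0.99 matches typical U-13C glucose lots).
    """

    abundances: dict = field(default_factory=lambda: dict(_DEFAULT_ABUNDANCES))
    tracer_purity: float = 1.0

    def __post_init__(self):
        for key, val in self.abundances.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"abundance {key}={val} outside [0, 1]")
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError("tracer purity must be in (0, 1]")

    def with_zero_abundances(self) -> "AbundanceTable":
        return replace(self, abundances={k: 0.0 for k in self.abundances})

    def shift_pmf(self, element: str) -> np.ndarray:
        """Per-atom mass-shift distribution [P(+0), P(+1), P(+2)]."""
        a = self.abundances
        if element == "C":
            return np.array([1 - a["13C"], a["13C"]])
        if element == "H":
            return np.array([1 - a["2H"], a["2H"]])
        if element == "N":
            return np.array([1 - a["15N"], a["15N"]])
        if element == "O":
            return np.array([1 - a["17O"] - a["18O"], a["17O"], a["18O"]])
        if element == "S":
            return np.array([1 - a["33S"] - a["34S"], a["33S"], a["34S"]])
        if element == "Si":
            return np.array([1 - a["29Si"] - a["30Si"], a["29Si"], a["30Si"]])
        raise FormulaError(f"unsupported element {element!r}")


@dataclass
class IsotopologueRecord:
    """Raw isotopologue intensities of one compound in one sample."""

    compound: str
    formula: ElementalFormula
    sample: str
    raw: np.ndarray
    corrected: np.ndarray | None = None

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        n = self.formula.n_carbon
        if self.raw.shape != (n + 1,):
            raise ValueError(
                f"raw vector length {self.raw.size} != C+1 = {n + 1} "
                f"for {self.compound} ({self.formula})"
            )
        if np.any(self.raw < 0):
            raise ValueError(f"negative raw intensity for {self.compound}")


def _element_pmf(pmf1: np.ndarray, n_atoms: int) -> np.ndarray:
    """Mass-shift distribution of ``n_atoms`` i.i.d. atoms (repeated convolution)."""
    out = np.array([1.0])
    for _ in range(n_atoms):
        out = np.convolve(out, pmf1)
    return out


def correction_matrix(
    formula: ElementalFormula,
    ab: AbundanceTable | None = None,
    mode: str = "carbon-only",
) -> np.ndarray:
    """Build the (C+1)x(C+1) natural-abundance correction matrix.

    Column ``j`` holds the probability of observing mass shift ``i`` given
    ``j`` tracer-labelled carbon positions: the convolution of

    * binomial(j, purity) — shifts actually contributed by labelled positions,
    * binomial(C-j, a_13C) — natural 13C on the unlabelled carbons,
    * (mode ``"all-elements"``) the natural +1/+2 shifts of H, N, O, S, Si,

    truncated at shift C (measured vectors stop at M+C) and renormalised so
    each column sums to 1.
    """
    if ab is None:
        ab = AbundanceTable()
    if mode not in ("carbon-only", "all-elements"):
        raise ValueError(f"unsupported mode {mode!r}")
    n = formula.n_carbon
    if n < 1:
        raise FormulaError("tracer compounds need at least one carbon")

    a_c = ab.abundances["13C"]
    other = np.array([1.0])
    if mode == "all-elements":
        for el in ("H", "N", "O", "S", "Si"):
            count = formula[el]
            if count:
                other = np.convolve(other, _element_pmf(ab.shift_pmf(el), count))

    M = np.zeros((n + 1, n + 1))
    shifts = np.arange(n + 1)
    for j in range(n + 1):
        labelled = binom.pmf(np.arange(j + 1), j, ab.tracer_purity)
        natural = binom.pmf(np.arange(n - j + 1), n - j, a_c)
        col = np.convolve(np.convolve(labelled, natural), other)[: n + 1]
        total = col.sum()
        if total > 0:
            col = col / total
        M[: col.size, j] = col
    return M


def correct_mid(
    record: IsotopologueRecord | np.ndarray,
    ab: AbundanceTable | None = None,
    mode: str = "carbon-only",
    formula: ElementalFormula | None = None,
    cond_warn: float = 1e8,
) -> tuple[np.ndarray, float]:
    """Natural-abundance-correct a raw isotopologue vector.

    Solves ``min ||M x - y||_2`` with ``x >= 0`` (non-negative least squares;
    plain inversion can produce negative isotopologues on noisy data), then
    normalises ``x`` to sum 1.  Returns ``(corrected MID, total corrected
    signal before normalisation)``.  If ``record`` is an IsotopologueRecord
    its ``corrected`` field is filled in.
    """
    if isinstance(record, IsotopologueRecord):
        y = record.raw
        formula = record.formula
    else:
        y = np.asarray(record, dtype=float)
        if formula is None:
            raise ValueError("formula required when passing a bare vector")
    if np.all(y == 0):
        raise ValueError("all-zero isotopologue vector: no signal to correct")
    M = correction_matrix(formula, ab, mode)
    cond = np.linalg.cond(M)
    if cond > cond_warn:
        warnings.warn(
            f"correction matrix ill-conditioned (cond={cond:.3g}); "
            "corrected MID may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    x_raw, _ = nnls(M, y)
    total = float(x_raw.sum())
    if total == 0:
        raise ValueError("corrected signal is identically zero")
    x = x_raw / total
    if isinstance(record, IsotopologueRecord):
        record.corrected = x
    return x, total


def enrichment_metrics(x: np.ndarray, atol: float = 1e-6) -> dict:
    """Labelling metrics from a corrected MID.

    * ``labelled_fraction`` = 1 - x0 (any tracer carbon present),
    * ``fractional_enrichment`` = mean number of labelled carbons / C,
    * ``isotopologue_distribution`` = the MID itself.
    """
    x = np.asarray(x, dtype=float)
    if abs(x.sum() - 1.0) > atol:
        raise ValueError(f"MID not normalised (sum={x.sum():.8f})")
    n = x.size - 1
    if n < 1:
        raise ValueError("MID must cover at least one carbon")
    return {
        "labelled_fraction": float(1.0 - x[0]),
        "fractional_enrichment": float(np.arange(n + 1) @ x / n),
        "isotopologue_distribution": x,
    }


def normalize_abundance(values, internal_standard=None, protein_or_cells=None):
    """Normalise per-sample totals to an internal standard and/or protein content.

    Either denominator may be omitted (treated as 1).  Accepts array-likes or
    pandas Series (aligned on index).  Zero or negative denominators raise,
    naming the offending sample.
    """
    values = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    out = values.copy()
    for name, denom in (("internal_standard", internal_standard), ("protein_or_cells", protein_or_cells)):
        if denom is None:
            continue
        denom = pd.Series(denom, dtype=float) if not isinstance(denom, pd.Series) else denom.astype(float)
        if not denom.index.equals(values.index):
            denom = denom.reindex(values.index)
        bad = denom.index[(denom.isna()) | (denom <= 0)]
        if len(bad):
            raise ValueError(f"non-positive {name} for sample(s): {list(bad)}")
        out = out / denom
    return out
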