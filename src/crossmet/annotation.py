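"""Formula-based ion annotation: monoisotopic masses, adduct m/z, ppm
error and ring-and-double-bond equivalents.

Supports the four common electrospray adducts of small-molecule
metabolomics — [M+H]+, [M-H]-, and the proton-bound dimers [2M+H]+ and
[2M-H]- — computed from elemental monoisotopic masses (via the NIST
table shipped with pyteomics) and the proton mass (hydrogen atom minus
electron).  RDB (degree of unsaturation) is computed on the ion formula,
so even-electron protonated/deprotonated species yield half-integers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from pyteomics import mass as _ptmass

PROTON_MASS = 1.00727646677  # H atom minus electron, Da

ADDUCTS = {
    "[M+H]+": (1, +1),    # (multiplier of M, protons added)
    "[M-H]-": (1, -1),
    "[2M+H]+": (2, +1),
    "[2M-H]-": (2, -1),
}
_POSITIVE = {"[M+H]+", "[2M+H]+"}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class AnnotationError(ValueError):
    pass


def _known(symbol: str) -> bool:
    return symbol in _ptmass.nist_mass


def parse_formula(text: str):
    """Parse a molecular formula into element counts.

    Accepts the plain dialect (``C11H12N2O2``) and the underscored one
    (``C_11_H_12_N_2_O_2_``); an omitted count means 1.
    """
    if not text or not text.strip():
        raise AnnotationError("empty formula")
    cleaned = text.replace("_", "").strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(cleaned):
        if m.start() != pos:
            raise AnnotationError(f"cannot parse formula {text!r} at {cleaned[pos:]!r}")
        pos = m.end()
        symbol, digits = m.group(1), m.group(2)
        if not _known(symbol):
            raise AnnotationError(f"unknown element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise AnnotationError(f"zero count for {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
    if pos != len(cleaned) or not counts:
        raise AnnotationError(f"cannot parse formula {text!r}")
    return counts


def monoisotopic_mass(formula) -> float:
    """Sum of most-abundant-isotope masses, in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for el, n in formula.items():
        if not _known(el):
            raise AnnotationError(f"no tabulated mass for element {el!r}")
        total += _ptmass.nist_mass[el][0][0] * n
    return total


def ion_mz(formula, adduct: str) -> float:
    """Theoretical m/z of a singly charged adduct ion."""
    if adduct not in ADDUCTS:
        raise AnnotationError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}")
    mult, protons = ADDUCTS[adduct]
    return mult * monoisotopic_mass(formula) + protons * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """(observed - theoretical) / theoretical * 1e6."""
    if theoretical <= 0:
        raise AnnotationError("theoretical m/z must be > 0")
    return (observed - theoretical) / theoretical * 1e6


_RDB_SUPPORTED = {"C", "H", "N", "O", "S", "P"}


def rdb_equivalents(formula, adduct: str | None = None) -> float:
    """Ring-and-double-bond equivalents of the (ion) formula.

    RDB = C - H/2 + (N + P)/2 + 1; O and S contribute nothing.  When an
    adduct is given the hydrogen count of the ion formula is used
    (neutral counts doubled for dimers, +/- one proton), which yields
    half-integer values for even-electron ions.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    unsupported = set(formula) - _RDB_SUPPORTED
    if unsupported:
        raise AnnotationError(
            f"no valence rule for element(s) {sorted(unsupported)}")
    counts = dict(formula)
    if adduct is not None:
        if adduct not in ADDUCTS:
            raise AnnotationError(f"unsupported adduct {adduct!r}")
        mult, protons = ADDUCTS[adduct]
        counts = {el: n * mult for el, n in counts.items()}
        counts["H"] = counts.get("H", 0) + protons
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    n = counts.get("N", 0)
    p = counts.get("P", 0)
    return c - h / 2 + (n + p) / 2 + 1


@dataclass
class AnnotationRecord:
    """One candidate assignment of a measured feature m/z."""

    name: str
    formula: dict
    formula_text: str
    adduct: str
    observed_mz: float
    theoretical_mz: float
    exact_mass: float
    delta_ppm: float
    rdb: float

    def as_row(self) -> dict:
        return {
            "name": self.name,
            "formula": self.formula_text,
            "adduct": self.adduct,
            "observed_mz": round(self.observed_mz, 4),
            "theoretical_mz": round(self.theoretical_mz, 4),
            "delta_ppm": round(self.delta_ppm, 1),
            "rdb": self.rdb,
            "exact_mass": round(self.exact_mass, 4),
        }


def annotate_feature(mz: float, polarity: str, candidates,
                     tol_ppm: float = 5.0) -> list:
    """Rank candidate (name, formula, adduct) triples against a feature m/z.

    Candidates whose adduct polarity matches and whose theoretical m/z
    lies within ``tol_ppm`` are returned sorted by |delta ppm|.  An empty
    result is allowed.
    """
    if not candidates:
        raise AnnotationError("candidate list is empty")
    records = []
    for name, formula_text, adduct in candidates:
        if adduct not in ADDUCTS:
            raise AnnotationError(f"unsupported adduct {adduct!r}")
        is_pos = adduct in _POSITIVE
        if (polarity == "positive") != is_pos:
            continue
        counts = parse_formula(formula_text) if isinstance(formula_text, str) \
            else formula_text
        theo = ion_mz(counts, adduct)
        dppm = ppm_error(mz, theo)
        if abs(dppm) > tol_ppm:
            continue
        records.append(AnnotationRecord(
            name=name,
            formula=counts,
            formula_text=formula_text if isinstance(formula_text, str) else
            "".join(f"{el}{n if n > 1 else ''}" for el, n in counts.items()),
            adduct=adduct,
            observed_mz=mz,
            theoretical_mz=theo,
            exact_mass=monoisotopic_mass(counts),
            delta_ppm=dppm,
            rdb=rdb_equivalents(counts, adduct),
        ))
    records.sort(key=lambda r: abs(r.delta_ppm))
    return records


def load_candidates_csv(path):
    """Read a candidate list CSV with columns name, formula, adduct."""
    import pandas as pd

    df = pd.read_csv(path)
    need = {"name", "formula", "adduct"}
    if not need <= set(df.columns):
        raise AnnotationError(f"candidate CSV must have columns {sorted(need)}")
    return list(df[["name", "formula", "adduct"]].itertuples(index=False, name=None))
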