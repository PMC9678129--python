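"""Adduct-based metabolite annotation for direct-infusion MS features.

Putative annotation of a measured ion m/z works by comparing it against the
theoretical m/z of every (compound, adduct) pair from a local compound table:

    m/z_theo = (M + mass_delta) / |z|

where ``M`` is the neutral monoisotopic mass and ``mass_delta`` is the sum of
the masses added/removed by the adduct, *including one electron per unit of
charge* (subtracted for positive ions, added for negative ions).  The
electron-mass correction of ~0.55 mDa matters at sub-ppm accuracy and is
required to reproduce printed mass errors on an Orbitrap-class instrument.

Mass error is reported as signed parts-per-million:

    ppm = (measured - theoretical) / theoretical * 1e6

A small compound table covering discriminative milk metabolites (sugars,
fatty acids, an acyl-carnitine and a phosphatidylglycerol) is bundled for
tests and demos; real use loads a CSV table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "AdductSpec",
    "AnnotationHit",
    "DEFAULT_POSITIVE_ADDUCTS",
    "DEFAULT_NEGATIVE_ADDUCTS",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate",
    "load_compound_table",
    "default_compound_table",
]

# IUPAC/AME monoisotopic masses of the most abundant isotope, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,  # exact by definition
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.9637064864,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Si": 27.9769265325,
    "Se": 79.9165213,
}

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727645...
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a molecular formula such as ``C6H13NO5``.

    Raises ``ValueError`` for unknown element symbols or unparseable input.
    """
    formula = formula.strip()
    if not formula:
        return 0.0
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"cannot parse formula {formula!r} at position {pos}"
            )
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        total += MONOISOTOPIC_MASS[element] * (int(count) if count else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return total


@dataclass(frozen=True)
class AdductSpec:
    """An ionisation adduct: name, signed charge and neutral mass delta.

    ``mass_delta`` is the mass of everything added to / removed from the
    neutral molecule *before* electron correction; the correction (one
    electron per charge unit, removed for cations, gained for anions) is
    applied by :func:`adduct_mz`.
    """

    name: str
    charge: int
    mass_delta: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")


def _adduct(name: str, charge: int, *deltas: float) -> AdductSpec:
    return AdductSpec(name=name, charge=charge, mass_delta=sum(deltas))


_H = MONOISOTOPIC_MASS["H"]
_NA = MONOISOTOPIC_MASS["Na"]
_K = MONOISOTOPIC_MASS["K"]

DEFAULT_POSITIVE_ADDUCTS: tuple[AdductSpec, ...] = (
    _adduct("[M+H]+", +1, _H),
    _adduct("[M+Na]+", +1, _NA),
    _adduct("[M+K]+", +1, _K),
    _adduct("[M+H-H2O]+", +1, _H, -WATER_MASS),
    _adduct("[M+2Na]2+", +2, 2 * _NA),
    _adduct("[M+2H]2+", +2, 2 * _H),
)

DEFAULT_NEGATIVE_ADDUCTS: tuple[AdductSpec, ...] = (
    _adduct("[M-H]-", -1, -_H),
    _adduct("[M-H-H2O]-", -1, -_H, -WATER_MASS),
)

_ADDUCTS_BY_NAME = {
    a.name: a for a in DEFAULT_POSITIVE_ADDUCTS + DEFAULT_NEGATIVE_ADDUCTS
}


def adduct_mz(M: float, adduct: AdductSpec) -> float:
    """Theoretical m/z of neutral mass ``M`` (Da) under ``adduct``.

    m/z = (M + mass_delta -/+ n_charge * m_e) / |charge|.
    """
    if M < 0:
        raise ValueError("neutral mass must be non-negative")
    n = abs(adduct.charge)
    electron = -n * ELECTRON_MASS if adduct.charge > 0 else n * ELECTRON_MASS
    return (M + adduct.mass_delta + electron) / n


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class AnnotationHit:
    compound: str
    formula: str | None
    monoisotopic_mass: float
    adduct: str
    theoretical_mz: float
    measured_mz: float
    ppm_error: float


# (name, formula) — discriminative milk metabolites observed in lame vs
# healthy dairy-cow dried milk spots, plus common milk constituents.
# CAR 13:3;O3 (tri-unsaturated, tri-oxygenated C13 acyl-carnitine) as
# C20H33NO7; PG 35:4 as C41H71O10P.
_DEFAULT_COMPOUNDS: tuple[tuple[str, str], ...] = (
    ("Glucosamine", "C6H13NO5"),
    ("Alpha-Lactose", "C12H22O11"),
    ("Trans-11-methyl-2-dodecenoic acid", "C13H24O2"),
    ("Carnitine 13:3;O3", "C20H33NO7"),
    ("Hexadecanedioic acid", "C16H30O4"),
    ("6-Hydroxyhexanoic acid", "C6H12O3"),
    ("Alpha-carboxyethyl hydrochroman", "C16H22O4"),
    ("1-Piperideine-2-carboxylic acid", "C6H9NO2"),
    ("Isobutylaldehyde", "C4H8O"),
    ("PG 35:4", "C41H71O10P"),
    ("Creatinine", "C4H7N3O"),
    ("L-Carnitine", "C7H15NO3"),
    ("Citric acid", "C6H8O7"),
    ("Urea", "CH4N2O"),
)


def default_compound_table() -> pd.DataFrame:
    """Bundled local compound table (name, formula, monoisotopic mass)."""
    rows = [
        {"name": n, "formula": f, "monoisotopic_mass": monoisotopic_mass(f)}
        for n, f in _DEFAULT_COMPOUNDS
    ]
    return pd.DataFrame(rows)


def load_compound_table(path) -> pd.DataFrame:
    """Load a compound table CSV with columns ``name`` and ``formula``
    and/or ``monoisotopic_mass``; masses are computed from formulas when
    absent."""
    df = pd.read_csv(path, comment="#")
    if "name" not in df.columns:
        raise ValueError("compound table needs a 'name' column")
    if "monoisotopic_mass" not in df.columns:
        if "formula" not in df.columns:
            raise ValueError(
                "compound table needs 'formula' or 'monoisotopic_mass'"
            )
        df["monoisotopic_mass"] = df["formula"].map(monoisotopic_mass)
    else:
        missing = df["monoisotopic_mass"].isna()
        if missing.any():
            if "formula" not in df.columns:
                raise ValueError("missing masses and no formula column")
            df.loc[missing, "monoisotopic_mass"] = df.loc[
                missing, "formula"
            ].map(monoisotopic_mass)
    if "formula" not in df.columns:
        df["formula"] = None
    return df[["name", "formula", "monoisotopic_mass"]]


def resolve_adducts(
    adducts: str | Sequence[AdductSpec | str],
) -> tuple[AdductSpec, ...]:
    """Accept ``"default_pos"``/``"default_neg"``, adduct names, or specs."""
    if isinstance(adducts, str):
        if adducts == "default_pos":
            return DEFAULT_POSITIVE_ADDUCTS
        if adducts == "default_neg":
            return DEFAULT_NEGATIVE_ADDUCTS
        raise ValueError(f"unknown adduct set {adducts!r}")
    out = []
    for a in adducts:
        if isinstance(a, AdductSpec):
            out.append(a)
        elif a in _ADDUCTS_BY_NAME:
            out.append(_ADDUCTS_BY_NAME[a])
        else:
            raise ValueError(f"unknown adduct {a!r}")
    return tuple(out)


def annotate(
    measured_mz: float | Iterable[float],
    compound_table: pd.DataFrame,
    adducts: str | Sequence[AdductSpec | str] = "default_pos",
    tol_ppm: float | None = 5.0,
    tol_abs: float | None = None,
) -> list[AnnotationHit]:
    """All (compound, adduct) matches within tolerance of the measured m/z.

    Exactly one of ``tol_ppm`` (relative, default 5 ppm) or ``tol_abs``
    (absolute m/z window, lipid-search style ±0.001) governs the match.
    Hits are sorted by |ppm error|; multiple measured m/z values may be
    passed and yield a concatenated list.
    """
    if tol_abs is not None:
        tol_ppm = None
    if tol_ppm is None and tol_abs is None:
        raise ValueError("one of tol_ppm or tol_abs is required")
    specs = resolve_adducts(adducts)
    if not specs:
        raise ValueError("adduct list is empty")
    try:
        mz_values = [float(measured_mz)]  # type: ignore[arg-type]
    except TypeError:
        mz_values = [float(v) for v in measured_mz]  # type: ignore[union-attr]

    hits: list[AnnotationHit] = []
    for mz in mz_values:
        for row in compound_table.itertuples(index=False):
            M = float(row.monoisotopic_mass)
            for spec in specs:
                theo = adduct_mz(M, spec)
                err = ppm_error(mz, theo)
                if tol_ppm is not None:
                    ok = abs(err) <= tol_ppm
                else:
                    ok = abs(mz - theo) <= tol_abs  # type: ignore[operator]
                if ok:
                    hits.append(
                        AnnotationHit(
                            compound=row.name,
                            formula=getattr(row, "formula", None),
                            monoisotopic_mass=M,
                            adduct=spec.name,
                            theoretical_mz=theo,
                            measured_mz=mz,
                            ppm_error=err,
                        )
                    )
    hits.sort(key=lambda h: abs(h.ppm_error))
    return hits


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    """Annotation hits as a DataFrame (one row per hit)."""
    return pd.DataFrame(
        [
            {
                "measured_mz": h.measured_mz,
                "compound": h.compound,
                "formula": h.formula,
                "monoisotopic_mass": h.monoisotopic_mass,
                "adduct": h.adduct,
                "theoretical_mz": h.theoretical_mz,
                "ppm_error": h.ppm_error,
            }
            for h in hits
        ],
        columns=[
            "measured_mz",
            "compound",
            "formula",
            "monoisotopic_mass",
            "adduct",
            "theoretical_mz",
            "ppm_error",
        ],
    )
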