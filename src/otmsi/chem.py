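"""Molecular formulas, adducts and theoretical isotopic envelopes.

Reference spectra for deconvolution are *aggregated* isotopic envelopes:
isotopologues are pooled by total nucleon count, each aggregate carrying the
probability-weighted mean mass.  At the resolving powers typical of MSI
instruments (R <= 60 000 in the data sets this package targets) fine isotopic
structure is not resolved, so the aggregated envelope matches the observed
peak pattern.

Isotope masses and abundances are embedded (IUPAC 2021 / CODATA values, see
``ISOTOPES``) so that envelopes do not drift with external library versions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ISOTOPES",
    "ELECTRON_MASS",
    "MolecularFormula",
    "TheoreticalSpectrum",
    "parse_formula",
    "apply_adduct",
    "monoisotopic_mass",
    "isotopic_envelope",
    "read_ion_library",
]

#: electron rest mass in Da (CODATA 2018)
ELECTRON_MASS = 0.000548579909

#: isotope table: element -> list of (mass in Da, relative abundance),
#: sorted by mass.  IUPAC 2021 atomic masses and representative abundances.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.00307400443, 0.99636), (15.00010889888, 0.00364)],
    "O": [
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ],
    "F": [(18.99840316273, 1.0)],
    "Na": [(22.98976928196, 1.0)],
    "P": [(30.97376199842, 1.0)],
    "S": [
        (31.97207117441, 0.9499),
        (32.97145890985, 0.0075),
        (33.96786700119, 0.0425),
        (35.96708071211, 0.0001),
    ],
    "Cl": [(34.96885268, 0.7576), (36.96590260, 0.2424)],
    "K": [
        (38.96370648661, 0.932581),
        (39.96399816600, 0.000117),
        (40.96182525792, 0.067302),
    ],
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map plus a signed charge in elementary units."""

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for element, count in self.counts.items():
            if element not in ISOTOPES:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise ValueError(f"negative or non-integer count for {element}")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("formula must contain at least one atom")
        # drop zero-count entries for a canonical representation
        object.__setattr__(
            self, "counts", {e: int(c) for e, c in self.counts.items() if c > 0}
        )

    def __str__(self) -> str:
        body = "".join(
            f"{e}{c if c != 1 else ''}" for e, c in sorted(self.counts.items())
        )
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            body += sign * abs(self.charge)
        return body


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Centroided reference spectrum of one ion.

    ``mz`` is strictly increasing; ``intensity`` is positive and sums to 1
    after the threshold-and-renormalize step of :func:`isotopic_envelope`.
    """

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size == 0:
            raise ValueError("empty theoretical spectrum")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z must be strictly increasing")
        if np.any(intensity <= 0):
            raise ValueError("intensities must be positive")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    @property
    def monoisotopic_mz(self) -> float:
        return float(self.mz[0])


def parse_formula(text: str, charge: int = 0) -> MolecularFormula:
    """Parse an element-count string like ``"C46H90NO8PK"``.

    An omitted count means 1.  Unknown element symbols and malformed strings
    raise ``ValueError``.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in ISOTOPES:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(counts, charge)


def apply_adduct(
    formula: MolecularFormula, adduct: str, polarity: int
) -> MolecularFormula:
    """Apply an ionization adduct such as ``"+K"``, ``"+Na"``, ``"-H"``.

    ``polarity`` is the resulting charge (+1 for cations, -1 for anions, 0
    with the identity adduct ``"none"``).  Removing atoms the formula lacks
    is an error.
    """
    adduct = adduct.strip()
    if adduct.lower() in ("", "none"):
        return MolecularFormula(dict(formula.counts), polarity or formula.charge)
    sign = adduct[0]
    if sign not in "+-":
        raise ValueError(f"adduct spec must start with '+' or '-': {adduct!r}")
    delta = parse_formula(adduct[1:]).counts
    counts = dict(formula.counts)
    for element, n in delta.items():
        if sign == "+":
            counts[element] = counts.get(element, 0) + n
        else:
            have = counts.get(element, 0)
            if have < n:
                raise ValueError(
                    f"adduct {adduct!r} removes {n} {element} but formula has {have}"
                )
            counts[element] = have - n
    return MolecularFormula(counts, polarity)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic mass in Da (m/z for charged species).

    Sum of lightest-stable-isotope masses, corrected by the electron mass per
    elementary charge (subtracted for cations, added for anions) and divided
    by |charge| when |charge| > 1.
    """
    mass = sum(ISOTOPES[e][0][0] * n for e, n in formula.counts.items())
    mass -= formula.charge * ELECTRON_MASS
    if abs(formula.charge) > 1:
        mass /= abs(formula.charge)
    return float(mass)


def _element_distribution(element: str, n: int, prune: float) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated isotope distribution of ``n`` atoms of one element.

    Returns (prob, prob_weighted_mass) arrays indexed by nucleon-count shift
    relative to the all-lightest species.  Computed by exponentiation by
    squaring of the single-atom distribution.
    """
    isotopes = ISOTOPES[element]
    base_nucleons = round(isotopes[0][0])
    shifts = np.array([round(m) - base_nucleons for m, _ in isotopes])
    size = int(shifts.max()) + 1
    p1 = np.zeros(size)
    a1 = np.zeros(size)  # probability-weighted mass
    for (mass, abundance), shift in zip(isotopes, shifts):
        p1[shift] += abundance
        a1[shift] += abundance * mass
    # normalize abundances defensively
    total = p1.sum()
    p1, a1 = p1 / total, a1 / total

    result_p, result_a = np.array([1.0]), np.array([0.0])
    base_p, base_a = p1, a1
    k = n
    while k:
        if k & 1:
            result_p, result_a = _convolve_pa(result_p, result_a, base_p, base_a, prune)
        k >>= 1
        if k:
            base_p, base_a = _convolve_pa(base_p, base_a, base_p, base_a, prune)
    return result_p, result_a


def _convolve_pa(p1, a1, p2, a2, prune):
    """Convolve two (prob, prob*mass) aggregate representations."""
    p = np.convolve(p1, p2)
    a = np.convolve(a1, p2) + np.convolve(p1, a2)
    # trim the negligible tail to keep arrays short for large formulas
    keep = np.nonzero(p > prune * p.max())[0]
    end = keep[-1] + 1 if keep.size else 1
    return p[:end], a[:end]


def isotopic_envelope(
    formula: MolecularFormula, threshold: float = 0.05, label: str | None = None
) -> TheoreticalSpectrum:
    """Aggregated (nucleon-count-resolved) isotopic envelope of a formula.

    Peaks below ``threshold`` times the most intense aggregate are removed and
    the remainder renormalized to sum 1.  Each aggregate's m/z is the
    probability-weighted mean mass of its isotopologues, electron-corrected
    for the formula's charge and divided by |charge| when |charge| > 1.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    prune = 1e-15
    p = np.array([1.0])
    a = np.array([0.0])
    for element, n in formula.counts.items():
        ep, ea = _element_distribution(element, n, prune)
        p, a = _convolve_pa(p, a, ep, ea, prune)
    # 'a' carries probability-weighted absolute masses, so the mean mass of
    # each aggregate is a/p.
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_mass = np.where(p > 0, a / np.where(p > 0, p, 1.0), 0.0)
    keep = p >= threshold * p.max()
    keep &= p > 0
    p, mean_mass = p[keep], mean_mass[keep]
    p = p / p.sum()
    mz = mean_mass - formula.charge * ELECTRON_MASS
    if abs(formula.charge) > 1:
        mz = mz / abs(formula.charge)
    return TheoreticalSpectrum(mz, p, label if label is not None else str(formula))


def read_ion_library(path) -> list[TheoreticalSpectrum]:
    """Read a candidate-ion library CSV with columns formula, adduct, label.

    The adduct column uses the ``"+K"`` / ``"-H"`` / ``"none"`` syntax of
    :func:`apply_adduct`; the sign of the adduct sets the polarity (+1 / -1).
    """
    import pandas as pd

    table = pd.read_csv(path, comment="#")
    required = {"formula", "adduct", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"ion library must have columns {sorted(required)}")
    library = []
    for _, row in table.iterrows():
        neutral = parse_formula(str(row["formula"]))
        adduct = str(row["adduct"])
        polarity = 0 if adduct.lower() in ("", "none") else (1 if adduct[0] == "+" else -1)
        ion = apply_adduct(neutral, adduct, polarity)
        library.append(isotopic_envelope(ion, label=str(row["label"])))
    return library
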