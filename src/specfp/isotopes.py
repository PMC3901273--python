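"""Isotope-pattern simulation and MS1 matching.

A chemical element E with r stable isotopes contributes, for a molecule
with l atoms of E, C(l + r - 1, r - 1) isotopologues; their relative
abundances follow the multinomial distribution over the isotope
abundances.  The full theoretical MS1 pattern of a molecular formula is
the convolution of its per-element patterns.  Matching a simulated
pattern against an observed MS1 spectrum reuses the probability product
kernel (cosine-normalised ``peaks`` variant), and the resulting
isotope-based candidate ranking can be fused with the fingerprint-based
one by average-rank, min-rank or tie-rerank aggregation.

The isotope masses and abundances are an embedded constants table
(CHNOPS plus Na, Cl, K); it can be overridden per call.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import PROTON_MASS
from .kernels import KernelParams, kernel_value
from .retrieval import CandidateRecord, RankedList
from .spectra import Peak, Spectrum

__all__ = [
    "ElementIsotopes",
    "IsotopePattern",
    "ISOTOPE_TABLE",
    "parse_formula",
    "monoisotopic_mass",
    "element_pattern",
    "molecule_pattern",
    "pattern_to_spectrum",
    "isotope_match_score",
    "rank_by_isotopes",
    "aggregate_ranks",
]


@dataclass(frozen=True)
class ElementIsotopes:
    """Stable isotopes of one element: (mass Da, abundance) ascending."""

    symbol: str
    isotopes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.isotopes]
        abund = [a for _, a in self.isotopes]
        if any(m2 <= m1 for m1, m2 in zip(masses, masses[1:])):
            raise ValueError(f"{self.symbol}: isotope masses must be strictly increasing")
        if abs(sum(abund) - 1.0) > 1e-9:
            raise ValueError(f"{self.symbol}: abundances must sum to 1")

    @property
    def r(self) -> int:
        return len(self.isotopes)


#: Embedded isotope table.  Carbon uses 98.890% / 1.110% (the convention
#: this package standardises on); the other entries are the matching
#: IUPAC values of that era.  Override via the ``isotope_table`` argument
#: of :func:`molecule_pattern` for other conventions.
ISOTOPE_TABLE: dict[str, ElementIsotopes] = {
    "H": ElementIsotopes("H", ((1.0078250319, 0.99985), (2.0141017780, 0.00015))),
    "C": ElementIsotopes("C", ((12.0, 0.98890), (13.0033548378, 0.01110))),
    "N": ElementIsotopes("N", ((14.0030740052, 0.99634), (15.0001088984, 0.00366))),
    "O": ElementIsotopes(
        "O", ((15.9949146221, 0.99762), (16.9991315000, 0.00038), (17.9991604000, 0.00200))
    ),
    "P": ElementIsotopes("P", ((30.97376151, 1.0),)),
    "S": ElementIsotopes(
        "S",
        (
            (31.97207069, 0.9502),
            (32.97145850, 0.0075),
            (33.96786683, 0.0421),
            (35.96708088, 0.0002),
        ),
    ),
    "Na": ElementIsotopes("Na", ((22.98976928, 1.0),)),
    "Cl": ElementIsotopes("Cl", ((34.96885271, 0.7577), (36.96590260, 0.2423))),
    "K": ElementIsotopes(
        "K", ((38.96370690, 0.932581), (39.96399870, 0.000117), (40.96182600, 0.067302))
    ),
}


@dataclass
class IsotopePattern:
    """Simulated isotopologue spectrum: (mass Da, relative abundance)."""

    masses: np.ndarray
    abundances: np.ndarray
    formula: str = ""

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        order = np.argsort(self.masses, kind="stable")
        self.masses = self.masses[order]
        self.abundances = self.abundances[order]

    def __len__(self) -> int:
        return self.masses.size

    @property
    def entries(self) -> list[tuple[float, float]]:
        return [(float(m), float(a)) for m, a in zip(self.masses, self.abundances)]


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula like ``C6H12O6`` into element counts."""
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + (int(m.group(2) or 1))
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(
    formula: str, isotope_table: Mapping[str, ElementIsotopes] = ISOTOPE_TABLE
) -> float:
    """Sum of lightest-isotope masses over the formula."""
    total = 0.0
    for el, count in parse_formula(formula).items():
        if el not in isotope_table:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        total += isotope_table[el].isotopes[0][0] * count
    return total


def element_pattern(element: ElementIsotopes, count: int) -> IsotopePattern:
    """Isotopologue pattern of ``count`` atoms of a single element.

    Enumerates all C(l + r - 1, r - 1) multisets of isotope choices; the
    abundance of occupancy vector (k_1 ... k_r) is the multinomial
    probability l!/(k_1! ... k_r!) * prod a_i^k_i.
    """
    if count < 0:
        raise ValueError("atom count must be non-negative")
    if count == 0:
        return IsotopePattern(np.array([0.0]), np.array([1.0]), formula="")
    masses, abund = [], []
    iso_masses = [m for m, _ in element.isotopes]
    iso_abund = [a for _, a in element.isotopes]
    r = element.r
    # occupancy vectors: weak compositions of `count` into r parts
    for cuts in itertools.combinations(range(count + r - 1), r - 1):
        ks = []
        prev = -1
        for c in cuts:
            ks.append(c - prev - 1)
            prev = c
        ks.append(count + r - 2 - prev)
        p = math.factorial(count)
        mass = 0.0
        for k, a, m in zip(ks, iso_abund, iso_masses):
            p = p // math.factorial(k)
            mass += k * m
        prob = p * math.prod(a**k for k, a in zip(ks, iso_abund))
        masses.append(mass)
        abund.append(prob)
    return IsotopePattern(np.array(masses), np.array(abund), formula=f"{element.symbol}{count}")


def _merge(masses: np.ndarray, abund: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge entries closer than tol (abundance-weighted mean mass)."""
    order = np.argsort(masses, kind="stable")
    masses, abund = masses[order], abund[order]
    # single sweep over sorted entries, chaining gaps <= tol
    out_m, out_a = [masses[0] * abund[0]], [abund[0]]
    last_mass = masses[0]
    for m, a in zip(masses[1:], abund[1:]):
        if m - last_mass <= tol:
            out_m[-1] += m * a
            out_a[-1] += a
        else:
            out_m.append(m * a)
            out_a.append(a)
        last_mass = m
    om = np.array(out_m) / np.array(out_a)
    return om, np.array(out_a)


def _convolve(
    p1: IsotopePattern, p2: IsotopePattern, merge_tol: float
) -> IsotopePattern:
    masses = (p1.masses[:, None] + p2.masses[None, :]).ravel()
    abund = (p1.abundances[:, None] * p2.abundances[None, :]).ravel()
    m, a = _merge(masses, abund, merge_tol)
    return IsotopePattern(m, a)


def molecule_pattern(
    formula: str,
    isotope_table: Mapping[str, ElementIsotopes] = ISOTOPE_TABLE,
    prune_below: float = 1e-5,
    merge_tol: float = 1e-4,
) -> IsotopePattern:
    """Theoretical isotope pattern of a molecular formula.

    Per-element multinomial patterns are convolved across the formula;
    isotopologues closer than ``merge_tol`` Da are merged (they are not
    resolvable at the modelled accuracy) and entries below
    ``prune_below`` relative abundance are dropped, after which the
    pattern is renormalised to sum to one.
    """
    if not 0 <= prune_below < 1:
        raise ValueError("prune_below must be in [0, 1)")
    counts = parse_formula(formula)
    unknown = sorted(set(counts) - set(isotope_table))
    if unknown:
        raise ValueError(f"unknown element symbol(s) {unknown} in formula {formula!r}")
    pattern = IsotopePattern(np.array([0.0]), np.array([1.0]))
    for el in sorted(counts):  # element order does not affect the result
        pattern = _convolve(pattern, element_pattern(isotope_table[el], counts[el]), merge_tol)
    keep = pattern.abundances >= prune_below if prune_below > 0 else slice(None)
    masses, abund = pattern.masses[keep], pattern.abundances[keep]
    total = abund.sum()
    if total <= 0:
        raise ValueError(f"pattern of {formula!r} pruned to nothing")
    return IsotopePattern(masses, abund / total, formula=formula)


def pattern_to_spectrum(
    pattern: IsotopePattern, mode: str = "positive", spectrum_id: str | None = None
) -> Spectrum:
    """Convert a neutral pattern to an MS1 spectrum of the adduct ion.

    Masses are shifted by +proton ([M+H]+, positive mode) or -proton
    ([M-H]-, negative mode); abundances become intensities.
    """
    if len(pattern) == 0:
        raise ValueError("empty isotope pattern")
    shift = PROTON_MASS if mode == "positive" else -PROTON_MASS
    peaks = [Peak(float(m + shift), float(a)) for m, a in pattern.entries]
    return Spectrum(
        peaks=peaks, ms_level="MS1", ionization_mode=mode, spectrum_id=spectrum_id
    )


def isotope_match_score(
    observed_ms1: Spectrum,
    pattern: IsotopePattern,
    mode: str = "positive",
    params: KernelParams | None = None,
) -> float:
    """Cosine-normalised probability product kernel between the observed
    MS1 spectrum and the simulated pattern (``peaks`` variant).

    Equals 1 when the observed envelope reproduces the pattern exactly.
    The mass sigma for MS1 matching can differ from the MS2 one; pass a
    dedicated ``params``.
    """
    if len(observed_ms1) == 0:
        raise ValueError("empty observed MS1 spectrum")
    params = params or KernelParams(variants=("peaks",))
    simulated = pattern_to_spectrum(pattern, mode=mode)
    k = kernel_value(observed_ms1, simulated, "peaks", params)
    k11 = kernel_value(observed_ms1, observed_ms1, "peaks", params)
    k22 = kernel_value(simulated, simulated, "peaks", params)
    return k / math.sqrt(k11 * k22)


def rank_by_isotopes(
    candidates: Sequence[CandidateRecord],
    observed_ms1: Spectrum,
    mode: str = "positive",
    params: KernelParams | None = None,
    query_id: str = "",
    isotope_table: Mapping[str, ElementIsotopes] = ISOTOPE_TABLE,
) -> RankedList:
    """Rank candidates by isotope-pattern match to an observed MS1.

    Candidates sharing a formula share a score (patterns are cached per
    formula); the score column holds log of the normalised kernel value.
    """
    cache: dict[str, float] = {}
    scored = []
    for rec in candidates:
        if rec.formula not in cache:
            pattern = molecule_pattern(rec.formula, isotope_table=isotope_table)
            cache[rec.formula] = isotope_match_score(observed_ms1, pattern, mode, params)
        s = cache[rec.formula]
        scored.append((rec, math.log(max(s, 1e-300))))
    scored.sort(key=lambda t: (-t[1], t[0].molecule_id))
    entries = [(rec, sc, rank) for rank, (rec, sc) in enumerate(scored, start=1)]
    return RankedList(entries=entries, query_id=query_id)


def aggregate_ranks(
    fp_list: RankedList, iso_list: RankedList, method: str = "average"
) -> RankedList:
    """Fuse fingerprint-based and isotope-based rankings.

    ``average`` / ``minrank`` re-sort by the mean / minimum of the two
    ranks; ``rerank`` sorts by the isotope score and breaks isotope-score
    ties by the fingerprint score.  Remaining ties break by ascending
    molecule id; ranks are re-assigned 1..n.  The score column of the
    output holds the (negated) aggregation key so it is non-increasing.
    """
    fp = {rec.molecule_id: (rank, score) for rec, score, rank in fp_list.entries}
    iso = {rec.molecule_id: (rank, score) for rec, score, rank in iso_list.entries}
    if set(fp) != set(iso):
        raise ValueError("fingerprint and isotope rankings cover different candidates")
    records = {rec.molecule_id: rec for rec, _, _ in fp_list.entries}
    if method == "average":
        keyed = [((fp[m][0] + iso[m][0]) / 2.0, m) for m in fp]
        keyed.sort(key=lambda t: (t[0], t[1]))
        entries = [(records[m], -k, r) for r, (k, m) in enumerate(keyed, start=1)]
    elif method == "minrank":
        keyed = [(float(min(fp[m][0], iso[m][0])), m) for m in fp]
        keyed.sort(key=lambda t: (t[0], t[1]))
        entries = [(records[m], -k, r) for r, (k, m) in enumerate(keyed, start=1)]
    elif method == "rerank":
        keyed2 = [((-iso[m][1], -fp[m][1]), m) for m in fp]
        keyed2.sort(key=lambda t: (t[0], t[1]))
        entries = [
            (records[m], -k[0], r) for r, (k, m) in enumerate(keyed2, start=1)
        ]
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return RankedList(entries=entries, query_id=fp_list.query_id)
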