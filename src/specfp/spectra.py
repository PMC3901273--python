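"""Mass-spectrum containers and I/O.

Spectra are sets of (mass, intensity) peaks with a little metadata: an
optional precursor mass, the MS level (MS1 survey scan or MS2 fragment
scan), the ionisation mode and an instrument tag.  Two text formats are
supported: MassBank-style records (used for training libraries) and plain
two-column peak lists (used for queries).

Conventions enforced on construction:

* peaks are sorted by ascending mass;
* peaks with identical mass are merged by summing their intensities;
* intensities are non-negative, masses non-negative (strictly positive for
  measured spectra; a mass-loss transform may legitimately produce 0.0).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .constants import PROTON_MASS

__all__ = [
    "Peak",
    "Spectrum",
    "MassEstimate",
    "SpectrumParseError",
    "parse_massbank_record",
    "parse_massbank_file",
    "write_massbank_record",
    "parse_peak_list",
    "normalize_intensities",
    "estimate_exact_mass",
]


class SpectrumParseError(ValueError):
    """Raised when a spectrum record cannot be parsed."""


class Peak(NamedTuple):
    """A single centroided peak: mass in Da, relative intensity."""

    mass: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided mass spectrum.

    Parameters
    ----------
    peaks:
        Sequence of (mass, intensity) pairs.  They are sorted and
        duplicate masses merged on construction.
    precursor_mass:
        m/z of the selected precursor ion, if known.
    ms_level:
        ``"MS1"`` or ``"MS2"``.
    ionization_mode:
        ``"positive"`` or ``"negative"``.
    instrument_tag:
        Free-form device/ionisation/fragmentation tag, e.g.
        ``"LC-ESI-ITFT-CID"``; selects which trained model applies.
    molecule_id:
        Identifier of the generating molecule, when known (training data).
    spectrum_id:
        Record identifier (MassBank accession or synthetic id).
    metadata:
        Unconsumed header fields, preserved for round-tripping.
    """

    peaks: Sequence[Peak]
    precursor_mass: float | None = None
    ms_level: str = "MS2"
    ionization_mode: str = "positive"
    instrument_tag: str = ""
    molecule_id: str | None = None
    spectrum_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ms_level not in ("MS1", "MS2"):
            raise ValueError(f"ms_level must be MS1 or MS2, got {self.ms_level!r}")
        if self.ionization_mode not in ("positive", "negative"):
            raise ValueError(
                f"ionization_mode must be positive or negative, got {self.ionization_mode!r}"
            )
        masses = np.asarray([p[0] for p in self.peaks], dtype=float)
        intens = np.asarray([p[1] for p in self.peaks], dtype=float)
        if masses.size:
            if np.any(masses < 0):
                raise ValueError("peak masses must be non-negative")
            if np.any(intens < 0):
                raise ValueError("peak intensities must be non-negative")
            order = np.argsort(masses, kind="stable")
            masses, intens = masses[order], intens[order]
            # merge exact-duplicate masses by summing intensity
            uniq, inverse = np.unique(masses, return_inverse=True)
            if uniq.size != masses.size:
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, intens)
                masses, intens = uniq, summed
        self._mz = masses
        self._intensity = intens
        self.peaks = [Peak(float(m), float(i)) for m, i in zip(masses, intens)]

    # -- array views -------------------------------------------------
    @property
    def mz(self) -> np.ndarray:
        """Peak masses, ascending, Da."""
        return self._mz

    @property
    def intensity(self) -> np.ndarray:
        """Peak intensities, aligned with :attr:`mz`."""
        return self._intensity

    def __len__(self) -> int:
        return len(self._mz)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self._mz, other._mz)
            and np.array_equal(self._intensity, other._intensity)
            and self.precursor_mass == other.precursor_mass
            and self.ms_level == other.ms_level
            and self.ionization_mode == other.ionization_mode
            and self.instrument_tag == other.instrument_tag
            and self.molecule_id == other.molecule_id
            and self.spectrum_id == other.spectrum_id
        )

    def replace(self, **kwargs) -> "Spectrum":
        """Return a copy with the given fields replaced."""
        fields = dict(
            peaks=self.peaks,
            precursor_mass=self.precursor_mass,
            ms_level=self.ms_level,
            ionization_mode=self.ionization_mode,
            instrument_tag=self.instrument_tag,
            molecule_id=self.molecule_id,
            spectrum_id=self.spectrum_id,
            metadata=dict(self.metadata),
        )
        fields.update(kwargs)
        return Spectrum(**fields)


@dataclass(frozen=True)
class MassEstimate:
    """Neutral exact mass inferred from an MS1 spectrum."""

    neutral_mass: float
    precursor_mass: float
    assumed_adduct: str


# ---------------------------------------------------------------------------
# MassBank records
# ---------------------------------------------------------------------------

_PEAK_LINE = re.compile(r"^\s+(\S+)\s+(\S+)(?:\s+(\S+))?\s*$")


def parse_massbank_record(text: str) -> Spectrum:
    """Parse one MassBank-style record into a :class:`Spectrum`.

    The dialect accepted is the subset used for training libraries:
    ``ACCESSION`` and a ``PK$PEAK:`` block are required; ``CH$NAME``,
    ``AC$INSTRUMENT_TYPE``, ``AC$MASS_SPECTROMETRY: MS_TYPE / ION_MODE``
    and ``MS$FOCUSED_ION: PRECURSOR_M/Z`` are interpreted when present.
    Unrecognised header fields are preserved in ``metadata`` rather than
    rejected.
    """
    accession = None
    molecule_id = None
    instrument_tag = ""
    ms_level = "MS2"
    mode = "positive"
    precursor = None
    metadata: dict[str, str] = {}
    peaks: list[Peak] = []
    saw_peak_block = False

    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        i += 1
        if not line.strip() or line.strip() == "//":
            continue
        if line.startswith("PK$PEAK:"):
            saw_peak_block = True
            while i < len(lines):
                pline = lines[i]
                if pline.strip() == "//" or not pline.strip():
                    break
                m = _PEAK_LINE.match(pline)
                if m is None:
                    raise SpectrumParseError(
                        f"malformed peak line {i + 1} in record "
                        f"{accession or '<no accession>'}: {pline!r}"
                    )
                try:
                    mass, inten = float(m.group(1)), float(m.group(2))
                except ValueError as exc:
                    raise SpectrumParseError(
                        f"non-numeric peak on line {i + 1} in record "
                        f"{accession or '<no accession>'}: {pline!r}"
                    ) from exc
                peaks.append(Peak(mass, inten))
                i += 1
            continue
        if ":" not in line:
            raise SpectrumParseError(f"malformed header line {i}: {line!r}")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "ACCESSION":
            accession = value
        elif key == "CH$NAME":
            molecule_id = value
        elif key == "AC$INSTRUMENT_TYPE":
            instrument_tag = value
        elif key == "AC$MASS_SPECTROMETRY":
            sub, _, sval = value.partition(" ")
            if sub == "MS_TYPE":
                ms_level = sval.strip()
            elif sub == "ION_MODE":
                mode = sval.strip().lower()
            else:
                metadata[f"{key}: {sub}"] = sval.strip()
        elif key == "MS$FOCUSED_ION":
            sub, _, sval = value.partition(" ")
            if sub == "PRECURSOR_M/Z":
                precursor = float(sval)
            else:
                metadata[f"{key}: {sub}"] = sval.strip()
        else:
            metadata[key] = value

    if accession is None:
        raise SpectrumParseError("record has no ACCESSION header")
    if not saw_peak_block:
        raise SpectrumParseError(f"record {accession} has no PK$PEAK block")
    if not peaks:
        raise SpectrumParseError(f"record {accession} has an empty PK$PEAK block")
    if ms_level not in ("MS1", "MS2"):
        ms_level = "MS2"
    return Spectrum(
        peaks=peaks,
        precursor_mass=precursor,
        ms_level=ms_level,
        ionization_mode=mode,
        instrument_tag=instrument_tag,
        molecule_id=molecule_id,
        spectrum_id=accession,
        metadata=metadata,
    )


def parse_massbank_file(text: str) -> list[Spectrum]:
    """Parse a concatenation of ``//``-terminated MassBank records."""
    records = [r for r in re.split(r"^//\s*$", text, flags=re.M) if r.strip()]
    return [parse_massbank_record(r) for r in records]


def write_massbank_record(s: Spectrum) -> str:
    """Serialise a spectrum as a MassBank-style record (round-trippable)."""
    if s.spectrum_id is None:
        raise ValueError("cannot serialise a spectrum without spectrum_id")
    out = io.StringIO()
    out.write(f"ACCESSION: {s.spectrum_id}\n")
    if s.molecule_id is not None:
        out.write(f"CH$NAME: {s.molecule_id}\n")
    if s.instrument_tag:
        out.write(f"AC$INSTRUMENT_TYPE: {s.instrument_tag}\n")
    out.write(f"AC$MASS_SPECTROMETRY: MS_TYPE {s.ms_level}\n")
    out.write(f"AC$MASS_SPECTROMETRY: ION_MODE {s.ionization_mode.upper()}\n")
    if s.precursor_mass is not None:
        out.write(f"MS$FOCUSED_ION: PRECURSOR_M/Z {float(s.precursor_mass)!r}\n")
    for key, value in s.metadata.items():
        out.write(f"{key}: {value}\n")
    out.write(f"PK$NUM_PEAK: {len(s)}\n")
    out.write("PK$PEAK: m/z int. rel.int.\n")
    for mass, inten in zip(s.mz, s.intensity):
        out.write(f"  {float(mass)!r} {float(inten)!r} {float(inten)!r}\n")
    out.write("//\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Plain peak lists
# ---------------------------------------------------------------------------

def parse_peak_list(
    text: str,
    precursor: float | None = None,
    mode: str = "positive",
    ms_level: str = "MS2",
    spectrum_id: str | None = None,
) -> Spectrum:
    """Parse a two-column (mass, intensity) peak list.

    Columns may be separated by whitespace or commas.  Lines that are
    empty or start with ``#`` are skipped.
    """
    peaks: list[Peak] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) < 2:
            raise SpectrumParseError(f"line {lineno}: expected two columns, got {raw!r}")
        try:
            mass, inten = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise SpectrumParseError(f"line {lineno}: non-numeric token in {raw!r}") from exc
        if mass <= 0:
            raise SpectrumParseError(f"line {lineno}: non-positive mass {mass}")
        peaks.append(Peak(mass, inten))
    if not peaks:
        raise SpectrumParseError("peak list contains no peaks")
    return Spectrum(
        peaks=peaks,
        precursor_mass=precursor,
        ms_level=ms_level,
        ionization_mode=mode,
        spectrum_id=spectrum_id,
    )


def normalize_intensities(s: Spectrum) -> Spectrum:
    """Scale intensities to sum to one (probability semantics).

    Idempotent; masses and peak count are unchanged.  Raises if the
    spectrum carries no intensity at all.
    """
    total = float(np.sum(s.intensity))
    if len(s) == 0 or total <= 0:
        raise ValueError("cannot normalize a spectrum with zero total intensity")
    if abs(total - 1.0) < 1e-15:
        return s
    return s.replace(peaks=[Peak(m, i / total) for m, i in zip(s.mz, s.intensity)])


def estimate_exact_mass(ms1: Spectrum, mode: str | None = None) -> MassEstimate:
    """Estimate the neutral exact mass from an MS1 spectrum.

    The most abundant MS1 peak is taken as the precursor ion (ties broken
    toward the lower mass, which favours the monoisotopic peak), and the
    neutral mass is obtained by removing the assumed protonation adduct:
    [M+H]+ in positive mode, [M-H]- in negative mode.  Other adducts
    (e.g. [M+Na]+) are out of scope here; callers that know the adduct
    should correct the mass themselves.
    """
    if len(ms1) == 0:
        raise ValueError("cannot estimate mass from an empty spectrum")
    mode = mode or ms1.ionization_mode
    if mode not in ("positive", "negative"):
        raise ValueError(f"unknown ionization mode {mode!r}")
    best = int(np.argmax(ms1.intensity))  # argmax returns the first (lowest-mass) tie
    precursor = float(ms1.mz[best])
    if mode == "positive":
        return MassEstimate(precursor - PROTON_MASS, precursor, "[M+H]+")
    return MassEstimate(precursor + PROTON_MASS, precursor, "[M-H]-")
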