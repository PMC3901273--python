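"""Self-contained toy worlds with known ground truth.

The generator plants a direct statistical link between fingerprint bits
and fragment peaks: every bit j is assigned a characteristic fragment
mass, and a molecule whose bit j is +1 produces a peak near that mass in
its spectra.  Peak positions get Gaussian mass jitter, intensities get
multiplicative noise, random noise peaks are added, and several spectra
per molecule emulate different collision energies by retaining random
subsets of the planted peaks.  This gives the SVM layer a recoverable
signal with tunable difficulty — it is a statistical stand-in for real
fragmentation chemistry, not a fragmenter.

Molecules carry real CHO formulas so the isotope engine can simulate
their MS1 envelopes; exact masses are monoisotopic masses of those
formulas.  Worlds can be exported in the same formats the production
parsers read (MassBank-style records plus a candidate table), so
fixtures exercise the real I/O paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import PROTON_MASS
from .fingerprints import FingerprintVector, schema_hash
from .isotopes import monoisotopic_mass
from .retrieval import CandidateRecord, RankedList, write_candidate_table
from .spectra import Peak, Spectrum, write_massbank_record

logger = logging.getLogger(__name__)

__all__ = [
    "ToyWorld",
    "generate_toy_world",
    "corrupt_fingerprints",
    "relative_rank",
    "export_toy_world",
]


@dataclass
class ToyWorld:
    """A synthetic identification problem with known ground truth."""

    molecules: list[CandidateRecord]
    spectra: list[Spectrum]
    planted_rule: dict[int, float]  # bit index -> characteristic fragment mass
    seed: int
    key_names: tuple[str, ...]

    @property
    def fingerprint_matrix(self) -> np.ndarray:
        return np.stack([m.fingerprint.bits for m in self.molecules])

    def fingerprint_of(self, molecule_id: str) -> FingerprintVector:
        for m in self.molecules:
            if m.molecule_id == molecule_id:
                return m.fingerprint
        raise KeyError(molecule_id)

    def spectra_of(self, molecule_id: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.molecule_id == molecule_id]


def _balanced_bits(rng: np.random.Generator, n: int, m: int, unique: bool) -> np.ndarray:
    """Random +/-1 matrix with per-column +1 fraction in [0.2, 0.8].

    With ``unique=True`` duplicate rows are redrawn until all rows are
    distinct (fingerprint uniqueness is a controlled property of the
    world, not an accident).
    """
    bits = np.where(rng.random((n, m)) < 0.5, 1, -1).astype(np.int8)
    for _ in range(200):
        frac = np.mean(bits == 1, axis=0)
        bad_cols = np.where((frac < 0.2) | (frac > 0.8))[0]
        for j in bad_cols:
            bits[:, j] = np.where(rng.random(n) < 0.5, 1, -1)
        dup_rows: list[int] = []
        if unique:
            seen: dict[bytes, int] = {}
            for i, row in enumerate(bits):
                key = row.tobytes()
                if key in seen:
                    dup_rows.append(i)
                else:
                    seen[key] = i
            for i in dup_rows:
                bits[i] = np.where(rng.random(m) < 0.5, 1, -1)
        if not len(bad_cols) and not dup_rows:
            return bits
    raise RuntimeError("could not draw a balanced fingerprint matrix")


def generate_toy_world(
    n_molecules: int = 100,
    m_bits: int = 20,
    peaks_per_molecule: int = 3,
    mass_jitter_sd: float = 0.002,
    seed: int = 0,
    n_energies: int = 3,
    keep_prob: float = 0.8,
    intensity_jitter_sd: float = 0.2,
    unique_fingerprints: bool = False,
) -> ToyWorld:
    """Generate a toy identification world.

    Parameters
    ----------
    n_molecules, m_bits:
        World size; every bit's +1 fraction lies in [0.2, 0.8] by
        construction so all bits survive the effective-bit mask.
    peaks_per_molecule:
        Number of additional uninformative noise peaks per spectrum.
    mass_jitter_sd:
        Gaussian sd (Da) applied to planted fragment masses; 0 plants
        peaks at the exact characteristic masses.
    n_energies:
        Spectra per molecule, emulating different collision energies;
        each spectrum keeps every planted peak with ``keep_prob``.
    unique_fingerprints:
        Force all molecules to have distinct fingerprints.
    """
    if n_molecules < 2 or m_bits < 2:
        raise ValueError("need n_molecules >= 2 and m_bits >= 2")
    if n_energies < 1:
        raise ValueError("n_energies must be >= 1")
    rng = np.random.default_rng(seed)
    key_names = tuple(f"bit:{j}" for j in range(m_bits))

    # characteristic fragment masses: spread over 60..~250 Da, jittered;
    # kept below every precursor so the mass-loss transform sees them all
    spacing = 190.0 / m_bits
    char_masses = 60.0 + spacing * np.arange(m_bits) + rng.uniform(0, spacing * 0.5, m_bits)
    planted_rule = {j: float(char_masses[j]) for j in range(m_bits)}

    bits = _balanced_bits(rng, n_molecules, m_bits, unique_fingerprints)

    molecules: list[CandidateRecord] = []
    spectra: list[Spectrum] = []
    width = len(str(n_molecules))
    for i in range(n_molecules):
        c = int(rng.integers(18, 31))
        h = int(rng.integers(c, 2 * c + 2))
        o = int(rng.integers(2, 9))
        formula = f"C{c}H{h}O{o}"
        mass = monoisotopic_mass(formula)
        mid = f"M{i:0{width}d}"
        molecules.append(
            CandidateRecord(
                molecule_id=mid,
                exact_mass=mass,
                formula=formula,
                fingerprint=FingerprintVector(bits[i], key_names=key_names, source="toy"),
            )
        )
        base_intensity = rng.uniform(0.3, 1.0, m_bits)
        on_bits = np.where(bits[i] == 1)[0]
        precursor = mass + PROTON_MASS
        for e in range(n_energies):
            keep = on_bits[rng.random(on_bits.size) < keep_prob]
            if keep.size == 0 and on_bits.size:
                keep = on_bits[:1]
            peaks = [
                Peak(
                    float(char_masses[j] + rng.normal(0, mass_jitter_sd))
                    if mass_jitter_sd > 0
                    else float(char_masses[j]),
                    float(base_intensity[j] * np.exp(rng.normal(0, intensity_jitter_sd))),
                )
                for j in keep
            ]
            for _ in range(peaks_per_molecule):
                peaks.append(
                    Peak(float(rng.uniform(55.0, 260.0)), float(rng.uniform(0.01, 0.15)))
                )
            spectra.append(
                Spectrum(
                    peaks=peaks,
                    precursor_mass=precursor,
                    ms_level="MS2",
                    ionization_mode="positive",
                    instrument_tag=f"TOY-ENERGY{e}",
                    molecule_id=mid,
                    spectrum_id=f"{mid}_E{e}",
                )
            )
    return ToyWorld(
        molecules=molecules,
        spectra=spectra,
        planted_rule=planted_rule,
        seed=seed,
        key_names=key_names,
    )


def corrupt_fingerprints(
    y: FingerprintVector | np.ndarray, w: np.ndarray | float, seed: int
) -> FingerprintVector | np.ndarray:
    """Simulate a predictor of known reliability.

    Bit j of the true fingerprint is flipped independently with
    probability 1 - w_j; w may be a scalar.  Returns the same type as
    the input.
    """
    is_fp = isinstance(y, FingerprintVector)
    bits = y.bits.copy() if is_fp else np.asarray(y).copy()
    w_arr = np.broadcast_to(np.asarray(w, dtype=float), bits.shape)
    rng = np.random.default_rng(seed)
    flip = rng.random(bits.shape) < (1.0 - w_arr)
    bits = np.where(flip, -bits, bits).astype(np.int8)
    if is_fp:
        return FingerprintVector(bits, key_names=y.key_names, source="corrupted")
    return bits


def relative_rank(result: RankedList, true_id: str) -> float:
    """Rank of the true molecule divided by the list length (lower = better).

    If the true molecule is absent from the list (pruned by the mass
    window, or missing from the database) the worst value 1.0 is
    returned and a warning logged.
    """
    if len(result) == 0:
        raise ValueError("empty ranked list")
    rank = result.rank_of(true_id)
    if rank is None:
        logger.warning("true molecule %s absent from ranked list %s",
                       true_id, result.query_id)
        return 1.0
    return rank / len(result)


def export_toy_world(world: ToyWorld, out_dir) -> dict[str, Path]:
    """Write the world as MassBank-style records plus a candidate table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra_path = out / "spectra.massbank.txt"
    with open(spectra_path, "w") as fh:
        for s in world.spectra:
            fh.write(write_massbank_record(s))
    table_path = out / "candidates.tsv"
    write_candidate_table(world.molecules, table_path, schema=schema_hash(world.key_names))
    return {"spectra": spectra_path, "candidates": table_path}
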