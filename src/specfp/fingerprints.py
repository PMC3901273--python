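"""Binary substructure fingerprints for molecules.

Molecules are described by a fixed 528-bit vector concatenating three
OpenBabel substructure-key families in a frozen order: FP3 (55 bits),
FP4 (307 bits) and MACCS (166 bits).  Bits are coded +1 (key present)
or -1 (absent) so they can serve directly as SVM labels.

Fingerprints are computed by invoking the ``obabel`` command-line tool,
the standard generator for these families; its hexadecimal fingerprint
output is decoded into bit vectors here.  A schema hash over the key
names guards against trained models and candidate databases silently
disagreeing on bit order.
"""

from __future__ import annotations

import hashlib
import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: (family name, number of keys) in frozen concatenation order.
FP_FAMILIES: tuple[tuple[str, int], ...] = (("FP3", 55), ("FP4", 307), ("MACCS", 166))

#: Frozen names of the 528 bits, e.g. "FP4:12", "MACCS:162".
KEY_NAMES: tuple[str, ...] = tuple(
    f"{family}:{i}" for family, n in FP_FAMILIES for i in range(n)
)

N_BITS = len(KEY_NAMES)

__all__ = [
    "FP_FAMILIES",
    "KEY_NAMES",
    "N_BITS",
    "FingerprintVector",
    "EffectiveBitMask",
    "FingerprintError",
    "compute_fingerprints",
    "compute_fingerprints_batch",
    "effective_bit_mask",
    "apply_mask",
    "fingerprint_similarity",
    "schema_hash",
]


class FingerprintError(ValueError):
    """Raised when a structure yields no fingerprint; carries molecule ids."""

    def __init__(self, molecule_ids: Sequence[str]):
        self.molecule_ids = list(molecule_ids)
        super().__init__(
            f"no fingerprint could be generated for molecule(s): {self.molecule_ids}"
        )


@dataclass
class FingerprintVector:
    """A +/-1 bit vector over named substructure keys."""

    bits: np.ndarray
    key_names: tuple[str, ...] = KEY_NAMES
    source: str = "FP3+FP4+MACCS"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.ndim != 1 or self.bits.size != len(self.key_names):
            raise ValueError(
                f"bit vector length {self.bits.size} does not match "
                f"{len(self.key_names)} key names"
            )
        if not np.all(np.isin(self.bits, (-1, 1))):
            raise ValueError("fingerprint bits must be +1 or -1")

    def positive_keys(self) -> set[str]:
        return {k for k, b in zip(self.key_names, self.bits) if b == 1}


@dataclass
class EffectiveBitMask:
    """Which fingerprint bits carry information in a training set.

    A bit that takes the same value on every training molecule cannot be
    learned and is excluded from training and scoring; its constant
    training value is retained so predictions can still report it.
    """

    keep: np.ndarray
    constants: np.ndarray  # +/-1 for dropped bits, 0 for kept bits

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.constants = np.asarray(self.constants, dtype=np.int8)

    @property
    def m_effective(self) -> int:
        return int(np.sum(self.keep))


# ---------------------------------------------------------------------------
# OpenBabel fingerprint generation
# ---------------------------------------------------------------------------

def _decode_hex_words(words: list[str], n_bits: int) -> np.ndarray:
    """Decode obabel's fpt hex dump (most-significant word first).

    Bit j of the fingerprint lives in 32-bit word j // 32 at position
    j % 32 (least significant bit first); obabel prints the words in
    reverse order.
    """
    bits = np.full(n_bits, -1, dtype=np.int8)
    for w_idx, word in enumerate(reversed(words)):
        val = int(word, 16)
        if val == 0:
            continue
        for b in range(32):
            if val >> b & 1:
                j = w_idx * 32 + b
                if j < n_bits:
                    bits[j] = 1
    return bits


def _run_obabel_fpt(infile: str, in_format: str, family: str) -> dict[str, list[str]]:
    """Run obabel fingerprint output for one family; map title -> hex words."""
    # -e: continue past unparseable molecules instead of aborting the batch
    cmd = ["obabel", f"-i{in_format}", infile, "-ofpt", "-xf", family, "-xh", "-e"]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0 and not proc.stdout.strip():
        raise RuntimeError(f"obabel failed: {proc.stderr.strip()}")
    out: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            title = line[1:].split()[0] if line[1:].split() else ""
            current = out.setdefault(title, [])
        elif current is not None:
            tokens = [t for t in line.split() if t]
            if all(_is_hex(t) for t in tokens) and tokens:
                current.extend(tokens)
    return out


def _is_hex(token: str) -> bool:
    try:
        int(token, 16)
        return True
    except ValueError:
        return False


def compute_fingerprints_batch(
    molecules: Sequence[tuple[str, str]],
) -> tuple[dict[str, FingerprintVector], list[str]]:
    """Compute 528-bit fingerprints for (molecule_id, SMILES) pairs.

    Returns ``(fingerprints_by_id, failed_ids)``.  Molecules OpenBabel
    cannot parse are reported in ``failed_ids`` rather than raising, so
    database loading can skip and log them.
    """
    if not molecules:
        return {}, []
    ids = [mid for mid, _ in molecules]
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique")
    with tempfile.TemporaryDirectory() as tmp:
        smi = Path(tmp) / "molecules.smi"
        smi.write_text("".join(f"{s}\t{mid}\n" for mid, s in molecules))
        per_family: dict[str, dict[str, list[str]]] = {}
        for family, _ in FP_FAMILIES:
            per_family[family] = _run_obabel_fpt(str(smi), "smi", family)
    result: dict[str, FingerprintVector] = {}
    failed: list[str] = []
    for mid in ids:
        blocks = []
        ok = True
        for family, n_keys in FP_FAMILIES:
            words = per_family[family].get(mid)
            if not words:
                ok = False
                break
            blocks.append(_decode_hex_words(words, n_keys))
        if ok:
            result[mid] = FingerprintVector(np.concatenate(blocks))
        else:
            failed.append(mid)
    if failed:
        logger.warning("no fingerprint generated for %d molecule(s): %s",
                       len(failed), failed[:10])
    return result, failed


def compute_fingerprints_file(
    path: str, in_format: str = "sdf"
) -> tuple[dict[str, FingerprintVector], list[str]]:
    """Compute fingerprints for every molecule in a structure file.

    Molecules are keyed by their title (SDF title line / SMILES name
    column).  Returns ``(fingerprints_by_id, failed_ids)`` where failed
    ids are titles present in the file but yielding no fingerprint.
    """
    titles = _molecule_titles(path, in_format)
    per_family = {
        family: _run_obabel_fpt(str(path), in_format, family) for family, _ in FP_FAMILIES
    }
    result: dict[str, FingerprintVector] = {}
    failed: list[str] = []
    for mid in titles:
        blocks = []
        for family, n_keys in FP_FAMILIES:
            words = per_family[family].get(mid)
            if not words:
                blocks = []
                break
            blocks.append(_decode_hex_words(words, n_keys))
        if blocks:
            result[mid] = FingerprintVector(np.concatenate(blocks))
        else:
            failed.append(mid)
    if failed:
        logger.warning("no fingerprint generated for %d molecule(s): %s",
                       len(failed), failed[:10])
    return result, failed


def _molecule_titles(path: str, in_format: str) -> list[str]:
    proc = subprocess.run(
        ["obabel", f"-i{in_format}", str(path), "-otxt", "-e"],
        capture_output=True, text=True,
    )
    return [line.strip() for line in proc.stdout.splitlines() if line.strip()]


def compute_fingerprints(structure: str, molecule_id: str = "query") -> FingerprintVector:
    """Compute the 528-bit fingerprint of a single SMILES structure."""
    fps, failed = compute_fingerprints_batch([(molecule_id, structure)])
    if failed:
        raise FingerprintError(failed)
    return fps[molecule_id]


# ---------------------------------------------------------------------------
# Effective bits and similarity
# ---------------------------------------------------------------------------

def _as_matrix(fps: Sequence[FingerprintVector] | np.ndarray) -> np.ndarray:
    if isinstance(fps, np.ndarray):
        mat = fps
    else:
        lengths = {fp.bits.size for fp in fps}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
        mat = np.stack([fp.bits for fp in fps])
    if mat.ndim != 2:
        raise ValueError("expected a 2-D fingerprint matrix")
    return mat


def effective_bit_mask(training_fps: Sequence[FingerprintVector] | np.ndarray) -> EffectiveBitMask:
    """Mask of bits that take both values across the training molecules."""
    mat = _as_matrix(training_fps)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 training fingerprints to assess bits")
    keep = np.array([np.unique(col).size > 1 for col in mat.T])
    constants = np.where(keep, 0, mat[0]).astype(np.int8)
    return EffectiveBitMask(keep=keep, constants=constants)


def apply_mask(mask: EffectiveBitMask, fps: Sequence[FingerprintVector] | np.ndarray) -> np.ndarray:
    """Project fingerprints onto the effective bits (columns kept by the mask)."""
    mat = _as_matrix(fps)
    if mat.shape[1] != mask.keep.size:
        raise ValueError("fingerprint length does not match the mask")
    return mat[:, mask.keep]


def fingerprint_similarity(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto coefficient on the sets of present (+1) keys.

    Two molecules with no present keys at all have identical (empty)
    key sets; the similarity is defined as 1 in that degenerate case.
    """
    if a.bits.size != b.bits.size:
        raise ValueError("fingerprint lengths differ")
    pa, pb = a.bits == 1, b.bits == 1
    union = int(np.sum(pa | pb))
    if union == 0:
        logger.info("similarity of two all-absent fingerprints defined as 1.0")
        return 1.0
    return float(np.sum(pa & pb)) / union


def schema_hash(key_names: Sequence[str] = KEY_NAMES) -> str:
    """Stable hash of the fingerprint bit order (model/database guard)."""
    h = hashlib.sha256("\n".join(key_names).encode())
    return h.hexdigest()[:16]
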