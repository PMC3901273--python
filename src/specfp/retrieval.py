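"""Candidate retrieval and Poisson-binomial ranking.

Given a predicted fingerprint y_hat, per-bit reliability scores w (the
cross-validated accuracies of the bit predictors) and a molecular
database, candidates inside a ppm mass window around the estimated
neutral mass are ranked by the log-likelihood that their true
fingerprint y generated the observed prediction:

    log P(y_hat | y) = sum_j [ log w_j        if y_j == y_hat_j
                               log (1 - w_j)  otherwise ]

i.e. each bit is an independent Bernoulli observation that is correct
with probability w_j — the Poisson-binomial model.  Reliabilities are
clipped into [eps, 1 - eps] so no single bit can force an infinite
score; scores are kept in log space because products over hundreds of
bits underflow.  Masked (uninformative) bits carry no signal and are
excluded from scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import EPS_RELIABILITY
from .fingerprints import EffectiveBitMask, FingerprintVector

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateRecord",
    "RankedList",
    "mass_window_filter",
    "poisson_binomial_log_score",
    "rank_candidates",
    "fingerprint_uniqueness_stats",
    "load_candidate_table",
    "read_table_schema",
    "write_candidate_table",
    "write_ranked_list",
]


@dataclass
class CandidateRecord:
    """One database molecule: id, neutral exact mass (Da), formula, bits."""

    molecule_id: str
    exact_mass: float
    formula: str
    fingerprint: FingerprintVector

    def __post_init__(self) -> None:
        if self.exact_mass <= 0:
            raise ValueError(f"candidate {self.molecule_id}: exact_mass must be positive")


@dataclass
class RankedList:
    """Candidates sorted by descending log-score with 1-based ranks."""

    entries: list[tuple[CandidateRecord, float, int]]
    query_id: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def rank_of(self, molecule_id: str) -> int | None:
        for rec, _, rank in self.entries:
            if rec.molecule_id == molecule_id:
                return rank
        return None

    def ids(self) -> list[str]:
        return [rec.molecule_id for rec, _, _ in self.entries]


def mass_window_filter(
    db: Sequence[CandidateRecord], mass: float, ppm: float
) -> list[CandidateRecord]:
    """Keep candidates with |exact_mass - mass| <= mass * ppm * 1e-6."""
    if mass <= 0:
        raise ValueError("query mass must be positive")
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    delta = mass * ppm * 1e-6
    return [rec for rec in db if abs(rec.exact_mass - mass) <= delta]


def _clip_w(w: np.ndarray, eps: float = EPS_RELIABILITY) -> np.ndarray:
    return np.clip(np.asarray(w, dtype=float), eps, 1.0 - eps)


def poisson_binomial_log_score(
    y: FingerprintVector | np.ndarray,
    y_hat: FingerprintVector | np.ndarray,
    w: np.ndarray,
    eps: float = EPS_RELIABILITY,
) -> float:
    """Log-likelihood of candidate fingerprint y generating prediction y_hat."""
    yb = y.bits if isinstance(y, FingerprintVector) else np.asarray(y)
    hb = y_hat.bits if isinstance(y_hat, FingerprintVector) else np.asarray(y_hat)
    if yb.size != hb.size:
        raise ValueError(f"fingerprint length mismatch: {yb.size} vs {hb.size}")
    wc = _clip_w(w, eps)
    if wc.size != yb.size:
        raise ValueError(f"reliability length {wc.size} does not match bits {yb.size}")
    agree = yb == hb
    return float(np.sum(np.where(agree, np.log(wc), np.log1p(-wc))))


def rank_candidates(
    candidates: Sequence[CandidateRecord],
    y_hat: FingerprintVector | np.ndarray,
    w: np.ndarray,
    query_id: str = "",
    mask: EffectiveBitMask | None = None,
) -> RankedList:
    """Rank candidates by Poisson-binomial log-score, descending.

    With a ``mask``, scoring is restricted to the effective bits (y_hat
    and w are then expected over effective bits already if their length
    matches m_effective, else they are masked too).  Score ties are
    expected — molecules sharing a fingerprint get equal scores — and
    are broken deterministically by ascending molecule id.
    """
    hb = y_hat.bits if isinstance(y_hat, FingerprintVector) else np.asarray(y_hat)
    w = np.asarray(w, dtype=float)
    scored: list[tuple[CandidateRecord, float]] = []
    for rec in candidates:
        yb = rec.fingerprint.bits
        if mask is not None:
            yb = yb[mask.keep]
            h = hb[mask.keep] if hb.size == mask.keep.size else hb
            ww = w[mask.keep] if w.size == mask.keep.size else w
        else:
            h, ww = hb, w
        scored.append((rec, poisson_binomial_log_score(yb, h, ww)))
    scored.sort(key=lambda t: (-t[1], t[0].molecule_id))
    entries = [(rec, score, rank) for rank, (rec, score) in enumerate(scored, start=1)]
    return RankedList(entries=entries, query_id=query_id)


def fingerprint_uniqueness_stats(db: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Duplicate statistics of fingerprint vectors in a database.

    Groups molecules by identical fingerprint; N_dp is the number of
    molecules sharing a vector.  The returned frame has one row per
    molecule with its N_dp, plus attrs:

    * ``unique_fraction`` — fraction of molecules whose fingerprint is
      unique in the database;
    * ``unique_mass_fraction`` — fraction unique by (fingerprint,
      exact mass) jointly.
    """
    if not db:
        raise ValueError("empty candidate database")
    keys = ["".join("1" if b == 1 else "0" for b in rec.fingerprint.bits) for rec in db]
    df = pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in db],
            "fingerprint_key": keys,
            "exact_mass": [r.exact_mass for r in db],
        }
    )
    df["N_dp"] = df.groupby("fingerprint_key")["molecule_id"].transform("size")
    pair_counts = df.groupby(["fingerprint_key", "exact_mass"])["molecule_id"].transform("size")
    df["N_dp_mass"] = pair_counts
    df.attrs["unique_fraction"] = float(np.mean(df["N_dp"] == 1))
    df.attrs["unique_mass_fraction"] = float(np.mean(df["N_dp_mass"] == 1))
    return df[["molecule_id", "exact_mass", "N_dp", "N_dp_mass"]]


# ---------------------------------------------------------------------------
# Candidate database I/O
# ---------------------------------------------------------------------------

def _bits_to_string(bits: np.ndarray) -> str:
    return "".join("1" if b == 1 else "0" for b in bits)


def _string_to_bits(s: str) -> np.ndarray:
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    return np.where(arr == ord("1"), 1, -1).astype(np.int8)


def load_candidate_table(path, key_names: Sequence[str] | None = None) -> list[CandidateRecord]:
    """Read a tab-separated (id, exact_mass, formula, bit-string) table.

    The bit string codes +1 as ``1`` and -1 as ``0``; lines starting
    with ``#`` are comments (``#schema`` carries the fingerprint schema
    hash, readable via :func:`read_table_schema`).
    """
    records: list[CandidateRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            mid, mass_s, formula, bit_s = parts
            bits = _string_to_bits(bit_s)
            names = tuple(key_names) if key_names else tuple(
                f"bit:{j}" for j in range(bits.size)
            )
            records.append(
                CandidateRecord(
                    molecule_id=mid,
                    exact_mass=float(mass_s),
                    formula=formula,
                    fingerprint=FingerprintVector(bits, key_names=names, source="table"),
                )
            )
    if not records:
        raise ValueError(f"candidate table {path} is empty")
    lengths = {r.fingerprint.bits.size for r in records}
    if len(lengths) > 1:
        raise ValueError(f"candidate table {path} mixes fingerprint lengths {sorted(lengths)}")
    return records


def read_table_schema(path) -> str | None:
    """Return the ``#schema`` hash of a candidate table, if recorded."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#schema\t"):
                return line.split("\t", 1)[1].strip()
            if not line.startswith("#"):
                break
    return None


def write_candidate_table(
    records: Sequence[CandidateRecord], path, schema: str | None = None
) -> None:
    with open(path, "w") as fh:
        if schema is not None:
            fh.write(f"#schema\t{schema}\n")
        fh.write("#molecule_id\texact_mass\tformula\tfingerprint\n")
        for rec in records:
            fh.write(
                f"{rec.molecule_id}\t{rec.exact_mass!r}\t{rec.formula}\t"
                f"{_bits_to_string(rec.fingerprint.bits)}\n"
            )


def write_ranked_list(result: RankedList, path) -> None:
    """Write a result table: rank, molecule_id, formula, exact_mass, log_score."""
    with open(path, "w") as fh:
        fh.write("#rank\tmolecule_id\tformula\texact_mass\tlog_score\n")
        for rec, score, rank in result.entries:
            fh.write(f"{rank}\t{rec.molecule_id}\t{rec.formula}\t"
                     f"{rec.exact_mass!r}\t{score!r}\n")
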