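"""Probability product kernels between mass spectra.

A spectrum is modelled as a uniform mixture of 2-D Gaussians, one per
peak, centred at the measured (mass, intensity) coordinates with a
diagonal covariance diag(sigma_mass^2, sigma_intensity^2) shared by all
peaks — the Gaussian widths express measurement uncertainty.  The kernel
between two spectra is the integral of the product of their mixture
densities, which reduces to a closed-form all-against-all sum of Gaussian
product integrals: no numerical integration is needed.

Three variants differ only in which pseudo-spectrum the mixture is built
over:

``peaks``
    the fragment peaks themselves;
``mloss``
    mass losses, precursor_mass - fragment_mass, capturing the neutral
    part cleaved off (requires a precursor mass);
``diff``
    all pairwise mass differences within the spectrum, a generalisation
    of ``mloss`` that does not single out the precursor (quadratically
    more pseudo-peaks).

Variant values are cosine-normalised (unit self-similarity) and summed
with unit weights; ``peaks + mloss`` is the default combination.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import (
    DEFAULT_SIGMA_INTENSITY,
    DEFAULT_SIGMA_MASS_HIGHRES,
    MIN_SIGMA_INTENSITY,
    MIN_SIGMA_MASS,
)
from .spectra import Peak, Spectrum, normalize_intensities

logger = logging.getLogger(__name__)

VARIANTS = ("peaks", "mloss", "diff")

__all__ = [
    "KernelParams",
    "GramMatrix",
    "ProbabilityProductKernel",
    "peak_pair_integral",
    "to_loss_spectrum",
    "to_diff_spectrum",
    "kernel_value",
    "normalize_and_combine",
    "combined_kernel_value",
    "gram_matrix",
    "estimate_peak_variances",
]


@dataclass(frozen=True)
class KernelParams:
    """Kernel hyperparameters.

    sigma_mass is in Da (0.01 suits high-resolution instruments, 0.5
    nominal-mass ones); sigma_intensity is in relative units after
    sum-to-one intensity normalisation.
    """

    sigma_mass: float = DEFAULT_SIGMA_MASS_HIGHRES
    sigma_intensity: float = DEFAULT_SIGMA_INTENSITY
    variants: tuple[str, ...] = ("peaks", "mloss")
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.sigma_mass <= 0 or self.sigma_intensity <= 0:
            raise ValueError("sigma_mass and sigma_intensity must be positive")
        if not self.variants:
            raise ValueError("variant set must be non-empty")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown kernel variants: {sorted(unknown)}")


def peak_pair_integral(p1: Peak | tuple, p2: Peak | tuple, params: KernelParams) -> float:
    """Closed-form integral of the product of two 2-D peak Gaussians.

    For N(x; p1, S) and N(x; p2, S) with shared S = diag(sm^2, si^2),
    the product integrates to N(p1 - p2; 0, 2S):

        1/(4 pi sm si) * exp(-dm^2/(4 sm^2) - di^2/(4 si^2))
    """
    sm, si = params.sigma_mass, params.sigma_intensity
    dm = p1[0] - p2[0]
    di = p1[1] - p2[1]
    return math.exp(-(dm * dm) / (4 * sm * sm) - (di * di) / (4 * si * si)) / (
        4 * math.pi * sm * si
    )


def to_loss_spectrum(s: Spectrum) -> Spectrum:
    """Map each fragment peak to its neutral loss from the precursor.

    Peak (m, i) becomes (precursor - m, i).  Fragments heavier than the
    precursor give negative losses; these typically indicate adduct or
    isotope peaks above the assumed precursor and are dropped with a
    warning.
    """
    if s.precursor_mass is None:
        raise ValueError(
            f"mass-loss transform needs a precursor mass (spectrum {s.spectrum_id!r})"
        )
    losses = s.precursor_mass - s.mz
    keep = losses >= 0
    if not np.all(keep):
        logger.warning(
            "spectrum %s: dropping %d peak(s) above the precursor mass",
            s.spectrum_id,
            int(np.sum(~keep)),
        )
    peaks = [Peak(float(m), float(i)) for m, i in zip(losses[keep], s.intensity[keep])]
    if not peaks:
        raise ValueError(f"spectrum {s.spectrum_id!r}: no peaks at or below the precursor")
    return s.replace(peaks=peaks)


def to_diff_spectrum(s: Spectrum) -> Spectrum:
    """Spectrum of all pairwise mass differences.

    For each unordered peak pair i < j (masses ascending) a pseudo-peak
    is placed at mass m_j - m_i with intensity i_i * i_j.  The product
    intensity keeps the transform symmetric in the contributing peaks
    and damps pairs involving noise peaks.
    """
    n = len(s)
    if n < 2:
        raise ValueError(
            f"diff variant needs at least 2 peaks (spectrum {s.spectrum_id!r} has {n})"
        )
    iu, ju = np.triu_indices(n, k=1)
    masses = s.mz[ju] - s.mz[iu]
    intens = s.intensity[iu] * s.intensity[ju]
    return s.replace(peaks=[Peak(float(m), float(i)) for m, i in zip(masses, intens)])


def _representation(s: Spectrum, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """(mass, intensity) arrays of the variant pseudo-spectrum.

    Intensities are normalised to sum to one first, so the mixture has
    probability semantics regardless of the caller's intensity scale.
    """
    if len(s) == 0:
        raise ValueError(f"cannot evaluate kernel on empty spectrum {s.spectrum_id!r}")
    s = normalize_intensities(s)
    if variant == "peaks":
        t = s
    elif variant == "mloss":
        t = to_loss_spectrum(s)
    elif variant == "diff":
        t = to_diff_spectrum(s)
    else:
        raise ValueError(f"unknown kernel variant {variant!r}")
    return t.mz, t.intensity


def _raw_kernel(rep1, rep2, params: KernelParams) -> float:
    m1, i1 = rep1
    m2, i2 = rep2
    sm, si = params.sigma_mass, params.sigma_intensity
    dm = (m1[:, None] - m2[None, :]) / (2 * sm)
    di = (i1[:, None] - i2[None, :]) / (2 * si)
    total = float(np.exp(-(dm * dm) - (di * di)).sum())
    return total / (4 * math.pi * sm * si * m1.size * m2.size)


def kernel_value(s1: Spectrum, s2: Spectrum, variant: str, params: KernelParams) -> float:
    """Unnormalised probability product kernel for one variant.

    The mixture weights are uniform (1/l per peak), hence the
    1/(l * l') prefactor on the all-against-all sum of peak-pair
    integrals.
    """
    return _raw_kernel(_representation(s1, variant), _representation(s2, variant), params)


def normalize_and_combine(
    values: dict[str, float],
    self1: dict[str, float],
    self2: dict[str, float],
    params: KernelParams,
) -> float:
    """Cosine-normalise each variant value and sum over the variant set."""
    total = 0.0
    for variant in params.variants:
        v = values[variant]
        if params.normalize:
            d = self1[variant] * self2[variant]
            if d <= 0:
                raise ValueError(f"non-positive self-similarity for variant {variant!r}")
            v = v / math.sqrt(d)
        total += v
    return total


def combined_kernel_value(s1: Spectrum, s2: Spectrum, params: KernelParams) -> float:
    """Normalised, combined kernel value between two spectra."""
    values = {v: kernel_value(s1, s2, v, params) for v in params.variants}
    self1 = {v: kernel_value(s1, s1, v, params) for v in params.variants}
    self2 = {v: kernel_value(s2, s2, v, params) for v in params.variants}
    return normalize_and_combine(values, self1, self2, params)


@dataclass
class GramMatrix:
    """A dense kernel matrix with row/column spectrum identifiers."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    params: KernelParams

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def to_tsv(self, path) -> None:
        """Write as a tab-separated matrix with an id header row/column."""
        with open(path, "w") as fh:
            fh.write("\t".join(["#id", *self.col_ids]) + "\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write("\t".join([rid, *(repr(float(v)) for v in row)]) + "\n")

    @classmethod
    def from_tsv(cls, path, params: KernelParams | None = None) -> "GramMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            col_ids = header[1:]
            row_ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                row_ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(np.asarray(rows), row_ids, col_ids, params or KernelParams())


def _spectrum_ids(spectra: Sequence[Spectrum]) -> list[str]:
    return [s.spectrum_id if s.spectrum_id is not None else f"spectrum_{k}"
            for k, s in enumerate(spectra)]


def gram_matrix(
    rows: Sequence[Spectrum],
    cols: Sequence[Spectrum] | None = None,
    params: KernelParams = KernelParams(),
) -> GramMatrix:
    """Dense (cross-)Gram matrix of the combined, normalised kernel.

    With ``cols=None`` the square training Gram is computed (symmetric,
    positive semidefinite, unit diagonal when normalised).
    """
    square = cols is None
    col_spectra = rows if square else cols
    n, m = len(rows), len(col_spectra)
    total = np.zeros((n, m))
    for variant in params.variants:
        try:
            row_reps = [_representation(s, variant) for s in rows]
        except ValueError as exc:
            raise ValueError(f"row spectra: {exc}") from exc
        col_reps = row_reps if square else [_representation(s, variant) for s in col_spectra]
        block = np.empty((n, m))
        if square:
            for i in range(n):
                for j in range(i, m):
                    block[i, j] = _raw_kernel(row_reps[i], row_reps[j], params)
                    block[j, i] = block[i, j]
            row_self = col_self = np.diagonal(block).copy()
        else:
            for i in range(n):
                for j in range(m):
                    block[i, j] = _raw_kernel(row_reps[i], col_reps[j], params)
            row_self = np.array([_raw_kernel(r, r, params) for r in row_reps])
            col_self = np.array([_raw_kernel(c, c, params) for c in col_reps])
        if params.normalize:
            block = block / np.sqrt(np.outer(row_self, col_self))
        total += block
    return GramMatrix(total, _spectrum_ids(rows), _spectrum_ids(col_spectra), params)


class ProbabilityProductKernel(TransformerMixin, BaseEstimator):
    """Kernel transformer producing precomputed Gram matrices.

    ``fit`` memorises the reference (training) spectra; ``transform``
    maps a list of spectra to their kernel values against the reference
    set — exactly the shape ``sklearn.svm.SVC(kernel="precomputed")``
    consumes downstream.

    Parameters
    ----------
    sigma_mass, sigma_intensity:
        Gaussian peak-model standard deviations (Da / relative units).
    variants:
        Subset of {"peaks", "mloss", "diff"} to combine.
    normalize:
        Cosine-normalise each variant before summing.
    """

    def __init__(
        self,
        sigma_mass: float = DEFAULT_SIGMA_MASS_HIGHRES,
        sigma_intensity: float = DEFAULT_SIGMA_INTENSITY,
        variants: tuple[str, ...] = ("peaks", "mloss"),
        normalize: bool = True,
    ):
        self.sigma_mass = sigma_mass
        self.sigma_intensity = sigma_intensity
        self.variants = variants
        self.normalize = normalize

    @property
    def params_(self) -> KernelParams:
        return KernelParams(
            sigma_mass=self.sigma_mass,
            sigma_intensity=self.sigma_intensity,
            variants=tuple(self.variants),
            normalize=self.normalize,
        )

    def fit(self, X: Sequence[Spectrum], y=None):
        params = self.params_  # validates
        self.reference_spectra_ = list(X)
        if not self.reference_spectra_:
            raise ValueError("cannot fit kernel on an empty spectrum list")
        # cache representations and self-similarities per variant
        self._reps = {
            v: [_representation(s, v) for s in self.reference_spectra_]
            for v in params.variants
        }
        self._selfs = {
            v: np.array([_raw_kernel(r, r, params) for r in reps])
            for v, reps in self._reps.items()
        }
        return self

    def transform(self, X: Sequence[Spectrum]) -> np.ndarray:
        """Cross Gram of X against the fitted reference spectra."""
        if not hasattr(self, "reference_spectra_"):
            raise ValueError("ProbabilityProductKernel is not fitted")
        params = self.params_
        n, m = len(X), len(self.reference_spectra_)
        total = np.zeros((n, m))
        for variant in params.variants:
            x_reps = [_representation(s, variant) for s in X]
            x_self = np.array([_raw_kernel(r, r, params) for r in x_reps])
            block = np.empty((n, m))
            for i, xr in enumerate(x_reps):
                for j, rr in enumerate(self._reps[variant]):
                    block[i, j] = _raw_kernel(xr, rr, params)
            if params.normalize:
                block = block / np.sqrt(np.outer(x_self, self._selfs[variant]))
            total += block
        return total

    def fit_transform(self, X: Sequence[Spectrum], y=None) -> np.ndarray:
        """Square training Gram (computed via the symmetric fast path)."""
        self.fit(X)
        return gram_matrix(self.reference_spectra_, params=self.params_).values


def estimate_peak_variances(
    replicate_groups: Iterable[Sequence[Spectrum]],
    match_tol: float = 0.5,
    min_sigma_mass: float = MIN_SIGMA_MASS,
    min_sigma_intensity: float = MIN_SIGMA_INTENSITY,
) -> tuple[float, float]:
    """Estimate (sigma_mass, sigma_intensity) from replicate spectra.

    Each group holds repeated measurements of the same molecule at the
    same energy.  Within a group, peaks of every replicate are greedily
    matched to the nearest peak of the first (reference) replicate within
    ``match_tol`` Da; the pooled within-cluster variances of matched
    masses and (sum-to-one normalised) intensities give the estimates.
    Estimates are floored at the configured minima so that noise-free
    replicates still yield a usable peak model.
    """
    mass_ss = inten_ss = 0.0
    dof = 0
    n_groups = 0
    for group in replicate_groups:
        n_groups += 1
        if len(group) < 2:
            continue
        specs = [normalize_intensities(s) for s in group]
        ref = specs[0]
        clusters_m = [[float(m)] for m in ref.mz]
        clusters_i = [[float(i)] for i in ref.intensity]
        for other in specs[1:]:
            dist = np.abs(ref.mz[:, None] - other.mz[None, :])
            pairs = np.argwhere(dist <= match_tol)
            order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
            used_ref: set[int] = set()
            used_other: set[int] = set()
            for r, o in pairs[order]:
                if r in used_ref or o in used_other:
                    continue
                used_ref.add(int(r))
                used_other.add(int(o))
                clusters_m[r].append(float(other.mz[o]))
                clusters_i[r].append(float(other.intensity[o]))
        for cm, ci in zip(clusters_m, clusters_i):
            k = len(cm)
            if k < 2:
                continue
            cm_arr, ci_arr = np.asarray(cm), np.asarray(ci)
            mass_ss += float(np.sum((cm_arr - cm_arr.mean()) ** 2))
            inten_ss += float(np.sum((ci_arr - ci_arr.mean()) ** 2))
            dof += k - 1
    if n_groups == 0 or dof == 0:
        raise ValueError(
            "no matchable replicate peaks; fall back to the default kernel parameters"
        )
    sigma_m = max(math.sqrt(mass_ss / dof), min_sigma_mass)
    sigma_i = max(math.sqrt(inten_ss / dof), min_sigma_intensity)
    return sigma_m, sigma_i
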