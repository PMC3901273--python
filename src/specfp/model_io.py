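"""Versioned on-disk bundles for trained fingerprint predictors.

A bundle is a directory of plain-text files:

``manifest.json``
    format version, estimator parameters, fingerprint key names and
    schema hash, effective-bit mask, reliability scores, molecule
    groups.
``training_spectra.massbank.txt``
    the training spectra (kernel evaluation against them is needed at
    query time), in record order matching the manifest.
``bit_models.json``
    per-effective-bit dual coefficients, support indices, bias and C
    (or the constant class for degenerate bits).

No timestamps or environment details are written, so retraining with
the same seed reproduces byte-identical bundles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fingerprints import EffectiveBitMask, schema_hash
from .kernels import ProbabilityProductKernel
from .learner import BitModel, FingerprintPredictor
from .spectra import parse_massbank_file, write_massbank_record

FORMAT_VERSION = 1

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]


def save_model(model: FingerprintPredictor, out_dir) -> Path:
    """Write a fitted predictor as a bundle directory."""
    if not hasattr(model, "bit_models_"):
        raise ValueError("model is not fitted")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "params": _jsonable(model.get_params()),
        "key_names": list(model.key_names_),
        "schema_hash": schema_hash(model.key_names_),
        "mask_keep": model.mask_.keep.astype(int).tolist(),
        "mask_constants": model.mask_.constants.astype(int).tolist(),
        "reliability": [float(w) for w in model.reliability_],
        "groups": [str(g) for g in model.groups_],
        "spectrum_ids": [s.spectrum_id for s in model.training_spectra_],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    bits = []
    for bm in model.bit_models_:
        if bm.constant is not None:
            bits.append({"bit_index": bm.bit_index, "constant": int(bm.constant)})
        else:
            bits.append(
                {
                    "bit_index": bm.bit_index,
                    "alpha_y": [float(a) for a in bm.alpha_y],
                    "support": [int(i) for i in bm.support],
                    "bias": bm.bias,
                    "C": bm.C,
                }
            )
    (out / "bit_models.json").write_text(json.dumps(bits, sort_keys=True, indent=1))
    with open(out / "training_spectra.massbank.txt", "w") as fh:
        for s in model.training_spectra_:
            fh.write(write_massbank_record(s))
    return out


def load_model(bundle_dir) -> FingerprintPredictor:
    """Reconstruct a fitted predictor from a bundle directory."""
    bundle = Path(bundle_dir)
    manifest = json.loads((bundle / "manifest.json").read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported bundle format version {manifest.get('format_version')!r}"
        )
    if schema_hash(manifest["key_names"]) != manifest["schema_hash"]:
        raise ValueError("bundle schema hash does not match its key names")
    params = manifest["params"]
    params["variants"] = tuple(params["variants"])
    params["c_grid"] = tuple(params["c_grid"])
    model = FingerprintPredictor(**params)
    spectra = parse_massbank_file(
        (bundle / "training_spectra.massbank.txt").read_text()
    )
    order = {sid: i for i, sid in enumerate(manifest["spectrum_ids"])}
    spectra.sort(key=lambda s: order[s.spectrum_id])
    model.training_spectra_ = spectra
    model.key_names_ = tuple(manifest["key_names"])
    model.mask_ = EffectiveBitMask(
        keep=np.array(manifest["mask_keep"], dtype=bool),
        constants=np.array(manifest["mask_constants"], dtype=np.int8),
    )
    model.reliability_ = np.array(manifest["reliability"], dtype=float)
    model.groups_ = np.array(manifest["groups"], dtype=object)
    model.kernel_ = ProbabilityProductKernel(
        sigma_mass=model.sigma_mass,
        sigma_intensity=model.sigma_intensity,
        variants=tuple(model.variants),
        normalize=model.normalize,
    ).fit(spectra)
    bit_models = []
    for entry in json.loads((bundle / "bit_models.json").read_text()):
        if "constant" in entry:
            bit_models.append(
                BitModel(bit_index=entry["bit_index"], constant=entry["constant"])
            )
        else:
            bit_models.append(
                BitModel(
                    bit_index=entry["bit_index"],
                    alpha_y=np.array(entry["alpha_y"], dtype=float),
                    support=np.array(entry["support"], dtype=int),
                    bias=float(entry["bias"]),
                    C=float(entry["C"]),
                )
            )
    model.bit_models_ = bit_models
    return model


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
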