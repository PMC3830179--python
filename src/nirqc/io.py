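"""Plain-text persistence: spectra/metadata CSV, a minimal JCAMP-DX writer,
and versioned model serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pls import PLSModel
from .simulate import SpectraSet, WavenumberGrid

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_jcamp_dx",
    "save_pls_model",
    "load_pls_model",
]

SPECTRA_FORMAT_VERSION = 1
MODEL_FORMAT_VERSION = 1
_WAVENUMBER_COL = "wavenumber_cm1"


class SpectraParseError(ValueError):
    pass


def write_spectra_csv(spectra: SpectraSet, path, meta_path=None) -> None:
    """Spectra as CSV: first column the wavenumber axis, one column per sample
    (12 significant digits); metadata in a companion CSV keyed by sample."""
    df = pd.DataFrame(
        spectra.absorbance.T, columns=spectra.meta["sample"].tolist()
    )
    df.insert(0, _WAVENUMBER_COL, spectra.grid.points)
    df.to_csv(path, index=False, float_format="%.12g")
    if meta_path is not None:
        spectra.meta.to_csv(meta_path, index=False, float_format="%.12g")


def read_spectra_csv(path, meta_path=None) -> SpectraSet:
    """Inverse of :func:`write_spectra_csv` (lossless at 12 significant
    digits).  Raises :class:`SpectraParseError` with the offending line for
    malformed files."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SpectraParseError(f"{path}: {exc}") from exc
    if _WAVENUMBER_COL not in df.columns:
        raise SpectraParseError(
            f"{path}: line 1: missing required column {_WAVENUMBER_COL!r}"
        )
    v = df[_WAVENUMBER_COL].to_numpy(float)
    if len(v) < 2:
        raise SpectraParseError(f"{path}: need at least 2 wavenumber rows")
    spacing = np.diff(v)
    if not np.allclose(spacing, spacing[0], rtol=0, atol=1e-9 * abs(spacing[0])):
        bad = int(np.argmax(np.abs(spacing - spacing[0]))) + 3
        raise SpectraParseError(f"{path}: line {bad}: non-uniform wavenumber grid")
    grid = WavenumberGrid(start=float(v[0]), stop=float(v[-1]), spacing=float(spacing[0]))
    samples = [c for c in df.columns if c != _WAVENUMBER_COL]
    X = df[samples].to_numpy(float).T
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
        if "sample" not in meta.columns:
            raise SpectraParseError(f"{meta_path}: line 1: missing 'sample' column")
        meta = meta.set_index("sample").loc[samples].reset_index()
    else:
        meta = pd.DataFrame({"sample": samples})
    return SpectraSet(grid, X, meta)


def write_jcamp_dx(spectra: SpectraSet, path, title: str = "nirqc spectra") -> None:
    """Minimal multi-block JCAMP-DX (XYDATA (X++(Y..Y))) writer."""
    lines: list[str] = []
    v = spectra.grid.points
    for i, sample in enumerate(spectra.meta["sample"]):
        y = spectra.absorbance[i]
        lines += [
            f"##TITLE={title}: {sample}",
            "##JCAMP-DX=4.24",
            "##DATA TYPE=NEAR INFRARED SPECTRUM",
            "##XUNITS=1/CM",
            "##YUNITS=ABSORBANCE",
            f"##FIRSTX={v[0]:.6g}",
            f"##LASTX={v[-1]:.6g}",
            f"##NPOINTS={len(v)}",
            "##XYDATA=(X++(Y..Y))",
        ]
        for j in range(0, len(v), 8):
            row = " ".join(f"{val:.6e}" for val in y[j : j + 8])
            lines.append(f"{v[j]:.6g} {row}")
        lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def save_pls_model(model: PLSModel, path) -> None:
    """Serialize a fitted PLS model to a single portable JSON file."""
    payload = {
        "format": "nirqc-pls",
        "version": MODEL_FORMAT_VERSION,
        "n_factors": model.n_factors,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "rmsec": model.rmsec,
        "r": model.r,
    }
    Path(path).write_text(json.dumps(payload))


def load_pls_model(path) -> PLSModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "nirqc-pls":
        raise ValueError(f"{path}: not a nirqc PLS model file")
    return PLSModel(
        n_factors=payload["n_factors"],
        weights=np.array(payload["weights"]),
        x_loadings=np.array(payload["x_loadings"]),
        y_loadings=np.array(payload["y_loadings"]),
        scores=np.empty((0, payload["n_factors"])),
        coef=np.array(payload["coef"]),
        x_mean=np.array(payload["x_mean"]),
        y_mean=payload["y_mean"],
        rmsec=payload["rmsec"],
        r=payload["r"],
    )
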