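"""Plain-text I/O: two-column spectrum CSVs, dataset manifests, impedance
CSVs and JSON run reports."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import ImpedanceSpectrum, RamanSpectrum

SPECTRUM_COLUMNS = ("wavenumber_cm-1", "intensity")
MANIFEST_COLUMNS = ("file", "label", "membrane_id", "spot_id")
IMPEDANCE_COLUMNS = ("frequency_hz", "z_real", "z_imag")


def write_spectrum_csv(s: RamanSpectrum, path: str | Path) -> None:
    """Write one spectrum as a two-column CSV (wavenumber, intensity)."""
    pd.DataFrame(
        {SPECTRUM_COLUMNS[0]: s.wavenumbers, SPECTRUM_COLUMNS[1]: s.intensities}
    ).to_csv(path, index=False, float_format="%.17g")


def read_spectrum_csv(
    path: str | Path,
    label: str | None = None,
    membrane_id: str | None = None,
    spot_id: str | None = None,
) -> RamanSpectrum:
    """Read a two-column spectrum CSV.

    Descending grids are re-sorted with a warning; non-numeric rows raise
    with their line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in SPECTRUM_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(values.isna() & df[col].notna())[0]
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: malformed {col} at line(s) {(bad + 2).tolist()}")
        df[col] = values
    if df[SPECTRUM_COLUMNS[0]].isna().any() or df[SPECTRUM_COLUMNS[1]].isna().any():
        raise ValueError(f"{path}: empty cells")
    wn = df[SPECTRUM_COLUMNS[0]].to_numpy()
    inten = df[SPECTRUM_COLUMNS[1]].to_numpy()
    if np.all(np.diff(wn) < 0):
        warnings.warn(f"{path}: descending wavenumbers, re-sorting")
        order = np.argsort(wn)
        wn, inten = wn[order], inten[order]
    return RamanSpectrum(
        wavenumbers=wn, intensities=inten,
        label=label, membrane_id=membrane_id, spot_id=spot_id,
    )


def write_dataset(
    dataset: list[RamanSpectrum], directory: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write every spectrum as CSV plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(dataset):
        fname = f"spectrum_{i:04d}.csv"
        write_spectrum_csv(s, directory / fname)
        rows.append(
            {"file": fname, "label": s.label, "membrane_id": s.membrane_id or "",
             "spot_id": s.spot_id or ""}
        )
    manifest = directory / manifest_name
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> list[RamanSpectrum]:
    """Load a dataset from a manifest CSV; missing files raise with the row."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{manifest_path}: missing columns {missing}")
    base = manifest_path.parent
    dataset = []
    for i, row in df.iterrows():
        f = base / row["file"]
        if not f.exists():
            raise FileNotFoundError(f"{manifest_path} row {i + 1}: file {f} not found")
        dataset.append(
            read_spectrum_csv(
                f,
                label=row["label"] or None,
                membrane_id=row["membrane_id"] or None,
                spot_id=row["spot_id"] or None,
            )
        )
    return dataset


def write_impedance_csv(spectrum: ImpedanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {
            IMPEDANCE_COLUMNS[0]: spectrum.frequencies,
            IMPEDANCE_COLUMNS[1]: spectrum.impedance.real,
            IMPEDANCE_COLUMNS[2]: spectrum.impedance.imag,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_impedance_csv(path: str | Path, condition: str | None = None) -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    missing = [c for c in IMPEDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return ImpedanceSpectrum(
        frequencies=df[IMPEDANCE_COLUMNS[0]].to_numpy(),
        impedance=df[IMPEDANCE_COLUMNS[1]].to_numpy()
        + 1j * df[IMPEDANCE_COLUMNS[2]].to_numpy(),
        condition=condition,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(payload: dict, path: str | Path) -> None:
    """Serialise a run report to JSON (numpy types coerced)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
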