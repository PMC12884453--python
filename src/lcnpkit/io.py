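"""Reading and writing the package's on-disk formats.

Profiles and spectra travel as two-column delimited text with a
one-line header; batches are described by JSON manifests mapping
particle ids to files (with a designated blank for Raman runs); masks
are CSV grids of 0/1.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .raman import RamanSpectrum, SpectrumBatch
from .saxs import SAXSProfile

__all__ = [
    "read_saxs_profile",
    "write_saxs_profile",
    "read_raman_spectrum",
    "write_raman_spectrum",
    "read_raman_manifest",
    "write_raman_manifest",
    "read_mask_csv",
    "write_mask_csv",
    "validate_manifest",
]


def _read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    p = Path(path)
    sep = r"\s+" if p.suffix.lower() == ".dat" else ","
    df = pd.read_csv(p, sep=sep, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{p}: expected two columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def read_saxs_profile(
    path: str | Path, label: str = "", ethanol_vv: Optional[float] = None
) -> SAXSProfile:
    q, i = _read_two_column(path)
    return SAXSProfile(q, i, label=label or Path(path).stem, ethanol_vv=ethanol_vv)


def write_saxs_profile(profile: SAXSProfile, path: str | Path) -> None:
    pd.DataFrame({"q_nm^-1": profile.q, "intensity": profile.intensity}).to_csv(
        path, index=False
    )


def read_raman_spectrum(path: str | Path, particle_id: str = "") -> RamanSpectrum:
    wn, i = _read_two_column(path)
    return RamanSpectrum(wn, i, particle_id=particle_id or Path(path).stem)


def write_raman_spectrum(s: RamanSpectrum, path: str | Path) -> None:
    pd.DataFrame({"wavenumber_cm^-1": s.wavenumber, "counts": s.intensity}).to_csv(
        path, index=False
    )


def write_raman_manifest(
    batch: SpectrumBatch, blank: RamanSpectrum, directory: str | Path
) -> Path:
    """Write every spectrum of a batch plus the blank, and a manifest JSON
    pointing at them; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in batch:
        f = directory / f"{s.particle_id}.csv"
        write_raman_spectrum(s, f)
        entries.append({"particle_id": s.particle_id, "file": f.name})
    blank_file = directory / "blank.csv"
    write_raman_spectrum(blank, blank_file)
    manifest = {"blank": blank_file.name, "spectra": entries}
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def validate_manifest(path: str | Path, require_blank: bool = True) -> dict:
    """Check a manifest and normalize its paths to absolute.

    All problems (missing files, non-monotone grids, absent blank) are
    collected and reported together.
    """
    path = Path(path)
    base = path.parent
    manifest = json.loads(path.read_text())
    problems: list[str] = []
    out = {"blank": None, "spectra": []}
    blank = manifest.get("blank")
    if blank is None:
        if require_blank:
            problems.append("manifest lists no blank spectrum (required for Raman runs)")
    else:
        bp = (base / blank).resolve()
        if not bp.exists():
            problems.append(f"blank file missing: {bp}")
        else:
            out["blank"] = str(bp)
    for entry in manifest.get("spectra", []):
        fp = (base / entry["file"]).resolve()
        if not fp.exists():
            problems.append(f"spectrum file missing: {fp}")
            continue
        try:
            read_raman_spectrum(fp)
        except ValueError as e:
            problems.append(f"{fp}: {e}")
            continue
        out["spectra"].append({"particle_id": entry.get("particle_id", fp.stem),
                               "file": str(fp)})
    if problems:
        raise ValueError("manifest validation failed:\n  " + "\n  ".join(problems))
    return out


def read_raman_manifest(path: str | Path) -> tuple[SpectrumBatch, Optional[RamanSpectrum]]:
    norm = validate_manifest(path)
    spectra = [read_raman_spectrum(e["file"], e["particle_id"]) for e in norm["spectra"]]
    blank = read_raman_spectrum(norm["blank"], "blank") if norm["blank"] else None
    return SpectrumBatch(spectra), blank


def read_mask_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", dtype=int).astype(bool)


def write_mask_csv(mask: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d", delimiter=",")
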