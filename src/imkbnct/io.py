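"""File formats and bundled reference data.

Formats
-------
* Cell-line parameter files: YAML mappings with keys ``alpha0``,
  ``beta0``, ``repair_rate`` (and optional ``*_sd``, ``name``).
* Lineal-energy spectra: two-column text (y keV/μm, density),
  whitespace- or comma-delimited, ``#`` comments.
* Survival data: CSV with columns ``dose_Gy``, ``dose_rate_Gy_per_min``,
  ``surviving_fraction``, ``quality`` (and optional ``sd``).
* Boron timelines: CSV with columns ``t_min``, ``ppm``.

Bundled fixtures: parameter sets for the HX34, M8 and Mel-J melanoma
lines, and the calibration field qualities (photon, neutron-only and
BNCT at 10 ppm) from which the two-component quality model derives.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CellLineParams
from .fitting import SurvivalDataset
from .microdosimetry import LinealEnergySpectrum, QualityComponents, calibrate_components
from .schedule import BoronTimeline

__all__ = [
    "load_params",
    "save_params",
    "bundled_cell_lines",
    "load_cell_line",
    "reference_field_quality",
    "bnct_quality_components",
    "load_spectrum",
    "load_survival_csv",
    "save_survival_csv",
    "load_timeline_csv",
]

_PARAM_KEYS = ("alpha0", "beta0", "repair_rate")


def _params_from_mapping(raw: dict, origin: str) -> CellLineParams:
    missing = [k for k in _PARAM_KEYS if k not in raw]
    if missing:
        raise ValueError(f"{origin}: missing required fields {missing}")
    bad = [k for k in _PARAM_KEYS if not isinstance(raw[k], (int, float))]
    if bad:
        raise ValueError(f"{origin}: non-numeric fields {bad}")
    try:
        return CellLineParams(
            alpha0=float(raw["alpha0"]),
            beta0=float(raw["beta0"]),
            repair_rate=float(raw["repair_rate"]),
            alpha0_sd=raw.get("alpha0_sd"),
            beta0_sd=raw.get("beta0_sd"),
            repair_rate_sd=raw.get("repair_rate_sd"),
            name=str(raw.get("name", "")),
        )
    except ValueError as e:
        raise ValueError(f"{origin}: {e}") from e


def load_params(path: str | Path) -> CellLineParams:
    """Load cell-line parameters from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return _params_from_mapping(raw, str(path))


def save_params(params: CellLineParams, path: str | Path) -> None:
    """Write cell-line parameters to YAML (round-trips exactly)."""
    out = {
        "name": params.name,
        "alpha0": params.alpha0,
        "beta0": params.beta0,
        "repair_rate": params.repair_rate,
    }
    for key in ("alpha0_sd", "beta0_sd", "repair_rate_sd"):
        val = getattr(params, key)
        if val is not None:
            out[key] = val
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


_CELL_LINE_FILES = {"hx34": "hx34.yaml", "m8": "m8.yaml", "mel-j": "mel-j.yaml"}


def bundled_cell_lines() -> list[str]:
    return sorted(_CELL_LINE_FILES)


def load_cell_line(name: str) -> CellLineParams:
    """Load a bundled cell-line parameter set ('hx34', 'm8' or 'mel-j')."""
    key = name.lower().replace("_", "-")
    if key not in _CELL_LINE_FILES:
        raise KeyError(f"unknown cell line {name!r}; bundled: {bundled_cell_lines()}")
    ref = resources.files("imkbnct.data") / _CELL_LINE_FILES[key]
    raw = yaml.safe_load(ref.read_text())
    return _params_from_mapping(raw, f"bundled:{key}")


def reference_field_quality() -> dict:
    """Bundled calibration (dose rate, y*) for photon/neutron/BNCT fields."""
    ref = resources.files("imkbnct.data") / "field_quality.yaml"
    return yaml.safe_load(ref.read_text())


def bnct_quality_components() -> QualityComponents:
    """Two-component field quality calibrated from the bundled constants."""
    q = reference_field_quality()
    return calibrate_components(
        neutron_rate=q["neutron_only"]["dose_rate_gy_min"],
        neutron_y_star=q["neutron_only"]["y_star"],
        bnct_rate=q["bnct"]["dose_rate_gy_min"],
        bnct_y_star=q["bnct"]["y_star"],
        ppm_ref=q["bnct"]["ppm"],
    )


def load_spectrum(path: str | Path, label: str | None = None) -> LinealEnergySpectrum:
    """Read a two-column (y, f(y)) text spectrum; '#' starts a comment.

    Delimiter may be whitespace or commas; the density is renormalised
    on load (a warning is logged when it is off by more than 1%).
    """
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected two columns")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, float)
    return LinealEnergySpectrum(arr[:, 0], arr[:, 1], label=label or Path(path).stem)


def load_survival_csv(
    path: str | Path, quality_map: dict[str, float], provenance: str = ""
) -> SurvivalDataset:
    """Read a survival CSV (header required) into a dataset."""
    df = pd.read_csv(path)
    return SurvivalDataset(
        data=df, quality_map=quality_map, provenance=provenance or str(path)
    )


def save_survival_csv(dataset: SurvivalDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False)


def load_timeline_csv(path: str | Path, method: str = "pchip") -> BoronTimeline:
    """Read a ¹⁰B timeline CSV with columns t_min, ppm."""
    df = pd.read_csv(path)
    for col in ("t_min", "ppm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return BoronTimeline(
        times_min=df["t_min"].to_numpy(float),
        ppm=df["ppm"].to_numpy(float),
        method=method,
    )
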