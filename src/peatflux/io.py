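"""CSV input/output.

Tabular interchange formats:

* dates CSV — columns ``depth_cm, lab_id, c14_age, c14_error`` plus optional
  ``material, is_bulk`` (and, for published tables, ``reported_cal_min/max``
  reference columns that are never used in computation);
* core CSV — one row per contiguous slice: ``depth_top_cm, thickness_cm``,
  either ``dry_mass_g`` or ``bulk_density_g_cm3``, optional ``C_pct, N_pct,
  d13C_permil, d15N_permil, DPH_abs, ftir_1040, ftir_1650, ftir_2920`` and
  element columns ``<El>_ppm`` with optional ``<El>_ppm_sd``;
* reference compositions — ``element,ppm`` with a ``# source:`` header.

All writers prepend ``#`` comment lines carrying provenance (stage, seed,
config hash) so every output file is self-describing.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .accumulation import CoreProfile, CoreSlice, DEFAULT_CORER_RADIUS_CM
from .calibrate import RadiocarbonDate

__all__ = [
    "load_dates_csv",
    "load_core_csv",
    "write_table",
    "read_table",
    "draftinge_dates",
    "draftinge_reported_ranges",
]

_ELEMENT_RE = re.compile(r"^([A-Z][a-z]?)_ppm$")


def load_dates_csv(path: str | Path) -> list[RadiocarbonDate]:
    df = read_table(path)
    required = {"depth_cm", "lab_id", "c14_age", "c14_error"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing date columns {sorted(missing)}")
    dates = []
    for _, row in df.iterrows():
        dates.append(
            RadiocarbonDate(
                depth=float(row["depth_cm"]),
                lab_id=str(row["lab_id"]),
                c14_age=float(row["c14_age"]),
                c14_error=float(row["c14_error"]),
                material=str(row.get("material", "")),
                is_bulk=bool(int(row.get("is_bulk", 0) or 0)),
            )
        )
    return dates


def load_core_csv(
    path: str | Path, corer_radius: float = DEFAULT_CORER_RADIUS_CM
) -> tuple[CoreProfile, pd.DataFrame]:
    """Read a core CSV into a (CoreProfile, full DataFrame) pair.

    The DataFrame keeps every column (the OM stage reads its variables from
    it); the profile holds the physical/geochemical subset.
    """
    df = read_table(path)
    for col in ("depth_top_cm", "thickness_cm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    elements = [m.group(1) for c in df.columns if (m := _ELEMENT_RE.match(c))]
    slices = []
    for _, row in df.iterrows():
        conc = {el: float(row[f"{el}_ppm"]) for el in elements if np.isfinite(row[f"{el}_ppm"])}
        conc_sd = {
            el: float(row[f"{el}_ppm_sd"])
            for el in elements
            if f"{el}_ppm_sd" in df.columns and np.isfinite(row[f"{el}_ppm_sd"])
        }
        slices.append(
            CoreSlice(
                depth_top=float(row["depth_top_cm"]),
                thickness=float(row["thickness_cm"]),
                dry_mass=float(row["dry_mass_g"]) if "dry_mass_g" in df.columns else None,
                corer_radius=float(row.get("corer_radius_cm", corer_radius)),
                bulk_density_value=float(row["bulk_density_g_cm3"])
                if "bulk_density_g_cm3" in df.columns
                else None,
                c_pct=float(row["C_pct"]) if "C_pct" in df.columns else None,
                n_pct=float(row["N_pct"]) if "N_pct" in df.columns else None,
                element_conc=conc,
                element_conc_sd=conc_sd,
            )
        )
    return CoreProfile(slices=tuple(slices), site_name=Path(path).stem), df


def write_table(
    df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a DataFrame as CSV with leading ``#`` provenance comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skipinitialspace=True)


def _packaged(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("peatflux.data") / name) as p:
        return read_table(p)


def draftinge_dates() -> list[RadiocarbonDate]:
    """The packaged published Draftinge Mosse date table."""
    with resources.as_file(
        resources.files("peatflux.data") / "draftinge_dates.csv"
    ) as p:
        return load_dates_csv(p)


def draftinge_reported_ranges() -> dict[str, tuple[float, float]]:
    """Published 95% calibrated ranges (cal yr BP) keyed by lab id."""
    df = _packaged("draftinge_dates.csv")
    return {
        str(r.lab_id): (float(r.reported_cal_min), float(r.reported_cal_max))
        for r in df.itertuples()
    }
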