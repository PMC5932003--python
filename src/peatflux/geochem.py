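"""Dust-provenance proxies from rare-earth-element patterns.

All indices are normalised to an upper-continental-crust (UCC) reference
composition, the standard way of removing the smooth abundance decline
across the lanthanides so that fractionation between light (La), middle
(Sm-Gd) and heavy (Lu) REE and the europium anomaly stand out:

    X_N        = X_sample / X_UCC
    La/Lu      = La_N / Lu_N            (LREE/HREE fractionation)
    Gd/Lu      = Gd_N / Lu_N            (MREE/HREE fractionation)
    [Eu/Eu*]   = Eu_N / sqrt(Sm_N Gd_N) (geometric-mean Eu anomaly)

Eu/Eu* > 1 signals feldspar-rich, less weathered material.  Net dust
deposition is estimated from the Al mass accumulation rate divided by the
crustal Al mass fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ReferenceComposition",
    "load_reference_composition",
    "builtin_reference",
    "ucc_normalize",
    "ree_ratio",
    "eu_anomaly",
    "ProxySeries",
    "proxy_errors",
    "dust_flux",
]

_REQUIRED_ELEMENTS = ("Al", "La", "Sm", "Eu", "Gd", "Lu")
_BUILTIN = {
    "ucc_mclennan2001": "ucc_mclennan2001.csv",
    "ucc_taylor_mclennan1985": "ucc_taylor_mclennan1985.csv",
    "ucc_rudnick_gao2003": "ucc_rudnick_gao2003.csv",
}


@dataclass(frozen=True)
class ReferenceComposition:
    """A named reference composition, element -> ppm of dry mass."""

    name: str
    conc: dict[str, float]

    def __post_init__(self) -> None:
        missing = [e for e in _REQUIRED_ELEMENTS if e not in self.conc]
        if missing:
            raise ValueError(f"{self.name}: missing required elements {missing}")
        bad = [e for e in _REQUIRED_ELEMENTS if self.conc[e] <= 0]
        if bad:
            raise ValueError(f"{self.name}: non-positive reference values {bad}")

    def __getitem__(self, element: str) -> float:
        try:
            return self.conc[element]
        except KeyError:
            raise KeyError(f"element {element!r} absent from reference {self.name}") from None

    @property
    def al_mass_fraction(self) -> float:
        return self.conc["Al"] * 1.0e-6


def load_reference_composition(path: str | Path) -> ReferenceComposition:
    """Read an ``element,ppm`` CSV with an optional ``# source:`` header."""
    path = Path(path)
    conc: dict[str, float] = {}
    name = path.stem
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "source:" in line:
                    name = line.split("source:", 1)[1].strip()
                continue
            el, _, val = line.partition(",")
            if el.strip().lower() == "element":
                continue
            conc[el.strip()] = float(val)
    return ReferenceComposition(name=name, conc=conc)


def builtin_reference(key: str = "ucc_mclennan2001") -> ReferenceComposition:
    """One of the packaged UCC tables (see ``_BUILTIN`` for keys)."""
    try:
        fname = _BUILTIN[key]
    except KeyError:
        raise KeyError(f"unknown reference {key!r}; options: {sorted(_BUILTIN)}") from None
    with resources.as_file(resources.files("peatflux.data") / fname) as p:
        ref = load_reference_composition(p)
    return ReferenceComposition(name=key, conc=ref.conc)


def ucc_normalize(conc, element: str, ref: ReferenceComposition):
    """Concentration divided by the reference value (unitless)."""
    return np.asarray(conc, dtype=float) / ref[element]


def ree_ratio(
    sample: dict[str, np.ndarray],
    numerator: str,
    denominator: str,
    ref: ReferenceComposition,
    normalised: bool = True,
):
    """Reference-normalised element ratio (raw ratio if ``normalised=False``)."""
    num = np.asarray(sample[numerator], dtype=float)
    den = np.asarray(sample[denominator], dtype=float)
    out = num / den
    if normalised:
        out = out * (ref[denominator] / ref[numerator])
    return out


def eu_anomaly(
    eu, sm, gd, ref: ReferenceComposition, mean: str = "geometric"
):
    """Europium anomaly Eu_N / mean(Sm_N, Gd_N).

    ``mean`` selects the Eu* convention: ``"geometric"`` (default,
    sqrt(Sm_N * Gd_N)) or ``"arithmetic"`` ((Sm_N + Gd_N)/2).
    """
    eu = np.asarray(eu, dtype=float)
    sm = np.asarray(sm, dtype=float)
    gd = np.asarray(gd, dtype=float)
    if np.any(eu <= 0) or np.any(sm <= 0) or np.any(gd <= 0):
        raise ValueError("Eu, Sm, Gd must all be > 0")
    eun = eu / ref["Eu"]
    smn = sm / ref["Sm"]
    gdn = gd / ref["Gd"]
    if mean == "geometric":
        estar = np.sqrt(smn * gdn)
    elif mean == "arithmetic":
        estar = 0.5 * (smn + gdn)
    else:
        raise ValueError("mean must be 'geometric' or 'arithmetic'")
    return eun / estar


@dataclass(frozen=True)
class ProxySeries:
    """A provenance proxy along the core with a replicate-based error."""

    midpoint_age: np.ndarray
    value: np.ndarray
    ratio_name: str
    rel_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rel_sd < 0:
            raise ValueError("rel_sd must be >= 0")


def proxy_errors(series: ProxySeries, replicate_rsd: float | None = None) -> np.ndarray:
    """Absolute error per point: value times the replicate RSD."""
    rsd = series.rel_sd if replicate_rsd is None else replicate_rsd
    if rsd < 0:
        raise ValueError("replicate RSD must be >= 0")
    return np.abs(series.value) * rsd


def dust_flux(al_mar, al_mass_fraction_ucc: float = 0.0804):
    """Dust deposition rate from Al MAR (same units as the MAR input).

    Accepts an array of Al MARs or an
    :class:`~peatflux.accumulation.AccumulationSeries` (all MC statistics
    are divided by the Al mass fraction).
    """
    from .accumulation import AccumulationSeries, dust_flux_series

    if isinstance(al_mar, AccumulationSeries):
        return dust_flux_series(al_mar, al_mass_fraction_ucc)
    if al_mass_fraction_ucc <= 0:
        raise ValueError("al_mass_fraction_ucc must be > 0")
    return np.asarray(al_mar, dtype=float) / al_mass_fraction_ucc
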