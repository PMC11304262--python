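"""Fatty-acid profile metrics and triglyceride normalization.

Fatty-acid species are named by the GC-MS shorthand ``Cxx:y`` with an
optional omega-class suffix (``n3``/``n6``/``n9``) and a cis/trans isomer
tag, e.g. ``C18:1n9c``.  Profiles are expressed in percent moles (values
sum to 100); class aggregates (SFA/MUFA/PUFA/UFA) partition by double-bond
count, the omega-6/omega-3 ratio sums the n6 and n3 species only, and
chain classes follow the long-chain (12 < C < 22) and very-long-chain
(C >= 22) conventions.

Triglyceride measurements are normalized first to starting tissue weight
and then to the mean of the control group within each batch, so the
control group's mean relative value is exactly 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FattyAcidSpecies",
    "parse_species",
    "normalize_profile",
    "aggregate_classes",
    "omega_ratio",
    "chain_class",
    "normalize_tg",
]

_SPECIES_RE = re.compile(
    r"^C(?P<carbons>\d+):(?P<bonds>\d+)(?:n\s?(?P<omega>\d+)(?P<isomer>[ct])?)?$"
)


@dataclass(frozen=True)
class FattyAcidSpecies:
    shorthand: str
    carbons: int
    double_bonds: int
    omega: str  # "n3" | "n6" | "n9" | "none"
    isomer: str  # "cis" | "trans" | ""


def parse_species(shorthand: str) -> FattyAcidSpecies:
    """Parse a ``Cxx:y[n z][c|t]`` shorthand; rejects unknown tokens."""
    m = _SPECIES_RE.match(shorthand.strip())
    if m is None:
        raise ValueError(f"unrecognized fatty-acid shorthand: {shorthand!r}")
    carbons = int(m.group("carbons"))
    bonds = int(m.group("bonds"))
    if carbons < 4:
        raise ValueError(f"{shorthand!r}: chain length must be >= 4")
    omega = f"n{m.group('omega')}" if m.group("omega") else "none"
    if bonds == 0 and omega != "none":
        raise ValueError(f"{shorthand!r}: saturated species cannot carry an omega class")
    if bonds > 0 and omega == "none":
        omega = "none"  # unsaturated species without stated omega position
    isomer = {"c": "cis", "t": "trans", None: ""}[m.group("isomer")]
    return FattyAcidSpecies(shorthand.strip(), carbons, bonds, omega, isomer)


def normalize_profile(raw: dict | pd.Series) -> pd.Series:
    """Convert raw abundances to percent moles (sum 100); idempotent."""
    s = pd.Series(raw, dtype=float)
    if s.empty:
        raise ValueError("profile has no species")
    if (s < 0).any():
        raise ValueError("abundances must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ValueError("profile total is zero")
    for name in s.index:
        parse_species(name)
    return s * 100.0 / total


def _require_normalized(profile: pd.Series) -> pd.Series:
    s = pd.Series(profile, dtype=float)
    if abs(s.sum() - 100.0) > 1e-6:
        raise ValueError(
            f"profile is not in percent moles (sum={s.sum():.6g}); "
            "call normalize_profile first"
        )
    return s


def aggregate_classes(profile: pd.Series) -> dict[str, float]:
    """SFA/MUFA/PUFA/UFA percent totals from a percent-mole profile."""
    s = _require_normalized(profile)
    sfa = mufa = pufa = 0.0
    for name, pct in s.items():
        sp = parse_species(name)
        if sp.double_bonds == 0:
            sfa += pct
        elif sp.double_bonds == 1:
            mufa += pct
        else:
            pufa += pct
    return {"SFA": sfa, "MUFA": mufa, "PUFA": pufa, "UFA": mufa + pufa}


def omega_ratio(profile: pd.Series) -> float:
    """omega-6 / omega-3 ratio; omega-9 species do not enter either sum."""
    s = _require_normalized(profile)
    n6 = n3 = 0.0
    for name, pct in s.items():
        sp = parse_species(name)
        if sp.omega == "n6":
            n6 += pct
        elif sp.omega == "n3":
            n3 += pct
    if n3 <= 0:
        raise ValueError("omega-3 total is zero; ratio undefined")
    return n6 / n3


def chain_class(species: str | FattyAcidSpecies) -> str:
    """Chain-length class: VLCFA (C >= 22), LCFA (12 < C < 22), else SCFA/MCFA."""
    sp = species if isinstance(species, FattyAcidSpecies) else parse_species(species)
    if sp.carbons >= 22:
        return "VLCFA"
    if sp.carbons > 12:
        return "LCFA"
    return "SCFA/MCFA"


def normalize_tg(measurements: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Normalize triglyceride measurements to tissue weight, then to the
    batch control mean.

    Expects columns ``sample_id, group, batch, tg_raw, tissue_mg``.  Adds
    ``tg_per_mg`` and ``tg_relative``; within each batch the control
    group's mean relative value is exactly 1.
    """
    required = {"sample_id", "group", "batch", "tg_raw", "tissue_mg"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = measurements.copy()
    if (out["tissue_mg"] <= 0).any():
        raise ValueError("tissue weight must be positive")
    out["tg_per_mg"] = out["tg_raw"] / out["tissue_mg"]
    rel = pd.Series(index=out.index, dtype=float)
    for batch, grp in out.groupby("batch", observed=True):
        controls = grp[grp["group"] == control_group]
        if controls.empty:
            raise ValueError(f"batch {batch!r} has no control-group ({control_group!r}) samples")
        ctrl_mean = controls["tg_per_mg"].mean()
        if ctrl_mean <= 0:
            raise ValueError(f"batch {batch!r}: control mean is not positive")
        rel.loc[grp.index] = grp["tg_per_mg"] / ctrl_mean
    out["tg_relative"] = rel
    return out
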