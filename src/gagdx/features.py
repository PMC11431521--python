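"""GAGome feature engineering.

A measured GAGome is the vector of absolute concentrations (µg/mL) of the 17
panel disaccharides. It is expanded to at most 39 features per sample:

* 17 absolute concentrations (µg/mL);
* ``total CS`` and ``total HS`` (µg/mL) — sums of the class concentrations;
* ``CS charge`` and ``HS charge`` (dimensionless) — the sulfo-count-weighted
  sums of the class mass fractions (÷100), summarizing average sulfation;
* two ratios ``4S CS/0S CS`` and ``6S CS/0S CS`` (dimensionless);
* 16 mass fractions (µg/µg%), one per CS and HS disaccharide, each absolute
  concentration as a percentage of its class total.

Features whose denominator is zero (or whose constituents are missing) are
marked *unavailable* rather than propagated as NaN, so that downstream
filtering is deterministic.

Detectability: a concentration feature is considered detectable in plasma if
its median across all cohort samples strictly exceeds the limit of detection
(default 0.1 µg/mL); only detectable disaccharides, and derived features built
from them, enter the statistical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .panel import (
    PANEL_COLUMNS,
    PANEL_NAMES,
    GagClass,
    class_members,
    disaccharide,
    sulfo_count,
)

_CS_NAMES = tuple(d.canonical_name for d in class_members(GagClass.CS))
_HS_NAMES = tuple(d.canonical_name for d in class_members(GagClass.HS))

#: Derived feature names in canonical order.
DERIVED_FEATURES: tuple[str, ...] = (
    "total CS",
    "total HS",
    "CS charge",
    "HS charge",
    "4S CS/0S CS",
    "6S CS/0S CS",
    *(f"{n} fraction" for n in _CS_NAMES),
    *(f"{n} fraction" for n in _HS_NAMES),
)

#: All 39 feature names: 17 measured concentrations then 22 derived features.
FEATURE_NAMES: tuple[str, ...] = PANEL_NAMES + DERIVED_FEATURES

FEATURE_UNITS: dict[str, str] = {
    **{n: "µg/mL" for n in PANEL_NAMES},
    "total CS": "µg/mL",
    "total HS": "µg/mL",
    "CS charge": "-",
    "HS charge": "-",
    "4S CS/0S CS": "-",
    "6S CS/0S CS": "-",
    **{f"{n} fraction": "µg/µg%" for n in _CS_NAMES + _HS_NAMES},
}


class FeatureValue(NamedTuple):
    value: float
    unit: str
    available: bool


@dataclass
class GagomeProfile:
    """Per-sample map of disaccharide identities to concentrations (µg/mL).

    Concentrations may be NaN to mark a missing measurement. Unknown
    disaccharide names and negative concentrations are rejected.
    """

    sample_id: str
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for name, value in self.concentrations.items():
            d = disaccharide(name)  # raises on unknown identity
            v = float(value)
            if v < 0:
                raise ValueError(
                    f"negative concentration for {d.canonical_name} in sample "
                    f"{self.sample_id!r}: {v}"
                )
            clean[d.canonical_name] = v
        self.concentrations = clean

    def as_row(self) -> pd.Series:
        """Series over the 17 canonical names, NaN where missing."""
        return pd.Series(
            {n: self.concentrations.get(n, np.nan) for n in PANEL_NAMES},
            name=self.sample_id,
            dtype=float,
        )


@dataclass
class FeatureRecord:
    """The expanded per-sample feature map (39 slots for a complete profile)."""

    sample_id: str
    features: dict[str, FeatureValue]

    def value(self, name: str) -> float:
        return self.features[name].value

    def available(self, name: str) -> bool:
        return self.features[name].available


@dataclass
class FeatureTable:
    """Cohort-level expanded features: values plus availability mask."""

    values: pd.DataFrame
    available: pd.DataFrame

    def __post_init__(self) -> None:
        assert list(self.values.columns) == list(self.available.columns)


@dataclass
class DetectabilityResult:
    """Outcome of the median-above-LOD detectability rule."""

    lod: float
    medians: pd.Series
    detectable: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        above = self.medians > self.lod  # strict inequality
        self.detectable = tuple(n for n in PANEL_NAMES if bool(above.get(n, False)))


def _as_frame(profiles: Iterable[GagomeProfile] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        df = profiles.copy()
        df.columns = [disaccharide(c).canonical_name for c in df.columns]
        missing = set(PANEL_NAMES) - set(df.columns)
        if missing:
            raise ValueError(f"gagome table lacks panel columns: {sorted(missing)}")
        df = df[list(PANEL_NAMES)].astype(float)
    else:
        rows = [p.as_row() for p in profiles]
        if not rows:
            raise ValueError("empty cohort: at least one GAGome profile is required")
        df = pd.DataFrame(rows)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative concentration in gagome table")
    return df


def expand_features_table(profiles: Iterable[GagomeProfile] | pd.DataFrame) -> FeatureTable:
    """Expand measured concentrations into the full feature set for a cohort.

    Missing measurements propagate unavailability to every feature that
    depends on them; zero denominators (class total, 0S CS) mark the
    dependent fractions, charges and ratios unavailable.
    """
    conc = _as_frame(profiles)
    present = conc.notna()

    values = pd.DataFrame(index=conc.index, columns=list(FEATURE_NAMES), dtype=float)
    avail = pd.DataFrame(False, index=conc.index, columns=list(FEATURE_NAMES))

    values[list(PANEL_NAMES)] = conc
    avail[list(PANEL_NAMES)] = present

    for cls, names in ((GagClass.CS, _CS_NAMES), (GagClass.HS, _HS_NAMES)):
        total_name = f"total {cls.value}"
        sub = conc[list(names)]
        complete = present[list(names)].all(axis=1)
        total = sub.sum(axis=1)
        values[total_name] = total.where(complete)
        avail[total_name] = complete

        frac_ok = complete & (total > 0)
        weights = np.array([sulfo_count(n) for n in names], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            fracs = 100.0 * sub.div(total, axis=0)
        for n in names:
            fname = f"{n} fraction"
            values[fname] = fracs[n].where(frac_ok)
            avail[fname] = frac_ok
        charge_name = f"{cls.value} charge"
        charge = (fracs.to_numpy() / 100.0) @ weights
        values[charge_name] = pd.Series(charge, index=conc.index).where(frac_ok)
        avail[charge_name] = frac_ok

    zero_s = conc["0S CS"]
    ratio_ok_base = present["0S CS"] & (zero_s > 0)
    for num in ("4S CS", "6S CS"):
        rname = f"{num}/0S CS"
        ok = ratio_ok_base & present[num]
        with np.errstate(divide="ignore", invalid="ignore"):
            values[rname] = (conc[num] / zero_s).where(ok)
        avail[rname] = ok

    values[~avail] = np.nan
    return FeatureTable(values=values, available=avail)


def expand_features(profile: GagomeProfile) -> FeatureRecord:
    """Expand a single profile into its (maximally 39) named features."""
    table = expand_features_table([profile])
    feats = {
        name: FeatureValue(
            value=float(table.values.iloc[0][name]),
            unit=FEATURE_UNITS[name],
            available=bool(table.available.iloc[0][name]),
        )
        for name in FEATURE_NAMES
    }
    return FeatureRecord(sample_id=profile.sample_id, features=feats)


def detectable_features(
    profiles: Iterable[GagomeProfile] | pd.DataFrame, lod: float = 0.1
) -> DetectabilityResult:
    """Apply the median-above-LOD rule across a cohort.

    The median of each disaccharide is taken over samples where the value is
    present; a disaccharide is detectable iff its median strictly exceeds
    ``lod``.
    """
    if lod <= 0:
        raise ValueError(f"lod must be positive, got {lod}")
    conc = _as_frame(profiles)
    if len(conc) == 0:
        raise ValueError("empty cohort: at least one GAGome profile is required")
    medians = conc.median(axis=0, skipna=True)
    return DetectabilityResult(lod=lod, medians=medians)


def select_analysis_features(det: DetectabilityResult) -> list[str]:
    """Analysis feature set implied by a detectable-disaccharide set.

    A concentration enters iff the disaccharide is detectable; a mass
    fraction iff its numerator is detectable; a ratio iff both its numerator
    and denominator are detectable; a class total iff at least one
    constituent is detectable; a class charge iff every constituent is
    detectable (its formula involves all fractions of the class).
    """
    d = set(det.detectable)
    selected: list[str] = [n for n in PANEL_NAMES if n in d]
    selected += [f"{n} fraction" for n in _CS_NAMES + _HS_NAMES if n in d]
    for num in ("4S CS", "6S CS"):
        if num in d and "0S CS" in d:
            selected.append(f"{num}/0S CS")
    for cls, names in (("CS", _CS_NAMES), ("HS", _HS_NAMES)):
        if any(n in d for n in names):
            selected.append(f"total {cls}")
        if all(n in d for n in names):
            selected.append(f"{cls} charge")
    return selected


def read_gagome_csv(path: str | Path) -> pd.DataFrame:
    """Read a wide GAGome CSV (sample_id + 17 ``CS_0S``-style columns).

    Returns a DataFrame indexed by sample_id with canonical-name columns;
    empty cells become NaN (missing).
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("gagome CSV must contain a 'sample_id' column")
    df = df.set_index("sample_id")
    unknown = [c for c in df.columns if c not in PANEL_COLUMNS and c not in PANEL_NAMES]
    if unknown:
        raise ValueError(f"unknown disaccharide columns: {unknown}")
    return _as_frame(df)


def write_gagome_csv(conc: pd.DataFrame, path: str | Path) -> None:
    """Write a gagome table (canonical-name columns) to the wide CSV dialect."""
    out = conc.copy()
    out.columns = [disaccharide(c).column_name for c in out.columns]
    out.index.name = "sample_id"
    out.to_csv(path)


def write_features_csv(
    table: FeatureTable, path: str | Path, include_availability: bool = False
) -> None:
    """Serialize an expanded feature table; unavailable values as empty cells."""
    out = table.values.copy()
    if include_availability:
        for name in table.available.columns:
            out[f"{name}__available"] = table.available[name]
    out.index.name = "sample_id"
    out.to_csv(path)
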