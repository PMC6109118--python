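"""Domain types, derived quantities and CSV I/O for stratigraphic profiles.

A :class:`Sample` is one stratigraphic horizon's organic sulfur and carbon
geochemistry: whole-rock TOC and carbonate contents, kerogen sulfur content,
stable isotope ratios and, where measured, the fractional speciation of
organic sulfur across bonding environments (:class:`Moiety`).  A
:class:`Profile` is an ordered (strictly upward) collection of samples.

Conventions
-----------
* S:C is the molar ratio of organic sulfur to organic carbon.  The functions
  here return it as a mol/mol fraction; report it multiplied by 100 when a
  percent figure is wanted (0.051 -> "5.1 %").
* δ34S is ‰ vs VCDT, δ13C is ‰ vs VPDB.
* "Carbonate-free basis" divides a whole-rock concentration by the
  non-carbonate mass fraction of the rock.
* Speciation maps are renormalized to sum to 1 on ingest; the raw
  (pre-normalization) sum is retained on the sample because externally fitted
  abundances frequently over- or under-close.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "S_ATOMIC_MASS",
    "C_ATOMIC_MASS",
    "Lithology",
    "Moiety",
    "TocClass",
    "REDUCED_MOIETIES",
    "OXIDIZED_MOIETIES",
    "Sample",
    "Profile",
    "GeochemError",
    "MissingFieldError",
    "ProfileValidationError",
    "molar_sc",
    "carbonate_free",
    "propagate_sc_sd",
    "toc_class",
    "read_profile",
    "write_profile",
    "PROFILE_COLUMNS",
]

logger = logging.getLogger(__name__)

S_ATOMIC_MASS = 32.06  # g/mol
C_ATOMIC_MASS = 12.011  # g/mol

#: Tolerated deviation of a raw speciation sum from closure before rejection.
SPECIATION_CLOSURE_TOL = 0.25


class GeochemError(ValueError):
    """Invalid geochemical input."""


class MissingFieldError(GeochemError):
    """An operation required an optional field that is absent."""


class ProfileValidationError(GeochemError):
    """A profile or profile file violates a structural invariant."""


class Lithology(str, enum.Enum):
    SHALE = "shale"
    MARL = "marl"
    LIMESTONE = "limestone"
    UNKNOWN = "unknown"


class Moiety(str, enum.Enum):
    """Organic sulfur bonding environments resolved by K-edge spectroscopy."""

    MONOSULFIDE = "monosulfide"
    DISULFIDE = "disulfide"
    AROMATIC = "aromatic"
    SULFONATE = "sulfonate"
    SULFOXIDE = "sulfoxide"
    SULFATE_ESTER = "sulfate_ester"


REDUCED_MOIETIES = frozenset(
    {Moiety.MONOSULFIDE, Moiety.DISULFIDE, Moiety.AROMATIC}
)
OXIDIZED_MOIETIES = frozenset(
    {Moiety.SULFONATE, Moiety.SULFOXIDE, Moiety.SULFATE_ESTER}
)


class TocClass(str, enum.Enum):
    RICH = "rich"
    LEAN = "lean"


def molar_sc(s_wt: float, c_wt: float) -> float:
    """Molar S:C ratio (mol/mol fraction) from wt% sulfur and carbon.

    Invariant to rescaling both inputs by a common factor, so whole-rock and
    carbonate-free inputs give the same ratio.
    """
    if c_wt <= 0:
        raise GeochemError(f"carbon content must be positive, got {c_wt}")
    if s_wt < 0:
        raise GeochemError(f"sulfur content must be non-negative, got {s_wt}")
    return (s_wt / S_ATOMIC_MASS) / (c_wt / C_ATOMIC_MASS)


def carbonate_free(value: float, carbonate: float) -> float:
    """Convert a whole-rock wt% to the carbonate-free residue basis."""
    if not 0 <= carbonate < 100:
        raise GeochemError(f"carbonate wt% must lie in [0, 100), got {carbonate}")
    return value / (1.0 - carbonate / 100.0)


def propagate_sc_sd(s_wt: float, s_sd: float, c_wt: float, c_sd: float) -> float:
    """1 s.d. of the molar S:C ratio from replicate reproducibilities.

    Relative variances add in quadrature:
    ``sd = ratio * sqrt((s_sd/s_wt)**2 + (c_sd/c_wt)**2)``.
    """
    if s_sd < 0 or c_sd < 0:
        raise GeochemError("standard deviations must be non-negative")
    if (s_wt <= 0 and s_sd > 0) or (c_wt <= 0 and c_sd > 0):
        raise GeochemError("zero mean with nonzero sd: relative error undefined")
    ratio = molar_sc(s_wt, c_wt)
    rel_s = s_sd / s_wt if s_sd > 0 else 0.0
    rel_c = c_sd / c_wt if c_sd > 0 else 0.0
    return ratio * math.hypot(rel_s, rel_c)


@dataclass
class Sample:
    """One stratigraphic horizon's geochemistry.

    ``toc``, ``carbonate`` and ``s_org`` are wt% of whole rock; optional
    fields default to ``None`` and operations that need them raise
    :class:`MissingFieldError` rather than propagating NaN.
    """

    height: float
    lithology: Lithology = Lithology.UNKNOWN
    toc: float = 0.0
    carbonate: float = 0.0
    s_org: float | None = None
    d34s: float | None = None
    d13c: float | None = None
    speciation: dict[Moiety, float] | None = None
    replicate_sd: dict[str, float] | None = None
    speciation_raw_sum: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.lithology = Lithology(self.lithology)
        if not 0 <= self.toc <= 100:
            raise GeochemError(f"toc {self.toc} outside [0, 100] wt%")
        if not 0 <= self.carbonate < 100:
            raise GeochemError(f"carbonate {self.carbonate} outside [0, 100) wt%")
        if self.toc + self.carbonate > 100:
            raise GeochemError(
                f"toc + carbonate = {self.toc + self.carbonate} exceeds 100 wt%"
            )
        if self.s_org is not None and self.s_org < 0:
            raise GeochemError(f"s_org {self.s_org} negative")
        if self.speciation is not None:
            self._normalize_speciation()

    def _normalize_speciation(self) -> None:
        spec = {Moiety(k): float(v) for k, v in self.speciation.items()}
        if any(v < 0 or v > 1 for v in spec.values()):
            raise GeochemError("speciation fractions must lie in [0, 1]")
        raw_sum = sum(spec.values())
        if raw_sum <= 0:
            raise GeochemError("speciation fractions sum to zero")
        if abs(raw_sum - 1.0) > SPECIATION_CLOSURE_TOL:
            raise GeochemError(
                f"speciation sum {raw_sum:.3f} too far from closure to renormalize"
            )
        if abs(raw_sum - 1.0) > 1e-9:
            logger.debug(
                "renormalizing speciation at height %s (raw sum %.4f)",
                self.height,
                raw_sum,
            )
            spec = {k: v / raw_sum for k, v in spec.items()}
        self.speciation = spec
        if self.speciation_raw_sum is None:
            self.speciation_raw_sum = raw_sum

    # -- derived quantities -----------------------------------------------

    @property
    def sc(self) -> float:
        """Molar S:C ratio of the kerogen (mol/mol fraction)."""
        if self.s_org is None:
            raise MissingFieldError(f"sample at {self.height} m: s_org missing")
        return molar_sc(self.s_org, self.toc)

    @property
    def toc_carbonate_free(self) -> float:
        return carbonate_free(self.toc, self.carbonate)

    def reduced_fraction(self) -> float:
        """Summed fractional abundance of reduced organic sulfur moieties."""
        if self.speciation is None:
            raise MissingFieldError(f"sample at {self.height} m: speciation missing")
        return sum(v for k, v in self.speciation.items() if k in REDUCED_MOIETIES)


def toc_class(sample: "Sample | float", threshold: float = 1.0) -> TocClass:
    """Classify a sample (or bare TOC value) as organic-rich or -lean.

    The boundary is strict: ``toc == threshold`` is lean.
    """
    toc = sample.toc if isinstance(sample, Sample) else float(sample)
    return TocClass.RICH if toc > threshold else TocClass.LEAN


@dataclass
class Profile:
    """Ordered stratigraphic collection of samples (heights strictly increasing)."""

    samples: list[Sample]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ProfileValidationError("profile must contain at least one sample")
        heights = [s.height for s in self.samples]
        bad = [
            i
            for i in range(1, len(heights))
            if heights[i] <= heights[i - 1]
        ]
        if bad:
            rows = ", ".join(
                f"row {i}: {heights[i - 1]} -> {heights[i]}" for i in bad
            )
            raise ProfileValidationError(
                f"heights must be strictly increasing; offending rows: {rows}"
            )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def heights(self) -> np.ndarray:
        return np.array([s.height for s in self.samples])

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with one column per CSV field (NaN = missing)."""
        rows = []
        for s in self.samples:
            row = {
                "height_m": s.height,
                "lithology": s.lithology.value,
                "toc_wt_pct": s.toc,
                "carbonate_wt_pct": s.carbonate,
                "sorg_wt_pct": np.nan if s.s_org is None else s.s_org,
                "d34s_vcdt_permil": np.nan if s.d34s is None else s.d34s,
                "d13c_vpdb_permil": np.nan if s.d13c is None else s.d13c,
            }
            for moiety in Moiety:
                key = f"frac_{moiety.value}"
                if s.speciation is None or moiety not in s.speciation:
                    row[key] = np.nan
                else:
                    row[key] = s.speciation[moiety]
            rows.append(row)
        return pd.DataFrame(rows, columns=PROFILE_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metadata: dict | None = None) -> "Profile":
        samples = []
        for _, row in df.iterrows():
            spec = {}
            for moiety in Moiety:
                v = row.get(f"frac_{moiety.value}", np.nan)
                if pd.notna(v):
                    spec[moiety] = float(v)
            litho = row.get("lithology", Lithology.UNKNOWN.value)
            if pd.isna(litho) or litho == "":
                litho = Lithology.UNKNOWN.value
            samples.append(
                Sample(
                    height=float(row["height_m"]),
                    lithology=litho,
                    toc=float(row["toc_wt_pct"]),
                    carbonate=float(row["carbonate_wt_pct"]),
                    s_org=_opt(row.get("sorg_wt_pct")),
                    d34s=_opt(row.get("d34s_vcdt_permil")),
                    d13c=_opt(row.get("d13c_vpdb_permil")),
                    speciation=spec or None,
                )
            )
        return cls(samples=samples, metadata=metadata or {})


def _opt(v) -> float | None:
    return None if v is None or pd.isna(v) else float(v)


PROFILE_COLUMNS = [
    "height_m",
    "lithology",
    "toc_wt_pct",
    "carbonate_wt_pct",
    "sorg_wt_pct",
    "d34s_vcdt_permil",
    "d13c_vpdb_permil",
] + [f"frac_{m.value}" for m in Moiety]


def read_profile(path) -> Profile:
    """Read a stratigraphic profile from CSV.

    Unknown columns are ignored with a warning; missing optional cells stay
    missing.  Non-monotone heights or invariant violations raise
    :class:`ProfileValidationError` / :class:`GeochemError` naming the rows.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in PROFILE_COLUMNS]
    if unknown:
        warnings.warn(f"{path.name}: ignoring unknown columns {unknown}")
        df = df.drop(columns=unknown)
    required = {"height_m", "toc_wt_pct", "carbonate_wt_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ProfileValidationError(f"{path.name}: missing columns {sorted(missing)}")
    return Profile.from_dataframe(df, metadata={"source": str(path)})


def write_profile(profile: Profile, path) -> None:
    """Write a profile to CSV (UTF-8, '.' decimal, empty cell = missing).

    Floats are written at shortest round-trip precision, so a read/write
    cycle is bit-lossless.
    """
    df = profile.to_dataframe()
    df.to_csv(path, index=False)
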