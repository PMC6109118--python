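"""Data-side statistics on stratigraphic profiles.

The observational fingerprint of sulfurization-controlled preservation is a
set of associations across a section: molar S:C of the kerogen rises with TOC
(the most organic-rich rocks are the most intensely sulfurized), δ34S of
organic sulfur falls as S:C rises (open-system sulfurization with full
microbial fractionation in the organic-rich intervals, closed-system
distillation in the lean ones), and the moiety mixture shifts between
lithological regimes.  This module quantifies those associations: ordinary
least-squares regression of S:C on TOC, TOC-class group summaries, the
rich/lean contrast, and the δ34S–S:C correlation.

S:C enters all statistics in percent (mol/mol x 100); TOC in wt%, on a
whole-rock or carbonate-free basis as requested.  The rich/lean partition
always uses the whole-rock 1.0 wt% threshold, even for carbonate-free
statistics, because the class definition is a whole-rock one.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .geochem import (
    MissingFieldError,
    GeochemError,
    Moiety,
    Profile,
    Sample,
    TocClass,
    toc_class,
)

__all__ = [
    "Basis",
    "RegressionResult",
    "GroupSummary",
    "regress_sc_vs_toc",
    "group_contrast",
    "group_summaries",
    "d34s_sc_association",
]


class Basis(str, enum.Enum):
    WHOLE_ROCK = "whole_rock"
    CARBONATE_FREE = "carbonate_free"


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of molar S:C (%) on TOC (wt%)."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    basis: Basis

    def predict(self, toc: float) -> float:
        return self.intercept + self.slope * toc


@dataclass(frozen=True)
class GroupSummary:
    """Mean and 1σ per variable for one TOC class."""

    group: TocClass
    n: int
    stats: dict[str, tuple[float, float, int]]  # var -> (mean, sd, n_valid)

    def mean(self, var: str) -> float:
        return self.stats[var][0]

    def sd(self, var: str) -> float:
        return self.stats[var][1]


def _toc_on_basis(sample: Sample, basis: Basis) -> float:
    if basis is Basis.CARBONATE_FREE:
        return sample.toc_carbonate_free
    return sample.toc


def _sc_toc_pairs(profile: Profile, basis: Basis) -> tuple[np.ndarray, np.ndarray]:
    toc, sc = [], []
    for s in profile:
        if s.s_org is None or s.toc <= 0:
            continue
        toc.append(_toc_on_basis(s, basis))
        sc.append(100.0 * s.sc)
    return np.array(toc), np.array(sc)


def regress_sc_vs_toc(
    profile: Profile, basis: Basis | str = Basis.WHOLE_ROCK
) -> RegressionResult:
    """Ordinary least squares of molar S:C (%) on TOC (wt%).

    R² is the squared Pearson correlation.  The molar ratio itself is
    basis-independent (sulfur and carbon rescale together), so the basis
    only moves the TOC axis.
    """
    basis = Basis(basis)
    toc, sc = _sc_toc_pairs(profile, basis)
    if len(toc) < 3:
        raise MissingFieldError(
            f"regression needs >= 3 samples with s_org and positive toc, got {len(toc)}"
        )
    if np.ptp(toc) == 0:
        raise GeochemError("TOC has zero variance: regression undefined")
    fit = stats.linregress(toc, sc)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(toc),
        basis=basis,
    )


def group_contrast(
    profile: Profile,
    variable: str = "toc",
    basis: Basis | str = Basis.WHOLE_ROCK,
    threshold: float = 1.0,
) -> float:
    """Percent difference of the lean-group mean below the rich-group mean.

    ``100 * (1 - mean_lean / mean_rich)`` for the requested variable
    (``toc`` or ``sc``).  Grouping is by whole-rock TOC against ``threshold``.
    """
    basis = Basis(basis)
    values: dict[TocClass, list[float]] = {TocClass.RICH: [], TocClass.LEAN: []}
    for s in profile:
        cls = toc_class(s, threshold)
        if variable == "toc":
            values[cls].append(_toc_on_basis(s, basis))
        elif variable == "sc":
            if s.s_org is None or s.toc <= 0:
                continue
            values[cls].append(100.0 * s.sc)
        else:
            raise ValueError(f"unknown variable {variable!r}")
    for cls, vals in values.items():
        if not vals:
            raise GeochemError(f"group {cls.value!r} is empty: contrast undefined")
    mean_rich = float(np.mean(values[TocClass.RICH]))
    mean_lean = float(np.mean(values[TocClass.LEAN]))
    if mean_rich == 0:
        raise GeochemError("rich-group mean is zero: contrast undefined")
    return 100.0 * (1.0 - mean_lean / mean_rich)


_SUMMARY_VARS = ["toc", "sc", "d34s"] + [f"frac_{m.value}" for m in Moiety]


def _sample_value(s: Sample, var: str) -> float | None:
    if var == "toc":
        return s.toc
    if var == "sc":
        return None if (s.s_org is None or s.toc <= 0) else 100.0 * s.sc
    if var == "d34s":
        return s.d34s
    if var.startswith("frac_"):
        if s.speciation is None:
            return None
        return s.speciation.get(Moiety(var[5:]), 0.0)
    raise ValueError(f"unknown variable {var!r}")


def group_summaries(
    profile: Profile, threshold: float = 1.0
) -> list[GroupSummary]:
    """Per-TOC-class means ± 1σ of TOC, S:C (%), δ34S and speciation fractions.

    Missing values are excluded variable-wise, with the effective n recorded
    per variable.  If a group is empty a warning is issued and only the
    populated group is returned.
    """
    groups: dict[TocClass, list[Sample]] = {TocClass.RICH: [], TocClass.LEAN: []}
    for s in profile:
        groups[toc_class(s, threshold)].append(s)
    out = []
    for cls in (TocClass.RICH, TocClass.LEAN):
        members = groups[cls]
        if not members:
            warnings.warn(f"no {cls.value} samples in profile")
            continue
        var_stats = {}
        for var in _SUMMARY_VARS:
            vals = [v for s in members if (v := _sample_value(s, var)) is not None]
            if vals:
                arr = np.array(vals)
                sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
                var_stats[var] = (float(arr.mean()), sd, len(arr))
        out.append(GroupSummary(group=cls, n=len(members), stats=var_stats))
    return out


def d34s_sc_association(profile: Profile) -> dict:
    """Pearson correlation between δ34S of organic S and molar S:C.

    Returns ``{"r", "p", "n"}``; on sections with the open/closed-system
    polarity, r is negative (abundant, high-S:C organic sulfur is strongly
    34S-depleted).
    """
    d34s, sc = [], []
    for s in profile:
        if s.d34s is None or s.s_org is None or s.toc <= 0:
            continue
        d34s.append(s.d34s)
        sc.append(100.0 * s.sc)
    if len(d34s) < 3:
        raise MissingFieldError(
            f"association needs >= 3 samples with d34s and s_org, got {len(d34s)}"
        )
    r, p = stats.pearsonr(d34s, sc)
    return {"r": float(r), "p": float(p), "n": len(d34s)}
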