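"""Forward model of organic carbon flow through three sequential environments.

Export production (``f0``, normalized to 1) transits three boxes — A: sinking
particles below the photic zone, B: the sediment–water interface, C: deeper
sediments.  In each box every reactivity class of the biomass pool can be
remineralized to CO2 by heterotrophs or abiotically sulfurized into a
refractory "preserved" pool; whatever remains passes to the next box.  Bulk
biomass is split into discrete reactivity classes (a multi-G representation):
class *i* reacts with pseudo-first-order rate constants ``k_het * g[i]`` and
``k_sulf * g[i]``, i.e. a single reactivity spectrum scales both reactions,
because the same functional groups are favourable for heterotrophy and for
sulfide addition.  Electron-acceptor and sulfide dependence is collapsed into
the rate constants (all substrates except organic matter are replete).

Two kinetic idealizations of a box are available:

``mixed``
    the box is a well-mixed steady-state reservoir with turnover time tau;
    the surviving fraction of class *i* is ``1 / (1 + (h + q) * tau)``.
``continuous``
    organic matter moves strictly downward while its concentration decays
    continuously; the surviving fraction is ``exp(-(h + q) * tau)``.

with ``h = k_het * g[i]`` and ``q = k_sulf * g[i]`` (q = 0 where sulfurization
is switched off).  Of the material lost, the share ``q / (h + q)`` becomes
refractory sulfurized carbon carrying sulfur at the box's product S:C ratio,
and ``h / (h + q)`` is remineralized.  Sulfurized carbon is fully refractory
downstream: it is never re-remineralized or re-sulfurized.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Kinetics",
    "ReactivitySpectrum",
    "BoxSpec",
    "ModelParams",
    "FluxState",
    "BoxLedger",
    "ChainResult",
    "box_transit",
    "run_chain",
    "preserved_sc",
    "WEEKS_PER_YEAR",
    "DEFAULT_G",
]

#: Conversion between the two time units used for box turnover.
WEEKS_PER_YEAR = 52.1775

#: Default decade-spaced reactivity multipliers for the three classes.
DEFAULT_G = (1.0, 1e-2, 1e-4)


class Kinetics(str, enum.Enum):
    """Idealization of transport/reaction within a box."""

    MIXED = "mixed"
    CONTINUOUS = "continuous"


class BoxModelError(ValueError):
    """Invalid state, parameters or box specification."""


@dataclass(frozen=True)
class ReactivitySpectrum:
    """Multi-G reactivity classes: multipliers ``g`` and initial fractions ``f``.

    ``g`` must be strictly decreasing with the most labile class first and
    normalized so that ``g[0] == 1`` (the base rate constants in
    :class:`ModelParams` refer to class 1).  ``f`` are the initial fractional
    abundances of export production and must sum to 1.
    """

    g: tuple[float, float, float] = DEFAULT_G
    f: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.g)
        f = tuple(float(x) for x in self.f)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "f", f)
        if len(g) != len(f):
            raise BoxModelError("g and f must have equal length")
        if any(x <= 0 for x in g):
            raise BoxModelError("reactivity multipliers must be positive")
        if any(b >= a for a, b in zip(g, g[1:])):
            raise BoxModelError("reactivity multipliers must be strictly decreasing")
        if not math.isclose(g[0], 1.0, rel_tol=0, abs_tol=1e-12):
            raise BoxModelError("g[0] must equal 1 (base-rate normalization)")
        if any(x < 0 for x in f):
            raise BoxModelError("initial fractions must be non-negative")
        if not math.isclose(sum(f), 1.0, rel_tol=0, abs_tol=1e-9):
            raise BoxModelError(f"initial fractions must sum to 1, got {sum(f)!r}")

    @property
    def n_classes(self) -> int:
        return len(self.g)

    def with_fractions(self, f2: float, f3: float) -> "ReactivitySpectrum":
        """Return a copy with fitted class-2/class-3 fractions (f1 = 1-f2-f3)."""
        return replace(self, f=(1.0 - f2 - f3, f2, f3))


@dataclass(frozen=True)
class BoxSpec:
    """One environment: turnover time, sulfurization switch and product S:C.

    ``tau`` is in years; ``sc_product`` is the molar S:C ratio (as a fraction,
    not percent) of organic matter sulfurized in this box.  ``tau == 0`` is the
    degenerate no-exposure box and passes material through unchanged.
    """

    name: str
    tau: float
    sulfurization_on: bool
    sc_product: float
    kinetics: Kinetics = Kinetics.MIXED

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise BoxModelError(f"box {self.name}: negative turnover time {self.tau}")
        if not 0.0 <= self.sc_product <= 0.10:
            raise BoxModelError(
                f"box {self.name}: sc_product {self.sc_product} outside [0, 0.10]"
            )
        object.__setattr__(self, "kinetics", Kinetics(self.kinetics))


@dataclass(frozen=True)
class ModelParams:
    """Base rate constants (1/yr, class-1) plus the reactivity spectrum."""

    k_het: float
    k_sulf: float
    spectrum: ReactivitySpectrum = field(default_factory=ReactivitySpectrum)

    def __post_init__(self) -> None:
        if self.k_het <= 0:
            raise BoxModelError("k_het must be positive")
        if self.k_sulf < 0:
            raise BoxModelError("k_sulf must be non-negative")


@dataclass(frozen=True)
class FluxState:
    """Carbon and organic sulfur tracked through the box chain.

    All carbon pools are fractions of export production f0 = 1; ``sulfurized_s``
    is mol S per mol C of f0.  ``sc_biomass`` is the molar S:C of the surviving
    biomass (r_bio), carried unchanged and lost proportionally with
    remineralized carbon.
    """

    biomass_c: tuple[float, ...]
    sulfurized_c: float = 0.0
    sulfurized_s: float = 0.0
    sc_biomass: float = 0.0

    def __post_init__(self) -> None:
        bc = tuple(float(x) for x in self.biomass_c)
        object.__setattr__(self, "biomass_c", bc)
        if any(x < 0 for x in bc) or self.sulfurized_c < 0 or self.sulfurized_s < 0:
            raise BoxModelError("flux components must be non-negative")

    @classmethod
    def initial(cls, spectrum: ReactivitySpectrum, r_bio: float = 0.0) -> "FluxState":
        """Export production split across reactivity classes, no sulfurized OM yet."""
        return cls(biomass_c=spectrum.f, sc_biomass=r_bio)

    @property
    def total_biomass_c(self) -> float:
        return sum(self.biomass_c)

    @property
    def total_c(self) -> float:
        return self.total_biomass_c + self.sulfurized_c

    @property
    def total_s(self) -> float:
        return self.sulfurized_s + self.sc_biomass * self.total_biomass_c

    @property
    def sc_total(self) -> float:
        """Bulk molar S:C of the flux (fraction)."""
        total = self.total_c
        if total <= 0:
            raise BoxModelError("S:C undefined for zero carbon flux")
        return self.total_s / total


@dataclass(frozen=True)
class BoxLedger:
    """Carbon bookkeeping for one box passage (fractions of f0)."""

    remineralized_c: float
    newly_sulfurized_c: float


def _survival(h: float, q: float, tau: float, kinetics: Kinetics) -> float:
    x = (h + q) * tau
    if x == 0.0:
        return 1.0
    if kinetics is Kinetics.MIXED:
        return 1.0 / (1.0 + x)
    return math.exp(-x)


def box_transit(
    state: FluxState, box: BoxSpec, params: ModelParams
) -> tuple[FluxState, BoxLedger]:
    """Pass a flux state through one box.

    Per class, of the lost fraction ``1 - phi``, the share ``q/(h+q)`` joins the
    refractory sulfurized pool (sulfur added at ``box.sc_product`` per carbon)
    and ``h/(h+q)`` is remineralized.  Previously sulfurized carbon and its
    sulfur pass through untouched.  Carbon is conserved exactly:
    influx = biomass out + sulfurized out + remineralized.
    """
    g = params.spectrum.g
    if len(g) != len(state.biomass_c):
        raise BoxModelError("state and spectrum class counts differ")
    q_on = 1.0 if box.sulfurization_on else 0.0
    out_biomass = []
    remineralized = 0.0
    newly_sulfurized = 0.0
    for gi, bi in zip(g, state.biomass_c):
        h = params.k_het * gi
        q = params.k_sulf * gi * q_on
        phi = _survival(h, q, box.tau, box.kinetics)
        out_biomass.append(bi * phi)
        lost = bi * (1.0 - phi)
        if lost > 0.0:
            sulf_share = q / (h + q)
            newly_sulfurized += lost * sulf_share
            remineralized += lost * (1.0 - sulf_share)
    new_state = FluxState(
        biomass_c=tuple(out_biomass),
        sulfurized_c=state.sulfurized_c + newly_sulfurized,
        sulfurized_s=state.sulfurized_s + newly_sulfurized * box.sc_product,
        sc_biomass=state.sc_biomass,
    )
    ledger = BoxLedger(remineralized_c=remineralized, newly_sulfurized_c=newly_sulfurized)
    return new_state, ledger


@dataclass(frozen=True)
class ChainResult:
    """Fluxes after each box of the chain plus the preserved totals.

    ``flux_after_*`` are total carbon (biomass + sulfurized) as fractions of
    f0; ``preserved_total_c`` is the flux after the final box — sulfurized OM
    from all boxes plus surviving biomass exported from box C.
    """

    states: tuple[FluxState, ...]
    ledgers: tuple[BoxLedger, ...]
    r_bio: float

    @property
    def flux_after_a(self) -> float:
        return self.states[-3].total_c

    @property
    def flux_after_b(self) -> float:
        return self.states[-2].total_c

    @property
    def flux_after_c(self) -> float:
        return self.states[-1].total_c

    @property
    def preserved_total_c(self) -> float:
        return self.flux_after_c

    @property
    def sc_after_b(self) -> float:
        return self.states[-2].sc_total

    @property
    def preserved_sc(self) -> float:
        return preserved_sc(self)


def run_chain(
    params: ModelParams,
    boxes: Sequence[BoxSpec],
    r_bio: float = 0.0,
) -> ChainResult:
    """Run export production sequentially through the boxes.

    ``boxes`` is ordered surface-down (A, B, C for the standard chain; a split
    scenario may insert sub-boxes, in which case the ``flux_after_b`` /
    ``sc_after_b`` checkpoints refer to positions counted from the end:
    the final box is always C).
    """
    if len(boxes) < 1:
        raise BoxModelError("at least one box required")
    state = FluxState.initial(params.spectrum, r_bio=r_bio)
    states = [state]
    ledgers = []
    for box in boxes:
        state, ledger = box_transit(state, box, params)
        states.append(state)
        ledgers.append(ledger)
    return ChainResult(states=tuple(states), ledgers=tuple(ledgers), r_bio=r_bio)


def preserved_sc(result: ChainResult) -> float:
    """Molar S:C (fraction) of the total preserved organic matter.

    Mass-weighted mean over surviving biomass (at r_bio) and the sulfurized
    pools (each at its box's product ratio); necessarily lies within the convex
    hull of those endmember ratios.
    """
    final = result.states[-1]
    if final.total_c <= 0:
        raise BoxModelError("no preserved carbon: S:C undefined")
    return final.sc_total
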