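"""Monte Carlo calibration of the box model against Cariaco Basin constraints.

The environmental parameters — box turnover times and the product S:C ratios —
are only known as plausible ranges, so calibration proceeds by ensemble: draw
an environment from the assigned ranges, then solve a weighted least-squares
problem for the four unknowns (base heterotrophy rate constant, base
sulfurization rate constant, and the initial fractions of the second and third
reactivity classes) against five constraints: the carbon flux leaving boxes A,
B and C (0.51, 0.38, 0.30 of export production) and the bulk molar S:C of the
flux leaving boxes B and C (2.0 %, 3.7 %).  Repeating this 1000 times yields an
ensemble of calibrated members whose spread reflects the environmental
uncertainty.  Sulfurization is active in all three boxes during calibration
(the modern-analog control configuration: chemocline above box A).

The public surface follows the fitted-model idiom: build a
:class:`SulfurizationModel` from constraints and ranges, call
:meth:`~SulfurizationModel.fit`, and work with the returned
:class:`CalibrationResults` (scenario experiments hang off the results
object; see :mod:`sulfoc.scenarios`).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import leastsq

from .boxmodel import (
    WEEKS_PER_YEAR,
    BoxSpec,
    ChainResult,
    Kinetics,
    ModelParams,
    ReactivitySpectrum,
    run_chain,
)

__all__ = [
    "ParamRanges",
    "CariacoConstraints",
    "EnvDraw",
    "FitOptions",
    "CalibratedMember",
    "SulfurizationModel",
    "CalibrationResults",
    "draw_env",
    "solve_unknowns",
    "calibrate_ensemble",
    "load_packaged_config",
]

CONSTRAINT_NAMES = ("c_a_to_b", "c_b_to_c", "c_final", "sc_b_to_c", "sc_final")


class CalibrationError(RuntimeError):
    """Calibration could not be completed (e.g. excessive attrition)."""


def load_packaged_config() -> dict:
    """Parsed contents of the packaged ``constraints.yaml``."""
    ref = importlib.resources.files("sulfoc.config") / "constraints.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ParamRanges:
    """Assigned environmental parameter ranges (min, max).

    Turnover times carry their natural units (weeks for box A, years for B
    and C); S:C ratios are molar fractions.
    """

    tau_a_weeks: tuple[float, float] = (0.5, 3.0)
    tau_b_years: tuple[float, float] = (2.0, 500.0)
    tau_c_years: tuple[float, float] = (2000.0, 20000.0)
    sc_bio: tuple[float, float] = (0.0, 0.01)
    sc_rapid: tuple[float, float] = (0.04, 0.05)
    sc_gradual: tuple[float, float] = (0.01, 0.03)

    def __post_init__(self) -> None:
        for name in (
            "tau_a_weeks",
            "tau_b_years",
            "tau_c_years",
            "sc_bio",
            "sc_rapid",
            "sc_gradual",
        ):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name}: invalid range ({lo}, {hi})")

    @classmethod
    def from_dict(cls, d: dict) -> "ParamRanges":
        return cls(**{k: tuple(v) for k, v in d.items()})

    @classmethod
    def packaged(cls) -> "ParamRanges":
        return cls.from_dict(load_packaged_config()["ranges"])


@dataclass(frozen=True)
class CariacoConstraints:
    """Calibration targets with 1-sigma fit tolerances.

    ``c_flux``: carbon flux (fraction of f0) leaving each box; ``sc``: bulk
    molar S:C (fraction) of the flux leaving boxes B and C.  The A-to-B S:C is
    poorly constrained observationally and is not a target.
    """

    c_flux: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "a_to_b": (0.51, 0.15),
            "b_to_c": (0.38, 0.05),
            "c_to_final": (0.30, 0.08),
        }
    )
    sc: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "b_to_c": (0.020, 0.005),
            "c_to_final": (0.037, 0.005),
        }
    )

    def __post_init__(self) -> None:
        for group in (self.c_flux, self.sc):
            for key, (target, sigma) in group.items():
                if sigma <= 0:
                    raise ValueError(f"{key}: sigma must be positive")
                if not 0 < target < 1:
                    raise ValueError(f"{key}: target must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "CariacoConstraints":
        return cls(
            c_flux={k: (v["target"], v["sigma"]) for k, v in d["c_flux"].items()},
            sc={k: (v["target"], v["sigma"]) for k, v in d["sc"].items()},
        )

    @classmethod
    def packaged(cls) -> "CariacoConstraints":
        return cls.from_dict(load_packaged_config()["constraints"])

    @property
    def targets(self) -> np.ndarray:
        return np.array(
            [
                self.c_flux["a_to_b"][0],
                self.c_flux["b_to_c"][0],
                self.c_flux["c_to_final"][0],
                self.sc["b_to_c"][0],
                self.sc["c_to_final"][0],
            ]
        )

    @property
    def sigmas(self) -> np.ndarray:
        return np.array(
            [
                self.c_flux["a_to_b"][1],
                self.c_flux["b_to_c"][1],
                self.c_flux["c_to_final"][1],
                self.sc["b_to_c"][1],
                self.sc["c_to_final"][1],
            ]
        )


@dataclass(frozen=True)
class EnvDraw:
    """One Monte Carlo draw of environmental parameters (times in years)."""

    tau_a: float
    tau_b: float
    tau_c: float
    sc_bio: float
    sc_rapid: float
    sc_gradual: float

    def in_ranges(self, ranges: ParamRanges, rel_tol: float = 1e-9) -> bool:
        pairs = [
            (self.tau_a * WEEKS_PER_YEAR, ranges.tau_a_weeks),
            (self.tau_b, ranges.tau_b_years),
            (self.tau_c, ranges.tau_c_years),
            (self.sc_bio, ranges.sc_bio),
            (self.sc_rapid, ranges.sc_rapid),
            (self.sc_gradual, ranges.sc_gradual),
        ]
        return all(
            lo * (1 - rel_tol) - 1e-15 <= v <= hi * (1 + rel_tol) + 1e-15
            for v, (lo, hi) in pairs
        )


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def draw_env(rng: np.random.Generator, ranges: ParamRanges) -> EnvDraw:
    """Draw one environment from the assigned ranges.

    The multi-decade turnover times of boxes B and C are scale parameters and
    are drawn log-uniformly; box A's narrow range and all S:C ratios are drawn
    uniformly.  Box A weeks are converted to years.
    """
    return EnvDraw(
        tau_a=_uniform(rng, *ranges.tau_a_weeks) / WEEKS_PER_YEAR,
        tau_b=_log_uniform(rng, *ranges.tau_b_years),
        tau_c=_log_uniform(rng, *ranges.tau_c_years),
        sc_bio=_uniform(rng, *ranges.sc_bio),
        sc_rapid=_uniform(rng, *ranges.sc_rapid),
        sc_gradual=_uniform(rng, *ranges.sc_gradual),
    )


@dataclass(frozen=True)
class FitOptions:
    """Solver configuration for one calibration solve.

    ``n_starts`` log-spaced initial guesses guard against local minima in the
    non-convex 4-parameter landscape; a member is accepted ("converged") when
    every weighted residual has magnitude at most ``residual_bound``.
    """

    n_starts: int = 8
    residual_bound: float = 2.0
    kinetics: Kinetics = Kinetics.MIXED
    g: tuple[float, float, float] = ReactivitySpectrum().g
    max_nfev: int = 400
    xtol: float = 1e-10


@dataclass(frozen=True)
class CalibratedMember:
    """One calibrated ensemble member: environment draw + fitted unknowns."""

    draw: EnvDraw
    params: ModelParams
    residuals: tuple[float, ...]
    converged: bool
    n_restarts: int

    @property
    def f2(self) -> float:
        return self.params.spectrum.f[1]

    @property
    def f3(self) -> float:
        return self.params.spectrum.f[2]


def control_boxes(draw: EnvDraw, kinetics: Kinetics = Kinetics.MIXED) -> list[BoxSpec]:
    """The calibration (control) configuration: sulfurization on in all boxes."""
    return boxes_for_flags(draw, (True, True, True), kinetics)


def boxes_for_flags(
    draw: EnvDraw,
    flags: tuple[bool, bool, bool],
    kinetics: Kinetics = Kinetics.MIXED,
) -> list[BoxSpec]:
    """Build the A, B, C box chain with the given sulfurization switches.

    Boxes A and B sulfurize at the rapid product ratio, box C at the gradual
    one, regardless of the switches.
    """
    return [
        BoxSpec("A", draw.tau_a, flags[0], draw.sc_rapid, kinetics),
        BoxSpec("B", draw.tau_b, flags[1], draw.sc_rapid, kinetics),
        BoxSpec("C", draw.tau_c, flags[2], draw.sc_gradual, kinetics),
    ]


def _unpack(x: np.ndarray, g: tuple[float, ...]) -> ModelParams:
    # (log10 k_het, log10 k_sulf, a2, a3) with a multinomial-logit map onto the
    # simplex so that f1 + f2 + f3 = 1 with every fraction positive.  Clipping
    # keeps the unconstrained optimizer out of overflow territory.
    x = np.clip(x, -40.0, 40.0)
    e2, e3 = np.exp(x[2]), np.exp(x[3])
    denom = 1.0 + e2 + e3
    spectrum = ReactivitySpectrum(g=g, f=(1.0 / denom, e2 / denom, e3 / denom))
    return ModelParams(k_het=10.0 ** x[0], k_sulf=10.0 ** x[1], spectrum=spectrum)


def forward_checkpoints(
    params: ModelParams,
    draw: EnvDraw,
    flags: tuple[bool, bool, bool] = (True, True, True),
    kinetics: Kinetics = Kinetics.MIXED,
) -> tuple[float, float, float, float, float]:
    """Constrained model quantities for one environment and parameter set.

    Returns ``(flux A->B, flux B->C, flux C->final, S:C B->C, S:C final)``.
    Scalar re-implementation of the :mod:`sulfoc.boxmodel` chain kept free of
    container overhead because it sits in the optimizer's inner loop; agreement
    with :func:`sulfoc.boxmodel.run_chain` is enforced by the test suite.
    """
    return _forward(
        params.k_het,
        params.k_sulf,
        params.spectrum.f,
        params.spectrum.g,
        draw,
        flags,
        Kinetics(kinetics) is Kinetics.MIXED,
    )


def _forward(
    k_het: float,
    k_sulf: float,
    f: Sequence[float],
    g: Sequence[float],
    draw: EnvDraw,
    flags: Sequence[bool],
    mixed: bool,
) -> tuple[float, float, float, float, float]:
    b = list(f)
    r_bio = draw.sc_bio
    taus = (draw.tau_a, draw.tau_b, draw.tau_c)
    sc_products = (draw.sc_rapid, draw.sc_rapid, draw.sc_gradual)
    sulf_c = 0.0
    sulf_s = 0.0
    totals = []
    scs = []
    for tau, on, sc_prod in zip(taus, flags, sc_products):
        for i, gi in enumerate(g):
            h = k_het * gi
            q = k_sulf * gi if on else 0.0
            x = (h + q) * tau
            if x == 0.0:
                continue
            phi = 1.0 / (1.0 + x) if mixed else math.exp(-x)
            lost = b[i] * (1.0 - phi)
            new_sulf = lost * q / (h + q)
            sulf_c += new_sulf
            sulf_s += new_sulf * sc_prod
            b[i] *= phi
        total_b = sum(b)
        total = total_b + sulf_c
        totals.append(total)
        scs.append((sulf_s + r_bio * total_b) / total if total > 0 else math.nan)
    return totals[0], totals[1], totals[2], scs[1], scs[2]


def _residuals(
    x: np.ndarray,
    draw: EnvDraw,
    mixed: bool,
    targets: np.ndarray,
    sigmas: np.ndarray,
    g: tuple[float, ...],
) -> np.ndarray:
    lk_het = min(max(x[0], -40.0), 40.0)
    lk_sulf = min(max(x[1], -40.0), 40.0)
    e2 = math.exp(min(max(x[2], -40.0), 40.0))
    e3 = math.exp(min(max(x[3], -40.0), 40.0))
    denom = 1.0 + e2 + e3
    f = (1.0 / denom, e2 / denom, e3 / denom)
    model = np.array(
        _forward(10.0**lk_het, 10.0**lk_sulf, f, g, draw, (True, True, True), mixed)
    )
    return (model - targets) / sigmas


def _initial_guesses(n_starts: int) -> np.ndarray:
    # Log-spaced over plausible class-1 rate constants (1/yr); sulfurization
    # slower than heterotrophy in half the starts, comparable in the other half.
    k_grid = np.logspace(0.0, 4.5, max(1, (n_starts + 1) // 2))
    guesses = []
    for lk in np.log10(k_grid):
        for ratio in (-1.0, 0.0):
            guesses.append((lk, lk + ratio, 0.0, 0.0))
    return np.array(guesses[:n_starts])


def solve_unknowns(
    draw: EnvDraw,
    constraints: CariacoConstraints,
    options: FitOptions | None = None,
) -> CalibratedMember:
    """Solve for (k_het, k_sulf, f2, f3) given one environmental draw.

    Weighted least squares over the five constraints with multistart; the
    returned member records the best solution found and whether it satisfies
    the acceptance bound on every weighted residual.
    """
    options = options or FitOptions()
    targets, sigmas = constraints.targets, constraints.sigmas
    mixed = options.kinetics is Kinetics.MIXED
    args = (draw, mixed, targets, sigmas, options.g)

    best_x = None
    best_cost = np.inf
    n_used = 0
    for x0 in _initial_guesses(options.n_starts):
        n_used += 1
        x_opt, _, info, _, ier = leastsq(
            _residuals,
            x0,
            args=args,
            full_output=True,
            maxfev=options.max_nfev,
            xtol=options.xtol,
        )
        cost = float(np.dot(info["fvec"], info["fvec"]))
        if cost < best_cost:
            best_x, best_cost = x_opt, cost
        if best_cost < 1e-18:
            break
    resid = _residuals(best_x, *args)
    converged = bool(np.max(np.abs(resid)) <= options.residual_bound)
    return CalibratedMember(
        draw=draw,
        params=_unpack(best_x, options.g),
        residuals=tuple(float(r) for r in resid),
        converged=converged,
        n_restarts=n_used,
    )


class SulfurizationModel:
    """Three-box organic carbon sulfurization model, calibrated by ensemble.

    Parameters
    ----------
    constraints
        Flux and S:C calibration targets; defaults to the packaged Cariaco
        Basin values.
    ranges
        Environmental parameter ranges to draw from; defaults packaged.
    kinetics
        Box idealization, ``mixed`` (default) or ``continuous``.
    g
        Reactivity multipliers of the three classes (decade-spaced default).
    options
        Full solver configuration; overrides ``kinetics``/``g`` if given.

    Examples
    --------
    >>> model = SulfurizationModel()
    >>> results = model.fit(n=50, seed=7)
    >>> round(results.mean_preserved, 2)  # doctest: +SKIP
    0.3
    """

    def __init__(
        self,
        constraints: CariacoConstraints | None = None,
        ranges: ParamRanges | None = None,
        kinetics: Kinetics | str = Kinetics.MIXED,
        g: tuple[float, float, float] | None = None,
        options: FitOptions | None = None,
    ) -> None:
        self.constraints = constraints or CariacoConstraints.packaged()
        self.ranges = ranges or ParamRanges.packaged()
        if options is None:
            kwargs = {"kinetics": Kinetics(kinetics)}
            if g is not None:
                kwargs["g"] = tuple(g)
            options = FitOptions(**kwargs)
        self.options = options

    @property
    def kinetics(self) -> Kinetics:
        return self.options.kinetics

    def draw_env(self, rng: np.random.Generator) -> EnvDraw:
        return draw_env(rng, self.ranges)

    def solve_unknowns(self, draw: EnvDraw) -> CalibratedMember:
        return solve_unknowns(draw, self.constraints, self.options)

    def fit(
        self,
        n: int = 1000,
        seed: int = 0,
        max_attrition: float = 0.9,
    ) -> "CalibrationResults":
        """Calibrate an ensemble of ``n`` converged members.

        Draws that fail to satisfy the residual bound are discarded and
        redrawn; if the failure rate exceeds ``max_attrition`` the run aborts
        with a summary of the worst-violated constraints.
        """
        if n < 1:
            raise ValueError("ensemble size must be at least 1")
        ss = np.random.SeedSequence(seed)
        members: list[CalibratedMember] = []
        n_attempts = 0
        failures = np.zeros(len(CONSTRAINT_NAMES))
        min_attempts_before_abort = max(20, n // 10)
        while len(members) < n:
            rng = np.random.default_rng(ss.spawn(1)[0])
            n_attempts += 1
            member = self.solve_unknowns(self.draw_env(rng))
            if member.converged:
                members.append(member)
            else:
                failures += np.abs(member.residuals) > self.options.residual_bound
                attrition = 1.0 - len(members) / n_attempts
                if n_attempts >= min_attempts_before_abort and attrition > max_attrition:
                    worst = {
                        name: int(cnt)
                        for name, cnt in zip(CONSTRAINT_NAMES, failures)
                        if cnt
                    }
                    raise CalibrationError(
                        f"calibration attrition {attrition:.0%} after "
                        f"{n_attempts} attempts; constraint violation counts: {worst}"
                    )
        return CalibrationResults(
            model=self, members=tuple(members), seed=seed, n_attempts=n_attempts
        )


class CalibrationResults:
    """A calibrated ensemble with diagnostics.

    Scenario experiments are available directly on this object
    (:meth:`run_scenario`, :meth:`percent_reduction`, :meth:`chemocline_sweep`,
    :meth:`scenario_table`) and re-run each member with its own environment
    draw and fitted parameters.
    """

    def __init__(
        self,
        model: SulfurizationModel,
        members: tuple[CalibratedMember, ...],
        seed: int,
        n_attempts: int,
    ) -> None:
        if not members:
            raise ValueError("empty ensemble")
        self.model = model
        self.members = members
        self.seed = seed
        self.n_attempts = n_attempts

    def __len__(self) -> int:
        return len(self.members)

    # -- control-run diagnostics ------------------------------------------

    def control_runs(self) -> list[ChainResult]:
        """Forward runs of each member in the calibration configuration."""
        kin = self.model.kinetics
        return [
            run_chain(m.params, control_boxes(m.draw, kin), r_bio=m.draw.sc_bio)
            for m in self.members
        ]

    @property
    def params(self) -> pd.DataFrame:
        """One row per member: draw values, fitted unknowns, residuals."""
        rows = []
        for i, m in enumerate(self.members):
            row = {
                "member": i,
                "tau_a_yr": m.draw.tau_a,
                "tau_b_yr": m.draw.tau_b,
                "tau_c_yr": m.draw.tau_c,
                "sc_bio": m.draw.sc_bio,
                "sc_rapid": m.draw.sc_rapid,
                "sc_gradual": m.draw.sc_gradual,
                "k_het": m.params.k_het,
                "k_sulf": m.params.k_sulf,
                "f1": m.params.spectrum.f[0],
                "f2": m.f2,
                "f3": m.f3,
                "converged": m.converged,
                "n_restarts": m.n_restarts,
            }
            row.update(
                {f"resid_{name}": r for name, r in zip(CONSTRAINT_NAMES, m.residuals)}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def fitted_fluxes(self) -> pd.DataFrame:
        """Per-member model fluxes and S:C at the constrained checkpoints."""
        rows = []
        for i, res in enumerate(self.control_runs()):
            rows.append(
                {
                    "member": i,
                    "flux_a_to_b": res.flux_after_a,
                    "flux_b_to_c": res.flux_after_b,
                    "flux_c_to_final": res.flux_after_c,
                    "sc_b_to_c": res.sc_after_b,
                    "sc_c_to_final": res.preserved_sc,
                }
            )
        return pd.DataFrame(rows)

    @property
    def mean_preserved(self) -> float:
        return float(self.fitted_fluxes()["flux_c_to_final"].mean())

    def to_csv(self, path) -> None:
        self.params.to_csv(path, index=False)

    def summary(self) -> str:
        """Human-readable calibration summary table."""
        fluxes = self.fitted_fluxes()
        t, s = self.model.constraints.targets, self.model.constraints.sigmas
        lines = [
            "Sulfurization box model: Monte Carlo calibration",
            "=" * 52,
            f"members: {len(self)}   attempts: {self.n_attempts}   seed: {self.seed}",
            f"kinetics: {self.model.kinetics.value}   "
            f"g = {self.model.options.g}",
            "",
            f"{'constraint':<16}{'target':>9}{'1 sigma':>9}{'ens. mean':>11}{'ens. sd':>9}",
        ]
        cols = ["flux_a_to_b", "flux_b_to_c", "flux_c_to_final", "sc_b_to_c", "sc_c_to_final"]
        for col, ti, si in zip(cols, t, s):
            lines.append(
                f"{col:<16}{ti:>9.3f}{si:>9.3f}"
                f"{fluxes[col].mean():>11.3f}{fluxes[col].std(ddof=1):>9.3f}"
            )
        p = self.params
        lines += [
            "",
            f"{'unknown':<10}{'median':>11}{'q16':>11}{'q84':>11}",
        ]
        for col in ("k_het", "k_sulf", "f2", "f3"):
            q16, q50, q84 = np.quantile(p[col], [0.16, 0.5, 0.84])
            lines.append(f"{col:<10}{q50:>11.4g}{q16:>11.4g}{q84:>11.4g}")
        return "\n".join(lines)

    # -- scenario delegation (implemented in sulfoc.scenarios) -------------

    def run_scenario(self, scenario):
        from . import scenarios

        return scenarios.run_scenario(self, scenario)

    def percent_reduction(self, scenario, control=None):
        from . import scenarios

        kwargs = {} if control is None else {"control": control}
        return scenarios.percent_reduction(self, scenario, **kwargs)

    def chemocline_sweep(self, box="A", grid=None):
        from . import scenarios

        return scenarios.chemocline_sweep(self, box, grid)

    def scenario_table(self, scenario_names=None):
        from . import scenarios

        return scenarios.sc_vs_preservation_table(self, scenario_names)


def calibrate_ensemble(
    n: int = 1000,
    seed: int = 0,
    ranges: ParamRanges | None = None,
    constraints: CariacoConstraints | None = None,
    options: FitOptions | None = None,
) -> CalibrationResults:
    """Functional entry point equivalent to ``SulfurizationModel(...).fit(...)``."""
    model = SulfurizationModel(
        constraints=constraints, ranges=ranges, options=options
    )
    return model.fit(n=n, seed=seed)
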