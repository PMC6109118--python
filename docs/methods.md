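# Methods

## Box model

The model is a steady-state mass balance for organic carbon flow through
three sequential environments: sinking particles below the photic zone (A),
the sediment–water interface (B) and deeper sediments (C). Export production
f₀ is the exogenous normalization (set to 1); there is no production model.
In each box, carbon is either remineralized by heterotrophs, converted to a
refractory sulfurized pool, or passed downstream. Both reactions are
pseudo-first-order in organic matter concentration; electron-acceptor and
sulfide dependences are collapsed into the rate constants on the assumption
that all substrates except organic matter are replete. Sulfurized carbon is
fully refractory downstream — never re-remineralized and never re-sulfurized
— so the "preserved" flux is the sum of the sulfurized pools from all boxes
plus whatever biomass survives box C.

Bulk biomass reactivity is represented by three discrete classes (multi-G)
with multipliers g = (1, 10⁻², 10⁻⁴), decade-spaced by convention; the same
spectrum scales heterotrophy and sulfurization because the two reactions
favour the same functional groups. The class multipliers are a modelling
choice, not a measured spectrum, and they are configurable
(`FitOptions(g=...)`); headline percent-reduction results carry a
correspondingly generous tolerance in the tests (±10 percentage points).

Two kinetic idealizations of a box are implemented:

* **mixed** (default): the box is a well-mixed steady-state reservoir with
  turnover time τ; survival of class i is 1/(1 + (h+q)τ), h = k_het·gᵢ,
  q = k_sulf·gᵢ.
* **continuous**: material sinks strictly downward while decaying
  continuously; survival is exp(−(h+q)τ).

Of the lost fraction, q/(h+q) is sulfurized (sulfur added at the box's
product S:C) and h/(h+q) remineralized. Carbon is conserved identically;
the test suite enforces a 10⁻¹² balance and the exp(−x) ≤ 1/(1+x) ordering
between the two modes. Scenario means under the two modes agree to within a
few percentage points of f₀ on calibrated ensembles, so the choice between
them is not load-bearing.

Sulfur bookkeeping: surviving biomass carries sulfur at the biomass ratio
r_bio and loses it proportionally with remineralized carbon; newly
sulfurized carbon carries sulfur at the box's product ratio (4–5 % in A and
B for rapid sulfurization of fresh organic matter, 1–3 % in C for gradual
sulfurization of degraded material), not additively with r_bio — the
product ratio already expresses carbon preserved per sulfur atom added.
The bulk S:C of any flux is therefore a convex combination of the
endmember ratios, which the property tests assert.

Degenerate inputs: τ = 0 or zero total rate passes material through
unchanged (no 0/0); zero preserved carbon makes S:C undefined and raises.

## Calibration

Environmental parameters are uncertain ranges, not point values: τ_A
0.5–3 weeks, τ_B 2–500 yr, τ_C 2000–20000 yr, biomass S:C 0–1 %, rapid
product 4–5 %, gradual product 1–3 %. The multi-decade τ_B and τ_C are
scale parameters and are drawn log-uniformly; everything else uniformly.
Each draw fixes an environment in which four unknowns — log k_het,
log k_sulf, f₂, f₃ (f₁ = 1 − f₂ − f₃ via a multinomial-logit
parameterization that keeps the fractions on the simplex) — are fitted by
weighted least squares to five constraints: carbon flux after A, B, C
(0.51 ± 0.15, 0.38 ± 0.05, 0.30 ± 0.08 of f₀) and bulk S:C after B and C
(2.0 ± 0.5 %, 3.7 ± 0.5 %). The S:C of the A→B flux is deliberately not a
constraint (poorly known observationally). With five constraints and four
unknowns the system is overdetermined; a draw is accepted when every
weighted residual is at most 2. Solves use Levenberg–Marquardt with eight
log-spaced multistarts; on realizable (self-consistent) synthetic problems
the solver recovers generating rate constants to machine precision, which
the recovery tests assert. Failed draws are discarded and redrawn; runs
abort with diagnostics if attrition exceeds 90 %. In practice attrition is
~5 %. Ensembles are byte-reproducible under a fixed seed (per-attempt
sub-seeds spawned from one `SeedSequence`).

The optimizer's inner loop uses a scalar re-implementation of the box chain
(`forward_checkpoints`) for speed; its agreement with the container-based
`run_chain` to 10⁻¹² relative is itself a test.

Two properties of the fitted ensembles are worth knowing. First, the
least-squares compromise settles with the final flux near 0.23 (low side of
0.30 ± 0.08) and final S:C near 3.9 % (high side of 3.7 ± 0.5 %): the final
S:C target pulls against the final flux target, since raising preserved
carbon dilutes preserved sulfur. All ensemble means remain inside their 1σ
tolerances. Second, the fitted class-2 fraction typically collapses toward
zero — the constraints are satisfiable with effectively two active classes —
so f₂ should be read as "not required by the data", not as an estimate.

## Scenarios

Chemocline position is encoded as the set of boxes with sulfurization
active: all boxes (control; chemocline above A), B and C (chemocline at the
sediment–water interface), C only (chemocline in the sediments). Every
scenario re-runs each calibrated member with its own draw and parameters;
heterotrophy always operates. Percent reductions are computed member-wise,
100·(1 − preserved/control), then averaged arithmetically. A continuously
moving chemocline splits box A or B into an oxic sub-box of turnover
(1−x)·τ followed by an anoxic sub-box of x·τ, inheriting the parent's
kinetics and product ratio; endpoints of the sweep reproduce the discrete
scenarios exactly (for mixed kinetics the split survival
1/(1+h(1−x)τ) · 1/(1+(h+q)xτ) degenerates to the parent forms at x ∈ {0,1}).

Sensitivity: holding the S:C draws at central values and recalibrating at
all eight corners of the (τ_A, τ_B, τ_C) range box changes scenario
preserved-carbon outcomes by at most ~13 percentage points of f₀
(`tau_sensitivity`, asserted < 15 in tests). The percent-reduction
statistic is much more tau-sensitive at the range corners (tens of
percentage points), because the corners reapportion rapid sulfurization
between boxes A and B; ensemble means over the full draw distribution are
nevertheless stable across seeds to well under a percentage point.

## Stratigraphic statistics

The data-side module quantifies the observational signature the model
explains: OLS regression of kerogen molar S:C (%) on TOC (wt%), on
whole-rock or carbonate-free bases (R² = squared Pearson correlation; no
p-values are reported); group summaries and the rich/lean contrast
100·(1 − mean_lean/mean_rich) with the rich class defined by whole-rock
TOC > 1.0 wt% (strict) even for carbonate-free statistics, since the class
definition is a whole-rock one; and the Pearson correlation between δ³⁴S
and S:C. S:C itself is basis-independent (both elements rescale together).
Error propagation for S:C uses relative variances in quadrature from
external replicate reproducibilities.

Speciation fractions arrive as externally fitted abundances that often do
not close to 100 %; ingest renormalizes to unit sum (tolerating up to ±25 %
misclosure) and retains the raw sum on the sample. Atomic masses are fixed
at S = 32.06, C = 12.011 g/mol.

## Synthetic data generator

The generator emulates the structure of a moderately organic-rich,
redox-fluctuating section so that every stage of the pipeline runs without
downloads: alternating fixed-thickness lithological bands (limestone–marl
vs shale); TOC lognormal per regime (shale median 1.8 wt%, clipped to
0.06–3.1; limestone median 0.2 wt%); S:C(%) = 1.0 + 1.35·TOC + N(0, 0.6),
floored at a 0.5 % biomass baseline, with the noise level chosen so the
default 40-sample profile regresses near R² ≈ 0.8; δ³⁴S from Rayleigh
systematics (below); speciation Dirichlet per regime (shale mean 49 %
monosulfide / 27 % aromatic with concentration 200, i.e. ~3–4 % spread;
lean mean more aromatic/oxidized with concentration 60); carbonate Normal
per regime (45 ± 8 vs 80 ± 4 wt%, clipped to keep TOC + carbonate ≤ 100).

δ³⁴S uses the logarithmic (small-fractionation) Rayleigh approximation for
transparency — residual sulfate δ₀ − ε·ln f, instantaneous product
δ₀ − ε·ln f − ε, cumulative product δ₀ + ε·f·ln f/(1−f) — with the exact
α-exponent form available via `exact=True`. Shale samples take the
open-system product δ₀ − ε; lean samples take the closed-system
instantaneous product with f drawn uniformly from (0.6, 0.95), yielding
³⁴S-enriched values. Defaults δ₀ = 19 ‰ and ε = 49 ‰ are **generator
choices**, selected so the open-system endmember sits near −30 ‰ and
closed-system values trend toward −7 ‰; they are conventional magnitudes
for seawater sulfate and microbial sulfate reduction, not measurements.
The isotope mass balance (1−f)·cumulative + f·residual = δ₀ is asserted to
10⁻⁹.

What the generator does **not** emulate: stratigraphic autocorrelation
beyond banding, diagenetic overprints, pyrite or carbonate-associated
sulfate systematics, detrital contributions, or any coupling of speciation
to δ³⁴S beyond shared regime membership. Passing round-trip tests on
synthetic profiles therefore demonstrates that the statistics recover known
generative structure at realistic n — not that real sections satisfy that
structure.

## Problem sizes and numerical choices

Default ensemble size is n = 1000 (a few tens of seconds on one CPU);
sweeps use an 11-point grid in the anoxic fraction. Tests exercise smaller
ensembles (30–60 members) where only structural properties are at stake and
the full n = 1000 where ensemble means are compared to targets. Solver:
MINPACK Levenberg–Marquardt (`scipy.optimize.leastsq`), xtol 10⁻¹⁰, at most
400 function evaluations per start, best of 8 starts with early exit only
at exactly-zero cost; ties in multistart are broken by first-found lowest
cost, which is deterministic. The unconstrained optimizer coordinates are
clipped to ±40 before exponentiation to avoid overflow.

## Known limitations

* The reactivity multipliers are convention, not data; only ratios of
  observable outcomes that are robust to them should be interpreted.
* No oxidant or sulfide budget: sulfurization switched "on" is never
  substrate-limited.
* The split-box sweep parameter x is a fraction of a box's turnover time,
  not a physical depth; the model deliberately does not locate the
  chemocline mechanistically.
* Calibration is to a single modern analog (Cariaco Basin); applying the
  calibrated ensemble to ancient sections assumes its flux structure
  transfers.
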