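# sulfoc

Organic-matter sulfurization as a control on marine carbon burial: a
three-box, multi-G mass-balance model with Monte Carlo calibration, plus the
stratigraphic organic-sulfur statistics that motivate it.

## The problem

Abiotic reaction of (poly)sulfide with organic matter ("sulfurization") makes
organic matter refractory to microbial heterotrophy, raising its molar S:C
ratio and its preservation potential. Where the chemocline — the boundary
between oxygenated and sulfidic conditions — sits relative to the water
column and the sediment determines *which* organic matter gets sulfurized:
rapid sulfurization of fresh, reactive material in sinking particles and at
the sediment–water interface, or gradual (kyr-scale) sulfurization of already
degraded material deeper in the sediments. `sulfoc` quantifies how much local
carbon burial changes as the chemocline moves, for geochemists and
paleoceanographers working on euxinic basins and ocean anoxic events.

## The model

Export production f₀ (normalized to 1) transits three environments in
sequence — **A** sinking particles, **B** the sediment–water interface,
**C** deeper sediments. Biomass is split into three reactivity classes with
multipliers g = (1, 10⁻², 10⁻⁴) (a multi-G representation) and initial
fractions (f₁, f₂, f₃). In box *j* with turnover time τⱼ, class *i* is
remineralized at rate k_het·gᵢ and sulfurized at rate k_sulf·gᵢ (zero where
the box is oxic). For a well-mixed steady-state box the surviving fraction is

    φᵢ = 1 / (1 + (k_het + k_sulf)·gᵢ·τⱼ)

(`exp(−(k_het+k_sulf)·gᵢ·τⱼ)` in the alternative continuous-transit mode);
lost material splits between remineralized CO₂ and a refractory sulfurized
pool in proportion to the two rates, with sulfur added at the box's product
S:C ratio (4–5 % for rapid sulfurization in A and B, 1–3 % for gradual
sulfurization in C). Preserved carbon is the sulfurized pools plus the
biomass surviving box C.

The four unknowns (k_het, k_sulf, f₂, f₃) are solved by weighted least
squares against five Cariaco Basin constraints — carbon flux after each box
(0.51, 0.38, 0.30 of f₀) and bulk S:C after boxes B and C (2.0 %, 3.7 %) —
once per Monte Carlo draw of the environmental parameters (turnover times
and S:C product ratios) from their assigned ranges; 1000 accepted draws form
the calibrated ensemble. Scenario experiments then toggle sulfurization per
box, or split a box into oxic/anoxic parts, to move the chemocline.

## Worked example

```python
from sulfoc import SulfurizationModel, percent_reduction, sc_vs_preservation_table

model = SulfurizationModel()          # packaged Cariaco constraints + ranges
results = model.fit(n=200, seed=1)
print(results.summary())
print(sc_vs_preservation_table(results).to_string(index=False))
for name in ("b_and_c", "c_only"):
    print(name, round(percent_reduction(results, name)["mean"]))
```

prints (abridged):

```
constraint          target  1 sigma  ens. mean  ens. sd
flux_a_to_b          0.510    0.150      0.597    0.083
flux_b_to_c          0.380    0.050      0.395    0.008
flux_c_to_final      0.300    0.080      0.229    0.012
sc_b_to_c            0.020    0.005      0.023    0.001
sc_c_to_final        0.037    0.005      0.039    0.002

 scenario  mean_preserved_c  mean_preserved_sc
all_boxes          0.229365           0.038581
  b_and_c          0.118543           0.032418
   c_only          0.056396           0.017979

b_and_c 48
c_only 75
```

Every ensemble-mean constraint sits inside its assigned 1σ tolerance. The
scenario table shows preservation and bulk S:C falling together as the
rapid-sulfurization boxes shut off: relative to the all-boxes control,
preserved carbon drops ~48 % when the chemocline sits at the sediment–water
interface (sulfurization in B and C only) and ~75 % when it is inside the
sediments (C only) — the model's account of the roughly ten-fold difference
in organic carbon content between interbedded shales and limestones
deposited under fluctuating redox conditions.

The same pipeline is available from a shell:

```bash
sulfoc synth --n-samples 40 --seed 0 --out profile.csv   # synthetic section
sulfoc analyze profile.csv                               # S:C-TOC statistics
sulfoc calibrate --n 1000 --seed 1 --out ensemble.csv
sulfoc reproduce --n 1000 --seed 1 --outdir out/         # full headline run
```

`sulfoc analyze` computes the data-side statistics on any stratigraphic
profile CSV (see column schema in `sulfoc.geochem`): S:C–TOC regression on
whole-rock and carbonate-free bases, TOC-class group summaries and
contrasts, and the δ³⁴S–S:C correlation.

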