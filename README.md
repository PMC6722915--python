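# nemadischarge

Physics of nematocyst discharge — the explosive ejection of the stylet from
the stinging organelle of Cnidaria (Hydra, jellyfish, sea anemones), the
fastest known process in the animal kingdom.

The package is for biophysicists and modellers who want a tested, inspectable
implementation of the classical-physics account of the discharge:

1. **Charge buildup.** Proteolysis of the poly-γ-glutamate matrix releases
   H+, which out-diffuses through the semipermeable capsule wall and leaves a
   trapped negative charge ρ(r) = ρ₀ e^{−λ(R−r)} near the wall, with
   screening length 1/λ, λ = √(μen₀/εD).
2. **Coulomb pressure.** The trapped charge stores self-energy U and pushes
   outward with p = −∂U/∂V (total charge fixed). In the dimensionless size
   X = λR, the closed forms interpolate between a uniformly charged sphere
   (p → ρ₀²R²/15ε as X → 0) and a charged shell (p → σ²/2ε as X → ∞).
3. **Stylet ejection.** The carrot-shaped stylet β(ξ) = aξ(l−ξ)/(d+ξ) is
   held by an elastic mini-collagen collar; the static force balance
   πβ²p = (−∂β/∂ξ)·2παY(β−β₀)/β₀ loses its solution at a saddle-node fold.
   The fold pressure — approximately (1−d)Yaα/2r₀² for a narrow collar — is
   the ejection threshold, and the peak acceleration is P_thres·πR_x²/m.

A small companion module classifies temperature-cycled quartz crystal
microbalance (QCM) series of cnidarian collagen as reversible or denaturing,
from the reproducibility of frequency shifts across temperature revisits.

See `docs/methods.md` for the full model description, numerical choices and
limitations.

## Worked example

Everything below is in scaled units: lengths in stylet lengths l, pressures
in units of the collar modulus Y. The packaged default configuration is the
reference stylet (a = 0.2, l = 1, d = 0.01) with a narrow collar
(α = 1, β₀ = r₀ = 0.005, Y = 1).

```sh
nemadischarge threshold
```

prints (abridged to the outputs):

```json
{
  "xi1": 0.0904987562112,
  "beta_x": 0.163800497516,
  "P_thres_numeric": 3956.11641131,
  "P_thres_approx": 3960.0,
  "f_max_thrust": 333.464317029,
  "f_max_parametric": 1231.62998391,
  "f_max_ratio_parametric_to_thrust": 3.69343861103
}
```

The stylet bulges to its apex radius β_x ≈ 0.1638 at ξ₁ ≈ 0.0905; the
closed-form ejection threshold is exactly 3960 Y and the independent fold
search on the force balance lands 0.1% below it. `f_max_thrust` is the peak
acceleration from the thrust balance with R_x = β_x and m = 1;
`f_max_parametric` is the alternative parametric estimate, which carries a
different prefactor (the ratio is reported, not reconciled — see the
methods note).

```sh
nemadischarge -v simulate
```

runs the quasi-static five-stage discharge with the default depletion
schedule (100 uniform steps of the depleted fraction χ; the Coulomb
pressure grows as χ²) and logs one line per stage transition:

```
nemadischarge INFO stage=1 name='trigger' step=0 p=0 lambda=0.167332 X=0.167332
nemadischarge INFO stage=2 name='charge buildup' step=0 p=0 p_full_depletion=4811.24
nemadischarge INFO stage=3 name='coulomb explosion' step=65 p=2032.75 p_operculum=1978.06
nemadischarge INFO stage=4 name='distension' step=91 p=3984.19 p_threshold=3956.12 f_max=335.831
nemadischarge INFO stage=5 name='eversion' step=91 p=3984.19 eversion_time=1 eversion_speed=1 tubule_length=1
nemadischarge INFO ejected at p=3984.19 (f_max=335.831)
```

The operculum opens when the pressure crosses half the fold threshold
(stage 3), and the stylet is ejected at the first scheduled pressure at or
above the fold (stage 4–5), here χ = 0.91.

```sh
nemadischarge qcm-classify
```

classifies the packaged temperature-cycle table of jellyfish exumbrella
collagen:

```json
{"upper": "irreversible", "lower": "reversible"}
```

— the series cycled to 45 °C scatters by 450 Hz across its 15 °C revisits
(denatured collagen), while the series cycled only to 37 °C reproduces its
frequency shifts exactly (intact triple helices).

All subcommands accept `--config FILE` (YAML, see
`src/nemadischarge/data/default_config.yaml`) and `--out DIR` for CSV/JSON
artifacts. The same functionality is available as a library
(`nemadischarge.electrostatics`, `.mechanics`, `.discharge`, `.qcm`).

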