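# pigmentox

Kinetics of pigment degradation and lipid oxidation in oil-in-water
emulsions: a toolkit for food chemists quantifying how anthocyanin colour
fades while lipid-oxidation products accumulate during storage, and how pH
and surfactants move the visible spectrum.

Natural red pigments such as black-carrot anthocyanins double as
antioxidants: in an oxidising emulsion they sacrifice themselves scavenging
lipid radicals, so colour loss and oxidation kinetics must be analysed
together. `pigmentox` covers the full quantitative workflow of such storage
studies:

* **First-order decay** C(t) = C₀·e^(−kt) for pigment loss, with half-life
  t½ = ln2/k.
* **Sigmoidal accumulation** c(t) = cmax/(1 + ((cmax−c0)/c0)·e^(−kt)) for
  hydroperoxides and volatile aldehydes, with the inflection point
  t\* = ln((cmax−c0)/c0)/k and the induction period
  t_ind = t\* − 2/k (x-intercept of the inflection tangent; reported as
  "—" when non-positive).
* **Spectral colorimetry**: turbidity correction A(522) − A(750), peak
  location and bathochromic/hypsochromic/hyperchromic shift metrics,
  absorbance → CIELAB under illuminant C / 2° observer, and the full
  CIEDE2000 colour difference.
* **External calibration** (OLS signal↔concentration with inverse
  prediction) and the stoichiometric conversions used in emulsion work.
* **Replicate statistics**: per-replicate fits aggregated as mean ± SD,
  one-way ANOVA + Tukey HSD compact letter displays, and a deterministic
  end-to-end reporting pipeline.
* **Synthetic study data**: a seeded generator of replicate kinetic series
  and pH-dependent spectra with presets for all 28 study conditions.

## Worked example

```python
import numpy as np
from pigmentox import FirstOrderDecay, SigmoidAccumulation, half_life
from pigmentox.synthetic import preset, gen_kinetic_series

# pigment decay at pH 2 (fastest condition): simulate 2 preparations × 2
# measurements over 21 days, then fit the pooled replicates
series = gen_kinetic_series(preset("pH2_anthocyanin", seed=3))
t = np.concatenate([s.times for s in series])
c = np.concatenate([s.values for s in series])
res = FirstOrderDecay(t, c).fit()
print(res.summary())
```

```
First-order decay fit
==========================================
analyte                        anthocyanin
n obs                                   36
C0 (µM)                            23.6085
k (day⁻¹)                          1.50571
t½ (days)                         0.460345
RSS (µM²)                          47.3446
converged                             True
```

The fitted rate (1.51 day⁻¹) sits within a few percent of the generating
truth k = 1.44 day⁻¹, giving a half-life of about 0.46 days — at the most
acidic pH the red colour halves in roughly half a day. For an oxidation
channel:

```python
from pigmentox import fit_sigmoid
fit = fit_sigmoid(gen_kinetic_series(preset("pH3_LOOH_noextract", seed=5))[0])
print(f"k = {fit.k_hat:.2f}/day, plateau = {fit.cmax_hat:.0f} µM, "
      f"induction = {fit.t_ind:.1f} days")
```

```
k = 1.21/day, plateau = 2234 µM, induction = 6.7 days
```

Hydroperoxides at pH 3 stay low for almost a week (the induction period)
before propagating toward a ~2200 µM plateau. The same objects drive the
CLI (`pigmentox simulate | fit-decay | fit-sigmoid | color | quantify |
report`); `pigmentox report --seed 1 --out-dir report/` writes the
kinetic-parameter table (mean ± SD with Tukey letters, "—" for absent
induction phases), the Lab/ΔE₀₀ colour table and the spectral-shift table.

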