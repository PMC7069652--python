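# hsibg — retrieved-background correction for hyperspectral imaging

Hyperspectral imaging (HSI) turns every image pixel into a full spectrum, and
biomedical HSI pipelines normalise those spectra into reflectance

    R(x,y,λ) = (I(x,y,λ) − I_dark) / (I₀(x,y,λ) − I_dark)

and absorbance A = −log₁₀R, where I₀ is a white-reference ("background")
measurement of the illumination. In endoscopy and other complex imaging
geometries the illumination power varies across the scene and with working
distance, so a single white reference taken beforehand is wrong almost
everywhere. The error is structured: an illumination mis-estimate by a factor
ω rescales reflectance by 1/ω and offsets absorbance by +log₁₀ω, which then
corrupts PCA, spectral-angle mapping and pixel classification in
characteristic ways.

`hsibg` implements a software-only fix — the **retrieved background (RB)**.
At a reference wavelength where the sample absorbs negligibly (800 nm, inside
the NIR tissue optical window and at a haemoglobin isosbestic point), the
measured intensity is essentially the illumination itself. Dividing the
per-pixel intensity there, C_s(x,y), by the normalised source profile's value
C_b = NS(800), and multiplying by the normalised source spectrum NS(λ) gives a
per-pixel illumination estimate

    RM(x,y,λ) = (C_s(x,y) / C_b) · NS(λ),

which replaces I₀ in the equations above. The toolkit provides, for whom this
matters — people building or analysing line-scan/endoscopic HSI systems:

- `hsibg.core` — hypercube / line-scan containers, pushbroom reconstruction,
  dark correction, synthetic RGB rendering (Rayleigh filter bank);
- `hsibg.correction` — reflectance/absorbance under ground-truth (GT), single
  (SB) and retrieved (RB) backgrounds, including the retrieval itself;
- `hsibg.synthesis` — a synthetic-hypercube generator (Gaussian illumination
  fields, a four-class phantom with muscle / oxygenated-blood /
  methylene-blue / nigrosin stand-in spectra, colour-chart noise) plus the
  noise-robustness simulation;
- `hsibg.analysis` — pixel-wise PCA and spectral angle mapping;
- `hsibg.classification` — minibatch k-means, incremental hinge-loss SVM and
  a six-layer 1D CNN evaluated across the 3×3 grid of training/test
  background conditions;
- `hsibg.cli` — the `hsibg` command (`synth`, `correct`, `analyze`,
  `classify`, `render`, `paper-experiment`).

## Worked example

Cluster synthetic absorbance hypercubes with k-means under all background
conditions, with cube-level scaling (which preserves background distortions):

```sh
hsibg classify --clf kmeans --kind absorbance --scaling cube \
      --scale 0.25 --seed 1 --out kmeans_report.json
```

prints the accuracy grid (rows: training condition, columns: test condition):

```
test       GT     SB      RB
train
GT     100.00  60.21   94.47
SB      88.94  44.05   83.41
RB     100.00  59.00  100.00
```

Reading it: clustering ground-truth or retrieved-background cubes recovers
the four phantom classes perfectly (100%), while the conventional
single-background condition collapses to 44% on its own data — the per-pixel
absorbance offsets −log₁₀M(x,y) left by the wrong background smear the
clusters along a brightness continuum. The RB column shows the retrieval
repairing almost all of that damage.

The retrieval leans on a single reference channel, so its accuracy degrades
with spectral noise:

```python
from hsibg.synthesis import SpectrumLibrary, noise_robustness_sim
lib = SpectrumLibrary.default()
raw = lib.source * lib.samples["blood_oxy"]
print(noise_robustness_sim(raw, lib.profile(), n_reps=200, seed=1).round(3))
```

```
   noise_level  mean_pct_error  sd_pct_error
0         0.01           4.060         1.430
1         0.05          20.733         7.644
2         0.10          39.309        13.566
3         0.20          81.090        31.524
```

— the mean RB absorbance error rises monotonically with the relative noise
level, so the method should be applied with care to noisy spectra.

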