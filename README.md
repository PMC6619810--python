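# renalkin

Single-kidney glomerular filtration rate (GFR) and renal perfusion from
dynamic contrast-enhanced CT (DCE-CT) time–attenuation curves, using a
modified two-compartment tracer-kinetic model.

Serum-clearance GFR cannot resolve single-kidney function, which matters in
asymmetric disease (renal artery stenosis, obstruction, tumors). DCE-CT
follows an iodinated contrast bolus through the kidney; because
baseline-subtracted CT attenuation is linear in iodine concentration,
region-of-interest curves over the abdominal aorta, renal parenchyma and
renal papilla carry enough information to estimate filtration and perfusion
per kidney. `renalkin` is for imaging scientists and renal physiologists who
have such curves (plus a kidney volume) and want quantitative physiology,
with the analysis and its robustness studies fully scriptable.

## The model

With C_p(t) = C_a(t)/(1 − Hct) the arterial plasma input, vascular and
tubular compartments obey

    dC_v/dt = k_perf (C_p(t − T_d) − C_v)
    dC_t/dt = k_GFR C_v − k_out C_out″(t)

and the fitted signal is C_tot = f·C_v + C_t. C_out″ — the tubular component
of the measured papilla curve, isolated by decomposing that curve into an
early perfusion compartment plus remainder — supplies the contrast-outflow
forcing, so the model inherently tracks tubular transit. Five parameters
(k_perf, T_d, f, k_GFR, k_out) are fitted by bound-constrained nonlinear
least squares, then

    GFR = k_GFR·V·60    perfusion = k_perf·f·60·100/(1−Hct)·σ    RBF = perfusion/100·V

A truncated-SVD deconvolution perfusion estimate (the conventional
comparator, deliberately without delay correction) and the robustness
studies — transit-delay neglect, fitting-range sweep, temporal-resolution
sweep, Pearson/Bland–Altman agreement — are included, together with a
ground-truthed synthetic-data generator that emulates the study's two-phase
acquisition (1 s/scan vascular, 8 s/scan tubular, additive noise).
See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from renalkin import (FitOptions, SyntheticSpec, fit_kidney, make_kidney,
                      preprocess, tsvd_perfusion)

kidney, truth = make_kidney(SyntheticSpec(seed=42))   # synthetic, known truth
prepped = preprocess(kidney, dt=0.5, t_max=120.0)
result = fit_kidney(prepped, FitOptions(seed=0))
print(f"k_perf = {result.params.k_perf:.3f} /s   (truth {truth.k_perf:.3f})")
print(f"GFR       = {result.gfr:.1f} mL/min")
print(f"perfusion = {result.perfusion:.0f} mL/100g/min")
print(f"r_multiple = {result.r_multiple:.3f}")
deconv = tsvd_perfusion(prepped.aorta, prepped.parenchyma)
print(f"TSVD perfusion = {deconv.perfusion:.0f} mL/100g/min")
```

prints

```
k_perf = 0.156 /s   (truth 0.150)
GFR       = 44.2 mL/min
perfusion = 329 mL/100g/min
r_multiple = 1.000
TSVD perfusion = 211 mL/100g/min
```

The fit recovers the generating perfusion rate constant within a few
percent despite ~2% measurement noise; GFR of 44 mL/min is a typical
single-kidney value; r_multiple ≈ 1 says the modelled parenchymal curve
overlays the data. The TSVD comparator reads ~35% lower — it applies no
transit-delay correction and clips the residue peak, which is exactly the
bias the delay-stratified agreement analysis quantifies.

Real data enter as CSV (columns `time_s, aorta_hu, parenchyma_hu,
papilla_hu`, optional `volume_ml`) or XLSX (one sheet per kidney), via
`read_curves`. A CLI wraps the same functionality:

```
renalkin fit --input curves.csv --volume 148 --window 0:120 --seed 7 --out fit.json
renalkin deconvolve --input curves.csv --volume 148 --out deconv.json
renalkin sweep --input curves.csv --volume 148 --mode td --out td.json
renalkin simulate --n 50 --seed 7 --out cohort/
renalkin validate --model model.csv --reference ref.csv --out agreement.json
```

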