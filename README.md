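# sonokinetics

Release-kinetics modelling for ultrasound-triggered (sonosensitive)
liposomal drug delivery.

In vitro release assays for sonosensitive liposomes record fluorescence of a
self-quenching dye (calcein) or an encapsulated drug (doxorubicin) while
low-frequency ultrasound is applied in ON/OFF pulses; pulsing avoids the
acoustic heating that would otherwise corrupt the fluorescence signal.
After release saturates, Triton X-100 lysis frees the remaining cargo and
fixes the 100%-release intensity. `sonokinetics` turns such traces into
kinetic-model comparisons:

1. **Normalization** — cumulative fractional release from the instantaneous
   intensity $I_t$, the baseline mean $I_o$ and the post-lysis plateau mean
   $I_\infty$:

   $$\mathrm{CFR}(t) = \frac{I_t - I_o}{I_\infty - I_o}$$

2. **De-stepping** — OFF segments are trimmed and each remaining sample is
   remapped to cumulative insonation time, producing the continuous curve
   kinetic models require.

3. **Model fitting** — eleven models fitted by bounded trust-region
   nonlinear least squares and scored by the sum of squared errors
   $SSE = \sum_i (y_i - \hat y_i)^2$: zero-order ($k_0 t$), first-order
   ($A(1-e^{-k_1 t})$), Higuchi ($k_H\sqrt t$), Hixson–Crowell
   ($(1-\mathrm{CFR})^{1/3} = 1 - k_{HC}t$, fitted linearized),
   Korsmeyer–Peppas ($k_{KP} t^n$), Baker–Lonsdale
   ($\tfrac32[1-(1-\mathrm{CFR})^{2/3}]-\mathrm{CFR}=k_{BL}t$, linearized),
   Weibull ($1-e^{-a t^b}$), Gompertz ($k_g e^{-c\,t^{b}}$), Hopfenberg
   ($1-(1-k_{HF}t)^b$), Lu–Hagen ($k_1 k_2 t/(1+k_2 t)$), and an empirical
   cubic polynomial benchmark.

4. **Mechanism classification** — for spherical carriers the
   Korsmeyer–Peppas exponent diagnoses transport: $n \le 0.43$ Fickian or
   below, $0.43 < n < 0.85$ anomalous transport, $n > 0.85$ super case II;
   the Weibull shape separates exponential/parabolic ($b \le 1$) from
   sigmoid ($b > 1$) curves.

5. **Study comparison** — replicate aggregation into log10-SSE heatmaps
   (moiety × model) and best-model selection, with the cubic excluded by
   default because it fits well but has no physical interpretation.

A synthetic pulsed-trace generator (`sonokinetics.simulate`) reproduces the
acquisition protocol — 60 s baseline, 20 s ON / 10 s OFF pulses for calcein
(20 s OFF for doxorubicin), lysis step, additive Gaussian detector noise —
so the whole pipeline can be validated end-to-end against known ground
truth, including a reference-scale study of seven targeting moieties
(albumin, cRGD, estrone, hyaluronic acid, Herceptin, lactobionic acid,
transferrin) at three 20 kHz power densities with nine replicates each.

## Worked example

```python
from sonokinetics import (SimulationDesign, simulate_trace, preprocess_trace,
                          fit_all, classify_kp)

design = SimulationDesign(
    model="korsmeyer_peppas", params=(3.50e-3, 0.73),   # power-law ground truth
    encapsulant="calcein", n_cycles=30, noise_sd=10.0,  # 1% of dynamic range
    seed=7, meta={"moiety": "albumin", "power_density": 6.2},
)
trace, _ = simulate_trace(design)
profile = preprocess_trace(trace)          # normalize + de-step
print(f"profile: {profile.n_points} samples over {profile.t_us[-1]:.0f} s")
for res in sorted(fit_all(profile), key=lambda r: r.sse_cfr_space)[:4]:
    print(f"{res.model_name:18s} SSE = {res.sse_cfr_space:.3e}  params = "
          + ", ".join(f"{s}={v:.4g}" for s, v in res.params_dict.items()))
kp = next(r for r in fit_all(profile) if r.model_name == "korsmeyer_peppas")
print("mechanism:", classify_kp(kp["n"]).label)
```

prints

```
profile: 600 samples over 599 s of insonation
korsmeyer_peppas   SSE = 5.604e-02  params = kkp=0.003446, n=0.734
cubic              SSE = 5.773e-02  params = p1=7.564e-10, p2=-1.012e-06, p3=0.0009457, p4=0.01446
weibull            SSE = 6.111e-02  params = a=0.002206, b=0.8365
lu_hagen           SSE = 7.827e-02  params = klh1=0.9036, klh2=0.001147
mechanism: anomalous
```

The generating power-law model attains the lowest SSE, its coefficients are
recovered to within the noise (true $k_{KP}=3.5\times10^{-3}$, $n=0.73$),
and the exponent falls in the anomalous-transport band — release driven
comparably by diffusion and bilayer relaxation.

The same pipeline is available from the shell:

```bash
sonokinetics simulate --out traces/ --seed 7 --replicates 9
sonokinetics fit traces/albumin*.csv --out results.csv --xlsx results.xlsx
sonokinetics heatmap results.csv --out-prefix heatmap
sonokinetics report results.csv --out report.md
```

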