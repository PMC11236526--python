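# cvrflow

Analysis of CO2-driven cerebrospinal-fluid (CSF) inflow and cerebrovascular
reactivity (CVR) dynamics from gas-challenge BOLD fMRI.

Controlled hypercapnia dilates cerebral vessels; when the end-tidal CO2
(PetCO2) returns to baseline, the vasoconstrictive rebound shrinks cerebral
blood volume (CBV) and — intracranial volume being constant (Monro–Kellie) —
fresh CSF flows into the imaging slab, producing a time-of-flight signal
spike in the bottom slices near the fourth ventricle. Brief hyperoxia, which
is not vasoactive, produces no such inflow and serves as a built-in negative
control. `cvrflow` is for researchers studying this vascular–neurofluid
coupling: it models the BOLD response, characterizes the inflow peak, and
relates the speed of the vascular response to peritumoral edema load.

## Models

**Vascular response time constant (tau).** The regional gray-matter BOLD
signal is modelled as the PetCO2 trace convolved with an exponential
hemodynamic response function,

```
s(t) = β0 + β1 · (PetCO2 ⊛ h_τ)(t),    h_τ(t) = (1/τ) e^(−t/τ),  t ≥ 0,
```

with `h_τ` normalized to unit sum so that β1 is the CVR amplitude in signal
units per mmHg. τ is estimated by exhaustive grid search (default 0.5–120 s
in 0.5-s steps) minimizing the residual sum of squares of the per-τ ordinary
least-squares fit over the analysis window.

**CSF inflow peak.** The inflow trace — the average of the highest-contrast
voxels in the two bottom slices — is fit over the post-block window with an
Azzalini skew-normal density plus a linear baseline,

```
y(t) = A · (2/ω) φ((t−ξ)/ω) Φ(α (t−ξ)/ω) + a + b·t,
```

and the peak width is summarized as the right-sided half width at half
maximum (HWHM) of the baseline-free component.

**Coupling.** Lags between the inflow signal and the (negated) temporal
derivatives of the BOLD signal and of the CO2 trace — the CBV-change
surrogates — come from a shifted cross-correlation; group analyses regress
τ on edema load (edema voxels / brain voxels) and on inflow HWHM, with a
paired t test for pre/post measurements.

Because no gas-challenge dataset is bundled, `cvrflow` ships a synthetic-data
generator that emulates the full experiment: a 90-s +10 mmHg hypercapnic
block, a 120-s ramp to +12 mmHg, and a 180-s hyperoxic block (680 mmHg)
interleaved with 120-s baselines, sampled at TR = 1.05 s over 1000 volumes,
with the coupled BOLD/inflow structure and known ground truth.

## Worked example

```python
import cvrflow as cf

protocol = cf.build_default_protocol()            # block / ramp / hyperoxia
co2, o2 = cf.render_traces(protocol)
params = cf.ForwardModelParams(tau_true=12.0, cvr_amplitude=2.0,
                               noise_sd=2.0, seed=11)
bold = cf.simulate_bold(co2, params, protocol)

co2_vols = cf.resample_trace(co2, protocol.tr, protocol.n_volumes)
fit = cf.fit_tau(cf.denoise_wavelet(bold.data), co2_vols, protocol.tr)
print(f"tau = {fit.tau:.1f} s, CVR amplitude = {fit.beta1:.3f} a.u./mmHg")

inflow = cf.simulate_csf_inflow(
    cf.simulate_bold(co2, cf.ForwardModelParams(tau_true=12.0,
                     cvr_amplitude=2.0, noise_sd=0.0), protocol),
    params,
)
window = cf.simulate.inflow_fit_window(protocol)
peak = cf.fit_inflow_peak(cf.denoise_wavelet(inflow.data), protocol.tr,
                          window=window)
print(f"inflow peak: right HWHM = {peak.hwhm_right:.2f} s, "
      f"skew alpha = {peak.alpha:.2f}")

cbv_change = cf.temporal_derivative(cf.denoise_wavelet(bold.data), protocol.tr)
res = cf.shifted_crosscorr(-cbv_change, cf.denoise_wavelet(inflow.data),
                           protocol.tr, max_lag=30.0)
print(f"inflow lags the CBV decrease by {res.lag:.2f} s (r = {res.r_max:.2f})")
```

prints

```
tau = 12.0 s, CVR amplitude = 2.013 a.u./mmHg
inflow peak: right HWHM = 18.60 s, skew alpha = 8.48
inflow lags the CBV decrease by 2.10 s (r = 0.36)
```

The fitted τ matches the simulated 12-s time constant, and β1 recovers the
2 a.u./mmHg CVR amplitude. The inflow peak is strongly right-skewed (α ≈ 8):
inflow rises sharply once CO2 starts falling and decays over ~19 s (right
HWHM). The inflow signal trails the CBV decrease by ~2 s — a transit delay
on top of the 1.05-s volume quantization — and the positive correlation ties
the inflow to the vasoconstrictive rebound, not to hyperoxia, which produces
no inflow at all.

The same analyses run from the shell on NIfTI/CSV inputs:

```
cvrflow simulate --out-dir sim --seed 11 --tau 12 --edema-fraction 0.08
cvrflow subject --bold sim/bold.nii.gz --mask-dir sim --co2 sim/co2.csv \
    --o2 sim/o2.csv --out-dir out --inflow-window 250 364
cvrflow cohort out1/report.json out2/report.json ... --out-dir group
```

`subject` writes `report.json` (bulk alignment, tau fit, inflow fit, lags,
edema fraction) and `traces.csv`; `cohort` aggregates reports into the
τ-vs-edema and τ-vs-HWHM regressions and the paired pre/post test. Note that
the subject pipeline aligns the CO2 trace to the whole-brain BOLD signal
before the τ fit (as acquisition clocks differ in real data), so the
pipeline τ describes the response shape after the bulk delay is removed —
see `docs/methods.md`.

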