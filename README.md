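# ribpet

Analysis toolkit for **image-guided particle therapy with radioactive ion
beams** (RIB). A β⁺-emitting beam such as ¹¹C is simultaneously therapeutic
and PET-visible: the implanted activity can be imaged *during* irradiation and
compared with the planned dose to verify the beam range in vivo. `ribpet`
implements the computational analysis such an experiment needs, exercised
end-to-end on a seeded synthetic cohort generator:

- **physical decay** of the implanted positron-emitter mixture
  (96% ¹¹C / 3% ¹⁰C / 0.5% ¹⁵O, renormalised);
- **biological washout kinetics** — fitting the two-factor activity model,
  selecting one vs two biological components with a nested F-test, screening
  outliers (1.5×IQR rule) and comparing dose groups (pooled-variance t-test);
- an **analytic beam model** — Bragg–Kleeman ranges with A/Z² isotope
  scaling, pristine and spread-out Bragg peaks (SOBP), implanted-activity
  depth profiles and spill-structured activity build-up;
- **range-verification metrics** on 3-D volumes — beam's-eye-view (BEV)
  aperture integration, peak depth, 80% distal fall-off, profile shifts;
- **cohort statistics** — caliper ellipsoid tumour volumes, grip-strength
  toxicity metrics, spine-activity correlation (Mood's median test,
  Mann–Whitney, Pearson with Fisher-z CI);
- a **synthetic cohort generator** producing every pipeline input with known
  ground truth, and a CLI tying the stages together.

## The model at the core

The post-irradiation activity of tissue implanted with a ¹¹C beam is the
product of physical decay and biological washout:

```
A(t) = A₀ · Σᵢ wᵢ 2^(−t/T½,ᵢ) · [ Wₛ e^(−kₛ t) + (1 − Wₛ) e^(−k_f t) ]
```

where `wᵢ, T½,ᵢ` are the fragment fractions and half-lives of the implanted
positron emitters, `Wₛ` is the weight of the slow washout component and
`kₛ ≤ k_f` are the slow and fast perfusion rate constants. Fits are weighted
least squares with Poisson weights `1/max(counts, 1)`; the one- vs
two-component choice uses the nested F statistic
`F = (Δχ²/Δdof) / (χ²₂/dof₂)` at α = 0.05 (the bare χ²₁/χ²₂ ratio is
reported alongside). Range verification compares the PET activity peak depth
with the depth at which the normalised SOBP dose falls to 80% on its distal
edge — for a radioactive beam the two are expected to align to well under a
millimetre.

## Worked example

```bash
ribpet run-all --seed 5 --out-dir run/
cat run/report.md
```

prints (numbers from this exact command):

```
# Synthetic study report

- activity peak 85.58 mm vs dose 80% fall-off 85.81 mm (shift -0.23 mm)
- 5Gy: double model chosen in 100% of animals, 1 outlier(s) excluded
- 20Gy: double model chosen in 100% of animals, 1 outlier(s) excluded
- grip strength control vs irradiated: Mood's median test p = 0.0013
- spine activity vs grip: r = -0.98 (p = 4.1e-11)
```

Reading: the PET activity peak of the synthetic SOBP field sits 0.23 mm from
the 80% distal dose fall-off (the range-verification anchor); the washout
F-test prefers the double-exponential model for the irradiated animals; the
irradiated group's grip strength is significantly reduced and anticorrelated
with the fraction of PET counts in the spinal cord — the toxicity structure
the generator injects and the pipeline is built to detect. `run/report.json`
holds the full per-animal fit parameters with standard errors, χ², F and p
values, and a provenance block (seed, config hash, package version).

Individual stages are available as `synth-cohort`, `simulate-beam`,
`fit-washout`, `profile` and `cohort-report`; see `ribpet --help`.

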