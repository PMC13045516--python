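# bladekit

Quantitative analysis of bladder multiparametric MRI: voxelwise model-based
fitting of diffusion-weighted (DW) and dynamic contrast-enhanced (DCE)
series into parametric biomarker maps, and a deep-feature classification
pipeline for anatomical images — with seeded digital phantoms so every
estimator is validated against known ground truth without any patient data.

It is written for imaging scientists who need reproducible quantitative
imaging biomarkers (QIBs) from bladder protocols: ADC and the non-Gaussian
IVIM parameters (f, D*, D, K) from DW-MRI; T10, Ktrans, ve, vp and kep from
DCE-MRI via variable-flip-angle T1 mapping, Patlak graphical analysis and
the extended Tofts model; and ROC-evaluated classification of image-derived
feature tables.

## Models

DW signal attenuation versus b-value (s/mm²):

    monoexponential:  S(b) = S0 · e^(−b·ADC)
    NG-IVIM:          S(b) = S0 · [ f·e^(−b·D*) + (1−f)·e^(−b·D + K(bD)²/6) ]

DCE tissue concentration from the dynamic SPGR signal under the
fast-exchange limit, R1(t) = R10 + r1·Ct(t), then either

    Patlak:           Ct(t)/Cp(t) = Ktrans · ∫₀ᵗCp(τ)dτ / Cp(t) + vp
    extended Tofts:   Ct(t) = Ktrans·∫₀ᵗ e^(−kep(t−τ)) Cp(τ) dτ + vp·Cp(t)

with kep = Ktrans/ve. All fits are bounded, flagged when a bound is hit, and
produce NaN outside the mask. See `docs/methods.md` for fitting strategies,
bounds, and known estimator behaviour.

## Worked example

Generate a DW phantom whose ground truth is a typical non-muscle-invasive
bladder-tumour parameter set, fit it back, and summarize the ROI:

```sh
blade phantom dwi --seed 11 --noise-model rician --noise-sd 0.02 --out ph
blade fit-dwi --image ph/dwi.nii.gz --bvalues ph/bvalues.txt \
              --mask ph/mask.nii.gz --model ngivim --out fit
```

which prints `wrote 5 parameter maps to fit` and writes
`dwi_D.nii.gz, dwi_Dstar.nii.gz, dwi_f.nii.gz, dwi_K.nii.gz, dwi_S0.nii.gz`
plus a flags map and `dwi_roi_summary.csv`. For region 1 (truth
f = 0.24, D* = 25.57×10⁻³, D = 1.21×10⁻³ mm²/s, K = 0.41) the summary of
the run above contains (digits truncated here for display):

```
parameter,mean,sd,median,n_voxels,n_excluded
S0,1001.52,20.84,999.42,64,0
f,0.23624,0.04760,0.24284,64,0
Dstar,0.035425,0.032701,0.027143,64,0
D,0.00125707,0.00025773,0.00120821,64,0
K,0.41886,0.45824,0.29803,64,0
```

i.e. at magnitude SNR 50 the ROI means recover D within ~4% and f within
~2% of truth, while D* shows the upward skew of its estimator discussed in
`docs/methods.md` (its median, 27.1×10⁻³, is much closer to truth). The same
pattern works for DCE (`blade phantom dce` then `blade fit-dce`) and for
classification (`blade phantom features` then `blade dfa --classifier dt
--scorer none`).

The library mirrors the CLI one-to-one — `bladekit.dwi.fit_ngivim`,
`bladekit.dce.fit_ext_tofts`, `bladekit.dfa.train_eval`, … — and all CLI
commands are thin wrappers over those functions.

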