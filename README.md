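# hsqcmultiplet

Automated multiplet assignment and isotopomer decomposition for
2D-¹H,¹³C-HSQC NMR spectra from stable-isotope tracing experiments.

## The problem

When cells are fed a ¹³C-labelled tracer (e.g. [1,2-¹³C₂]-glucose), the
label spreads through metabolism and each metabolite ends up as a mixture
of *isotopomers* — molecules with ¹³C in different positions.  In an
ultra-high-resolution 2D-¹H,¹³C-HSQC spectrum every CH pair gives a cross
peak whose ¹³C fine structure encodes which neighbouring carbons are
labelled: no labelled neighbour gives a singlet, one gives a doublet split
by the one-bond ¹³C/¹³C coupling (≈ 30–60 Hz), two give a doublet of
doublets.  The relative intensities of these multiplet components are the
isotopomer fractions — the raw material of flux analysis.  Extracting them
by hand means locating every resonance (shifts drift with pH and matrix),
disentangling overlapping signals, deciding which multiplet is which, and
fitting component intensities: slow, subjective work.  This package
automates all of it, with a per-resonance quality score so the user knows
which results to trust.

## The method

For each CH resonance of each requested metabolite:

1. **Search window** — the spectrum is restricted to ±0.15 ppm (¹H) ×
   ±3.0 ppm (¹³C) around the library shifts (`maxWidth1H`, `maxWidth13C`).
2. **Unmixing** — the window's ¹³C columns are treated as observations of
   the linear mixing model **Y = W S** and separated into statistically
   independent source traces by FastICA; each source is placed along ¹H at
   the column with the highest Pearson correlation, and sources below
   `minCorr = 0.8` are discarded as noise.
3. **Identification** — the resonance's isotopomer components are simulated
   as first-order stick patterns (all sign combinations of ± s·J/2, where
   s is the apparent-J scaling factor) dressed with Lorentzian lines.  Every
   subset of the p components (p!/((p−q)!q!) subsets of size q) is aligned
   with each peak-filtered source by cross-correlation and scored with the
   coefficient of determination ρ of a nonnegative fit, weighted by the
   distance from the library position:

       Γ_adjusted = 20·(γ_H/γ_C) ≈ 79.5
       Δppm  = √( (x_H − x_Hlib)² + ((x_C − x_Clib)/Γ_adjusted)² )
       ρ_adj = ρ / (ε + Δppm²)

   so that among equally good fits the library-proximal candidate wins.
4. **Quantification** — after a hill-climb refinement of the ¹H column,
   the experimental ¹³C trace is regressed on all component traces with
   nonnegativity constraints (**F = X·B**, B ≥ 0, solved by NNLS); the
   normalised **B** are the isotopomer fractions, and

       ρ = 100 · (SStot − SSres) / SStot

   is reported with a trust flag: trustworthy (ρ ≥ 80 %), borderline
   (70 % < ρ < 80 %), not trustworthy (ρ ≤ 70 %); an absent signal is
   reported as ρ = 0.  Apparent-J scaling factors {1, 2, 4, 8} used to
   enhance splittings during acquisition are auto-detected from reference
   resonances and compensated.

## Worked example

Generate a synthetic ground-truth spectrum (lactate + alanine, peak
signal-to-noise 50, shifts perturbed to emulate matrix effects), then
analyse it:

```
$ hsqc-multiplet simulate --metabolites lactate,alanine --out demo.npz \
      --snr 50 --perturb-1h 0.03 --perturb-13c 0.3 --seed 11
wrote demo.npz and demo.truth.json

$ hsqc-multiplet analyze --spectrum demo.npz --metabolites lactate,alanine \
      --out analysis --report both --seed 11
analysed 4 resonance(s); j_scaling=1
wrote analysis/report.json
wrote analysis/report.md
```

The markdown report:

| metabolite | moiety | 1H (ppm) | 13C (ppm) | dist (ppm) | rho (%) | trust | composition |
|---|---|---|---|---|---|---|---|
| lactate | C2 | 4.0846 | 69.2996 | 0.0254 | 98.16 | GREEN trustworthy | s 11.0%; d(C1) 28.4%; d(C3) 57.0%; d(C1,C3) 3.5% |
| lactate | C3 | 1.3301 | 20.5166 | 0.0107 | 99.15 | GREEN trustworthy | s 3.1%; d(C2) 96.9% |
| alanine | C2 | 3.7479 | 51.4570 | 0.0223 | 95.72 | GREEN trustworthy | s 6.2%; d(C1) 15.2%; d(C3) 25.2%; d(C1,C3) 53.4% |
| alanine | C3 | 1.4449 | 16.5788 | 0.0252 | 98.97 | GREEN trustworthy | s 29.9%; d(C2) 70.1% |

Reading lactate C3: the resonance was found 0.011 ppm from its library
position; 96.9 % of the signal is the doublet split by C2 (the ¹³C-C2
isotopomer) versus a true simulated composition of 97.0 %, and ρ = 99.1 %
marks the fit trustworthy.  The same pipeline is available from Python via
`hsqcmultiplet.analyze_metabolite(grid, library, "lactate", config)`.

Spectra can be read from NMRPipe `.ft2`, Sparky `.ucsf` or the portable
`.npz` grid format that `simulate` writes.

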