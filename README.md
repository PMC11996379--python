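# tdfret

Time-domain (TCSPC) FRET lifetime analysis: reconvolution fitting of
photon-count decay histograms with FRET models over Gaussian donor–acceptor
distance distributions, global multi-condition fits, chi-square
identifiability analysis, and conversion of conformational state fractions
into free energies and ligand dose–response parameters.

## What it does

* **`tdfret.tcspc`** — decay-record domain types (`DecayHistogram`,
  `ModelCurve`, `AcquisitionPair`) and plain-text histogram I/O
  (two-column delimited files with `#` metadata headers; bit-exact
  round-trips).
* **`tdfret.model`** — the decay model: biexponential donor, up-to-four
  exponential buffer fluorescence, FRET quenching averaged over one- or
  two-Gaussian distance distributions, an independent-second-acceptor
  (intersubunit) extension evaluated as a product of single integrals, and
  reconvolution with a measured instrument response function (sub-bin IRF
  shift, background handling).
* **`tdfret.fitting`** — chi-square minimization against measured
  histograms: buffer fits, donor-only fits, single-decay FRET fits, global
  fits with parameter sharing across conditions, the fixed-intersubunit
  two-acceptor protocol, and true profile-likelihood chi-square curves and
  surfaces. Poisson weighting by default (`sigma = sqrt(max(counts, 1))`);
  the literal `sigma = counts` rule is available as `weighting="as-printed"`.
* **`tdfret.energetics`** — Boltzmann conversion of active-state fractions
  to free energies, ligand-induced energy differences, and the quadratic
  (ligand-depletion) binding isotherm with least-squares fitting.
* **`tdfret.simulate`** — synthetic TCSPC fixtures: Gaussian IRF, Poisson
  shot noise per bin, buffer fluorescence and uniform background, plus
  study-scenario builders (`donor_only`, `cterm_hetero_titration`,
  `intersubunit`, `cterm_homo`, `full_length`) parameterized by published
  fitted values so the whole pipeline is testable without measured data.
* **`tdfret.cli`** — a `tdfret` executable with subcommands
  `simulate`, `fit-buffer`, `fit-donor`, `fit-fret`, `fit-global`,
  `profile`, `energetics`, `dose-response`. Every run writes a
  `manifest.json` with the configuration hash, seed and version.

## CLI quick start

```sh
# simulate a 5-condition titration scenario
tdfret simulate --scenario cterm_hetero_titration --outdir sim --seed 1

# fit the donor-only decay of a scenario
tdfret simulate --scenario donor_only --outdir donor --seed 1
tdfret fit-donor --sample donor/donor_only_sample.txt \
    --irf donor/donor_only_irf.txt --outdir donor_fit

# global fit with distances/widths shared across conditions
tdfret fit-global --manifest sim/manifest.json \
    --share r1,sigma1,r2,sigma2 --outdir global_fit

# free energies and dose-response
tdfret energetics --fractions fractions.csv --reference-label apo --outdir en
tdfret dose-response --titration titration.csv --outdir dr
```

## Model conventions

Times are nanoseconds, distances angstroms. Distance integrals use a fixed
trapezoid grid (2–150 Å, 0.1 Å step, extended adaptively for far acceptors)
with the density renormalized on the grid. Convolution is discrete linear
convolution at bin resolution, truncated to the data window; the buffer term
is added to the sample model before convolving. The 15 decay-fit parameters
are named `f_D, tau_D1, alpha_D1, tau_D2, R0, r1, sigma1, f_A2, r2, sigma2,
shift_irf, f_B, A0, bkgr_dec, bkgr_irf`; the two-acceptor protocol adds the
fixed intersubunit shape `r1_inter, sigma1_inter, r2_inter, sigma2_inter`
whose state fraction is linked to `f_A2`.
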