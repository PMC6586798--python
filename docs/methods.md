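# Methods

## Assay model

The pipeline analyses real-time fluorescence progress curves of enzymes
that create or destroy base-paired nucleic acid. The measured signal of a
well is modelled as

    F(t) = [ α·C·(L_primary(t) + f_ss·L_secondary(t)) · sat(mass) + B ] · e^(−λt) + ε

where `L_primary` is the dye's full-weight species (duplex bp for the
dsDNA dye, RNA nt for the RNA dye), `L_secondary` the reduced-weight
single-stranded species, `C` the substrate concentration (nM), `α` the
fluorescence yield per nt per nM, `f_ss` the relative ssDNA signal, `B`
the free-dye background, `λ` the photobleaching rate shared by all wells
of a run, and `ε` Gaussian read noise. `sat(·)` is a soft clip that is
exactly the identity below the dye's linear-range cap (2.5 ng/µL
equivalent mass) and bends hyperbolically to a plateau above it; its
functional form above the cap is a modelling choice, since only the cap
itself is an observed quantity.

Normalising a sample to its matched no-enzyme control
(`F_s/F_c × F_c(0)`) removes the `e^(−λt)` factor exactly because
bleaching is modelled (and in practice behaves) as multiplicative and
shared. The standard curve is an OLS fit of fluorescence against ladder
length at each timepoint; with normalisation enabled (the default) every
ladder well is its own control, so `m(t)` and `c(t)` are pinned at their
t₀ values. Conversion inverts the line; timepoints with non-positive
fitted gradient are excluded rather than clipped, and more than 20%
excluded is an error.

### Ladder styles

Conversion is exact only when the ladder's single-strand content mirrors
the reaction's. Resection of an 80-bp duplex through one front leaves an
(80−L)-nt single strand alongside every L bp of remaining duplex, so the
packaged resection scenarios use "resection-intermediate" standards (L-bp
duplex + (80−L)-nt ss tail) with the full-length ss oligomer as the 0-bp
end product. Nonspecific digestion leaves no intact strand, so the DNase
scenario uses plain duplex standards with a blank 0-point. A plain-duplex
ladder with the ss end-point (the physically simplest ladder) is also
provided; its 0-bp point sits `f_ss·80` bp-equivalents above background,
which tilts the line slightly — with the default `f_ss = 0.10` its fit
R² is ≈ 0.992, consistent with the assay's published linearity. A larger
`f_ss` of 0.15 would push that R² below 0.99, which is why 0.10 is the
default; the parameter is configurable.

## Simulator

Each well simulates `n_molecules = 2000` independent molecules in
continuous time; replicate wells are independent populations, so replicate
scatter arises from molecule sampling plus read noise, as in real plates.

* **Directional resection (3'→5', 5'→3').** Initiation sites come from the
  structural rules: blocked ends excluded, an attacking-strand overhang
  longer than the enzyme's permissive maximum excluded (the 3'→5' enzyme's
  threshold is 3 nt: 2-nt overhangs are permissive and 4-nt inhibitory;
  the untested 3-nt case defaults to permissive and is configurable),
  otherwise a length-keyed attenuation multiplier is attached. Each front
  advances with exponential per-nt waiting times of hazard
  `base_rate × [E] × site multiplier × lesion multiplier`, traversing its
  own ss overhang before entering the duplex (which produces the delayed
  start observed on long 5' overhangs). A front approaching a terminus
  whose biotin-TEG+streptavidin block is present halts a protected window
  (default 20 nt) short of it. Duplex length is the count of positions
  with both strands intact; exposed single strand is the count with
  exactly one.
* **Synthesis purity.** Each *blocked strand* is synthesised intact with
  probability `purity = 0.85`; a molecule missing a block exposes that end.
  A duplex blocked at both ends therefore has `0.85² ≈ 72%` fully
  protected molecules, and the ~28% with at least one open end reproduce
  the characteristic 15–20% fluorescence loss of enzyme-treated blocked
  controls. Because a one-end-blocked substrate runs one front on 85% of
  molecules and two on 15%, the packaged scenarios convert published bulk
  per-nM rates to intrinsic per-front rates by dividing by `(2 − purity)`.
* **Mismatches.** Lesion sites carry a hazard multiplier over a window.
  The packaged mismatch substrates place four lesions every 20 nt with
  20-nt windows so the whole tract is covered and the *bulk* front speed
  changes by the multiplier (1.65 for A:C, 0.125 for T:G) — matching how
  such substrates shift the observed maximum gradient. Single-nt windows
  are the type's default for point-lesion modelling.
* **Methylcytosine.** Methylation adds an exponential initiation delay
  with mean `Σ delay_i × (5 nM / [E])` — strong at low enzyme
  concentration, attenuated at high, which staggers completion times
  without changing the maximum rate.
* **Nickase coupling.** Nicks appear at motif sites as Poisson events
  (per-site rate per nM nickase; the CCA/CCG motifs nick ~5× faster than
  CCT) and become initiation sites for the co-simulated exonuclease.
  Pre-formed nicks and gaps are initiation sites from t = 0.
* **Distributive modes.** The nonspecific nuclease and the hybrid-specific
  RNase assign each position an independent exponential cleavage clock, so
  the population mean decays exponentially with initial slope
  `L₀ × hazard` — the per-nt hazard is the published bulk per-nM rate
  divided by the reference length.
* **Polymerase.** The primer 3' terminus extends with the same waiting-time
  machinery, converting template ss to duplex, with an optional hard stop
  (default 52 in the packaged scenario) modelling the internal-hairpin
  stall at the 50–55-mer position; primers annealed past the stall extend
  to full length. Template-length preference is encoded as a rate
  multiplier keyed by overhang length (the 60-nt overhang extends 3× faster
  than 20/40-nt).
* **Deterministic limit.** `deterministic=True` replaces all waiting times
  by their means and combines purity cases by exact probability weight,
  giving the N→∞ mean-field trajectory used by closed-form tests. The
  stochastic population mean agrees with it to <2% away from the
  completion boundary (near completion the Poisson front's cap at the
  substrate end biases the mean upward — an intrinsic boundary effect, not
  an implementation artefact).

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| substrate_conc | 50 | nM | standard assay input (≈2.6 ng/µL for 80 bp, at the linear-range cap) |
| sampling_interval_s | 45 (40 for fast RNA runs) | s | plate-reader cadence of 40–50 s |
| duration_s | 3600 | s | 30–60 min runs |
| n_replicates | 3 | — | matches the assay's n = 3 throughout |
| purity | 0.85 | — | stated oligo synthesis purity |
| protected_window_nt | 20 | nt | streptavidin shields the final ~20 nt |
| α (alpha_ds) | 0.25 | AU nt⁻¹ nM⁻¹ | sets full-length signal ≈ 1000 AU |
| f_ss (ss_fraction) | 0.10 | — | ss end-product visibly above background while keeping ladder R² ≥ 0.99 |
| background | 2.5 | AU | free dye ≈ signal / enhancement (≈400×) |
| bleach_rate | 1e-4 | s⁻¹ | ~30% loss over an hour |
| saturation_mass | 2.5 | ng/µL | observed linear-range cap |
| noise | 0.3% of clean t₀ signal | AU | typical monochromator plate-reader CV at 20 flashes/well |
| n_molecules | 2000 | — | replicate SEM comparable to real error bars; mean-field within ~1% |

## Kinetics estimation

The maximum gradient scans every contiguous window of `window_points`
samples with an OLS slope and takes the largest absolute value (earliest
window on ties). The default window is 5 samples (~3–4 min); the packaged
slow scenarios (nonspecific digestion, hybrid RNase) use 11- and 9-sample
windows because a max-over-windows statistic on a nearly flat noisy curve
is upward-biased, and widening the window shrinks the per-window slope
variance faster than it blunts the true initial slope of their shallow
exponential decays. Rates are computed per replicate and aggregated as
mean ± SEM. Titration regression is forced through the origin (no enzyme,
no rate); its uncentered R² is the first-order diagnostic, and it
deliberately weights high concentrations, where the gradient is best
determined. Completion time is the earliest sample from which the curve
stays within ε (default 5% of substrate length) of its final level
(median of the last 10% of samples) through to the end of the trace;
controls are excluded by role. Group comparisons use one-way ANOVA
(`scipy.stats.f_oneway`) and Tukey's HSD (`statsmodels
pairwise_tukeyhsd`); an all-tied input is reported as degenerate rather
than raising.

The linear-range scan fits the dilution series from the bottom up and ends
the linear range at the largest concentration whose fit keeps R² ≥ 0.98
while the next point falls more than 3 residual-SDs off the line; a series
that never breaks returns the top concentration flagged "no plateau
detected".

## What the simulator does and does not emulate

Passing parameter-recovery tests shows the *pipeline* is unbiased and
precise under the modelled data-generating process: shared multiplicative
bleaching, Gaussian read noise, per-molecule kinetic stochasticity, purity
mixtures, and the documented structural rules. Real plates can violate
these assumptions in ways the simulator deliberately omits: dye-binding
cooperativity and photophysics beyond exponential bleaching, temperature
effects, sequence-dependent rates beyond the lesion windows, the
non-monotone concentration optimum some enzymes show (the pipeline can
report such titrations — the first-order R² flags them — but the simulator
does not generate them), and the delayed-start/faster-intermediate-rate
phenomenology of long 5' overhangs beyond its net attenuation. Fragment
size distributions are not modelled: for distributive enzymes the
converted "length" is a duplex-equivalent signal, not a physical fragment
length, and is flagged as such.

## Numerical and design choices

* Coordinates are 0-based nt offsets; overhangs are lengths, not sequence;
  sequence is optional annotation, and nickase motif positions are given
  explicitly in the library.
* The per-timepoint standard-curve fit averages replicate ladder wells
  before fitting; OLS, not errors-in-variables.
* Ladder wells are normalised (to themselves) before fitting by default,
  matching the sample normalisation order; the raw fit is available and is
  the one that exhibits `m(t) = m(0)e^{−λt}`.
* No smoothing before conversion — QC sees raw conversions; smoothing is a
  kinetics-stage option only.
* Normalisation requires identical time bases and refuses zero-valued
  controls; no resampling is performed.
* Converted lengths are clipped to `[0, substrate length]` with pre-clip
  values retained for QC.
* Control wells are normalised against the next replicate's control
  (cyclically) so the no-enzyme noise floor is measured without dividing a
  trace by itself.
* `enhancement_fold` is retained as dye metadata without entering the
  rendered signal, since reported values for the bound/free enhancement
  vary; `alpha_ds` and `background` parameterise the signal directly.

## Known limitations

* The protected-window rule applies to every front approaching a
  streptavidin-blocked terminus, so one-end-blocked resections plateau at
  ~20 bp rather than 0; maximum gradients and completion ordering are
  unaffected.
* Maximum-gradient estimates at very low rates (signal change per window
  comparable to noise) are upward-biased by the max selection; the
  origin-weighted titration regression suppresses most of this, but
  single-concentration estimates near the noise floor should be read as
  upper bounds.
* The nickase's own exonucleolytic side activity is not modelled (the
  coupled scenario uses it purely as a nick generator).
* RNA-dye mode treats signal as linear in RNA nt for all RNA species;
  species-specific yields of short ssRNA vs duplex RNA are not
  distinguished.
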