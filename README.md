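# nucleokit

Real-time fluorescence nuclease assay analysis: plate simulation,
standard-curve calibration, and resection kinetics.

## The problem

Intercalating dyes such as PicoGreen fluoresce strongly when bound to
double-stranded DNA and only weakly when free or bound to single strands, so
the bulk duplex content of a reaction can be read continuously on a
microplate fluorimeter. When a nuclease degrades a duplex substrate — or a
polymerase synthesises one — the fluorescence time course becomes a direct,
real-time progress curve of the reaction. `nucleokit` implements the full
quantitative workflow for such assays, for people characterising nuclease
catalytic rates, directionality and substrate-structure preferences
(overhangs, end blocks, nicks/gaps, mismatches, methylcytosines), plus
single-strand nucleases, polymerases, and RNA/RNA:DNA enzymes read out with
an RNA-sensitive dye.

The analysis chain is:

1. **Calibration** — a ladder of duplex standards (80/60/40/20 bp, with the
   fully single-stranded 80-mer as the 0-bp end product of complete
   resection) is fitted by OLS at every timepoint:
   `F = m(t)·L + c(t)`, tracking shared photobleaching.
2. **Normalisation** — each sample trace is divided by its matched
   no-enzyme control and rescaled to t₀:
   `F_norm(t) = F_s(t)/F_c(t) · F_c(0)`, cancelling multiplicative
   photobleaching exactly.
3. **Conversion** — `L(t) = (F_norm(t) − c(t)) / m(t)` gives remaining
   duplex length in bp (or nt / bp-synthesised for single-strand and
   polymerase modes).
4. **Kinetics** — the reaction rate is the *maximum gradient*: the steepest
   OLS slope of `L(t)` over a sliding window. Dividing by enzyme
   concentration (or regressing a titration through the origin) gives the
   per-nM rate, `bp nM⁻¹ s⁻¹`, with a linearity R² as the first-order
   diagnostic; plateau detection gives completion times; replicate groups
   are compared with one-way ANOVA + Tukey HSD.

Because the original assay deposits no raw plate data, the package includes
a mechanistic **plate simulator**: a per-molecule continuous-time model of
directional resection fronts (exponential per-nt waiting times, hazard =
rate × [E] × site/lesion multipliers), distributive cleavage, nickase
coupling, primer extension, and ss digestion, rendered through a dye model
with photobleaching, signal saturation above 2.5 ng/µL, reduced ssDNA
signal, oligo synthesis purity (~85%) and Gaussian read noise. Packaged
scenarios reproduce every experiment family and serve as ground-truthed
test beds for the pipeline.

## Worked example

```python
from nucleokit import run_scenario

rep = run_scenario("dnase_titration", seed=1, outdir="out/dnase", plot=True)
print(rep.summary)
```

prints

```
{'per_nM_rate_bp_nM_s': 0.0010361213145131647,
 'first_order_r2': 0.9756058181108004,
 'standard_curve_r2_t0': 0.9999720982874096}
```

The scenario simulates a DNase I titration (0/2/4/8/16 nM on a 50 nM 80-bp
blunt duplex, 45-s sampling, 3 replicates, ground-truth bulk rate
0.001 bp nM⁻¹ s⁻¹), runs the full pipeline, and recovers a per-nM digestion
rate of **0.00104 bp nM⁻¹ s⁻¹** (within 4% of ground truth) from the
origin-constrained regression of per-concentration max gradients:

```
enzyme_conc_nM      mean       sem      # max gradient, bp/s
2.0             0.003917  0.000228
4.0             0.005393  0.000072
8.0             0.008920  0.000276
16.0            0.015720  0.000154
```

`first_order_r2` is the proportionality diagnostic (rate ∝ [DNase I]);
`standard_curve_r2_t0` is the ladder-fit R² at the first read. The
`out/dnase/` bundle contains `plate.csv`, `map.csv`, `curve.json`,
`curves.csv`, `rates.csv`, `report.json` and `curves.png`.

The same workflow runs from the shell:

```bash
nucleokit run-scenario --list
nucleokit simulate --scenario exoiii_titration --seed 1 --out out/exo
nucleokit calibrate --plate out/exo/plate.csv --map out/exo/map.csv --out out/exo/curve.json
nucleokit quantify  --plate out/exo/plate.csv --map out/exo/map.csv \
                    --curve out/exo/curve.json --out out/exo/curves.csv
nucleokit kinetics  --curves out/exo/curves.csv --map out/exo/map.csv \
                    --out out/exo/rates.csv --window 7
nucleokit compare   --rates out/exo/rates.csv --out out/exo/stats.json
```

Packaged scenarios: `dnase_titration`, `exoiii_titration`,
`exoiii_overhangs`, `t7_overhangs`, `mismatches`, `methylation`,
`nickase_coupling`, `trex2_ss`, `klenow`, `rnase_a`, `rnase_h`.

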