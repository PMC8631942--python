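# shpkit

Quantitative toolkit for analyzing how ITIM/ITSM-bearing immune
checkpoint receptors (PD-1, BTLA) recruit the tandem-SH2 phosphatases
SHP1 and SHP2. The package re-implements, as tested reusable components,
the analyses that establish the receptors' phosphatase-binding
specificities:

- **`shpkit.synthetic`** — generators for every input the pipeline
  consumes, with known ground truth and fixed seeds: equilibrium SPR
  isotherms, 20 Hz two-state binding trajectories, sparse two-channel
  single-molecule movies, and microcluster cell-image pairs.
- **`shpkit.spr`** — 1:1 Langmuir equilibrium isotherm fitting (Kd, Rmax),
  the bundled affinity table of measured pY-motif:SH2 dissociation
  constants, fold-ratio arithmetic, binding free energies, and a
  closed-form sensorgram simulator.
- **`shpkit.modes`** — free energies and ranking of the six candidate
  tandem-SH2 binding modes (four monovalent, bivalent parallel,
  bivalent antiparallel) using an effective-concentration avidity cycle;
  Boltzmann mode occupancies and the minimal C_eff for bivalent advantage.
- **`shpkit.localize`** — sub-pixel spot detection (DoG band-pass +
  2-D Gaussian refinement), intensity-histogram mixture fits,
  photobleaching step counting by change-point segmentation, and
  two-channel colocalization with a configurable 0.5-s window rule.
- **`shpkit.hmm`** — two-state Gaussian-emission hidden Markov model:
  deterministic Baum-Welch fitting, Viterbi decoding, dwell-time
  extraction with censoring, and kinetic rate estimation.
- **`shpkit.clusters`** — rolling-ball style background subtraction,
  microcluster mask generation, per-cell effector/receptor enrichment
  ratios, and per-condition group comparison.
- **`shpkit.motifs`** — ITIM/ITSM consensus scanning, ITIM–ITSM tyrosine
  spacing, hexamer mismatch comparison, and the quadratic fit of
  recruitment signal against pY+1 residue molecular volume.

## Command-line interface

All functionality is exposed under a single `shpkit` entry point:

```bash
# synthetic data (ground truth written as a JSON sidecar)
shpkit simulate isotherm   --seed 1 --out out/
shpkit simulate trajectory --seed 1 --out out/
shpkit simulate movie      --seed 1 --out out/ --config config.json
shpkit simulate clusters   --seed 1 --out out/

# equilibrium SPR fitting (CSV: analyte,ligand,concentration_nM,response_RU)
shpkit fit-spr out/isotherm.csv --out fits.json

# tandem-SH2 binding-mode ranking from the bundled affinity table
shpkit modes --receptor PD-1 --phosphatase SHP2 --ceff-mM 1

# single-molecule analyses
shpkit spots detect movie/receptor.tif --out receptor_spots.csv
shpkit spots coloc receptor_spots.csv ligand_spots.csv --radius 2 --window 0.5
shpkit spots bleach trajectories.csv --out steps.csv
shpkit hmm fit trajectories.csv --out params.json
shpkit hmm decode trajectories.csv params.json --out decoded.csv
shpkit hmm rates decoded.csv --out rates.json

# microcluster enrichment
shpkit clusters quantify receptor.tif effector.tif --radius 50 --thresh 3

# motif analyses
shpkit motifs scan proteins.fasta
shpkit motifs compare VDYGEL IVYASL
shpkit motifs spacing --itim-y 223 --itsm-y 248
```

## Notes on the bundled affinity table

`shpkit/data/affinity_reference.csv` carries one dissociation constant
per (receptor motif, SH2 domain) pair. Rows with `source=printed` are
measured values (including the `ND` sentinel for the undetectable
SHP1-cSH2:PD-1-ITIM interaction). Four BTLA rows marked `source=ordinal`
have no published numeric value; they are placeholders that only
preserve each SH2 domain's established motif preference and must not be
used quantitatively. All categorical mode-ranking conclusions are
invariant to their exact values (property-tested).
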