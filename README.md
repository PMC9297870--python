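# dupepi

Gene-duplication genotyping from qPCR copy-number panels, plus a
microsatellite (SSR) population-genetics stack, built for surveying the
origins and spread of a herbicide-resistance gene duplication across
plant populations.

The pipeline has two arms:

1. **Copy-number epidemiology** — qPCR Ct tables are converted to
   relative copies per haploid genome by the comparative-Ct method
   (`2^(Ct_ref − Ct_target)` against a single-copy reference gene), and
   each individual is assigned a duplication genotype by a rule
   cascade:
   - **S** — single-copy (EPSPS ≤ 1.4),
   - **A** — increased EPSPS with both repeat-junction markers present,
   - **B** — increased EPSPS, no repeat markers, MGE ≥ 10,
   - **C** — increased EPSPS, no repeat markers, MGE < 10.

   Calls aggregate to per-population and per-region genotype
   proportions with marker means and standard errors.

2. **SSR population genetics** — capillary fragment sizes are binned
   onto a fixed-motif ladder into a genotype matrix, which feeds:
   missing-data filtering, Monte Carlo exact tests of Hardy–Weinberg
   and linkage equilibrium (Fisher-combined across populations),
   diversity summaries (H_O, unbiased H_E, rarefied allelic richness,
   multilocus F_IS with bootstrap CI), Prevosti distances with
   neighbour-joining trees and locus-bootstrap supports, PCA of allele
   dosages, and a simplified admixture-model Gibbs sampler with
   CLUMPP-style run alignment and Evanno ΔK model choice.

A synthetic-data module generates Ct panels and SSR datasets (island
model with Balding–Nichols population frequencies and inbreeding) with
full ground truth, so every stage is testable end to end.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(round-trip oracles, estimator calibration/recovery checks); the rest
are per-module unit and property tests.

## CLI

All commands are deterministic given `--seed`.

```sh
dupepi simulate --seed 17 --out-dir fixtures/          # synthetic panel + SSR data + truth
dupepi quantify --panel panel.csv --out profiles.csv   # Ct -> copy numbers
dupepi classify --profiles profiles.csv --meta meta.csv \
    --out-calls calls.csv --out-summary summary.csv    # A/B/C/S calls + summaries
dupepi bin --fragments fragments.csv --motif 5 \
    --out-matrix matrix.csv --out-binmap binmap.json   # fragment sizes -> genotypes
dupepi diversity --matrix matrix.csv --out diversity.csv --bootstrap 1000 --seed 7
dupepi tree --matrix matrix.csv --reps 1000 --seed 7 --out tree.nwk
dupepi cluster --matrix matrix.csv --k-min 1 --k-max 5 --runs 4 --seed 7 --out-dir runs/
dupepi evanno --runs-dir runs/ --out deltak.csv
```

The genotype matrix is also exportable to GENEPOP
(`dupepi.io_formats.write_genepop`) and STRUCTURE
(`write_structure_input`) formats for cross-validation against those
tools.

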