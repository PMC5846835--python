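# codonopt

Analysis toolkit asking whether the standard genetic code is nonrandomly
organized with respect to the biophysics of nucleic acids.  It quantifies the
impact of every single-base codon substitution on molecular-dynamics summary
statistics (dFLUX: mask-averaged atomic fluctuation; dCORR: mask-averaged
atomic correlation) and on a sequence-based DNA flexibility score (dTRX, from
a 16-entry dinucleotide percent-BII scale), splits those impacts into
synonymous/nonsynonymous and strand-symmetry categories, and compares the
canonical code's category totals against the exhaustive ensemble of **13,823**
degeneracy-preserving alternative codes (all position-wise base-permutation
triples of the 4x4x4 codon cube, identity excluded) via empirical ECDF
p-values.

Because the original per-codon MD summaries came from thousands of GPU
simulations, a seeded synthetic-profile generator with controlled statistical
structure (`aa_determined`, `gc_linear`, `iid_noise`) stands in for them so
the entire pipeline is testable at desk scale; real trajectory-analysis
summary tables can be dropped in through the same consolidated profile
format.

## Layout

| module | purpose |
| --- | --- |
| `codonopt.code_tables` | codons, the canonical code, 576 directed transitions, S/N and SS/NN/SN classification |
| `codonopt.alt_codes` | the 13,824 base-permutation triples and induced alternative codes |
| `codonopt.impact_metrics` | profile summaries, per-transition dFLUX/dCORR impact tables, category totals |
| `codonopt.trx_flex` | dinucleotide flexibility table, TRX scoring, dTRX impacts |
| `codonopt.optimization_test` | streamed exhaustive ensemble evaluation, ECDF p-values, metric correlation |
| `codonopt.md_io` | parsers for per-atom fluctuation / correlation-matrix text files, consolidated profile TSV |
| `codonopt.synthetic_data` | seeded synthetic profile generator |
| `codonopt.report` / `codonopt.cli` | positional impact profiles, result tables, manifests, figures, CLI |

Conventions (recorded in every run manifest): transitions are directed (576;
category sums double undirected totals, ECDF p-values unaffected); STOP is a
21st label with degeneracy 3; the complementary-strand codon is the reverse
complement of the codon read 5'->3'; the ECDF counts ties as <=; strand-class
membership varies per code and a category empty under a given code is dropped
(NaN) from that category's ensemble.

The packaged dinucleotide scale (`codonopt/data/trx_bii.tsv`) is an editable
best-effort transcription of the published experimental percent-BII scale;
swap in your own 16-line `MN<TAB>value` file via `--trx-table` to use
different values.

## CLI

```sh
# synthetic profiles -> impact tables -> ensemble test
codonopt simulate --model aa_determined --noise-sd 0 --seed 1 --out profiles.tsv
codonopt impacts --profiles profiles.tsv --out impacts.tsv
codonopt test --metric dflux --profiles profiles.tsv --out-dir out/

# sequence-based flexibility test with the packaged scale
codonopt test --metric dtrx --out-dir out_trx/ --dump-ensemble --plot

# sliding-window TRX scan of a FASTA file
codonopt trx --fasta genome.fa --window 5 --out scan.tsv

# end-to-end YAML-configured run (profiles, results, positional heatmaps)
codonopt report --config run.yaml --seed 1 --out-dir report/
```

Example `run.yaml`:

```yaml
input:
  mode: synthetic            # synthetic | profiles | trx
  generator: {model: iid_noise, noise_sd: 0.1}
metrics: [dflux, dcorr, dtrx]
categories: [N, S, NN, SN, SS]
plots: true
seed: 1
```

Real MD summaries enter through `codonopt profiles --input-dir DIR` where
`DIR` holds one subdirectory per codon containing paired `rmsf*` (two-column
per-atom fluctuation) and `corr*` (square correlation matrix) text files.

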