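# mosaicstage

Low-level somatic mosaicism analysis from multi-tissue deep read counts:
reciprocal all-pairs variant calling, artifact filtering, classification of
mutations as **early** (shared across ≥2 organs), **late** (restricted to one
organ) or **tumor**, and downstream characterization by mutational
signatures, transcriptional strand asymmetry, dN/dS selection, context
mutability and pLI — together with a synthetic cohort generator so the full
pipeline is testable without any external data.

## Layout

| module | purpose |
| --- | --- |
| `mosaicstage.synthetic` | cohort generator: planted early/late/tumor clones, oxoG and blacklist artifacts, gene models, pLI table, reference signatures, BED blacklists |
| `mosaicstage.calling` | exact binomial presence test, BH correction, case/control `call_pair`, reciprocal `all_pairs_call` |
| `mosaicstage.classify` | oxoG and region blacklist filter cascade, shared-variant VAF-concordance rescue, early/late/tumor stage assignment |
| `mosaicstage.signatures` | 96-channel catalogs, multiplicative-update KL NMF, NNLS reference refitting with pruning, reduced indel catalog, strand asymmetry, exposure clustering |
| `mosaicstage.selection` | coding consequence annotation, 192-class opportunity tensor, global-ω dN/dS with profile-likelihood CI, atypical-mutability fraction, pLI profiles |
| `mosaicstage.pipeline` / `mosaicstage.io` | end-to-end driver, group summaries, truth-table validation harness, VCF/BED/TSV I/O |

## CLI

```bash
# full pipeline on a synthetic cohort
mosaicstage run --config config.yaml --out runs/demo --seed 7

# or stage by stage
mosaicstage simulate --config config.yaml --out runs/demo --seed 7
mosaicstage call     --calls runs/demo --out runs/demo/candidates.tsv
mosaicstage classify --calls runs/demo --blacklists runs/demo/blacklists \
                     --out runs/demo/classified.tsv
mosaicstage signatures --input runs/demo --out runs/demo/signatures.json
mosaicstage selection  --input runs/demo --out runs/demo/selection.json
mosaicstage report     --input runs/demo --out runs/demo/report.json
```

`config.yaml` keys mirror `CohortConfig` fields (all optional), e.g.:

```yaml
n_individuals: 50
organs_per_individual: [brain, blood, heart, liver]
depth_mean: 500
seq_error_rate: 0.001
early_rate: 2.0
tumor_fraction: 0.1
```

Outputs are plain text: per-tissue VCF 4.2 (`DP`/`AD` plus orientation-split
`F1R2`/`F2R1` FORMAT fields), 0-based half-open BED blacklists, and tidy TSV
tables for truth, classified variants and group summaries.

## Notes

- Coordinates are 0-based half-open internally and 1-based in VCF output.
- The presence test is an exact one-sample binomial tail; organ specificity
  and shared-variant concordance reuse it one-sided vs. the error rate and
  two-sided vs. the partner VAF respectively.
- The two ensemble pass flags (`pass_primary`, `pass_secondary`) model a
  two-caller PASS conjunction: BH-corrected presence + control absence, and
  a strand-balance/support heuristic.
- NMF minimizes generalized KL divergence with multiplicative updates
  (200 iterations default, best of N restarts); signature columns are
  normalized with scale absorbed into exposures.
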