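# gradientnet

Tissue-gradient co-expression grouping and signed hormone-integrated
network assembly for seed-germination genetics in *Arabidopsis*.

The pipeline ingests a tissue-resolved microarray expression table
(funiculus FUN, chalazal seed coat CSC, distal seed coat DSC) plus
hormone-regulon gene lists and:

1. **normalizes** the DSC signal by the tissue-area ratio (default 26.8)
   and drops genes whose raw signal is below 10 in both FUN and CSC;
2. **groups** each auxin-regulated gene by its FUN→CSC expression
   gradient crossed with its auxin-response direction (four groups,
   G1–G4), and partitions the six AFB/TIR1 auxin co-receptor loci into a
   down-gradient (AFB1) and an up-gradient (AFB5) group;
3. **subgroups** each gradient group by greedy complete-linkage
   agglomeration under an all-pairs 3-point R² ≥ 0.90 criterion, with
   leave-one-out group-sum validation;
4. **assembles** a signed, directed gene network from the AFB-group
   gradient rule and hormone-regulon membership (ABA via ABI3/4/5,
   brassinosteroid via BES1/BZR1), exported as SIF, GraphML, and TSV;
5. **scores** paired mutant-vs-wild-type germination assays with a
   paired two-tailed t-test.

A synthetic-data generator plants co-expression subgroups (scalar
multiples of shared 3-point base profiles with multiplicative log-normal
noise) with full ground truth, so every stage is testable offline.

## CLI

```sh
# generate a synthetic dataset with ground truth
gradientnet simulate --out-dir fixtures/ --seed 1

# full pipeline from a YAML config
gradientnet run --config pipeline.yaml --out-dir out/

# individual stages
gradientnet subgroup --expr fixtures/expression.tsv \
    --auxin-up fixtures/auxin_up.txt --auxin-down fixtures/auxin_down.txt \
    --r2-min 0.90 --linkage complete --out-dir out/

# paired germination analysis (real or simulated assays)
gradientnet germination --simulate --n-pairs 8 --effect 0.2 --seed 4
```

A minimal `pipeline.yaml`:

```yaml
expression_table: fixtures/expression.tsv
regulons:
  auxin_up: fixtures/auxin_up.txt
  auxin_down: fixtures/auxin_down.txt
area_ratio: 26.8
low_signal_threshold: 10
r2_min: 0.90
```

Outputs: `groups.tsv`, `excluded.tsv`, `subgroups.tsv`, `r2_matrix.tsv`,
`loo_validation.tsv`, `net.sif`, `net.graphml`, `net.nodes.tsv`,
`net.edges.tsv`, and a `manifest.json` with input checksums and stage
counts. Reruns on identical inputs are byte-identical (manifest
timestamp aside).

## Input formats

* **Expression table** — TSV with columns `gene`, `FUN`, `CSC`, `DSC`
  (raw microarray signals; column names/separator configurable via
  `TableDialect`). Gene IDs are locus identifiers (`At2g28470`),
  canonicalized case-insensitively. To use a spreadsheet source, export
  the relevant sheet to TSV first; no binary formats are parsed.
* **Regulon lists** — one gene ID per line.
* **Germination assays** — TSV with columns `genotype`, `dish_id`,
  `germinated`, `total`, `paired_control_dish` (empty for control
  dishes).

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(R² symmetry/affine invariance, filter partition identities, t-test
closed form), a brute-force oracle for the greedy subgrouping on small
instances, and Monte-Carlo checks of planted-partition recovery and
paired-t type-I error.

## Notes on methodology

* The published subgroup assignment was manual; the deterministic greedy
  complete-linkage rule here is a reconstruction. Threshold (`r2_min`),
  linkage (`complete` vs `single` reference-gene mode), and a positive-
  slope constraint are configurable.
* R² is the squared Pearson correlation of the ordered
  (FUN, CSC, DSC/area-ratio) triple, intercept included; no p-values
  are attached to 3-point correlations.
* Germination-role labels for network nodes come from a bundled
  annotation table (`src/gradientnet/data/table_annotations.tsv`); they
  are consumed, never inferred.
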