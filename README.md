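# coexscreen

Seed-gene co-expression screening and downstream analysis for
gene-by-sample expression matrices, with a synthetic-data generator for
end-to-end validation.

Given a log2 expression matrix and one seed gene, the pipeline:

1. scores every gene against the seed with a **centered cosine
   similarity** (identical to Pearson correlation; the un-centered
   statistic is available via a flag),
2. assigns significance with a **permutation test** (default B = 1000,
   shared seed-profile permutations; exhaustive enumeration is used
   automatically when the sample count is small enough),
3. controls FDR with **Benjamini–Hochberg** adjustment and splits
   significant genes into positive/negative correlates (default
   FDR < 0.1),
4. clusters gene panels by **Spearman similarity** with average-linkage
   hierarchical clustering,
5. tests gene-set catalogs for **hypergeometric over-representation**
   and merges redundant terms by **Cohen's kappa** (threshold 0.3),
6. detects dense complexes in a gene network with **MCODE**
   (k-core-based vertex weighting, seeded expansion, haircut/fluff),
7. runs a **Welch two-sample contrast** between groups and a
   **Spearman-vs-log10(dose) permutation trend test** for titration
   designs.

The `coexscreen.synthetic` module generates expression matrices,
metadata, GMT catalogs and networks with planted structure (correlated
modules around a seed gene, group effects, dose slopes, enriched terms,
cliques) plus a machine-readable truth record, so every stage can be
validated without external data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(statistic equivalence, exhaustive-permutation and brute-force oracles,
null calibration, planted-structure recovery, determinism).

The acceptance self-check can also be run standalone; it re-derives all
acceptance quantities from scratch and writes the (empty — all checks
are property-based, there are no headline numeric targets) target map:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## CLI

```sh
# generate a synthetic study with planted structure
coexscreen simulate --out-dir data/ --rng-seed 1

# run a single stage
coexscreen screen --matrix data/matrix.tsv --seed-gene GENE_SEED \
    --permutations 1000 --fdr 0.1 --rng-seed 1 --out screen.tsv
coexscreen enrich --query neg_genes.txt --gmt data/sets.gmt \
    --background all_genes.txt --out-prefix enr
coexscreen mcode --edges data/network.tsv --out complexes.json

# or the whole pipeline from a config file
coexscreen run --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
rng_seed: 1
output_dir: out/
simulate:            # or an `inputs:` block with matrix/metadata/gmt/edges paths
  n_null: 800
  n_pos: 50
  n_neg: 50
  planted_r: 0.8
screen:
  permutations: 1000
  fdr: 0.1
```

All tabular outputs are TSV with a version/config-hash/seed stamp;
`report.json` summarizes every stage. Identical config + seed gives
byte-identical tabular outputs.

## File formats

- **Expression matrix**: TSV, genes in rows, samples in columns, header
  row of sample ids, first column gene ids. `#` lines are ignored.
- **Metadata**: TSV with columns `sample_id, group, subset, dose, replicate`.
- **Gene sets**: standard GMT (term, description, members).
- **Networks**: two-column TSV edge list (undirected, simple).
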