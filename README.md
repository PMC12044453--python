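# fragcompare

Comparative analysis of molecular fragment libraries: retrosynthetic (RECAP)
decomposition, structure standardization, rule-of-three profiling,
synthetic-accessibility scoring, fingerprint-based diversity statistics,
inter-library overlap and scaffold censuses, and 2D chemical-space
embeddings — plus a synthetic-data generator so the whole pipeline is
testable without downloading any compound collection.

## Layout

| module | what it does |
| --- | --- |
| `fragcompare.chem_io` | SMILES-table/SDF readers and writers, library registry |
| `fragcompare.standardize` | element whitelist, largest component, reionize, neutralize, canonical tautomer, deduplication |
| `fragcompare.recap` | the eleven named cleavage rules, hierarchical leaf decomposition, per-library fragment aggregation |
| `fragcompare.properties` | rule-of-three profiles/filter and the 18-descriptor constitutional/complexity panel |
| `fragcompare.sa_score` | synthetic-accessibility score (fragment contributions minus complexity penalty, scaled to [1, 10]) |
| `fragcompare.similarity` | MACCS/Morgan fingerprints, Tanimoto, exhaustive or ten-subsets-of-5000 diversity distributions |
| `fragcompare.overlap_freq` | unique/overlap tables, most-frequent-fragment tables (70–300 Da window), Bemis–Murcko scaffold census |
| `fragcompare.chemspace` | kNN graph → minimum spanning tree → tree layout, and t-SNE embeddings |
| `fragcompare.synthetic_data` | block-and-linker generator for NP-like / synthetic-like toy libraries with planted duplicates |
| `fragcompare.pipeline` / `fragcompare.cli` | end-to-end orchestration and the `fragcompare` command |

## CLI

```bash
# generate a toy natural-product-like library
fragcompare generate --profile np_like --n 500 --seed 7 --out npgen.smi

# standardize + RECAP-decompose it
fragcompare fragment --library npgen.smi --mw-cutoff 1000 --out fragments.smi

# property profiles, SA scores, diversity, overlap, scaffolds, embeddings
fragcompare profile   --library npgen.smi --out profile.csv
fragcompare sascore   --library npgen.smi --threshold 6 --out sa.csv
fragcompare diversity --library npgen.smi --fingerprint morgan2 --seed 42 --out cdf.csv
fragcompare overlap   --a npgen.smi --b other.smi
fragcompare topfrags  --library npgen.smi --top 20 --mw-min 70 --mw-max 300
fragcompare scaffolds --library npgen.smi
fragcompare embed     --method tmap --libraries a.smi,b.smi --fingerprint maccs --seed 42 --out coords.csv

# or everything at once from one YAML config
fragcompare run --config run.yaml
```

A run config is a flat YAML file:

```yaml
registry: libraries.cfg   # INI file: one [name] section per library
out_dir: bundle
mw_cutoff: 1000
fingerprints: [maccs166, morgan2_1024]
seed: 42
```

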