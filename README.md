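# fpscreen

Ligand-based virtual screening on molecular count fingerprints.

The package implements a text-retrieval-derived similarity measure for
sparse count fingerprints alongside classical coefficients, a seeded
reference-based screening protocol, early-recognition evaluation, and a
synthetic dataset generator so the whole pipeline can be exercised
without any licensed compound database.

## What's inside

| module | contents |
|---|---|
| `fpscreen.fingerprints` | `CountFingerprint` / `FingerprintDataset` data model, dense-csv and sparse-pairs text I/O, modulo folding, optional RDKit SMILES adapter |
| `fpscreen.similarity` | the adapted text-processing measure (`asmtp`) with dataset-level feature scaling (`compute_feature_scaling`), Tanimoto (continuous + binary), Dice, cosine, Euclidean, extended Jaccard; a uniform measure registry with vectorised batch scorers |
| `fpscreen.screening` | seeded per-class reference selection (unified across measures), deterministic decreasing-score ranking of the whole database, CSV/JSON serialization |
| `fpscreen.evaluation` | recall@p%, sensitivity/specificity, ROC/AUC (tie-aware trapezoid), enrichment factor, BEDROC(α), cross-measure class summaries and best-per-class tallies |
| `fpscreen.synthdata` | class-structured ~90%-sparse synthetic count fingerprints (class core features + geometric counts), YAML-configurable |
| `fpscreen.cli` | `fpscreen simulate / screen / evaluate` subcommands with JSON run manifests |

### The similarity measure

For molecules `m1`, `m2` over features `j = 0..M-1`, with `mu_j` the mean
of the non-zero values of feature `j` across the screened dataset:

- both non-zero: reward `0.5 * (1 + exp(-((m1j - m2j) / mu_j)^2))`
  (1 at equality, lower-bounded by 0.5);
- exactly one non-zero: penalty `-lam` (default `lam = 0.0001`);
- both zero: no contribution.

The per-feature sum is divided by the number of features present in either
molecule and rescaled to `[0, 1]` via `S = (F + lam) / (1 + lam)`.
Identical fingerprints score exactly 1.0; disjoint supports exactly 0.0.
A `scaling_mode="nonzero-stddev"` variant (the original text-processing
formulation) is available for comparison.

Feature scaling is computed once over the entire screened database,
references included; reference structures stay in the ranked database and
count as retrievable actives (switchable via `ScreenConfig(exclude_query=True)`).

## CLI

```bash
# 1. generate a synthetic dataset: 5 classes x 50 actives + 2000 decoys
fpscreen simulate --classes 5 --actives 50 --decoys 2000 --seed 42 --out run/sim

# 2. screen it with two measures (reference selection is seed-unified)
fpscreen screen --dataset run/sim/dataset.csv --measure asmtp    --refs 10 --seed 42 --out run/asmtp
fpscreen screen --dataset run/sim/dataset.csv --measure tanimoto --refs 10 --seed 42 --out run/tanimoto

# 3. evaluate recall@1/5%, AUC, EF(1%), BEDROC(20)
fpscreen evaluate --rankings run/asmtp/rankings.csv --dataset run/sim/dataset.csv --out run/eval
```

Every step writes a `manifest.json` (parameters, seed, input hashes) next
to its results; all randomness is seeded, so repeat runs are
byte-identical.

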