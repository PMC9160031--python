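# targetscreen

Layered in silico target prediction for small molecules, with a consensus
QSAR stage for candidate confirmation.

Given a query molecule, which proteins does it plausibly bind? Single
ligand-based predictors and single QSAR models are individually noisy; this
package implements a stepwise screening strategy that narrows the target
space layer by layer:

1. **Similarity voting** — four heterogeneous similarity predictors
   (fingerprint scheme × score-aggregation rule) each rank targets from a
   reference ligand–target library; each keeps its top 15; identifiers are
   normalized to UniProt accessions and targets predicted by **at least two
   voters** survive.
2. **Enrichment screen** — the surviving set is checked for functional
   coherence with an exact upper-tail hypergeometric test against GO/KEGG
   style gene sets (GMT), selecting terms at raw *P* < 0.01.
3. **Consensus SAR modelling** — per candidate target, bioactivity records
   (IC50/EC50/Ki) are curated, converted to µM, InChIKey-deduplicated,
   binarized at 10 µM (strictly below = active) and scaffold-thinned; random
   forests are trained on three descriptor families — CATS (210-d
   pharmacophore-pair counts), MACCS keys (166-d), and a frozen 206-column
   2D physicochemical panel — under stratified 5-fold cross-validation, and
   the consensus classifier averages the three active-class probabilities:

   p(active | x) = ⅓ · [p_CATS(x) + p_MACCS(x) + p_2D(x)],

   reported as SE/SP/ACC and the Mann–Whitney (midrank-tied) ROC AUC on
   pooled out-of-fold predictions.

Externally produced docking score tables can be ingested and ranked
alongside, and small binding-kinetics consistency checks (K_D = k_off/k_on)
are included. Everything runs offline: a seeded synthetic-data module
generates reference libraries, bioactivity tables with planted
structure–activity signal, and annotation sets with planted enrichment, so
the whole strategy is testable end to end with no external services.

Intended users: cheminformaticians and computational pharmacologists who
want a reproducible, self-contained implementation of multi-platform target
triage with consensus QSAR confirmation.

## Worked example

Fit the consensus SAR model on a planted-signal synthetic bioactivity set
(200 molecules, 20 scaffold classes, half potent, noise sd 0.2 log10 µM):

```python
from targetscreen import ConsensusQSAR, RFConfig, curate, scaffold_thin
from targetscreen.synthetic import SyntheticSpec, gen_bioactivity

records, truth = gen_bioactivity(SyntheticSpec(seed=7))
dataset = scaffold_thin(curate(records), max_per_scaffold=5, seed=7)
results = ConsensusQSAR(dataset, RFConfig(seed=7)).fit()
print(results.summary())
```

```
Consensus SAR model (random forest x {CATS, MACCS, PHYSCHEM2D})
  molecules: 100 (50 active / 50 inactive)
  cross-validation: stratified 5-fold, seed 7
  forest: 500 trees, max_features=sqrt

    scheme    SE    SP   ACC   AUC
      CATS 0.900 0.820 0.860 0.912
     MACCS 0.900 0.840 0.870 0.939
PHYSCHEM2D 0.920 0.900 0.910 0.974
 CONSENSUS 0.940 0.920 0.930 0.970
```

Reading the table: after thinning, 100 molecules remain (5 per scaffold
class). Each row is one descriptor scheme's random forest, evaluated on
pooled out-of-fold predictions; `CONSENSUS` averages the three probability
sets. The consensus AUC (0.970) sits at the top of the single-scheme range
and, across repeated cross-validation seeds, varies less than any single
scheme — the motivation for averaging. `results.predict(mols)` then scores
new molecules with per-scheme and consensus probabilities plus the binary
call at probability ≥ 0.5.

The full layered screen runs from one seeded config, from Python
(`targetscreen.run_pipeline`) or the CLI:

```bash
targetscreen run --seed 17 --out runs/demo        # synthetic end-to-end
targetscreen simulate --seed 1 --out fixtures/    # just the inputs
targetscreen qsar-train --activity fixtures/bioactivity.csv --seed 1 \
    --model-out model.joblib
```

Each pipeline stage writes an immutable artifact (predictions, consensus
support with Venn overlap counts, enrichment table, QSAR metrics), and the
run closes with a schema-validated `summary.json` and a timestamped log.

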