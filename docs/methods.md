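# Methods

`targetscreen` implements a layered, ligand-based strategy for narrowing the
protein target space of a small molecule, followed by a consensus
structure–activity (SAR) classification stage for the surviving candidates.
This note records the models, conventions and design choices behind each
stage, what the synthetic study conditions do and do not emulate, and the
known limitations.

## 1. Structure handling and identity

All structures pass through a single canonicalization engine (RDKit).
Salts/mixtures are reduced to the largest organic fragment (carbon-containing
preferred, ties broken by heavy-atom count then lexicographic SMILES) before
canonicalization; stereochemistry is preserved. Duplicate detection uses the
full 27-character InChIKey, i.e. it is stereo-sensitive — two stereoisomers
are distinct molecules. Cross-toolkit SMILES equality is deliberately not
promised: only internal consistency matters for deduplication and scaffold
grouping, which is all the pipeline needs.

Bemis–Murcko scaffolds (ring systems plus linkers, side chains removed) are
the unit of structural redundancy. Acyclic molecules have the empty scaffold
and are treated as singleton classes wherever scaffold grouping occurs.

## 2. Descriptor families

Three fixed-width descriptor schemes feed the SAR models.

**CATS (210 columns).** Pharmacophore-point pair counts over topological
distance. Six point types are assigned per atom from the 2D graph only:

- `D` donor: O or N carrying at least one hydrogen;
- `A` acceptor: any O; or N that is not positively charged and not
  amide-like (bonded to a carbonyl carbon);
- `P` positively ionizable: formal positive charge, or a basic amine
  (non-aromatic sp3 N, not amide-like);
- `N` negatively ionizable: formal negative charge, or an acidic OH
  (carboxylic/sulfonic);
- `L` lipophilic: carbon whose explicit neighbours are all carbon;
- `R` aromatic: aromatic flag.

An atom may carry several types. For each of the 21 unordered type pairs and
each shortest-path distance 0–9, typed atom pairs are counted; pairs beyond
distance 9 are discarded, not clamped. Conventions that a CATS
implementation must fix and that are oracle-tested here: an atom carrying a
type contributes one self-pair to that type's distance-0 bin; two distinct
types on one atom contribute once to their cross-pair distance-0 bin; a pair
of distinct atoms contributes once per combination of one type from each
atom. The vector is scaled by 1/n_heavy (size normalization) — raw counts
would let molecular size dominate; the scaling choice is frozen here, not
inferred. Layout is pair-major (D,D), (D,A), …, (R,R), distance-minor.

**MACCS (166 columns).** The public 166 structural keys as 0/1 bits. The
fingerprint engine exposes 167 positions with an unused padding bit 0, which
is dropped so the contract is exactly 166.

**2D physchem panel (206 columns).** A frozen panel of 206 two-dimensional
descriptors (constitutional counts, topological and connectivity indices,
E-state sums, logP/MR estimates, charge proxies, autocorrelations) drawn
from RDKit's descriptor set. The engine ships 210 2D descriptors; four are
excluded to fix the panel at 206: `qed` and `SPS` (composite scores, not
physchem descriptors), `Ipc` (numerically explosive on larger graphs) and
`NumRadicalElectrons` (constant zero on standard organics). Membership and
order are frozen in a versioned JSON manifest shipped with the package
(`data/physchem2d_manifest.json`). Column semantics intentionally do not
mirror any commercial 2D panel name-for-name — only the dimension and
2D-only character are contractual. A descriptor that fails or returns a
non-finite value on a molecule is set to 0 with a logged warning; matrices
never contain missing values.

## 3. Pseudo-platform target prediction and consensus

The strategy's first layer asks four heterogeneous ligand-based predictors
for ranked targets and keeps what at least two agree on. Remote prediction
services are versioned and not callable reproducibly, so each voter is an
internal similarity predictor over a reference ligand–target library,
distinctly configured by fingerprint scheme × aggregation rule:

| voter | fingerprint | per-target score |
|---|---|---|
| sim-morgan2-max | Morgan r=2, 2048 bits | max ligand similarity |
| sim-morgan3-top3 | Morgan r=3, 2048 bits | mean of top-3 similarities |
| sim-path-max | RDKit path, 2048 bits | max ligand similarity |
| sim-maccs-top3 | MACCS 166 | mean of top-3 similarities |

Similarity is the Tanimoto coefficient; two all-zero fingerprints are
defined to have similarity 1.0 (they are indistinguishable). Each voter's
list is truncated to the top 15 targets — one uniform, documented screening
rule in place of per-service heuristics — with ties broken lexicographically
by accession for determinism. Identifiers are normalized to UniProt
accessions (a small gene-symbol table is packaged; unmapped ids are dropped
with a warning, and raw ids collapsing onto one accession keep the best
score). The consensus keeps targets predicted by ≥ `min_support` voters
(default 2) and reports per-target support plus Venn-style overlap counts
for every voter combination. Externally produced platform result files can
be imported and vote on equal terms.

## 4. Enrichment screen

Functional coherence of the surviving target set is screened with an exact
upper-tail hypergeometric test per annotation term: with a universe of N
annotated genes, a term of size K, and n annotatable query genes of which k
hit the term, P = P(X ≥ k), X ~ Hypergeom(N, K, n). Selection uses the raw
P < 0.01 gate — no multiple-testing correction enters the selection, which
mirrors the screening character of this stage; a Benjamini–Hochberg column
is emitted alongside for inspection. The universe defaults to all genes
annotated in the loaded GMT, an explicit and configurable stand-in for the
tool-defined backgrounds of web enrichment services. Annotations are taken
as flat sets; no ontology-graph propagation is performed.

## 5. Consensus SAR modelling

Bioactivity curation, in order, with per-molecule provenance: keep only
IC50/EC50/Ki endpoints; convert values to µM (nM ÷ 1000, M × 10⁶);
canonicalize and InChIKey-deduplicate structures, pooling duplicate entries'
records; per-molecule potency = arithmetic mean of the qualifying µM values
(pooling across endpoint types; a geometric/−log10 mean is available as a
switch, off by default); label active iff mean < 10 µM — the boundary is
strict, exactly 10 µM is inactive. Scaffold classes larger than
`max_per_scaffold` (default 5) are thinned to a seeded uniform random subset
of exactly that size, so a single heavily explored chemotype cannot dominate
the fit.

One random forest per descriptor scheme (500 trees, √p features per split,
unlimited depth, seeded — frozen defaults recorded in every report) under
seeded stratified 5-fold cross-validation; each class must have ≥ 5 members.
The consensus model averages the three schemes' active-class probabilities;
a molecule is called active at probability ≥ 0.5 (the boundary counts as
active). SE, SP, ACC and AUC are computed from the pooled out-of-fold
predictions (contractual; per-fold values are reported alongside — pooling
uses every prediction once, at the cost of mixing fold calibrations). AUC
uses the Mann–Whitney formulation with midrank tie handling:
AUC = (concordant + 0.5·tied) / (n_pos · n_neg). Identical configuration and
seed reproduce folds, forests and metrics byte-for-byte.

The user-facing surface follows the model/results convention:
`ConsensusQSAR(dataset, rf_config).fit()` returns a results object with the
fitted scheme forests, the CV record, `summary()`, `predict()` and
persistence.

## 6. Synthetic study conditions

The generators stand in for external ligand–target knowledge bases,
bioactivity exports, and annotation databases, with planted ground truth.

*Reference library*: 6 synthetic targets (UniProt-syntax accessions), 30
ligands each; each target owns a distinct Bemis–Murcko scaffold, and ligands
are that scaffold with two seeded decorations. A query minted from a
target's scaffold should recover that target.

*Bioactivity*: 200 molecules over 20 scaffold classes, half planted potent.
Scaffold classes are two-ring linked cores — the typical Bemis–Murcko shape
of drug-like molecules — so the class signature is large relative to the
1–3-atom decorations and the planted structure–activity signal is genuinely
scaffold-borne. Per-molecule potency is lognormal around the scaffold mean:
log10(µM) centres at −0.5 (≈0.3 µM) for potent and +2.5 (≈316 µM) for
impotent classes, Gaussian noise sd 0.2 log units; records report that
potency in nM under endpoints sampled from {IC50, EC50, Ki}. Optional
adversarial content exercises every curation filter: distractor endpoints
(Kd), InChIKey duplicates re-emitted under fresh ids (sharing the original's
drawn potency, so pooling is lossless and truth stays one-to-one), and
unparsable SMILES rows. Decoration pairs are drawn in seeded order with
InChIKey-repeat skipping, so planted truth maps 1:1 onto curated molecules.

*Annotations*: a 500-gene universe, 50 background terms of size 10–40, and
one planted term of size 40 overlapping a designated 20-gene query in 80% of
its members.

Every generator is a pure function of its spec (seed included): repeated
calls are byte-identical.

What passing on these conditions shows — and does not. The planted datasets
have noiseless endpoint records around a clean two-class potency split,
perfectly scaffold-coherent labels, and no assay heterogeneity,
inter-laboratory variance, activity cliffs or class imbalance. Results on
them validate the machinery (curation logic, descriptor contracts, CV
bookkeeping, consensus behaviour), not expected performance on real
bioactivity data, where AUCs will be lower and curation choices (endpoint
pooling in particular) carry real disagreement.

## 7. Numerical and procedural choices

- Hypergeometric tail probabilities are evaluated through the survival
  function of the hypergeometric distribution (log-space internally);
  equivalence with exact combinatorial enumeration is tested to 1e−12 for
  all populations N ≤ 25.
- Ranking ties anywhere (targets, docking rows, enrichment terms) break
  lexicographically by identifier; sorts are stable.
- Problem sizes in the test suite: the model-quality and stability checks
  run the full stated conditions (n=200, 10-seed sweeps, 500 trees); other
  modelling tests use reduced forests and datasets (50–200 trees, 60–120
  molecules), which exercise the identical code paths.
- `kd_from_rates` reports K_D = koff/kon to 3 significant figures;
  `KineticParams` enforces kd ≈ koff/kon within 0.5%. The caliper tumour
  volume is V = D/2 · d² (mm³); width > length triggers a swapped-axes
  warning but still computes.
- Docking is ingest-only: externally produced score tables are ranked
  per target (more-negative-is-better by default, recorded in the output)
  and juxtaposed with consensus support; no fused score is invented.

## 8. Known limitations

- The pseudo-platforms share one reference library; real prediction
  services differ in both knowledge base and scoring, so inter-voter
  disagreement here underestimates reality.
- The CATS typing rules are one published, frozen reading of pharmacophore
  typing; other implementations type amides, anilines and tautomers
  differently, and vectors are not comparable across implementations.
- The 2D panel matches no commercial descriptor set name-for-name.
- Enrichment ignores the annotation graph and uses raw-P selection by
  design; with many terms the screen is permissive (a BH column is provided
  but not used for selection).
- No applicability-domain estimate accompanies consensus predictions;
  probabilities on structures far from the training scaffolds are
  extrapolations.
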