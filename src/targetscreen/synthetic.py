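"""Seeded generators for every input the pipeline consumes.

The external resources this strategy was designed around — ligand–target
knowledge bases behind the prediction platforms, bulk bioactivity exports,
and curated annotation databases — are versioned, remote, and not
redistributable. This module generates structurally meaningful stand-ins
with planted ground truth, so every stage of the pipeline can be exercised
and validated end to end with no download:

- a reference ligand–target library where each synthetic target owns a
  distinct Bemis–Murcko scaffold (queries built from a scaffold should
  recover its target);
- bioactivity tables with scaffold-linked potency: whole scaffold classes
  are potent or impotent, potencies are lognormal around the scaffold mean
  (Gaussian noise on log10 µM), and the 10 µM activity threshold separates
  the planted classes;
- GMT annotation sets with one planted enriched term for a designated query.

Every generator is a pure function of its spec — the seed fully determines
each emitted artifact, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .chemio import Molecule, parse_molecule
from .enrichment import AnnotationDB
from .qsar import ActivityRecord
from .target_similarity import ReferenceLibrary

#: Two-slot scaffold templates. Each template defines one Bemis–Murcko
#: scaffold class: substituents attach via single bonds, so every molecule
#: minted from a template shares its framework, and the 24 frameworks are
#: pairwise distinct. Every core links two ring systems — the typical shape
#: of drug-like scaffolds — so a class's framework signature is large
#: relative to the 1–3 atom decorations and the planted structure–activity
#: signal is genuinely scaffold-borne.
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "{0}c1ccc(-c2ncc({1})s2)cc1",             # benzene-thiazole
    "{0}c1ccc(C2CCC({1})CC2)cc1",             # benzene-cyclohexane
    "{0}c1ccc(-c2ccc({1})o2)cn1",             # pyridine-furan
    "{0}c1ccc(N2CCOC({1})C2)cn1",             # pyridine-morpholine
    "{0}c1cnc(-c2ccc({1})s2)cn1",             # pyrazine-thiophene
    "{0}c1cnc(C2CCC({1})C2)cn1",              # pyrazine-cyclopentane
    "{0}c1cc(-c2ccc({1})[nH]2)ncn1",          # pyrimidine-pyrrole
    "{0}c1cc(C2CCOC({1})C2)ncn1",             # pyrimidine-tetrahydropyran
    "{0}c1ccc2cc(-c3ncc({1})o3)ccc2c1",       # naphthalene-oxazole
    "{0}c1ccc2cc(C3CCN({1})CC3)ccc2c1",       # naphthalene-piperidine
    "{0}c1cc2cc(-c3cc({1})n(C)n3)ccc2[nH]1",  # indole-N-methylpyrazole
    "{0}c1cnc2ccc(-c3nnc({1})s3)cc2c1",       # azanaphthalene-thiadiazole
    "{0}C1CCC(-c2ncc({1})[nH]2)CC1",          # cyclohexane-imidazole
    "{0}C1CCC(-c2cc({1})ncn2)CC1",            # cyclohexane-pyrimidine
    "{0}C1CCN(-c2ccc({1})cc2)CC1",            # piperidine-benzene
    "{0}N1CCN(-c2ccc({1})s2)CC1",             # piperazine-thiophene
    "{0}C1COCCN1-c1ccc({1})o1",               # morpholine-furan
    "{0}C1CCC(-c2ccc({1})cn2)C1",             # cyclopentane-pyridine
    "{0}c1ccc(-c2cc({1})n(C)n2)cc1",          # benzene-N-methylpyrazole
    "{0}c1ccc(-c2nnc({1})s2)cn1",             # pyridine-thiadiazole
    "{0}c1ccc2cc(C3COC({1})C3)ccc2c1",        # naphthalene-tetrahydrofuran
    "{0}c1cc2cc(-c3ncc({1})o3)ccc2[nH]1",     # indole-oxazole
    "{0}c1cnc2ccc(C3CCN({1})CC3)cc2c1",       # azanaphthalene-piperidine
    "{0}C1CCN(-c2ncc({1})[nH]2)CC1",          # piperidine-imidazole
)

#: Substituent fragments; valid both as a leading chain and inside a branch.
DECORATIONS: tuple[str, ...] = (
    "C", "CC", "CCC", "O", "OC", "N", "NC", "Cl", "F", "Br",
    "C(C)C", "CO", "CN", "C=C", "CCO", "OCC",
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Activity is planted on the log10(µM) scale: potent scaffolds centre at
    ``active_mean_log10_um`` (default 0.3 µM), impotent ones at
    ``inactive_mean_log10_um`` (default ~316 µM), with Gaussian noise of
    ``noise_sd`` log units per molecule — mirroring the lognormal spread of
    measured potencies and keeping the 10 µM binarization threshold
    meaningful.
    """

    seed: int = 0
    # reference library
    n_targets: int = 6
    ligands_per_target: int = 30
    scaffold_vocab: tuple[str, ...] = SCAFFOLD_TEMPLATES
    decoration_vocab: tuple[str, ...] = DECORATIONS
    # bioactivity
    n_molecules: int = 200
    n_scaffolds: int = 20
    frac_active_scaffolds: float = 0.5
    active_mean_log10_um: float = -0.5
    inactive_mean_log10_um: float = 2.5
    noise_sd: float = 0.2
    distractor_endpoint_frac: float = 0.0
    duplicate_frac: float = 0.0
    invalid_frac: float = 0.0
    # annotation database
    universe_size: int = 500
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    planted_term_size: int = 40
    query_size: int = 20
    hit_fraction: float = 0.8

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("scaffold_vocab", "decoration_vocab", "term_size_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _mint(template: str, pair: Sequence[str], mol_id: str) -> Molecule:
    return parse_molecule(template.format(*pair), mol_id)


def _mint_series(
    rng: np.random.Generator,
    template: str,
    vocab: Sequence[str],
    count: int,
    id_prefix: str,
    start_index: int = 0,
) -> list[Molecule]:
    """Mint ``count`` structurally distinct molecules from one template.

    Substituent pairs are drawn in a seeded random order; candidates whose
    InChIKey repeats an earlier structure (substituent fragments can
    coincide after attachment) are skipped, so planted per-molecule truth
    stays one-to-one.
    """
    n = len(vocab)
    all_pairs = [(i, j) for i in range(n) for j in range(i, n)]
    order = rng.permutation(len(all_pairs))
    mols: list[Molecule] = []
    seen: set[str] = set()
    for c in order:
        if len(mols) >= count:
            break
        i, j = all_pairs[c]
        mol = _mint(template, (vocab[i], vocab[j]),
                    f"{id_prefix}{start_index + len(mols)}")
        if mol.inchikey in seen:
            continue
        seen.add(mol.inchikey)
        mols.append(mol)
    if len(mols) < count:
        raise ValueError(
            f"decoration vocabulary yields only {len(mols)} distinct "
            f"molecules for template {template!r}, {count} requested"
        )
    return mols


# ---------------------------------------------------------------------------
# reference library


def gen_reference_library(spec: SyntheticSpec) -> tuple[ReferenceLibrary, dict[str, str]]:
    """Synthesize a ligand–target library with one scaffold per target.

    Returns the library plus the ground-truth map ``target_id →
    scaffold_smiles``. Target accessions are minted in UniProt syntax
    (``P10000``…).
    """
    if len(spec.scaffold_vocab) < spec.n_targets:
        raise ValueError(
            f"scaffold vocabulary ({len(spec.scaffold_vocab)}) smaller than "
            f"n_targets ({spec.n_targets})"
        )
    rng = np.random.default_rng(spec.seed)
    entries: list[tuple[Molecule, str]] = []
    truth: dict[str, str] = {}
    for t in range(spec.n_targets):
        target_id = f"P{10000 + t}"
        template = spec.scaffold_vocab[t]
        for mol in _mint_series(
            rng, template, spec.decoration_vocab, spec.ligands_per_target,
            id_prefix=f"{target_id}_lig",
        ):
            entries.append((mol, target_id))
        truth[target_id] = entries[-1][0].scaffold_smiles
    return ReferenceLibrary(entries), truth


def gen_query_for_target(
    spec: SyntheticSpec, target_index: int, query_seed: int | None = None
) -> Molecule:
    """A query molecule minted from one target's scaffold template."""
    rng = np.random.default_rng(spec.seed if query_seed is None else query_seed)
    template = spec.scaffold_vocab[target_index]
    pair = tuple(rng.choice(spec.decoration_vocab, size=2))
    return _mint(template, pair, f"query_t{target_index}")


# ---------------------------------------------------------------------------
# bioactivity


def gen_bioactivity(spec: SyntheticSpec) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Synthesize a BindingDB-style activity table with planted truth.

    Molecules are minted from ``n_scaffolds`` scaffold classes; a seeded
    half (``frac_active_scaffolds``) of the classes is planted potent. Each
    molecule's true potency is drawn lognormally around its scaffold mean;
    its records report that potency in nM under endpoints sampled from
    {IC50, EC50, Ki}. Optional adversarial content exercises every curation
    filter: distractor endpoints (Kd), InChIKey duplicates re-emitted under
    fresh ids (sharing the original's true potency, so pooling is lossless),
    and unparsable SMILES rows.

    Returns the record list and the truth table (mol_id, scaffold_smiles,
    true_activity_uM, true_label).
    """
    if spec.n_scaffolds > len(spec.scaffold_vocab):
        raise ValueError("n_scaffolds exceeds the scaffold vocabulary")
    rng = np.random.default_rng(spec.seed)
    n_active = int(round(spec.frac_active_scaffolds * spec.n_scaffolds))
    active_scaffolds = set(
        rng.choice(spec.n_scaffolds, size=n_active, replace=False).tolist()
    )
    per_scaffold = spec.n_molecules // spec.n_scaffolds
    remainder = spec.n_molecules - per_scaffold * spec.n_scaffolds

    records: list[ActivityRecord] = []
    truth_rows = []
    mol_counter = 0
    for s in range(spec.n_scaffolds):
        template = spec.scaffold_vocab[s]
        count = per_scaffold + (1 if s < remainder else 0)
        mean = (
            spec.active_mean_log10_um if s in active_scaffolds
            else spec.inactive_mean_log10_um
        )
        minted = _mint_series(
            rng, template, spec.decoration_vocab, count,
            id_prefix="mol_", start_index=mol_counter,
        )
        for mol in minted:
            mol_id = f"mol{mol_counter:04d}"
            mol_counter += 1
            mol = Molecule(
                mol_id=mol_id,
                smiles_input=mol.smiles_input,
                smiles_canonical=mol.smiles_canonical,
                inchikey=mol.inchikey,
                scaffold_smiles=mol.scaffold_smiles,
                n_heavy=mol.n_heavy,
            )
            log_act = mean + rng.normal(0.0, spec.noise_sd)
            act_um = float(10.0 ** log_act)
            truth_rows.append(
                {
                    "mol_id": mol_id,
                    "smiles": mol.smiles_canonical,
                    "scaffold_smiles": mol.scaffold_smiles,
                    "true_activity_uM": act_um,
                    "true_label": int(act_um < 10.0),
                }
            )
            n_rec = int(rng.integers(1, 3))
            endpoints = rng.choice(["IC50", "EC50", "Ki"], size=n_rec)
            for ep in endpoints:
                records.append(
                    ActivityRecord(mol_id, mol.smiles_canonical, str(ep),
                                   act_um * 1e3, "nM")
                )
            if rng.random() < spec.distractor_endpoint_frac:
                records.append(
                    ActivityRecord(mol_id, mol.smiles_canonical, "Kd",
                                   act_um * 1e3, "nM")
                )
            if rng.random() < spec.duplicate_frac:
                dup_id = f"{mol_id}_dup"
                records.append(
                    ActivityRecord(dup_id, mol.smiles_input, "IC50",
                                   act_um * 1e3, "nM")
                )
            if rng.random() < spec.invalid_frac:
                records.append(
                    ActivityRecord(f"bad{mol_counter:04d}", "not_a_smiles",
                                   "IC50", 1000.0, "nM")
                )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def records_to_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    """Emit records in the tabular dialect the curation reader consumes."""
    return pd.DataFrame(
        {
            "mol_id": [r.mol_id for r in records],
            "smiles": [r.smiles for r in records],
            "endpoint": [r.endpoint for r in records],
            "value": [r.value for r in records],
            "unit": [r.unit for r in records],
        }
    )


# ---------------------------------------------------------------------------
# annotation database


def gen_annotation_db(
    spec: SyntheticSpec,
) -> tuple[AnnotationDB, str, list[str]]:
    """Synthesize a GMT-style annotation DB with one planted enriched term.

    A designated query of ``query_size`` genes overlaps the planted term in
    ``round(hit_fraction * query_size)`` members; background terms are
    uniform random subsets of the universe. Returns ``(db, planted_term_id,
    query)``.
    """
    rng = np.random.default_rng(spec.seed)
    universe = [f"G{i:04d}" for i in range(spec.universe_size)]
    uni_arr = np.array(universe)

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = spec.term_size_range
    for t in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(uni_arr, size=size, replace=False).tolist())
        terms[f"TERM{t:03d}"] = (f"background term {t}", members)

    query = rng.choice(uni_arr, size=spec.query_size, replace=False).tolist()
    n_hits = int(round(spec.hit_fraction * spec.query_size))
    hits = query[:n_hits]
    non_query = np.array(sorted(set(universe) - set(query)))
    fill = rng.choice(
        non_query, size=spec.planted_term_size - n_hits, replace=False
    ).tolist()
    planted_id = "TERM_PLANTED"
    terms[planted_id] = ("planted enriched term", frozenset(hits + fill))

    db = AnnotationDB(terms=terms, universe=frozenset(universe))
    return db, planted_id, query
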