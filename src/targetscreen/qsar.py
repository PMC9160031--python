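"""Consensus SAR modelling: curation, binarization, scaffold thinning, and
random-forest classifiers over three descriptor families.

The modelling follows a fixed recipe. Bioactivity records are filtered to
the IC50/EC50/Ki endpoints, converted to µM, pooled per unique structure
(InChIKey), and the per-molecule arithmetic mean potency is binarized at the
10 µM threshold (strictly below 10 µM = active). Scaffold classes larger
than a cap are randomly thinned so a single heavily explored chemotype
cannot dominate the fit. A random forest is then trained per descriptor
scheme (CATS, MACCS, 2D physchem panel) under seeded stratified 5-fold
cross-validation, and the consensus model averages the three active-class
probabilities. Performance is reported as SE/SP/ACC/AUC, contractually from
pooled out-of-fold predictions (per-fold values are reported alongside).

The user-facing surface follows the model/results convention:
``ConsensusQSAR(dataset).fit()`` returns a :class:`ConsensusQSARResults`
carrying the fitted scheme models, cross-validation metrics and a
``summary()`` table, plus ``predict`` for new molecules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .chemio import Molecule, ParseError, dedup_by_inchikey, parse_molecule
from .descriptors import SCHEMES, DescriptorMatrix, compute_matrices

logger = logging.getLogger(__name__)

QUALIFYING_ENDPOINTS = ("IC50", "EC50", "Ki")
ACTIVITY_THRESHOLD_UM = 10.0  # strictly below => active

_UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "µM": 1.0, "M": 1e6}


@dataclass(frozen=True)
class ActivityRecord:
    """One measured endpoint for one molecule."""

    mol_id: str
    smiles: str
    endpoint: str
    value: float
    unit: str

    def value_um(self) -> float:
        if self.unit not in _UNIT_TO_UM:
            raise ValueError(f"unrecognized unit {self.unit!r}")
        if self.value <= 0:
            raise ValueError(f"non-positive activity value for {self.mol_id!r}")
        return self.value * _UNIT_TO_UM[self.unit]


@dataclass
class QSARDataset:
    """Curated, binarized activity table with per-molecule provenance."""

    molecules: list[Molecule]
    mean_activity_um: np.ndarray
    labels: np.ndarray
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_activity_um = np.asarray(self.mean_activity_um, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.molecules) == len(self.mean_activity_um) == len(self.labels)):
            raise ValueError("dataset fields have inconsistent lengths")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mol_id": [m.mol_id for m in self.molecules],
                "smiles_canonical": [m.smiles_canonical for m in self.molecules],
                "inchikey": [m.inchikey for m in self.molecules],
                "scaffold_smiles": [m.scaffold_smiles for m in self.molecules],
                "mean_activity_uM": self.mean_activity_um,
                "label": self.labels,
            }
        )


def records_from_table(df: pd.DataFrame) -> list[ActivityRecord]:
    """Build activity records from a (smiles, endpoint, value, unit) table.

    This is the documented subset of a BindingDB-style TSV export; a
    ``mol_id`` column is optional (row numbers are used otherwise).
    """
    cols = {c.lower(): c for c in df.columns}
    out = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        mol_id = str(row[cols["mol_id"]]) if "mol_id" in cols else f"row{i}"
        out.append(
            ActivityRecord(
                mol_id=mol_id,
                smiles=str(row[cols["smiles"]]),
                endpoint=str(row[cols["endpoint"]]),
                value=float(row[cols["value"]]),
                unit=str(row[cols["unit"]]),
            )
        )
    return out


def curate(records: Sequence[ActivityRecord], use_log_mean: bool = False) -> QSARDataset:
    """Apply the full curation chain to raw activity records.

    Steps, each recorded in per-molecule provenance:

    1. endpoint whitelist — only IC50, EC50 and Ki records survive;
    2. unit conversion of every surviving value to µM;
    3. canonicalization and InChIKey deduplication of structures, pooling
       the records of duplicate entries;
    4. per-molecule mean activity: arithmetic mean of the µM values (or of
       the −log10 values when ``use_log_mean``, reported back as µM);
    5. binarization: active iff mean < 10 µM (exactly 10 µM is inactive).

    Molecules with no qualifying record, and unparsable structures, are
    excluded with a log message; a bad record never aborts curation.
    """
    parsed: dict[str, Molecule] = {}
    rejected_structures: set[str] = set()
    by_key: dict[str, list[float]] = {}
    representative: dict[str, Molecule] = {}
    order: list[str] = []
    provenance: dict[str, list[str]] = {}

    for rec in records:
        if rec.mol_id in rejected_structures:
            continue
        if rec.mol_id not in parsed:
            try:
                parsed[rec.mol_id] = parse_molecule(rec.smiles, rec.mol_id)
            except ParseError as exc:
                logger.warning("curation: %s", exc)
                rejected_structures.add(rec.mol_id)
                continue
        mol = parsed[rec.mol_id]
        prov = provenance.setdefault(mol.inchikey, [])
        if rec.endpoint not in QUALIFYING_ENDPOINTS:
            prov.append(f"dropped endpoint {rec.endpoint} ({rec.mol_id})")
            continue
        try:
            value_um = rec.value_um()
        except ValueError as exc:
            logger.warning("curation: %s", exc)
            prov.append(f"dropped unusable record ({rec.mol_id}): {exc}")
            continue
        if mol.inchikey not in by_key:
            by_key[mol.inchikey] = []
            representative[mol.inchikey] = mol
            order.append(mol.inchikey)
            prov.append(f"kept structure {mol.mol_id}")
        elif representative[mol.inchikey].mol_id != mol.mol_id:
            prov.append(f"pooled duplicate {mol.mol_id} (InChIKey match)")
        prov.append(f"{rec.endpoint}={value_um:g} µM ({rec.mol_id})")
        by_key[mol.inchikey].append(value_um)

    molecules, means, labels = [], [], []
    for key in order:
        vals = np.array(by_key[key])
        if len(vals) == 0:  # pragma: no cover - keys only created with a value
            continue
        if use_log_mean:
            mean = float(10 ** np.mean(np.log10(vals)))
        else:
            mean = float(np.mean(vals))
        label = int(mean < ACTIVITY_THRESHOLD_UM)
        provenance[key].append(
            f"mean={mean:g} µM -> {'active' if label else 'inactive'}"
        )
        molecules.append(representative[key])
        means.append(mean)
        labels.append(label)

    n_dropped = len(rejected_structures)
    if n_dropped:
        logger.info("curation excluded %d unparsable structures", n_dropped)
    return QSARDataset(
        molecules=molecules,
        mean_activity_um=np.array(means),
        labels=np.array(labels),
        provenance=provenance,
    )


def scaffold_thin(ds: QSARDataset, max_per_scaffold: int = 5, seed: int = 0) -> QSARDataset:
    """Randomly thin over-represented Bemis–Murcko scaffold classes.

    Classes larger than ``max_per_scaffold`` retain a seeded uniform random
    subset of exactly that size; smaller classes are untouched. Acyclic
    molecules (empty scaffold) each form their own singleton class. Input
    order is preserved among survivors and the result is a deterministic
    function of the seed.
    """
    if max_per_scaffold < 1:
        raise ValueError("max_per_scaffold must be >= 1")
    classes: dict[str, list[int]] = {}
    for i, mol in enumerate(ds.molecules):
        key = mol.scaffold_smiles or f"__acyclic__{mol.inchikey}"
        classes.setdefault(key, []).append(i)

    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for key in sorted(classes):
        idx = classes[key]
        if len(idx) <= max_per_scaffold:
            keep.update(idx)
        else:
            keep.update(rng.choice(idx, size=max_per_scaffold, replace=False).tolist())

    survivors = sorted(keep)
    prov = {
        m.inchikey: ds.provenance.get(m.inchikey, []) for m in ds.molecules
    }
    for i, mol in enumerate(ds.molecules):
        if i not in keep:
            prov[mol.inchikey] = prov.get(mol.inchikey, []) + [
                f"removed by scaffold thinning (cap {max_per_scaffold}, seed {seed})"
            ]
    return QSARDataset(
        molecules=[ds.molecules[i] for i in survivors],
        mean_activity_um=ds.mean_activity_um[survivors],
        labels=ds.labels[survivors],
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# metrics


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC via the Mann–Whitney statistic with midrank tie handling.

    AUC = (number of concordant positive–negative pairs + half the tied
    pairs) / (n_pos · n_neg). Requires both classes to be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _confusion_metrics(labels: np.ndarray, calls: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((labels == 1) & (calls == 1)))
    fn = int(np.sum((labels == 1) & (calls == 0)))
    tn = int(np.sum((labels == 0) & (calls == 0)))
    fp = int(np.sum((labels == 0) & (calls == 1)))
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / len(labels)
    return {"SE": se, "SP": sp, "ACC": acc}


@dataclass
class CVMetrics:
    """Cross-validation metrics: pooled out-of-fold (contractual) + per-fold."""

    scheme: str
    se: float
    sp: float
    acc: float
    auc: float
    per_fold: pd.DataFrame
    fold_assignments: np.ndarray

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "SE": self.se, "SP": self.sp, "ACC": self.acc, "AUC": self.auc,
            "per_fold": self.per_fold.to_dict(orient="records"),
        }


@dataclass(frozen=True)
class RFConfig:
    """Frozen random-forest settings (defaults recorded in every report)."""

    n_trees: int = 500
    max_features: str = "sqrt"
    seed: int = 0


# ---------------------------------------------------------------------------
# the model / results pair


class ConsensusQSAR:
    """Consensus SAR model over the three descriptor schemes.

    Parameters
    ----------
    dataset : QSARDataset
        Curated, binarized (and typically scaffold-thinned) training data.
    rf_config : RFConfig
        Random-forest settings; the seed drives fold assignment and every
        forest, so identical configuration reproduces identical metrics.
    """

    def __init__(self, dataset: QSARDataset, rf_config: RFConfig = RFConfig()):
        self.dataset = dataset
        self.rf_config = rf_config

    @classmethod
    def from_activity_table(
        cls,
        df: pd.DataFrame,
        rf_config: RFConfig = RFConfig(),
        max_per_scaffold: int = 5,
        use_log_mean: bool = False,
    ) -> "ConsensusQSAR":
        """Curate and scaffold-thin a raw activity table, then build the model."""
        ds = curate(records_from_table(df), use_log_mean=use_log_mean)
        ds = scaffold_thin(ds, max_per_scaffold=max_per_scaffold, seed=rf_config.seed)
        return cls(ds, rf_config=rf_config)

    def _make_rf(self, scheme_index: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.rf_config.n_trees,
            max_features=self.rf_config.max_features,
            random_state=self.rf_config.seed + scheme_index,
            n_jobs=1,
        )

    def fit(self, n_folds: int = 5) -> "ConsensusQSARResults":
        """Run seeded stratified cross-validation and fit the final forests.

        Per scheme: out-of-fold probabilities from ``n_folds`` stratified
        splits give the cross-validated metrics; a final forest refitted on
        the full dataset backs :meth:`ConsensusQSARResults.predict`.
        The consensus metrics come from the arithmetic mean of the three
        schemes' out-of-fold probabilities.
        """
        ds = self.dataset
        if len(ds) < 20:
            raise ValueError(f"need at least 20 molecules to cross-validate, got {len(ds)}")
        n_active = ds.n_active
        if min(n_active, len(ds) - n_active) < n_folds:
            raise ValueError(
                f"each class needs >= {n_folds} members for {n_folds}-fold "
                f"stratification (got {n_active} active / {len(ds) - n_active} inactive)"
            )

        matrices = compute_matrices(ds.molecules)
        labels = ds.labels
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.rf_config.seed)
        folds = list(skf.split(np.zeros(len(ds)), labels))
        fold_of = np.empty(len(ds), dtype=int)
        for f, (_, test_idx) in enumerate(folds):
            fold_of[test_idx] = f

        oof: dict[str, np.ndarray] = {}
        scheme_models: dict[str, RandomForestClassifier] = {}
        scheme_metrics: dict[str, CVMetrics] = {}
        for si, scheme in enumerate(SCHEMES):
            X = matrices[scheme].values
            probs = np.empty(len(ds))
            for train_idx, test_idx in folds:
                rf = self._make_rf(si)
                rf.fit(X[train_idx], labels[train_idx])
                probs[test_idx] = rf.predict_proba(X[test_idx])[:, 1]
            oof[scheme] = probs
            scheme_metrics[scheme] = _cv_metrics(scheme, probs, labels, fold_of)
            final = self._make_rf(si)
            final.fit(X, labels)
            scheme_models[scheme] = final

        consensus_probs = np.mean([oof[s] for s in SCHEMES], axis=0)
        consensus_metrics = _cv_metrics("CONSENSUS", consensus_probs, labels, fold_of)

        return ConsensusQSARResults(
            model=self,
            scheme_models=scheme_models,
            oof_probabilities=oof,
            consensus_oof=consensus_probs,
            scheme_metrics=scheme_metrics,
            consensus_metrics=consensus_metrics,
            fold_assignments=fold_of,
            n_folds=n_folds,
        )


def _cv_metrics(
    scheme: str, probs: np.ndarray, labels: np.ndarray, fold_of: np.ndarray
) -> CVMetrics:
    calls = (probs >= 0.5).astype(int)
    pooled = _confusion_metrics(labels, calls)
    rows = []
    for f in sorted(set(fold_of)):
        m = fold_of == f
        row = {"fold": int(f), **_confusion_metrics(labels[m], calls[m])}
        try:
            row["AUC"] = auc_rank(probs[m], labels[m])
        except ValueError:
            row["AUC"] = float("nan")
        rows.append(row)
    return CVMetrics(
        scheme=scheme,
        se=pooled["SE"], sp=pooled["SP"], acc=pooled["ACC"],
        auc=auc_rank(probs, labels),
        per_fold=pd.DataFrame(rows),
        fold_assignments=fold_of.copy(),
    )


class ConsensusQSARResults:
    """Fitted consensus SAR model with its cross-validation record."""

    def __init__(
        self,
        model: ConsensusQSAR,
        scheme_models: Mapping[str, RandomForestClassifier],
        oof_probabilities: Mapping[str, np.ndarray],
        consensus_oof: np.ndarray,
        scheme_metrics: Mapping[str, CVMetrics],
        consensus_metrics: CVMetrics,
        fold_assignments: np.ndarray,
        n_folds: int,
    ):
        self.model = model
        self.scheme_models = dict(scheme_models)
        self.oof_probabilities = dict(oof_probabilities)
        self.consensus_oof = consensus_oof
        self.scheme_metrics = dict(scheme_metrics)
        self.consensus_metrics = consensus_metrics
        self.fold_assignments = fold_assignments
        self.n_folds = n_folds

    # -- reporting ---------------------------------------------------------

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for scheme in (*SCHEMES, "CONSENSUS"):
            m = self.consensus_metrics if scheme == "CONSENSUS" else self.scheme_metrics[scheme]
            rows.append({"scheme": scheme, "SE": m.se, "SP": m.sp, "ACC": m.acc, "AUC": m.auc})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.model.rf_config
        df = self.metrics_frame()
        lines = [
            "Consensus SAR model (random forest x {CATS, MACCS, PHYSCHEM2D})",
            f"  molecules: {len(self.model.dataset)} "
            f"({self.model.dataset.n_active} active / "
            f"{len(self.model.dataset) - self.model.dataset.n_active} inactive)",
            f"  cross-validation: stratified {self.n_folds}-fold, seed {cfg.seed}",
            f"  forest: {cfg.n_trees} trees, max_features={cfg.max_features}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def report_dict(self) -> dict:
        return {
            "rf_config": asdict(self.model.rf_config),
            "n_folds": self.n_folds,
            "n_molecules": len(self.model.dataset),
            "n_active": self.model.dataset.n_active,
            "schemes": {s: self.scheme_metrics[s].as_dict() for s in SCHEMES},
            "consensus": self.consensus_metrics.as_dict(),
        }

    def save_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report_dict(), indent=1))

    def plot_cv_auc(self, ax=None):
        """Bar plot of single-scheme vs consensus cross-validated AUC."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        df = self.metrics_frame()
        ax.bar(df["scheme"], df["AUC"], color=["#7f9fc4"] * 3 + ["#c47f7f"])
        ax.set_ylabel("cross-validated AUC")
        ax.set_ylim(0, 1)
        return ax

    # -- prediction --------------------------------------------------------

    def predict(self, mols: Sequence[Molecule]) -> pd.DataFrame:
        """Score new molecules with the consensus model.

        Returns per-scheme probabilities, the averaged consensus probability
        and the binary call (consensus >= 0.5 => active). A molecule whose
        descriptor block is unusable is reported with ``scored = False``
        rather than silently scored 0.
        """
        matrices = compute_matrices(mols)
        probs = {}
        for scheme in SCHEMES:
            probs[scheme] = self.scheme_models[scheme].predict_proba(
                matrices[scheme].values
            )[:, 1]
        consensus = np.mean([probs[s] for s in SCHEMES], axis=0)
        scored = np.all(
            [np.isfinite(matrices[s].values).all(axis=1) for s in SCHEMES], axis=0
        )
        return pd.DataFrame(
            {
                "mol_id": [m.mol_id for m in mols],
                **{f"prob_{s}": probs[s] for s in SCHEMES},
                "prob_consensus": consensus,
                "call_active": (consensus >= 0.5) & scored,
                "scored": scored,
            }
        )

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist the fitted bundle (joblib) with JSON metadata alongside."""
        path = Path(path)
        joblib.dump(
            {"scheme_models": self.scheme_models, "rf_config": asdict(self.model.rf_config)},
            path,
        )
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.report_dict(), indent=1)
        )
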