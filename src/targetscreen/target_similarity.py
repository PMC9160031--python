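"""Similarity-based target prediction and multi-platform consensus screening.

The first screening layer of the pipeline asks several heterogeneous
ligand-based predictors which proteins a query molecule is likely to bind,
keeps each predictor's top 15 targets, normalizes all identifiers to UniProt
accessions, and retains the targets supported by at least two predictors.

The remote prediction platforms this strategy was designed around are
versioned web services that cannot be queried reproducibly, so each voter is
emulated locally: a distinctly configured similarity predictor (fingerprint
scheme × score-aggregation rule) over a reference ligand–target library.
Externally produced platform result files can also be imported and enter the
consensus on equal footing.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemio import Molecule, parse_batch
from .descriptors import FP_SCHEMES, fingerprint, tanimoto

logger = logging.getLogger(__name__)

UNIPROT_RE = re.compile(
    r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}$"
)

#: Small gene-symbol → UniProt accession table for identifier normalization
#: of human targets that recur in this pipeline's domain. Extend via the
#: ``mapping`` argument of :func:`normalize_ids` for anything else.
GENE_TO_UNIPROT: dict[str, str] = {
    "HMGCR": "P04035",
    "CYP17A1": "P05093",
    "AR": "P10275",
    "AGTR1": "P30556",
    "HSD11B1": "P28845",
    "PTPN1": "P18031",
    "EGFR": "P00533",
    "BRAF": "P15056",
    "TP53": "P04637",
    "SRC": "P12931",
}

TOP_K_DEFAULT = 15


@dataclass(frozen=True)
class PredictorConfig:
    """One pseudo-platform: a fingerprint scheme plus an aggregation rule.

    ``aggregation`` is either ``"max"`` (per-target score = best query–ligand
    similarity) or ``"top3_mean"`` (mean of the three best similarities).
    """

    name: str
    fp_scheme: str
    aggregation: str = "max"

    def __post_init__(self) -> None:
        if self.fp_scheme not in FP_SCHEMES:
            raise ValueError(f"unknown fingerprint scheme {self.fp_scheme!r}")
        if self.aggregation not in ("max", "top3_mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


#: Four distinctly configured voters standing in for the four platforms.
DEFAULT_PLATFORMS: tuple[PredictorConfig, ...] = (
    PredictorConfig("sim-morgan2-max", "morgan2", "max"),
    PredictorConfig("sim-morgan3-top3", "morgan3", "top3_mean"),
    PredictorConfig("sim-path-max", "rdkit_path", "max"),
    PredictorConfig("sim-maccs-top3", "maccs", "top3_mean"),
)


class ReferenceLibrary:
    """A ligand–target annotation library with per-scheme fingerprint cache.

    Every target identifier must be a syntactically valid UniProt accession;
    a ligand may annotate several targets.
    """

    def __init__(self, entries: Sequence[tuple[Molecule, str]]):
        for _, tid in entries:
            if not UNIPROT_RE.match(tid):
                raise ValueError(f"not a UniProt accession: {tid!r}")
        self.entries: list[tuple[Molecule, str]] = list(entries)
        self._fp_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def targets(self) -> set[str]:
        return {tid for _, tid in self.entries}

    def fingerprints(self, scheme: str) -> np.ndarray:
        """Stacked fingerprints of all ligands under one scheme (cached)."""
        if scheme not in self._fp_cache:
            self._fp_cache[scheme] = np.vstack(
                [fingerprint(mol, scheme) for mol, _ in self.entries]
            )
        return self._fp_cache[scheme]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceLibrary":
        """Load a ``smiles,uniprot`` CSV/TSV; bad structures are skipped."""
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep)
        cols = {c.lower(): c for c in df.columns}
        smiles_col, target_col = cols["smiles"], cols.get("uniprot", cols.get("target_id"))
        records = [
            (row[smiles_col], f"lib{i}") for i, (_, row) in enumerate(df.iterrows(), start=1)
        ]
        mols, rejected = parse_batch(records)
        by_id = {m.mol_id: m for m in mols}
        entries = []
        for i, (_, row) in enumerate(df.iterrows(), start=1):
            mol = by_id.get(f"lib{i}")
            if mol is not None:
                entries.append((mol, str(row[target_col]).strip()))
        if rejected:
            logger.warning("reference library: skipped %d unparsable ligands", len(rejected))
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"smiles": [m.smiles_canonical for m, _ in self.entries],
             "uniprot": [t for _, t in self.entries]}
        ).to_csv(path, index=False)


@dataclass
class PlatformPrediction:
    """One predictor's ranked target list, truncated to its screening depth."""

    platform_name: str
    ranked_targets: list[tuple[str, float]]
    k_kept: int

    @property
    def target_ids(self) -> list[str]:
        return [t for t, _ in self.ranked_targets]


def predict_targets(
    query: Molecule,
    library: ReferenceLibrary,
    method: PredictorConfig,
    top_k: int = TOP_K_DEFAULT,
) -> PlatformPrediction:
    """Rank library targets by query–ligand similarity; keep the top ``top_k``.

    Each target's score aggregates the Tanimoto similarities between the
    query and that target's annotated ligands (``max`` or ``top3_mean``).
    Ties are broken lexicographically by accession so rankings are
    deterministic.
    """
    if len(library) == 0:
        raise ValueError("empty reference library")
    qfp = fingerprint(query, method.fp_scheme)
    lib_fps = library.fingerprints(method.fp_scheme)
    sims = np.array([tanimoto(qfp, fp) for fp in lib_fps])

    per_target: dict[str, list[float]] = {}
    for (_, tid), s in zip(library.entries, sims):
        per_target.setdefault(tid, []).append(float(s))

    scored: list[tuple[str, float]] = []
    for tid, vals in per_target.items():
        vals = sorted(vals, reverse=True)
        score = vals[0] if method.aggregation == "max" else float(np.mean(vals[:3]))
        scored.append((tid, score))

    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    kept = scored[:top_k]
    return PlatformPrediction(platform_name=method.name, ranked_targets=kept, k_kept=len(kept))


def normalize_ids(
    raw: PlatformPrediction, mapping: Mapping[str, str] | None = None
) -> PlatformPrediction:
    """Convert raw identifiers to UniProt accessions.

    Already-valid accessions pass through; other identifiers are looked up in
    ``mapping`` (defaulting to the packaged gene-symbol table). Unmapped ids
    are dropped with a warning; raw ids that collapse onto one accession keep
    the best score.
    """
    table = dict(GENE_TO_UNIPROT)
    if mapping:
        table.update(mapping)
    best: dict[str, float] = {}
    for tid, score in raw.ranked_targets:
        if UNIPROT_RE.match(tid):
            acc = tid
        elif tid in table:
            acc = table[tid]
        else:
            logger.warning("%s: dropping unmappable target id %r", raw.platform_name, tid)
            continue
        if acc not in best or score > best[acc]:
            best[acc] = score
    ranked = sorted(best.items(), key=lambda ts: (-ts[1], ts[0]))
    return PlatformPrediction(
        platform_name=raw.platform_name, ranked_targets=ranked, k_kept=len(ranked)
    )


@dataclass
class ConsensusTargetSet:
    """Union, per-target support, and the support-filtered consensus."""

    union_targets: set[str]
    support_counts: dict[str, int]
    consensus_targets: set[str]
    min_support: int
    platform_names: list[str] = field(default_factory=list)
    overlap_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.support_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "target_id": [t for t, _ in rows],
                "support": [s for _, s in rows],
                "selected": [t in self.consensus_targets for t, _ in rows],
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "min_support": self.min_support,
            "platforms": self.platform_names,
            "union_size": len(self.union_targets),
            "consensus_targets": sorted(self.consensus_targets),
            "support_counts": dict(sorted(self.support_counts.items())),
            "overlap_counts": self.overlap_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def aggregate_consensus(
    predictions: Sequence[PlatformPrediction], min_support: int = 2
) -> ConsensusTargetSet:
    """Combine platform predictions by voting.

    A target enters the consensus when at least ``min_support`` platforms
    predict it. Venn-style overlap counts for every platform combination are
    emitted for reporting.
    """
    if len(predictions) < 2:
        raise ValueError("consensus requires at least two platform predictions")
    if not 1 <= min_support <= len(predictions):
        raise ValueError(
            f"min_support must be in [1, {len(predictions)}], got {min_support}"
        )
    sets = {p.platform_name: set(p.target_ids) for p in predictions}
    support: dict[str, int] = {}
    for tids in sets.values():
        for t in tids:
            support[t] = support.get(t, 0) + 1
    union = set(support)
    consensus = {t for t, s in support.items() if s >= min_support}

    overlap: dict[str, int] = {}
    names = sorted(sets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            overlap["&".join(combo)] = len(inter)

    return ConsensusTargetSet(
        union_targets=union,
        support_counts=support,
        consensus_targets=consensus,
        min_support=min_support,
        platform_names=[p.platform_name for p in predictions],
        overlap_counts=overlap,
    )


def import_platform_csv(path: str | Path, top_k: int = TOP_K_DEFAULT) -> list[PlatformPrediction]:
    """Import externally obtained platform results.

    Expected columns: ``platform, target_id, score`` (``rank`` optional; when
    present it orders ties). Each platform's list is truncated to ``top_k``.
    """
    df = pd.read_csv(path)
    preds = []
    for name, grp in df.groupby("platform", sort=True):
        grp = grp.sort_values(
            by=["score", "target_id"], ascending=[False, True], kind="mergesort"
        )
        ranked = [(str(r.target_id), float(r.score)) for r in grp.itertuples()][:top_k]
        preds.append(PlatformPrediction(str(name), ranked, k_kept=len(ranked)))
    return preds
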