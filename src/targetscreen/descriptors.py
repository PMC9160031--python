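"""Descriptor families for the consensus SAR models and similarity search.

Three fixed-width descriptor schemes are produced:

``CATS``
    210 columns: counts of pharmacophore-point pairs binned by topological
    (shortest bond path) distance 0–9, for all 21 unordered pairs of the six
    point types, scaled by heavy-atom count. Implemented here from scratch;
    the typing rules are published verbatim in :func:`assign_ppp`.
``MACCS``
    The 166 public MACCS structural keys as 0/1 bits (RDKit's padding bit 0
    is dropped so the contract is exactly 166 positions).
``PHYSCHEM2D``
    A frozen panel of 206 two-dimensional physicochemical and topological
    descriptors. Panel membership and order live in a versioned JSON manifest
    shipped with the package; only the dimension and 2D-only character are
    contractual.

Failed descriptor values are set to 0 with a logged warning — a descriptor
matrix never contains missing values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _rd_desc
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chemio import Molecule

logger = logging.getLogger(__name__)

# Pharmacophore point types, in the fixed order that defines the CATS layout.
PPP_TYPES = ("D", "A", "P", "N", "L", "R")
N_DISTANCE_BINS = 10  # topological distances 0..9; longer pairs are discarded

#: The 21 unordered type pairs, pair-major order: (D,D),(D,A),...,(R,R).
PPP_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (PPP_TYPES[i], PPP_TYPES[j])
    for i in range(len(PPP_TYPES))
    for j in range(i, len(PPP_TYPES))
)

CATS_DIM = len(PPP_PAIRS) * N_DISTANCE_BINS  # 210
MACCS_DIM = 166
PHYSCHEM2D_DIM = 206

SCHEMES = ("CATS", "MACCS", "PHYSCHEM2D")


@dataclass(frozen=True)
class PPPAssignment:
    """Pharmacophore point types carried by one atom (2D graph only)."""

    atom_index: int
    types: frozenset[str]


def _is_amide_like(atom: Chem.Atom) -> bool:
    """N bonded to a carbon that carries a double bond to oxygen."""
    for nbr in atom.GetNeighbors():
        if nbr.GetAtomicNum() != 6:
            continue
        for bond in nbr.GetBonds():
            other = bond.GetOtherAtom(nbr)
            if other.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def _is_acidic_oxygen(atom: Chem.Atom) -> bool:
    """O of a carboxylic/sulfonic acid group or a negatively charged O."""
    if atom.GetFormalCharge() < 0:
        return True
    if atom.GetTotalNumHs() < 1:
        return False
    for nbr in atom.GetNeighbors():
        if nbr.GetAtomicNum() not in (6, 16):
            continue
        for bond in nbr.GetBonds():
            other = bond.GetOtherAtom(nbr)
            if (
                other.GetIdx() != atom.GetIdx()
                and other.GetAtomicNum() == 8
                and bond.GetBondType() == Chem.BondType.DOUBLE
            ):
                return True
    return False


def _is_basic_amine(atom: Chem.Atom) -> bool:
    """Non-aromatic sp3 nitrogen that is not amide-like."""
    if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
        return False
    if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
        return False
    return not _is_amide_like(atom)


def assign_ppp(mol: Molecule | Chem.Mol) -> list[PPPAssignment]:
    """Assign pharmacophore point types to every atom.

    The rules are deterministic functions of the 2D molecular graph:

    - ``D`` (donor): O or N carrying at least one hydrogen.
    - ``A`` (acceptor): any O; or N that is not positively charged and not
      amide-like (bonded to a carbonyl carbon).
    - ``P`` (positively ionizable): atom with positive formal charge, or a
      basic amine (non-aromatic sp3 N that is not amide-like).
    - ``N`` (negatively ionizable): atom with negative formal charge, or an
      acidic oxygen (OH of a carboxylic/sulfonic acid).
    - ``L`` (lipophilic): carbon whose explicit neighbours are all carbon.
    - ``R`` (aromatic): atom flagged aromatic by the perception engine.

    An atom may carry zero, one, or several types.
    """
    if isinstance(mol, Molecule):
        mol = mol.to_rdkit()
    out: list[PPPAssignment] = []
    for atom in mol.GetAtoms():
        types: set[str] = set()
        z = atom.GetAtomicNum()
        if z in (7, 8) and atom.GetTotalNumHs() >= 1:
            types.add("D")
        if z == 8:
            types.add("A")
        elif z == 7 and atom.GetFormalCharge() <= 0 and not _is_amide_like(atom):
            types.add("A")
        if atom.GetFormalCharge() > 0 or _is_basic_amine(atom):
            types.add("P")
        if atom.GetFormalCharge() < 0 or (z == 8 and _is_acidic_oxygen(atom)):
            types.add("N")
        if z == 6 and all(n.GetAtomicNum() == 6 for n in atom.GetNeighbors()):
            types.add("L")
        if atom.GetIsAromatic():
            types.add("R")
        out.append(PPPAssignment(atom_index=atom.GetIdx(), types=frozenset(types)))
    return out


_PAIR_INDEX = {pair: i for i, pair in enumerate(PPP_PAIRS)}


def _pair_key(t1: str, t2: str) -> tuple[str, str]:
    i, j = PPP_TYPES.index(t1), PPP_TYPES.index(t2)
    return (PPP_TYPES[min(i, j)], PPP_TYPES[max(i, j)]) if i > j else (t1, t2)


def cats2d(mol: Molecule | Chem.Mol) -> np.ndarray:
    """CATS pharmacophore-pair vector, length 210.

    For every unordered pair of point types and every topological distance
    0–9, count the typed atom pairs at that distance and divide by the
    heavy-atom count. Conventions (frozen, oracle-tested):

    - a single atom carrying type ``t`` contributes one self-pair to the
      ``(t, t)`` distance-0 bin; two distinct types on one atom contribute
      once to their cross-pair distance-0 bin;
    - a pair of distinct atoms contributes once per ordered combination of
      one type from each atom, mapped to the unordered pair bin (so two
      atoms sharing types ``{D, A}`` add 2 to the ``(D, A)`` bin);
    - pairs at topological distance > 9 are discarded, not clamped.

    Layout is pair-major, distance-minor: index = 10 * pair + distance.
    """
    if isinstance(mol, Molecule):
        mol = mol.to_rdkit()
    assignments = assign_ppp(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    dmat = Chem.GetDistanceMatrix(mol)
    vec = np.zeros(CATS_DIM, dtype=float)

    for a in assignments:
        # same-atom contributions (distance 0)
        for t1 in a.types:
            vec[_PAIR_INDEX[_pair_key(t1, t1)] * N_DISTANCE_BINS] += 1.0
        tlist = sorted(a.types)
        for i in range(len(tlist)):
            for j in range(i + 1, len(tlist)):
                vec[_PAIR_INDEX[_pair_key(tlist[i], tlist[j])] * N_DISTANCE_BINS] += 1.0

    n = len(assignments)
    for i in range(n):
        for j in range(i + 1, n):
            d = dmat[i, j]
            if not math.isfinite(d) or d >= N_DISTANCE_BINS:
                continue
            d = int(d)
            for t1 in assignments[i].types:
                for t2 in assignments[j].types:
                    vec[_PAIR_INDEX[_pair_key(t1, t2)] * N_DISTANCE_BINS + d] += 1.0

    return vec / max(n_heavy, 1)


def maccs166(mol: Molecule | Chem.Mol) -> np.ndarray:
    """The 166 public MACCS keys as a 0/1 vector (padding bit 0 dropped)."""
    if isinstance(mol, Molecule):
        mol = mol.to_rdkit()
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    arr = np.zeros(167, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr[1:].astype(float)


@dataclass(frozen=True)
class _Physchem2DPanel:
    names: tuple[str, ...]
    funcs: tuple[Callable, ...]
    version: int


def _load_physchem_panel() -> _Physchem2DPanel:
    raw = json.loads(
        resources.files("targetscreen.data").joinpath("physchem2d_manifest.json").read_text()
    )
    names = tuple(raw["columns"])
    if len(names) != PHYSCHEM2D_DIM:  # pragma: no cover - manifest is frozen
        raise RuntimeError("physchem2d manifest does not define 206 columns")
    lookup = dict(_rd_desc._descList)
    funcs = tuple(lookup[n] for n in names)
    return _Physchem2DPanel(names=names, funcs=funcs, version=raw["version"])


_PHYSCHEM_PANEL = _load_physchem_panel()


def physchem2d_columns() -> tuple[str, ...]:
    """The frozen, ordered names of the 206-column 2D physchem panel."""
    return _PHYSCHEM_PANEL.names


def physchem206(mol: Molecule | Chem.Mol) -> np.ndarray:
    """The 206-column 2D physicochemical panel; failed values become 0."""
    if isinstance(mol, Molecule):
        mol_id, mol = mol.mol_id, mol.to_rdkit()
    else:
        mol_id = "<mol>"
    vec = np.zeros(PHYSCHEM2D_DIM, dtype=float)
    for i, (name, fn) in enumerate(zip(_PHYSCHEM_PANEL.names, _PHYSCHEM_PANEL.funcs)):
        try:
            v = float(fn(mol))
        except Exception:
            logger.warning("descriptor %s failed on %s; set to 0", name, mol_id)
            v = 0.0
        if not math.isfinite(v):
            logger.warning("descriptor %s non-finite on %s; set to 0", name, mol_id)
            v = 0.0
        vec[i] = v
    return vec


# ---------------------------------------------------------------------------
# descriptor matrices


@dataclass
class DescriptorMatrix:
    """Per-molecule numeric feature block for one named scheme."""

    scheme: str
    mol_ids: list[str]
    values: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = {"CATS": CATS_DIM, "MACCS": MACCS_DIM, "PHYSCHEM2D": PHYSCHEM2D_DIM}
        if self.scheme not in expected:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != expected[self.scheme]:
            raise ValueError(
                f"{self.scheme} matrix must have {expected[self.scheme]} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.mol_ids) != self.values.shape[0]:
            raise ValueError("mol_ids length does not match row count")
        if not self.column_names:
            self.column_names = _default_columns(self.scheme)

    @classmethod
    def from_molecules(cls, scheme: str, mols: Sequence[Molecule]) -> "DescriptorMatrix":
        fn = {"CATS": cats2d, "MACCS": maccs166, "PHYSCHEM2D": physchem206}[scheme]
        values = np.vstack([fn(m) for m in mols]) if mols else np.empty((0, 0))
        if not len(mols):
            dim = {"CATS": CATS_DIM, "MACCS": MACCS_DIM, "PHYSCHEM2D": PHYSCHEM2D_DIM}[scheme]
            values = np.empty((0, dim))
        return cls(scheme=scheme, mol_ids=[m.mol_id for m in mols], values=values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.mol_ids, name="mol_id"),
                            columns=self.column_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, scheme: str, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="mol_id")
        return cls(scheme=scheme, mol_ids=[str(i) for i in df.index],
                   values=df.to_numpy(float), column_names=list(df.columns))


def _default_columns(scheme: str) -> list[str]:
    if scheme == "CATS":
        return [f"cats_{a}{b}_{d}" for (a, b) in PPP_PAIRS for d in range(N_DISTANCE_BINS)]
    if scheme == "MACCS":
        return [f"maccs_{i}" for i in range(1, MACCS_DIM + 1)]
    return list(_PHYSCHEM_PANEL.names)


def compute_matrices(mols: Sequence[Molecule]) -> dict[str, DescriptorMatrix]:
    """All three scheme matrices for one molecule list."""
    return {s: DescriptorMatrix.from_molecules(s, mols) for s in SCHEMES}


# ---------------------------------------------------------------------------
# similarity fingerprints (behind the pseudo-platform predictors)

_FP_GENERATORS: dict[str, Callable[[], object]] = {
    "morgan2": lambda: rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048),
    "morgan3": lambda: rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048),
    "rdkit_path": lambda: rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048),
}

FP_SCHEMES = ("morgan2", "morgan3", "rdkit_path", "maccs")

_fp_cache: dict[str, object] = {}


def fingerprint(mol: Molecule | Chem.Mol, scheme: str) -> np.ndarray:
    """Binary fingerprint under one of the named schemes."""
    if scheme == "maccs":
        return maccs166(mol).astype(bool)
    if scheme not in _FP_GENERATORS:
        raise ValueError(f"unknown fingerprint scheme {scheme!r}")
    if isinstance(mol, Molecule):
        mol = mol.to_rdkit()
    gen = _fp_cache.setdefault(scheme, _FP_GENERATORS[scheme]())
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(bv.GetNumBits(), dtype=bool)
    for bit in bv.GetOnBits():
        arr[bit] = True
    return arr


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two equal-length bit vectors.

    Two all-zero vectors are defined to have similarity 1.0.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union
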