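"""Molecule ingestion, canonicalization, deduplication and scaffold extraction.

All structure handling in the package goes through this module so that a
single canonicalization engine (RDKit) is applied uniformly to every input.
Cross-toolkit SMILES equality is not promised — only internal consistency,
which is what identity deduplication and scaffold grouping require.

Salts and mixtures are reduced to the largest organic fragment before
canonicalization. Stereochemistry is preserved; duplicate detection uses the
full 27-character (stereo-sensitive) InChIKey.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparsable record; rejection is reported through
# this module's logger instead.
RDLogger.DisableLog("rdApp.error")

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


@dataclass(frozen=True)
class Molecule:
    """A canonical structure record.

    Attributes
    ----------
    mol_id : str
        Caller-supplied opaque identifier.
    smiles_input : str
        The structure string exactly as provided.
    smiles_canonical : str
        Canonical isomeric SMILES of the largest organic fragment.
    inchikey : str
        27-character InChIKey (stereo-sensitive), used for deduplication.
    scaffold_smiles : str
        Canonical Bemis–Murcko framework; empty string for acyclic molecules.
    n_heavy : int
        Number of non-hydrogen atoms.
    """

    mol_id: str
    smiles_input: str
    smiles_canonical: str
    inchikey: str
    scaffold_smiles: str
    n_heavy: int

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild the RDKit molecule from the canonical SMILES."""
        mol = Chem.MolFromSmiles(self.smiles_canonical)
        if mol is None:  # pragma: no cover - canonical SMILES always reparse
            raise ValueError(f"canonical SMILES failed to reparse: {self.mol_id}")
        return mol


class ParseError(ValueError):
    """A structure record that could not be interpreted."""


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    def key(f: Chem.Mol) -> tuple:
        has_c = any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        # prefer carbon-containing, then larger; lexicographic SMILES breaks ties
        return (has_c, f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))

    return max(frags, key=key)


def _mol_from_record(record: str) -> Chem.Mol | None:
    if "M  END" in record or "\n" in record.strip():
        return Chem.MolFromMolBlock(record)
    return Chem.MolFromSmiles(record)


def parse_molecule(record: str, mol_id: str) -> Molecule:
    """Parse one SMILES string or SDF/mol block into a :class:`Molecule`.

    Hydrogens are left implicit; salts/mixtures keep the largest organic
    fragment. Raises :class:`ParseError` on unparsable input — batch readers
    catch it, log the offending id, and continue.
    """
    mol = _mol_from_record(record)
    if mol is None:
        raise ParseError(f"unparsable structure for id {mol_id!r}")
    mol = _largest_organic_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # valence errors etc.
        raise ParseError(f"structure for id {mol_id!r} failed sanitization: {exc}") from exc
    if mol.GetNumHeavyAtoms() < 1:
        raise ParseError(f"no heavy atoms in record {mol_id!r}")

    canonical = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    if not INCHIKEY_RE.match(inchikey or ""):
        raise ParseError(f"InChIKey generation failed for id {mol_id!r}")
    return Molecule(
        mol_id=mol_id,
        smiles_input=record,
        smiles_canonical=canonical,
        inchikey=inchikey,
        scaffold_smiles=murcko_scaffold_smiles(mol),
        n_heavy=mol.GetNumHeavyAtoms(),
    )


def parse_batch(records: Iterable[tuple[str, str]]) -> tuple[list[Molecule], list[str]]:
    """Parse ``(record, mol_id)`` pairs; rejected ids are logged and returned.

    A bad record never aborts the batch.
    """
    accepted: list[Molecule] = []
    rejected: list[str] = []
    for record, mol_id in records:
        try:
            accepted.append(parse_molecule(record, mol_id))
        except ParseError as exc:
            logger.warning("skipping record: %s", exc)
            rejected.append(mol_id)
    return accepted, rejected


def murcko_scaffold_smiles(mol: Chem.Mol | Molecule) -> str:
    """Canonical Bemis–Murcko framework (ring systems + linkers).

    Returns the empty string for ring-free molecules.
    """
    if isinstance(mol, Molecule):
        mol = mol.to_rdkit()
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def dedup_by_inchikey(mols: Sequence[Molecule]) -> tuple[list[Molecule], list[str]]:
    """Keep the first occurrence of every InChIKey, preserving input order.

    Returns ``(unique, dropped_ids)`` with ``len(unique) + len(dropped) ==
    len(mols)``.
    """
    seen: set[str] = set()
    unique: list[Molecule] = []
    dropped: list[str] = []
    for mol in mols:
        if mol.inchikey in seen:
            dropped.append(mol.mol_id)
        else:
            seen.add(mol.inchikey)
            unique.append(mol)
    return unique, dropped


# ---------------------------------------------------------------------------
# file I/O


def read_smiles_file(path: str | Path) -> tuple[list[Molecule], list[str]]:
    """Read a ``.smi`` file: one record per line, ``SMILES[ ws id]``.

    Records without an explicit id get ``line<N>``.
    """
    pairs: list[tuple[str, str]] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"line{i}"
        pairs.append((smiles, mol_id))
    return parse_batch(pairs)


def read_sdf(path: str | Path) -> tuple[list[Molecule], list[str]]:
    """Read a V2000 multi-record SDF; record name or ``sdf<N>`` as id."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    mols: list[Molecule] = []
    rejected: list[str] = []
    for i, raw in enumerate(supplier, start=1):
        mol_id = f"sdf{i}"
        if raw is None:
            logger.warning("skipping unreadable SDF record %d", i)
            rejected.append(mol_id)
            continue
        if raw.HasProp("_Name") and raw.GetProp("_Name").strip():
            mol_id = raw.GetProp("_Name").strip()
        try:
            mols.append(parse_molecule(Chem.MolToMolBlock(raw, kekulize=False), mol_id))
        except ParseError as exc:
            logger.warning("skipping record: %s", exc)
            rejected.append(mol_id)
    return mols, rejected


def write_smiles_file(mols: Sequence[Molecule], path: str | Path) -> None:
    """Write canonical SMILES, one ``smiles<TAB>id`` per line."""
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{mol.smiles_canonical}\t{mol.mol_id}\n")


def write_molecule_table(mols: Sequence[Molecule], path: str | Path) -> None:
    """Write the CSV molecule table used by downstream reports."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "smiles_canonical", "inchikey", "scaffold_smiles", "n_heavy"])
        for mol in mols:
            writer.writerow(
                [mol.mol_id, mol.smiles_canonical, mol.inchikey, mol.scaffold_smiles, mol.n_heavy]
            )
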