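"""Molecule library I/O, canonicalization, and topology-level deduplication.

Libraries are ordered collections of :class:`MoleculeRecord`. Two records are
"the same chemical entity" iff their canonical SMILES (stereo retained) are
identical; stereoisomers, tautomers and protomers written differently stay
distinct. Multi-component inputs (salts) are reduced to the largest organic
component before canonicalization.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: roles a record may carry: parent natural product, extensive (leaf) fragment,
#: non-extensive (intermediate) fragment.  Screening adds ACTIVE/DECOY.
ROLES = ("NP", "EXT", "NON", "ACTIVE", "DECOY")


class LibraryFormatError(ValueError):
    """Raised when a library file yields zero parseable records."""


@dataclass
class MoleculeRecord:
    """One chemical entity with provenance.

    Parameters
    ----------
    id : str
        Unique identifier within a library.
    smiles_in : str
        The SMILES string as read from the source.
    canonical : str
        RDKit canonical isomeric SMILES; round-trip stable.
    role : str
        One of ``NP``, ``EXT``, ``NON``, ``ACTIVE``, ``DECOY``.
    parent_ids : set of str
        Parent molecule ids; empty iff role is ``NP`` (or ACTIVE/DECOY).
    source : str
        Library tag.
    """

    id: str
    smiles_in: str
    canonical: str
    role: str = "NP"
    parent_ids: set = field(default_factory=set)
    source: str = ""

    def mol(self) -> Chem.Mol:
        """Return an RDKit molecule parsed from the canonical SMILES."""
        m = Chem.MolFromSmiles(self.canonical)
        if m is None:  # canonical strings are parse-round-trip stable
            raise ValueError(f"record {self.id}: unparseable canonical SMILES")
        return m


@dataclass
class Library:
    """An ordered, id-unique collection of molecule records."""

    records: list = field(default_factory=list)
    name: str = "library"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def ids(self) -> list:
        return [r.id for r in self.records]

    def canonical_set(self) -> set:
        return {r.canonical for r in self.records}


def canonicalize(smiles: str) -> Optional[str]:
    """Canonical isomeric SMILES for ``smiles``, or None if unparseable.

    Multi-component strings are reduced to the largest component by heavy-atom
    count (ties broken by canonical string for determinism).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        logger.info("multi-component input reduced to largest component: %s", smiles)
        frags = sorted(
            frags, key=lambda m: (-m.GetNumHeavyAtoms(), Chem.MolToSmiles(m))
        )
        mol = frags[0]
    return Chem.MolToSmiles(mol)


def record_from_smiles(
    smiles: str, rec_id: str, role: str = "NP", parent_ids: Iterable = (),
    source: str = "",
) -> Optional[MoleculeRecord]:
    """Build a canonicalized record; None when the SMILES does not parse."""
    can = canonicalize(smiles)
    if can is None:
        return None
    return MoleculeRecord(
        id=rec_id, smiles_in=smiles, canonical=can, role=role,
        parent_ids=set(parent_ids), source=source,
    )


def read_library(path, fmt: Optional[str] = None, name: Optional[str] = None) -> Library:
    """Read a .smi or SDF (V2000) molecule library.

    .smi lines are ``SMILES<whitespace>ID``; a missing ID is auto-generated as
    ``<name>_<lineno>``. Unparseable records are skipped with a warning and
    counted on the returned library as ``lib.skipped``.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    LibraryFormatError
        If no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in (".sdf", ".mol", ".sd") else "smi"
    name = name or path.stem
    records: list = []
    skipped = 0
    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            rec_id = parts[1].strip() if len(parts) > 1 else f"{name}_{lineno}"
            rec = record_from_smiles(smi, rec_id, source=name)
            if rec is None:
                skipped += 1
                logger.warning("%s line %d: unparseable SMILES %r", path, lineno, smi)
                continue
            records.append(rec)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("%s: unparseable SDF record %d", path, i)
                continue
            rec_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{name}_{i + 1}"
            role = mol.GetProp("role") if mol.HasProp("role") else "NP"
            parents = (
                set(p for p in mol.GetProp("parent_ids").split(";") if p)
                if mol.HasProp("parent_ids")
                else set()
            )
            smi = Chem.MolToSmiles(mol)
            records.append(
                MoleculeRecord(
                    id=rec_id, smiles_in=smi, canonical=smi, role=role,
                    parent_ids=parents, source=name,
                )
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not records:
        raise LibraryFormatError(f"{path}: no parseable records")
    _uniquify_ids(records)
    lib = Library(records=records, name=name)
    lib.skipped = skipped
    return lib


def _uniquify_ids(records) -> None:
    # colliding input ids get a "_dupN" suffix; first occurrence keeps its id
    seen: dict = {}
    for rec in records:
        n = seen.get(rec.id, 0)
        seen[rec.id] = n + 1
        if n:
            rec.id = f"{rec.id}_dup{n}"


def write_library(lib: Library, path, fmt: Optional[str] = None) -> None:
    """Write a library as SDF (with role/parent tags) or CSV."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "sdf"
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for rec in lib:
                mol = rec.mol()
                mol.SetProp("_Name", rec.id)
                mol.SetProp("role", rec.role)
                mol.SetProp("parent_ids", ";".join(sorted(rec.parent_ids)))
                mol.SetProp("source", rec.source)
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "canonical", "role", "parent_ids", "source"])
            for rec in lib:
                w.writerow(
                    [rec.id, rec.canonical, rec.role, ";".join(sorted(rec.parent_ids)), rec.source]
                )
    elif fmt == "smi":
        with open(path, "w") as fh:
            for rec in lib:
                fh.write(f"{rec.canonical} {rec.id}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def dedup(lib: Library):
    """Collapse records sharing a canonical SMILES; first occurrence wins.

    Parent ids of merged duplicates are unioned onto the survivor. Returns
    ``(deduplicated library, duplicate_count)``.
    """
    survivors: dict = {}
    order: list = []
    dup_count = 0
    for rec in lib:
        keep = survivors.get(rec.canonical)
        if keep is None:
            keep = replace(rec, parent_ids=set(rec.parent_ids))
            survivors[rec.canonical] = keep
            order.append(keep)
        else:
            dup_count += 1
            keep.parent_ids |= rec.parent_ids
    out = Library(records=order, name=lib.name)
    return out, dup_count
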