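"""Physicochemical and scaffold-diversity descriptors.

MW is the average-isotope molecular weight of the H-capped form; logP is the
Crippen atomic-contribution estimate; complexity is Bertz's graph-theoretic
index (reported as ``complexity_bertz`` — deterministic and citable, unlike
proprietary complexity scores, and only relative orderings are interpreted).
H-bond counts follow the fragment Rule-of-Three convention: donors are N-H/O-H
hydrogens, acceptors are nitrogen+oxygen atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import Library, MoleculeRecord

#: Rule-of-Three limits; a violation is a *strict* exceedance (value > limit).
RO3_LIMITS = {"MW": 300.0, "LOGP": 3.0, "HBD": 3, "HBA": 3, "ROTB": 3}


@dataclass
class PropertyProfile:
    mol_id: str
    role: str
    mw: float
    logp: float
    complexity: float
    hbd: int
    hba: int
    rotb: int
    murcko_skeleton: Optional[str]
    ro3_violations: List[str] = field(default_factory=list)


def _as_mol(mol):
    if isinstance(mol, MoleculeRecord):
        return mol.mol(), mol.id, mol.role
    return mol, "", ""


def murcko_skeleton(mol) -> Optional[str]:
    """Bemis-Murcko graph framework: ring systems + linkers, substituents
    removed, every heteroatom replaced by carbon, all bonds single.

    Returns canonical SMILES, or None for acyclic molecules.
    """
    m, _, _ = _as_mol(mol)
    # exocyclic double-bonded atoms (e.g. amide O) survive the first scaffold
    # pass but become removable side chains once bonds are single — iterate to
    # the fixed point so the skeleton is idempotent
    prev = None
    smi = None
    for _ in range(5):
        scaffold = MurckoScaffold.GetScaffoldForMol(m)
        if scaffold is None or scaffold.GetNumAtoms() == 0:
            return None
        generic = MurckoScaffold.MakeScaffoldGeneric(scaffold)
        smi = Chem.MolToSmiles(generic)
        if smi == prev:
            break
        prev = smi
        m = generic
    return smi


def ro3_profile(mol) -> List[str]:
    """Rule-of-Three violation flags (strict inequalities)."""
    m, _, _ = _as_mol(mol)
    values = {
        "MW": Descriptors.MolWt(m),
        "LOGP": Crippen.MolLogP(m),
        "HBD": Lipinski.NHOHCount(m),
        "HBA": Lipinski.NOCount(m),
        "ROTB": Lipinski.NumRotatableBonds(m),
    }
    return [k for k in RO3_LIMITS if values[k] > RO3_LIMITS[k]]


def profile(mol) -> PropertyProfile:
    """Full descriptor profile of one molecule."""
    m, mol_id, role = _as_mol(mol)
    return PropertyProfile(
        mol_id=mol_id,
        role=role,
        mw=Descriptors.MolWt(m),
        logp=Crippen.MolLogP(m),
        complexity=GraphDescriptors.BertzCT(m),
        hbd=Lipinski.NHOHCount(m),
        hba=Lipinski.NOCount(m),
        rotb=Lipinski.NumRotatableBonds(m),
        murcko_skeleton=murcko_skeleton(m),
        ro3_violations=ro3_profile(m),
    )


def count_skeletons(lib: Library) -> int:
    """Number of distinct (non-null) Murcko graph frameworks in a library."""
    return len({s for s in (murcko_skeleton(rec) for rec in lib) if s is not None})


def profile_library(lib: Library) -> pd.DataFrame:
    """Descriptor table for a whole library (one row per record)."""
    rows = []
    for rec in lib:
        p = profile(rec)
        rows.append(
            {
                "id": p.mol_id,
                "role": p.role,
                "mw": p.mw,
                "logp": p.logp,
                "complexity_bertz": p.complexity,
                "hbd": p.hbd,
                "hba": p.hba,
                "rotb": p.rotb,
                "murcko_skeleton": p.murcko_skeleton or "",
                "ro3_violations": ";".join(p.ro3_violations),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "role", "mw", "logp", "complexity_bertz", "hbd", "hba",
            "rotb", "murcko_skeleton", "ro3_violations",
        ],
    )
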