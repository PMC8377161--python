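"""Synthetic inputs with known ground truth.

Natural-product-like molecules are assembled from a small vocabulary of
cleavage-inert blocks (rings and short chains carrying no cleavable bond of
their own) joined by retrosynthetically cleavable linkages (amide, ester,
ether, olefin, ...). By construction the detected cleavage sites are exactly
the planted linkage bonds, and fragment ground truths are brute-forced over
all bond subsets at build time — so the fast enumeration engine can be tested
against a known answer on every fixture.

The screening fixture plants signal the same way: a reference model is derived
from a rigid para-donor/acceptor benzene template whose feature atoms are all
ring-attached (hence conformation-independent); actives are ring-decorated
analogues sharing that substitution pattern, decoys are property-matched
molecules carrying no H-bond donor at all, so they can never satisfy a model
that requires one. The decoy:active ratio defaults to 30:1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chem_io import Library, MoleculeRecord, record_from_smiles
from .pharmacophore import (
    ModelPair,
    PharmacophoreModel,
    derive_model_from_reference,
    generate_conformers,
    match_ensemble,
    perceive_feature_groups,
)
from .recap import (
    FragmentationResult,
    bruteforce_fragments,
    cut_bonds,
    detect_sites,
    unique_bonds,
)

logger = logging.getLogger(__name__)


class AssemblyError(ValueError):
    """A block/linkage combination cannot be realized chemically."""


# Cleavage-inert building blocks: rings and short chains. None contains an
# acyclic bond matching a cleavage rule, so every site of an assembly is a
# planted linkage bond. "aminophenol" doubles as the pharmacophore signal
# block (donor + acceptor + aromatic ring, all ring-attached).
BLOCKS: Dict[str, str] = {
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "cyclohexane": "C1CCCCC1",
    "cyclopentane": "C1CCCC1",
    "cyclopropane": "C1CC1",
    "furan": "c1ccoc1",
    "thiophene": "c1ccsc1",
    "pyridine": "c1ccncc1",
    "thf": "C1CCOC1",
    "hydroxy_thf": "OC1CCOC1",
    "pyrrole": "c1cc[nH]c1",
    "imidazole": "c1c[nH]cn1",
    "pyrrolidinone": "O=C1CCCN1",
    "aminophenol": "Nc1ccc(O)cc1",
    "phenol": "Oc1ccccc1",
    "fluorobenzene": "Fc1ccccc1",
    "trifluorotoluene": "FC(F)(F)c1ccccc1",
    "ethane": "CC",
    "propane": "CCC",
    "isobutane": "CC(C)C",
}

SIGNAL_BLOCK = "aminophenol"

#: linkage -> (inserted-atom SMILES spec, expected number of cleavage sites)
#: ether/amine/urea linkages expose two cleavable bonds each.
LINKAGE_SITES = {
    "amide": 1,
    "ester": 1,
    "ether": 2,
    "olefin": 1,
    "amine": 2,
    "urea": 2,
    "sulfonamide": 1,
    "biaryl": 1,
    "aromatic_n": 1,
    "lactam": 1,
}

DEFAULT_LINKAGE_MIX = {
    "amide": 0.35,
    "ester": 0.25,
    "ether": 0.15,
    "olefin": 0.10,
    "biaryl": 0.10,
    "sulfonamide": 0.05,
}


@dataclass
class FixtureSpec:
    """A reproducible recipe for a block-assembled molecule library."""

    n_molecules: int = 12
    block_count_range: Tuple[int, int] = (3, 5)
    topology: str = "path"  # path | tree | mixed
    linkage_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LINKAGE_MIX))
    seed: int = 0
    signal_prob: float = 0.6  # chance the signal block is among the blocks


# ---------------------------------------------------------------------------
# assembly


def _attachable_atoms(mol: Chem.Mol, kind: str) -> List[int]:
    """Atom indices usable as an attachment point of the given flavour."""
    out = []
    for atom in mol.GetAtoms():
        if kind == "carbon":
            ok = atom.GetAtomicNum() == 6 and atom.GetTotalNumHs() >= 1
        elif kind == "aromatic_carbon":
            ok = atom.GetAtomicNum() == 6 and atom.GetIsAromatic() and atom.GetTotalNumHs() >= 1
        elif kind == "aliphatic_carbon_d2":
            # aliphatic C that will not be a bare terminal cap after bonding
            ok = (
                atom.GetAtomicNum() == 6
                and not atom.GetIsAromatic()
                and atom.GetTotalNumHs() >= 1
                and atom.GetDegree() >= 1
            )
        elif kind == "pyrrole_n":
            ok = atom.GetAtomicNum() == 7 and atom.GetIsAromatic() and atom.GetTotalNumHs() == 1
        elif kind == "lactam_n":
            ok = (
                atom.GetAtomicNum() == 7
                and atom.IsInRing()
                and not atom.GetIsAromatic()
                and atom.GetTotalNumHs() >= 1
                and any(
                    n.GetAtomicNum() == 6
                    and any(b.GetBondTypeAsDouble() == 2.0 and b.GetOtherAtom(n).GetAtomicNum() == 8
                            for b in n.GetBonds())
                    for n in atom.GetNeighbors()
                )
            )
        else:
            raise ValueError(kind)
        if ok:
            out.append(atom.GetIdx())
    return out


#: per linkage: (A-side attachment flavour, B-side attachment flavour)
_LINKAGE_ATTACH = {
    "amide": ("carbon", "carbon"),
    "ester": ("carbon", "carbon"),
    "ether": ("carbon", "carbon"),
    "olefin": ("carbon", "carbon"),
    "amine": ("carbon", "carbon"),
    "urea": ("carbon", "carbon"),
    "sulfonamide": ("carbon", "carbon"),
    "biaryl": ("aromatic_carbon", "aromatic_carbon"),
    "aromatic_n": ("pyrrole_n", "aliphatic_carbon_d2"),
    "lactam": ("lactam_n", "aliphatic_carbon_d2"),
}


def _add_linkage(rw: Chem.RWMol, linkage: str, ai: int, aj: int) -> List[Tuple[int, int]]:
    """Insert linkage atoms between attachment atoms ai, aj; return the bonds
    expected to be detected as cleavage sites (parent numbering)."""
    single = Chem.BondType.SINGLE
    double = Chem.BondType.DOUBLE

    def atom(symbol, charge=0):
        a = Chem.Atom(symbol)
        a.SetFormalCharge(charge)
        return rw.AddAtom(a)

    if linkage == "amide":
        c, o, n = atom("C"), atom("O"), atom("N")
        rw.AddBond(ai, c, single)
        rw.AddBond(c, o, double)
        rw.AddBond(c, n, single)
        rw.AddBond(n, aj, single)
        return [(c, n)]
    if linkage == "ester":
        c, o1, o2 = atom("C"), atom("O"), atom("O")
        rw.AddBond(ai, c, single)
        rw.AddBond(c, o1, double)
        rw.AddBond(c, o2, single)
        rw.AddBond(o2, aj, single)
        return [(c, o2)]
    if linkage == "ether":
        o = atom("O")
        rw.AddBond(ai, o, single)
        rw.AddBond(o, aj, single)
        return [(ai, o), (o, aj)]
    if linkage == "olefin":
        c1, c2 = atom("C"), atom("C")
        rw.AddBond(ai, c1, single)
        rw.AddBond(c1, c2, double)
        rw.AddBond(c2, aj, single)
        return [(c1, c2)]
    if linkage == "amine":
        n = atom("N")
        rw.AddBond(ai, n, single)
        rw.AddBond(n, aj, single)
        return [(ai, n), (n, aj)]
    if linkage == "urea":
        n1, c, o, n2 = atom("N"), atom("C"), atom("O"), atom("N")
        rw.AddBond(ai, n1, single)
        rw.AddBond(n1, c, single)
        rw.AddBond(c, o, double)
        rw.AddBond(c, n2, single)
        rw.AddBond(n2, aj, single)
        return [(n1, c), (c, n2)]
    if linkage == "sulfonamide":
        s, o1, o2, n = atom("S"), atom("O"), atom("O"), atom("N")
        rw.AddBond(ai, s, single)
        rw.AddBond(s, o1, double)
        rw.AddBond(s, o2, double)
        rw.AddBond(s, n, single)
        rw.AddBond(n, aj, single)
        return [(n, s)]
    if linkage in ("biaryl", "aromatic_n", "lactam"):
        rw.AddBond(ai, aj, single)
        return [(ai, aj)]
    raise ValueError(f"unknown linkage {linkage!r}")


def assemble_np(
    blocks: Sequence[str],
    topology: str = "path",
    linkages: Optional[Sequence[str]] = None,
    seed: int = 0,
    mol_id: str = "FIX",
    edges: Optional[Sequence[Tuple[int, int]]] = None,
) -> Tuple[MoleculeRecord, FragmentationResult]:
    """Assemble blocks into one molecule and brute-force its ground truth.

    ``blocks`` are vocabulary names or raw SMILES; ``linkages`` names one
    cleavable linkage per edge (default all-amide). ``edges`` overrides the
    block-connection tree (defaults: a path; ``topology='tree'`` requires
    explicit edges). Raises :class:`AssemblyError` when an attachment cannot
    be realized, and validates that the detected cleavage sites are exactly
    the planted linkage bonds.
    """
    n = len(blocks)
    if n < 1:
        raise AssemblyError("need at least one block")
    if edges is None:
        if topology != "path":
            raise AssemblyError("non-path topology requires explicit edges")
        edges = [(i, i + 1) for i in range(n - 1)]
    edges = list(edges)
    if linkages is None:
        linkages = ["amide"] * len(edges)
    if len(linkages) != len(edges):
        raise AssemblyError("one linkage required per edge")

    mols = []
    for b in blocks:
        smi = BLOCKS.get(b, b)
        m = Chem.MolFromSmiles(smi)
        if m is None:
            raise AssemblyError(f"unparseable block {b!r}")
        mols.append(m)

    rw = Chem.RWMol()
    offsets = []
    for m in mols:
        offsets.append(rw.GetNumAtoms())
        rw.InsertMol(m)

    used: Dict[int, set] = {i: set() for i in range(n)}
    planted: List[Tuple[int, int]] = []
    for (u, v), linkage in zip(edges, linkages):
        kind_u, kind_v = _LINKAGE_ATTACH[linkage]
        cand_u = [a for a in _attachable_atoms(mols[u], kind_u) if a not in used[u]]
        cand_v = [a for a in _attachable_atoms(mols[v], kind_v) if a not in used[v]]
        if not cand_u or not cand_v:
            raise AssemblyError(
                f"blocks {u}/{v} have no free {linkage} attachment point"
            )
        au, av = cand_u[0], cand_v[0]
        used[u].add(au)
        used[v].add(av)
        if kind_u in ("pyrrole_n", "lactam_n"):
            rw.GetAtomWithIdx(offsets[u] + au).SetNumExplicitHs(
                rw.GetAtomWithIdx(offsets[u] + au).GetTotalNumHs() - 1
            )
        bonds = _add_linkage(rw, linkage, offsets[u] + au, offsets[v] + av)
        planted.extend((min(a, b), max(a, b)) for a, b in bonds)

    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise AssemblyError(f"valence-impossible junction: {exc}") from exc
    smiles = Chem.MolToSmiles(mol)
    record = record_from_smiles(smiles, mol_id, role="NP", source="fixture")

    # planted bonds were recorded in assembly numbering; re-detect on the
    # canonical record and require exact agreement in *count* and, on the
    # assembly-numbered mol, in identity.
    detected_raw = unique_bonds(detect_sites(mol))
    if set(detected_raw) != set(planted):
        raise AssemblyError(
            f"site mismatch: planted {sorted(set(planted))}, detected {detected_raw}"
        )

    truth = FragmentationResult(parent_id=record.id)
    truth.sites = detect_sites(record)
    bonds = unique_bonds(truth.sites)
    if bonds:
        leaves = {Chem.MolToSmiles(f) for f in cut_bonds(record.mol(), bonds)}
        everything = bruteforce_fragments(record.mol(), bonds)
        non = everything - leaves
        truth.extensive = [
            MoleculeRecord(id=f"{mol_id}_EXT{i:03d}", smiles_in=s, canonical=s,
                           role="EXT", parent_ids={mol_id}, source="fixture")
            for i, s in enumerate(sorted(leaves))
        ]
        truth.non_extensive = [
            MoleculeRecord(id=f"{mol_id}_NON{i:03d}", smiles_in=s, canonical=s,
                           role="NON", parent_ids={mol_id}, source="fixture")
            for i, s in enumerate(sorted(non))
        ]
    else:
        truth.undeconstructable = True
    return record, truth


# ---------------------------------------------------------------------------
# library generation


def generate_library(spec: FixtureSpec):
    """Sample a reproducible fixture library.

    Returns ``(Library, dict parent_id -> FragmentationResult ground truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = [b for b in BLOCKS if b not in ("pyrrolidinone",)]
    records, truths = [], {}
    attempts = 0
    i = 0
    while len(records) < spec.n_molecules and attempts < 50 * spec.n_molecules:
        attempts += 1
        k = int(rng.integers(spec.block_count_range[0], spec.block_count_range[1] + 1))
        names = list(rng.choice(vocab, size=k, replace=False))
        if spec.signal_prob and rng.random() < spec.signal_prob and SIGNAL_BLOCK not in names:
            names[int(rng.integers(0, k))] = SIGNAL_BLOCK
        if spec.topology == "tree" or (spec.topology == "mixed" and rng.random() < 0.5 and k >= 4):
            edges = [(int(rng.integers(0, j)), j) for j in range(1, k)]
            topo = "tree"
        else:
            edges = [(j, j + 1) for j in range(k - 1)]
            topo = "path"
        kinds = list(spec.linkage_mix)
        probs = np.array([spec.linkage_mix[x] for x in kinds], dtype=float)
        probs /= probs.sum()
        links = []
        for u, v in edges:
            lk = str(rng.choice(kinds, p=probs))
            if lk == "biaryl":
                # both endpoints must be aromatic; fall back to amide
                mu = Chem.MolFromSmiles(BLOCKS.get(names[u], names[u]))
                mv = Chem.MolFromSmiles(BLOCKS.get(names[v], names[v]))
                if not (_attachable_atoms(mu, "aromatic_carbon") and _attachable_atoms(mv, "aromatic_carbon")):
                    lk = "amide"
            links.append(lk)
        mol_id = f"{spec.topology.upper()[:1]}NP{i + 1:04d}"
        try:
            rec, truth = assemble_np(
                names, topology=topo, linkages=links, seed=spec.seed,
                mol_id=mol_id, edges=edges,
            )
        except AssemblyError as exc:
            logger.debug("assembly retry (%s)", exc)
            continue
        if any(r.canonical == rec.canonical for r in records):
            continue
        records.append(rec)
        truths[rec.id] = truth
        i += 1
    if len(records) < spec.n_molecules:
        raise AssemblyError("could not assemble requested library size")
    return Library(records=records, name=f"fixture_seed{spec.seed}"), truths


# ---------------------------------------------------------------------------
# screening fixture


def reference_screening_model(
    tolerance: float = 1.5, seed: int = 7, name: str = "aminophenol_ref"
) -> PharmacophoreModel:
    """Pharmacophore model derived from a rigid 4-aminophenol reference:
    HBD + HBA on both para heteroatoms plus the ring centroid (5 features)."""
    ref = Chem.MolFromSmiles(BLOCKS[SIGNAL_BLOCK])
    ens = generate_conformers(ref, n=1, seed=seed)
    if ens.GetNumConformers() == 0:  # pragma: no cover
        raise RuntimeError("reference embedding failed")
    return derive_model_from_reference(
        ens, conf_id=0, kinds_filter=("AR", "HBD", "HBA"),
        tolerance_default=tolerance, name=name,
    )


def reference_model_pair(tolerance: float = 1.5, seed: int = 7) -> ModelPair:
    """Overlapping left/right models of the same reference site: the right
    model drops the donor constraints (AR + 2 HBA), so it is the permissive
    partner of the full 5-feature left model."""
    ref = Chem.MolFromSmiles(BLOCKS[SIGNAL_BLOCK])
    ens = generate_conformers(ref, n=1, seed=seed)
    left = derive_model_from_reference(
        ens, conf_id=0, kinds_filter=("AR", "HBD", "HBA"),
        tolerance_default=tolerance, name="ref_left",
    )
    right = derive_model_from_reference(
        ens, conf_id=0, kinds_filter=("AR", "HBA"),
        tolerance_default=tolerance, name="ref_right",
    )
    return ModelPair.build(left, right)


_DONORS = ("O", "N", "NC", "NCC")
_RING_DECOR = ("", "C", "F", "Cl", "CC", "C(C)C")
_DECOY_CORES = ("c1ccccc1", "c1ccc2ccccc2c1", "c1ccncc1", "C1CCCCC1")
_DECOY_SUBS = ("C", "CC", "CCC", "C(C)C", "F", "Cl", "OC", "C(=O)C", "C#N", "CC(C)C")


def _enumerate_actives(rng: np.random.Generator) -> List[str]:
    """Shuffled pool of para donor/donor benzenes with inert ring decorations."""
    pool = []
    for d1 in _DONORS:
        for d2 in _DONORS:
            for m1 in _RING_DECOR:
                for m2 in _RING_DECOR:
                    b1 = f"({m1})" if m1 else ""
                    b2 = f"({m2})" if m2 else ""
                    pool.append(f"{d1}c1cc{b1}c({d2})cc1{b2}".replace("cc1()", "cc1"))
    smis = []
    seen = set()
    for s in pool:
        m = Chem.MolFromSmiles(s)
        if m is None:
            continue
        can = Chem.MolToSmiles(m)
        if can not in seen:
            seen.add(can)
            smis.append(can)
    rng.shuffle(smis)
    return smis


def _random_decoy(rng: np.random.Generator) -> Optional[str]:
    core = Chem.MolFromSmiles(str(rng.choice(_DECOY_CORES)))
    rw = Chem.RWMol(core)
    n_subs = int(rng.integers(1, 5))
    for _ in range(n_subs):
        sites = [
            a.GetIdx()
            for a in rw.GetMol().GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
        ]
        if not sites:
            break
        site = int(rng.choice(sites))
        sub = Chem.MolFromSmiles(str(rng.choice(_DECOY_SUBS)))
        off = rw.GetNumAtoms()
        rw.InsertMol(sub)
        rw.AddBond(site, off, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if any(kind == "HBD" for kind, _ in perceive_feature_groups(mol)):
        return None  # decoys must lack every donor
    return Chem.MolToSmiles(mol)


def make_screening_fixture(
    model: PharmacophoreModel,
    n_actives: int = 20,
    n_decoys: Optional[int] = None,
    seed: int = 0,
    verify_conformers: int = 20,
):
    """Planted-signal actives/decoys for ``model`` (30 decoys per active by
    default).

    Actives are template analogues verified to self-match the model within
    ``verify_conformers`` conformers at build time; decoys carry no H-bond
    donor, so any model that requires one rejects them on feature kinds alone.
    Deterministic per seed.
    """
    if n_decoys is None:
        n_decoys = 30 * n_actives
    rng = np.random.default_rng(seed)
    actives: List[MoleculeRecord] = []
    for can in _enumerate_actives(rng):
        mol = Chem.MolFromSmiles(can)
        ens = generate_conformers(mol, n=verify_conformers, seed=int(rng.integers(2**31 - 1)))
        if ens.GetNumConformers() == 0 or match_ensemble(model, ens) is None:
            continue
        actives.append(
            MoleculeRecord(
                id=f"ACT{len(actives) + 1:04d}", smiles_in=can, canonical=can,
                role="ACTIVE", source="fixture",
            )
        )
        if len(actives) == n_actives:
            break
    if len(actives) < n_actives:
        raise RuntimeError(
            f"only {len(actives)} verified actives for model {model.name!r}"
        )
    decoys: List[MoleculeRecord] = []
    seen = set(r.canonical for r in actives)
    attempts = 0
    while len(decoys) < n_decoys and attempts < 200 * n_decoys:
        attempts += 1
        can = _random_decoy(rng)
        if can is None or can in seen:
            continue
        seen.add(can)
        decoys.append(
            MoleculeRecord(
                id=f"DEC{len(decoys) + 1:05d}", smiles_in=can, canonical=can,
                role="DECOY", source="fixture",
            )
        )
    if len(decoys) < n_decoys:
        raise RuntimeError("decoy generation exhausted")
    return (
        Library(records=actives, name="fixture_actives"),
        Library(records=decoys, name="fixture_decoys"),
    )


def save_ground_truth(truths: Dict[str, FragmentationResult], path) -> None:
    """Serialize fixture ground truths as JSON (canonical SMILES sets)."""
    payload = {
        pid: {
            "n_sites": t.n_sites,
            "undeconstructable": t.undeconstructable,
            "extensive": sorted(r.canonical for r in t.extensive),
            "non_extensive": sorted(r.canonical for r in t.non_extensive),
        }
        for pid, t in sorted(truths.items())
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
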