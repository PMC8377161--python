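"""RECAP retrosynthetic fragmentation in extensive and non-extensive modes.

Cleavage sites are acyclic bonds whose chemical environment matches one of the
eleven classic retrosynthetic rules (amide, ester, amine, urea, ether, olefin,
quaternary N-C, aromatic N - aliphatic C, lactam N - aliphatic C, aryl-aryl,
sulphonamide). Cutting *all* sites yields the extensive (leaf) fragments — the
smallest building blocks. Cutting *subsets* of sites yields the non-extensive
(intermediate) fragments: every connected multi-block piece strictly between a
single leaf and the intact parent.

Severed attachment points are capped with hydrogen, so fragments are ordinary
molecules whose properties (MW, logP, ...) can be profiled directly.

The enumeration of intermediates walks connected node subsets of the block
graph (blocks = leaves, edges = cleavage sites); a brute-force path over all
nonempty bond subsets is kept in :func:`bruteforce_fragments` as the reference
oracle and for fixture ground truths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
from rdkit import Chem

from .chem_io import Library, MoleculeRecord, dedup

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Rule table.  Each SMARTS marks the cut bond with atom maps :1 and :2; the
# bond must additionally be acyclic (checked at match time, ring bonds are
# never cut).  Guards follow the standard conventions:
#   - carbonyl-adjacent N/O are not amines/ethers (handled by the dedicated
#     amide/ester/urea/sulphonamide/lactam rules),
#   - terminal single-heavy-atom caps (D1) are not cleaved off where that
#     would merely shave a methyl/hydroxyl,
#   - aromatic nitrogen is handled by its own rule, not the amine rule.
RECAP_SMARTS = {
    # carboxamide C-N; ureas excluded (their own rule)
    "amide": "[C;$([C]=O);!$([C]([#7])[#7]):1]-!@[#7;+0;!D1:2]",
    # ester carbonyl-C to bridging O
    "ester": "[C;$([C]=O):1]-!@[O;+0;!D1:2]",
    # secondary/tertiary aliphatic amine N-C
    "amine": (
        "[N;+0;D2,D3;!$([N]=*);!$([N][C,S]=[O,S,N,P]):1]"
        "-!@[#6;!D1;!$([#6]=[O,S,N]):2]"
    ),
    # urea N-C(=O) (matches both N-C bonds)
    "urea": "[#7;+0;D2,D3:1]-!@[C;$([C](=O)([#7])[#7]):2]",
    # dialkyl/aryl ether C-O (both acyclic C-O bonds of the O match)
    "ether": "[#6;!D1;!$([#6]=[O,S,N]):1]-!@[O;+0;D2;$([O]([#6])[#6]);!$([O][C,S,P]=[O,S,N]):2]",
    # acyclic olefin C=C (internal only)
    "olefin": "[C;!D1;!$([C]=[O,S,N]):1]=!@[C;!D1;!$([C]=[O,S,N]):2]",
    # quaternary nitrogen - carbon
    "quaternary_n": "[N;+1;D4:1]-!@[#6;!D1:2]",
    # aromatic nitrogen - aliphatic carbon
    "aromatic_n": "[n;+0:1]-!@[C;!D1:2]",
    # lactam nitrogen - exocyclic aliphatic carbon
    "lactam_n": "[N;+0;R;$([N]@[C]=O):1]-!@[C;!D1:2]",
    # biaryl C-C
    "biaryl": "[c:1]-!@[c:2]",
    # sulphonamide N-S
    "sulfonamide": "[#7;+0;D2,D3:1]-!@[S;$([S](=O)=O):2]",
}

RULE_IDS = tuple(RECAP_SMARTS)

_COMPILED = {}


def _queries():
    if not _COMPILED:
        for rule, smarts in RECAP_SMARTS.items():
            q = Chem.MolFromSmarts(smarts)
            maps = {a.GetAtomMapNum(): a.GetIdx() for a in q.GetAtoms() if a.GetAtomMapNum()}
            _COMPILED[rule] = (q, maps[1], maps[2])
    return _COMPILED


@dataclass(frozen=True)
class CleavageSite:
    """One cleavable acyclic bond, identified by parent atom indices."""

    bond: Tuple[int, int]  # (min, max) atom indices in the parent
    rule_id: str

    def __post_init__(self):
        if self.rule_id not in RECAP_SMARTS:
            raise ValueError(f"unknown rule {self.rule_id!r}")


@dataclass
class BlockGraph:
    """Leaf blocks and the cleavage sites connecting them."""

    blocks: List[Tuple[int, ...]]  # atom-index tuples partitioning heavy atoms
    edges: List[Tuple[int, int, Tuple[int, int]]]  # (block_u, block_v, bond)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.blocks)))
        for u, v, bond in self.edges:
            g.add_edge(u, v, bond=bond)
        return g


@dataclass
class FragmentationResult:
    parent_id: str
    sites: List[CleavageSite] = field(default_factory=list)
    extensive: List[MoleculeRecord] = field(default_factory=list)
    non_extensive: List[MoleculeRecord] = field(default_factory=list)
    undeconstructable: bool = False
    truncated: bool = False

    @property
    def n_sites(self) -> int:
        return len({s.bond for s in self.sites})


def detect_sites(mol) -> List[CleavageSite]:
    """All cleavage sites of ``mol`` (an RDKit Mol or a MoleculeRecord).

    Every acyclic bond matching a rule's environment is reported once per
    (bond, rule) pair, sorted by atom indices then rule name. A bond shared by
    several rule environments appears once per rule.
    """
    if isinstance(mol, MoleculeRecord):
        mol = mol.mol()
    found: Set[CleavageSite] = set()
    for rule, (query, i1, i2) in _queries().items():
        for match in mol.GetSubstructMatches(query, uniquify=False):
            a1, a2 = match[i1], match[i2]
            bond = mol.GetBondBetweenAtoms(a1, a2)
            if bond is None or bond.IsInRing():
                continue
            found.add(CleavageSite(bond=(min(a1, a2), max(a1, a2)), rule_id=rule))
    return sorted(found, key=lambda s: (s.bond, s.rule_id))


def unique_bonds(sites: Iterable[CleavageSite]) -> List[Tuple[int, int]]:
    return sorted({s.bond for s in sites})


def cut_bonds(mol: Chem.Mol, bonds: Sequence[Tuple[int, int]]) -> List[Chem.Mol]:
    """Cut the given bonds, cap open valences with hydrogen, return fragments.

    Atom indices are preserved (no atoms are removed), so fragment atom maps
    refer back to parent numbering via ``GetMolFrags`` on the returned parent
    copy; see :func:`cut_components`.
    """
    return [m for m, _ in cut_components(mol, bonds)]


def cut_components(mol, bonds):
    """As :func:`cut_bonds` but yields (fragment, parent-atom-index tuple)."""
    rw = Chem.RWMol(mol)
    # an atom may lose several bonds at once; tally all hydrogen caps first
    added: dict = {}
    for a1, a2 in bonds:
        b = rw.GetBondBetweenAtoms(a1, a2)
        if b is None:
            raise ValueError(f"no bond between atoms {a1}-{a2}")
        order = int(b.GetBondTypeAsDouble())
        added[a1] = added.get(a1, 0) + order
        added[a2] = added.get(a2, 0) + order
    for idx, extra in added.items():
        atom = rw.GetAtomWithIdx(idx)
        atom.SetNumExplicitHs(mol.GetAtomWithIdx(idx).GetTotalNumHs() + extra)
        atom.SetNoImplicit(True)
    for a1, a2 in bonds:
        rw.RemoveBond(a1, a2)
    cut = rw.GetMol()
    Chem.SanitizeMol(cut)
    atom_groups = Chem.GetMolFrags(cut)
    mols = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    # round-trip through SMILES to shed the explicit-H bookkeeping flags
    out = []
    for m, atoms in zip(mols, atom_groups):
        norm = Chem.MolFromSmiles(Chem.MolToSmiles(m))
        out.append((norm if norm is not None else m, atoms))
    return out


def _frag_record(smiles: str, parent_id: str, role: str, idx: int) -> MoleculeRecord:
    return MoleculeRecord(
        id=f"{parent_id}_{role}{idx:03d}", smiles_in=smiles, canonical=smiles,
        role=role, parent_ids={parent_id}, source="fragmentation",
    )


def fragment_extensive(record: MoleculeRecord, sites: Optional[List[CleavageSite]] = None):
    """Leaf fragments: cut every cleavage site simultaneously.

    Returns a list of EXT records (unique canonical SMILES, sorted). Empty when
    the molecule has no sites.
    """
    mol = record.mol()
    if sites is None:
        sites = detect_sites(mol)
    bonds = unique_bonds(sites)
    if not bonds:
        return []
    smis = set()
    for frag in cut_bonds(mol, bonds):
        try:
            smis.add(Chem.MolToSmiles(frag))
        except Exception:  # pragma: no cover - capping valence failure
            logger.warning("%s: dropped uncappable fragment", record.id)
    return [_frag_record(s, record.id, "EXT", i) for i, s in enumerate(sorted(smis))]


def build_block_graph(mol: Chem.Mol, sites: List[CleavageSite]) -> BlockGraph:
    """Partition heavy atoms into leaf blocks and wire them by cleavage site."""
    bonds = unique_bonds(sites)
    rw = Chem.RWMol(mol)
    for a1, a2 in bonds:
        rw.RemoveBond(a1, a2)
    groups = Chem.GetMolFrags(rw.GetMol(), sanitizeFrags=False)
    atom2block = {}
    for bi, grp in enumerate(groups):
        for a in grp:
            atom2block[a] = bi
    edges = [(atom2block[a1], atom2block[a2], (a1, a2)) for a1, a2 in bonds]
    return BlockGraph(blocks=list(groups), edges=edges)


def _connected_subsets(g: nx.Graph, max_count: int):
    """Yield connected node subsets with >=2 nodes, excluding the full set.

    Breadth-first growth over frozensets; a subset is reached by adding one
    adjacent node to a smaller connected subset, so every connected subset is
    produced exactly once. Stops (flagging truncation) once ``max_count``
    multi-node subsets have been emitted.
    """
    all_nodes = frozenset(g.nodes)
    seen = {frozenset([v]) for v in g.nodes}
    frontier = sorted(seen, key=lambda s: min(s))
    emitted = 0
    truncated = False
    while frontier and not truncated:
        nxt = []
        for sub in frontier:
            nbrs = set()
            for v in sub:
                nbrs.update(g[v])
            for u in sorted(nbrs - sub):
                grown = sub | {u}
                if grown in seen:
                    continue
                seen.add(grown)
                nxt.append(grown)
                if grown != all_nodes:
                    if emitted >= max_count:
                        truncated = True
                        break
                    emitted += 1
                    yield grown, False
            if truncated:
                break
        frontier = nxt
    if truncated:
        yield frozenset(), True


def fragment_non_extensive(
    record: MoleculeRecord,
    sites: Optional[List[CleavageSite]] = None,
    max_fragments: int = 10_000,
):
    """Intermediate fragments: every connected multi-block piece except the parent.

    Returns ``(records, truncated)``; ``truncated`` is True when enumeration
    was stopped at ``max_fragments`` subsets (never silently).
    """
    mol = record.mol()
    if sites is None:
        sites = detect_sites(mol)
    bonds = unique_bonds(sites)
    if not bonds:
        return [], False
    bg = build_block_graph(mol, sites)
    g = bg.graph()
    truncated = False
    smis = set()
    for subset, trunc_flag in _connected_subsets(g, max_fragments):
        if trunc_flag:
            truncated = True
            break
        cut = [
            data["bond"]
            for u, v, data in g.edges(data=True)
            if (u in subset) != (v in subset)
        ]
        anchor = min(min(bg.blocks[b]) for b in subset)
        for frag, atoms in cut_components(mol, cut):
            if anchor in atoms:
                smis.add(Chem.MolToSmiles(frag))
                break
    if truncated:
        logger.warning("%s: non-extensive enumeration truncated at %d", record.id, max_fragments)
    recs = [_frag_record(s, record.id, "NON", i) for i, s in enumerate(sorted(smis))]
    return recs, truncated


def bruteforce_fragments(mol: Chem.Mol, bonds: Optional[Sequence[Tuple[int, int]]] = None):
    """Reference oracle: canonical SMILES of every fragment obtainable by
    cutting any nonempty bond subset, minus the intact parent.

    Exponential in the number of sites — use on small cases only (fixture
    ground truths, tests).
    """
    if bonds is None:
        bonds = unique_bonds(detect_sites(mol))
    bonds = list(bonds)
    if len(bonds) > 16:
        raise ValueError("brute force limited to 16 sites")
    parent_smi = Chem.MolToSmiles(mol)
    out = set()
    for mask in range(1, 1 << len(bonds)):
        chosen = [b for i, b in enumerate(bonds) if mask >> i & 1]
        for frag in cut_bonds(mol, chosen):
            out.add(Chem.MolToSmiles(frag))
    out.discard(parent_smi)
    return out


def fragment_molecule(
    record: MoleculeRecord, mode: str = "both", max_fragments: int = 10_000
) -> FragmentationResult:
    """Fragment one molecule in the requested mode."""
    sites = detect_sites(record)
    res = FragmentationResult(parent_id=record.id, sites=sites)
    if not sites:
        res.undeconstructable = True
        return res
    if mode in ("extensive", "both"):
        res.extensive = fragment_extensive(record, sites)
    if mode in ("non_extensive", "both"):
        res.non_extensive, res.truncated = fragment_non_extensive(
            record, sites, max_fragments
        )
    return res


def fragment_library(
    lib: Library,
    mode: str = "both",
    max_fragments: int = 10_000,
    min_heavy_atoms: int = 1,
):
    """Fragment every library member; dedup fragments globally.

    Returns ``(fragment Library, list of FragmentationResult)``. Duplicate
    fragments across parents are merged with parent ids unioned (first
    occurrence wins); fragment ids are renumbered ``EXT_00001``/``NON_00001``
    in encounter order. Per-molecule failures are logged and skipped.
    """
    if mode not in ("extensive", "non_extensive", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    results = []
    pooled: List[MoleculeRecord] = []
    for rec in lib:
        try:
            res = fragment_molecule(rec, mode=mode, max_fragments=max_fragments)
        except Exception as exc:
            logger.warning("%s: fragmentation failed (%s), skipped", rec.id, exc)
            continue
        results.append(res)
        if min_heavy_atoms > 1:
            res.extensive = _size_filter(res.extensive, min_heavy_atoms)
            res.non_extensive = _size_filter(res.non_extensive, min_heavy_atoms)
        pooled.extend(res.extensive)
        pooled.extend(res.non_extensive)
    # global dedup within each role; EXT and NON stay independent entities
    out_records: List[MoleculeRecord] = []
    for role, prefix in (("EXT", "EXT"), ("NON", "NON")):
        sub = Library(records=[r for r in pooled if r.role == role], name=role)
        merged, _ = dedup(sub)
        for i, rec in enumerate(merged, start=1):
            rec.id = f"{prefix}_{i:05d}"
            out_records.append(rec)
    frag_lib = Library(records=out_records, name=f"{lib.name}_fragments")
    return frag_lib, results


def _size_filter(records, min_heavy):
    return [r for r in records if r.mol().GetNumHeavyAtoms() >= min_heavy]
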