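"""3D pharmacophore models: feature perception, conformers, matching, scoring.

A model is a set of typed feature spheres (center + tolerance radius, one of
HBA/HBD/HY/AR/PI/NI) plus optional exclusion volumes marking receptor-occupied
space. A conformer matches when an injective, kind-compatible assignment of at
least ``min_features`` model features onto perceived ligand feature points
exists such that, after least-squares rigid superposition of the assigned
points onto the model centers, every assigned point lies inside its tolerance
sphere and no ligand heavy atom falls inside an exclusion volume.

The fit score ranks accepted matches:

    FS = 10 * (sum of matched feature weights) + max(0, 9 - 3 * RMSD)

so the matched-feature term dominates and the RMSD term breaks ties within a
match size — the two ingredients any feature-count + deviation score combines.
Candidate assignments are pruned on pairwise inter-feature distances: a pair
of model features (i, j) can map onto ligand points (p, q) only when
``|d_model(i,j) - d_ligand(p,q)| <= tol_i + tol_j``.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

SCHEMA = "npvs-phar/1"
FEATURE_KINDS = ("HBA", "HBD", "HY", "AR", "PI", "NI")

# --- feature perception SMARTS --------------------------------------------
# HBD: any N/O bearing a hydrogen.
_HBD = Chem.MolFromSmarts("[N,O;!H0]")
# HBA: oxygens (incl. anionic), pyridine-type aromatic N, and sp3/sp2 N with a
# lone pair — excluding amide/sulfonamide N and protonated N.
_HBA = [
    Chem.MolFromSmarts(s)
    for s in (
        "[O;+0]",
        "[O;-1]",
        "[n;+0;X2;H0]",
        "[N;+0;X3;v3;!$([N][C,S,P]=[O,S,N,P])]",
        "[N;+0;X2;H0;!$([N]=O)]",
    )
]
# PI: protonated/quaternary N, basic aliphatic amines, amidine/guanidine.
_PI = [
    Chem.MolFromSmarts(s)
    for s in (
        "[#7;+1]",
        "[N;X3;+0;!$([N][a]);!$([N][C,S,P]=[O,S,N,P]);!$([N]=*)]",
        "NC(=[NH])N",
    )
]
# NI: acids and their anions (carboxyl / sulfo / phospho), point = group centroid.
_NI = [
    Chem.MolFromSmarts(s)
    for s in ("C(=O)[O;H1,-1]", "S(=O)(=O)[O;H1,-1]", "P(=O)[O;H1,-1]")
]
_HALOGENS = {9, 17, 35, 53}
_POLAR = {7, 8, 15, 16}


@dataclass
class Feature:
    kind: str
    center: np.ndarray
    tolerance: float = 1.5
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class ExclusionVolume:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class PharmacophoreModel:
    """Feature spheres + exclusion volumes + matching policy."""

    name: str
    features: List[Feature]
    xvols: List[ExclusionVolume] = field(default_factory=list)
    min_features: Optional[int] = None  # None -> all features required

    def __post_init__(self):
        if len(self.features) < 3:
            raise ValueError("a pharmacophore model needs >= 3 features")
        if self.min_features is None:
            self.min_features = len(self.features)
        if not 1 <= self.min_features <= len(self.features):
            raise ValueError("min_features out of range")

    # -- JSON (schema "npvs-phar/1", units Angstrom) -----------------------
    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA,
            "name": self.name,
            "features": [
                {
                    "kind": f.kind,
                    "center": [round(float(c), 6) for c in f.center],
                    "tolerance": f.tolerance,
                    "weight": f.weight,
                }
                for f in self.features
            ],
            "xvols": [
                {"center": [round(float(c), 6) for c in x.center], "radius": x.radius}
                for x in self.xvols
            ],
            "min_features": self.min_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreModel":
        if d.get("schema", SCHEMA) != SCHEMA:
            raise ValueError(f"unsupported schema {d.get('schema')!r}")
        return cls(
            name=d["name"],
            features=[
                Feature(
                    kind=f["kind"], center=f["center"],
                    tolerance=f.get("tolerance", 1.5), weight=f.get("weight", 1.0),
                )
                for f in d["features"]
            ],
            xvols=[
                ExclusionVolume(center=x["center"], radius=x["radius"])
                for x in d.get("xvols", [])
            ],
            min_features=d.get("min_features"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "PharmacophoreModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ModelPair:
    """Two overlapping models of the same binding site (left / right)."""

    left: PharmacophoreModel
    right: PharmacophoreModel
    overlap: set = field(default_factory=set)

    @classmethod
    def build(cls, left, right, dist_thresh: float = 2.0) -> "ModelPair":
        overlap = {
            i
            for i, f in enumerate(left.features)
            for g in right.features
            if f.kind == g.kind
            and float(np.linalg.norm(f.center - g.center)) <= dist_thresh
        }
        if not overlap:
            raise ValueError("models do not overlap; not a valid pair")
        return cls(left=left, right=right, overlap=overlap)


@dataclass
class MatchResult:
    mapping: Tuple[Tuple[int, int], ...]  # (model feature idx, ligand point idx)
    rmsd: float
    n_matched: int
    fit_score: float
    conformer_index: int = -1


# ---------------------------------------------------------------------------
# feature perception


def perceive_feature_groups(mol: Chem.Mol) -> List[Tuple[str, Tuple[int, ...]]]:
    """Topological feature assignment: (kind, atom-index group) pairs.

    Coordinates are not needed; used both for point placement on conformers
    and as the kind-availability prefilter before conformer generation.
    """
    out: List[Tuple[str, Tuple[int, ...]]] = []
    for match in mol.GetSubstructMatches(_HBD):
        out.append(("HBD", (match[0],)))
    hba_atoms = set()
    for q in _HBA:
        for match in mol.GetSubstructMatches(q):
            hba_atoms.add(match[0])
    out.extend(("HBA", (a,)) for a in sorted(hba_atoms))
    # aromatic rings -> centroid
    for ring in Chem.GetSymmSSSR(mol):
        ring = tuple(ring)
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            out.append(("AR", ring))
    # hydrophobic groups: contiguous C/halogen atoms with no polar neighbours;
    # a group counts with >=3 heavy atoms, or >=4 atoms including hydrogens
    # (so methane/ethane-like caps still carry a hydrophobic point).
    eligible = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 6 or atom.GetAtomicNum() in _HALOGENS:
            if all(n.GetAtomicNum() not in _POLAR for n in atom.GetNeighbors()):
                eligible.add(atom.GetIdx())
    seen = set()
    for a in sorted(eligible):
        if a in seen:
            continue
        comp, stack = [], [a]
        seen.add(a)
        while stack:
            v = stack.pop()
            comp.append(v)
            for n in mol.GetAtomWithIdx(v).GetNeighbors():
                if n.GetIdx() in eligible and n.GetIdx() not in seen:
                    seen.add(n.GetIdx())
                    stack.append(n.GetIdx())
        n_h = sum(mol.GetAtomWithIdx(v).GetTotalNumHs() for v in comp)
        if len(comp) >= 3 or len(comp) + n_h >= 4:
            out.append(("HY", tuple(sorted(comp))))
    pi_atoms = set()
    for q in _PI:
        for match in mol.GetSubstructMatches(q):
            pi_atoms.add(tuple(sorted(match)))
    out.extend(("PI", grp) for grp in sorted(pi_atoms))
    for q in _NI:
        for match in mol.GetSubstructMatches(q):
            out.append(("NI", tuple(sorted(match))))
    return out


def perceive_features(mol: Chem.Mol, conf_id: int = -1) -> List[Tuple[str, np.ndarray]]:
    """Perceived (kind, 3D point) list for one conformer; points are group
    centroids (heavy atoms only)."""
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    return [
        (kind, pos[list(group)].mean(axis=0))
        for kind, group in perceive_feature_groups(mol)
    ]


def kind_counts(groups) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for kind, _ in groups:
        counts[kind] = counts.get(kind, 0) + 1
    return counts


def can_possibly_match(model: PharmacophoreModel, mol: Chem.Mol) -> bool:
    """Necessary condition from topology alone: enough ligand feature points of
    each kind to cover ``min_features`` model features (kind-wise matching)."""
    have = kind_counts(perceive_feature_groups(mol))
    need = kind_counts((f.kind, None) for f in model.features)
    attainable = sum(min(n, have.get(k, 0)) for k, n in need.items())
    return attainable >= model.min_features


# ---------------------------------------------------------------------------
# conformers


def generate_conformers(
    mol: Chem.Mol,
    n: int = 100,
    seed: int = 42,
    prune_rms: float = 0.5,
    optimize: bool = False,
) -> Chem.Mol:
    """Distance-geometry conformer ensemble (ETKDG), RMSD-pruned.

    Returns a copy of ``mol`` (hydrogens stripped) carrying up to ``n``
    conformers; 0 conformers signals an embedding failure. Deterministic for a
    given seed (single-threaded embedding).
    """
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.pruneRmsThresh = prune_rms
    params.numThreads = 1
    try:
        AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    except Exception:  # pragma: no cover - exotic embedding failures
        logger.warning("conformer embedding failed for %s", Chem.MolToSmiles(mol))
        molh.RemoveAllConformers()
    if optimize and molh.GetNumConformers():
        AllChem.MMFFOptimizeMoleculeConfs(molh, numThreads=1)
    return Chem.RemoveHs(molh)


# ---------------------------------------------------------------------------
# matching


def _kabsch(P: np.ndarray, Q: np.ndarray, w: np.ndarray):
    """Weighted least-squares rigid transform (R, t) minimizing ||R P + t - Q||."""
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    H = (P - pc).T @ (w[:, None] * (Q - qc))
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


def _assignments(model_idx, candidates, dm_model, dm_lig, tols):
    """Backtracking enumeration of injective, distance-consistent assignments."""
    order = sorted(model_idx, key=lambda i: len(candidates[i]))
    n = len(order)
    assign: List[int] = []
    used: set = set()

    def rec(k):
        if k == n:
            yield dict(zip(order, assign))
            return
        i = order[k]
        for j in candidates[i]:
            if j in used:
                continue
            ok = True
            for k2 in range(k):
                i2 = order[k2]
                if abs(dm_model[i, i2] - dm_lig[j, assign[k2]]) > tols[i] + tols[i2]:
                    ok = False
                    break
            if ok:
                assign.append(j)
                used.add(j)
                yield from rec(k + 1)
                assign.pop()
                used.discard(j)

    yield from rec(0)


def match(
    model: PharmacophoreModel,
    mol: Chem.Mol,
    conf_id: int = -1,
    points: Optional[Sequence[Tuple[str, np.ndarray]]] = None,
) -> Optional[MatchResult]:
    """Best accepted match of ``model`` onto one conformer, or None.

    Search proceeds from the largest feature subset downward; since every unit
    of matched weight is worth 10 fit-score points and the RMSD bonus at most
    9, the search stops as soon as no smaller subset can beat the incumbent.
    Ties on fit score are broken by lower RMSD, then lexicographic mapping.
    """
    if points is None:
        points = perceive_features(mol, conf_id)
    if not points:
        return None
    pos = mol.GetConformer(conf_id).GetPositions()
    centers = np.array([f.center for f in model.features])
    tols = np.array([f.tolerance for f in model.features])
    weights = np.array([f.weight for f in model.features])
    lig_pts = np.array([p for _, p in points])
    dm_model = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    dm_lig = np.linalg.norm(lig_pts[:, None] - lig_pts[None, :], axis=-1)
    candidates = {
        i: [j for j, (kind, _) in enumerate(points) if kind == f.kind]
        for i, f in enumerate(model.features)
    }
    nf = len(model.features)
    sorted_w = np.sort(weights)[::-1]
    best: Optional[MatchResult] = None
    best_key = None
    for size in range(nf, model.min_features - 1, -1):
        if best is not None and 10.0 * sorted_w[:size].sum() + 9.0 <= best.fit_score:
            break
        for subset in itertools.combinations(range(nf), size):
            if any(not candidates[i] for i in subset):
                continue
            for amap in _assignments(subset, candidates, dm_model, dm_lig, tols):
                res = _evaluate(amap, model, centers, tols, weights, lig_pts, pos)
                if res is None:
                    continue
                key = (-res.fit_score, res.rmsd, res.mapping)
                if best_key is None or key < best_key:
                    best, best_key = res, key
    return best


def _evaluate(amap, model, centers, tols, weights, lig_pts, heavy_pos):
    idx = sorted(amap)
    P = lig_pts[[amap[i] for i in idx]]
    Q = centers[idx]
    w = weights[idx]
    R, t = _kabsch(P, Q, w)
    P_t = P @ R.T + t
    dev = np.linalg.norm(P_t - Q, axis=1)
    if np.any(dev > tols[idx] + 1e-9):
        return None
    if model.xvols:
        atoms_t = heavy_pos @ R.T + t
        for xv in model.xvols:
            if np.any(np.linalg.norm(atoms_t - xv.center, axis=1) < xv.radius):
                return None
    rmsd = float(np.sqrt((dev**2).mean()))
    fs = fit_score_value(float(w.sum()), rmsd)
    return MatchResult(
        mapping=tuple(sorted(amap.items())),
        rmsd=rmsd,
        n_matched=len(idx),
        fit_score=fs,
    )


def fit_score_value(matched_weight: float, rmsd: float) -> float:
    """FS = 10 * matched weight + max(0, 9 - 3 * RMSD)."""
    return 10.0 * matched_weight + max(0.0, 9.0 - 3.0 * rmsd)


def fit_score(result: MatchResult, model: PharmacophoreModel) -> float:
    """Recompute the fit score of an accepted match against its model."""
    w = sum(model.features[i].weight for i, _ in result.mapping)
    return fit_score_value(w, result.rmsd)


def match_ensemble(
    model: PharmacophoreModel, mol: Chem.Mol, mode: str = "first_match"
) -> Optional[MatchResult]:
    """Match every conformer of ``mol``; first accepted or best-scoring one."""
    if mode not in ("first_match", "best_match"):
        raise ValueError(f"unknown mode {mode!r}")
    groups = perceive_feature_groups(mol)
    best: Optional[MatchResult] = None
    for conf in mol.GetConformers():
        cid = conf.GetId()
        pos = conf.GetPositions()
        points = [(kind, pos[list(grp)].mean(axis=0)) for kind, grp in groups]
        res = match(model, mol, conf_id=cid, points=points)
        if res is None:
            continue
        res.conformer_index = cid
        if mode == "first_match":
            return res
        if best is None or (res.fit_score, -res.rmsd) > (best.fit_score, -best.rmsd):
            best = res
    return best


def derive_model_from_reference(
    mol: Chem.Mol,
    conf_id: int = -1,
    kinds_filter: Optional[Sequence[str]] = None,
    tolerance_default: float = 1.5,
    name: str = "derived",
) -> PharmacophoreModel:
    """Single-reference model: one feature sphere per perceived ligand point.

    A deliberately simple stand-in for interactive model building — no feature
    selection beyond an optional kind filter, uniform tolerances, no exclusion
    volumes.
    """
    pts = perceive_features(mol, conf_id)
    if kinds_filter is not None:
        kinds = set(kinds_filter)
        pts = [(k, p) for k, p in pts if k in kinds]
    if len(pts) < 3:
        raise ValueError(f"model too small: only {len(pts)} perceivable features")
    feats = [Feature(kind=k, center=p, tolerance=tolerance_default) for k, p in pts]
    return PharmacophoreModel(name=name, features=feats)
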