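"""Virtual screening over libraries and ROC/AUC model validation.

A molecule is retrieved when at least one conformer of its ensemble satisfies
the pharmacophore model ("first-match" stops at that conformer; "best-match"
keeps the best-scoring one — acceptance is identical, only the reported score
differs). Validation ranks actives and decoys by fit score (unmatched
compounds score -inf, below every matched one) and reports the ROC AUC over
the full ranking and over early windows: the AUC at top fraction f is the
standard average-rank AUC computed over the top ceil(f*N) ranked compounds,
i.e. the window-normalized partial AUC, which is bounded in [0, 1] and equals
the full AUC at f = 1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .chem_io import Library
from .pharmacophore import (
    ModelPair,
    PharmacophoreModel,
    can_possibly_match,
    generate_conformers,
    match_ensemble,
)

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 1.00)
UNMATCHED = float("-inf")


@dataclass
class Hit:
    mol_id: str
    role: str
    model_name: str
    conformer_index: int
    n_matched: int
    rmsd: float
    fit_score: float


@dataclass
class ScreenReport:
    """Hits plus per-library screening bookkeeping."""

    hits: List[Hit]
    n_screened: int
    n_unmatched: int
    n_embed_failures: int


@dataclass
class RocReport:
    fractions: Tuple[float, ...]
    auc_at: Dict[float, float]
    tpr: float
    n_actives: int
    n_decoys: int

    def to_dict(self) -> dict:
        return {
            "fractions": list(self.fractions),
            "auc_at": {f"{f:g}": self.auc_at[f] for f in self.fractions},
            "tpr": self.tpr,
            "n_actives": self.n_actives,
            "n_decoys": self.n_decoys,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def screen(
    model: PharmacophoreModel,
    lib: Library,
    n_conformers: int = 100,
    mode: str = "first_match",
    seed: int = 42,
    prune_rms: float = 0.5,
) -> ScreenReport:
    """Screen a (deduplicated) library against one model.

    Molecules that cannot possibly satisfy ``min_features`` on topological
    feature-kind grounds are reported unmatched without conformer generation;
    embedding failures are logged and counted as screened-but-unmatched.
    """
    hits: List[Hit] = []
    n_unmatched = 0
    n_embed_fail = 0
    for rec in lib:
        mol = rec.mol()
        if not can_possibly_match(model, mol):
            n_unmatched += 1
            continue
        ens = generate_conformers(mol, n=n_conformers, seed=seed, prune_rms=prune_rms)
        if ens.GetNumConformers() == 0:
            logger.warning("%s: embedding failed, unscreened", rec.id)
            n_embed_fail += 1
            n_unmatched += 1
            continue
        res = match_ensemble(model, ens, mode=mode)
        if res is None:
            n_unmatched += 1
            continue
        hits.append(
            Hit(
                mol_id=rec.id,
                role=rec.role,
                model_name=model.name,
                conformer_index=res.conformer_index,
                n_matched=res.n_matched,
                rmsd=res.rmsd,
                fit_score=res.fit_score,
            )
        )
    return ScreenReport(
        hits=hits,
        n_screened=len(lib),
        n_unmatched=n_unmatched,
        n_embed_failures=n_embed_fail,
    )


def scores_for(lib: Library, hits: Sequence[Hit]) -> List[float]:
    """Per-record fit scores in library order; unmatched records get -inf."""
    by_id = {h.mol_id: h.fit_score for h in hits}
    return [by_id.get(rec.id, UNMATCHED) for rec in lib]


def _window_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Average-rank (Mann-Whitney) AUC; ties share average ranks.

    Equivalent to the trapezoid area under the ROC curve with tied scores
    traversed diagonally.
    """
    a = int(labels.sum())
    d = len(labels) - a
    if a == 0:
        return 0.0
    if d == 0:
        return 1.0
    ranks = rankdata(scores)  # ascending; -inf ranks lowest
    return float((ranks[labels == 1].sum() - a * (a + 1) / 2) / (a * d))


def roc(
    scores_actives: Sequence[float],
    scores_decoys: Sequence[float],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> RocReport:
    """ROC validation of a ranked actives/decoys screen.

    ``auc_at[f]`` is the AUC over the top ceil(f*N) compounds of the pooled
    ranking (descending score; boundary ties resolved by input order, actives
    listed first). ``tpr`` is the fraction of actives retrieved at all
    (score > -inf). Raises on an empty class.
    """
    sa = np.asarray(list(scores_actives), dtype=float)
    sd = np.asarray(list(scores_decoys), dtype=float)
    if sa.size == 0 or sd.size == 0:
        raise ValueError("degenerate validation set: one class is empty")
    fractions = tuple(sorted(set(float(f) for f in fractions) | {1.0}))
    scores = np.concatenate([sa, sd])
    labels = np.concatenate([np.ones(sa.size, dtype=int), np.zeros(sd.size, dtype=int)])
    order = np.argsort(-scores, kind="stable")
    n = scores.size
    auc_at = {}
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
        k = math.ceil(f * n)
        top = order[:k]
        auc_at[f] = _window_auc(labels[top], scores[top])
    tpr = float(np.mean(sa > UNMATCHED))
    return RocReport(
        fractions=fractions,
        auc_at=auc_at,
        tpr=tpr,
        n_actives=int(sa.size),
        n_decoys=int(sd.size),
    )


def validate(
    model: PharmacophoreModel,
    actives: Library,
    decoys: Library,
    n_conformers: int = 100,
    seed: int = 42,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> Tuple[RocReport, ScreenReport, ScreenReport]:
    """Screen actives and decoys, then rank and report ROC/AUC."""
    rep_a = screen(model, actives, n_conformers=n_conformers, seed=seed)
    rep_d = screen(model, decoys, n_conformers=n_conformers, seed=seed)
    report = roc(
        scores_for(actives, rep_a.hits),
        scores_for(decoys, rep_d.hits),
        fractions=fractions,
    )
    return report, rep_a, rep_d


def screen_pair(
    pair: ModelPair,
    lib: Library,
    n_conformers: int = 100,
    mode: str = "first_match",
    seed: int = 42,
):
    """Screen against both models of an overlapping pair.

    Returns ``(left hits, right hits, union hits)``; the union is deduplicated
    on molecule id, keeping the higher-scoring hit (left wins ties).
    """
    left = screen(pair.left, lib, n_conformers=n_conformers, mode=mode, seed=seed)
    right = screen(pair.right, lib, n_conformers=n_conformers, mode=mode, seed=seed)
    union: Dict[str, Hit] = {}
    for h in left.hits + right.hits:
        prev = union.get(h.mol_id)
        if prev is None or h.fit_score > prev.fit_score:
            union[h.mol_id] = h
    union_hits = [union[k] for k in sorted(union)]
    return left.hits, right.hits, union_hits


def tally_by_role(hits: Sequence[Hit]) -> Dict[str, int]:
    """Hit counts per role (NP / EXT / NON / ...), mirroring a left-right-union
    accounting table."""
    out: Dict[str, int] = {}
    for h in hits:
        out[h.role] = out.get(h.role, 0) + 1
    return out


def hits_to_frame(hits: Sequence[Hit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mol_id": h.mol_id,
                "role": h.role,
                "model": h.model_name,
                "conformer_index": h.conformer_index,
                "n_matched": h.n_matched,
                "rmsd": round(h.rmsd, 6),
                "fit_score": round(h.fit_score, 6),
            }
            for h in hits
        ],
        columns=[
            "mol_id", "role", "model", "conformer_index", "n_matched", "rmsd", "fit_score",
        ],
    )
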