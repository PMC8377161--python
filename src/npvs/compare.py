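"""Comparative statistics between parent, leaf, and intermediate hit populations.

Hits are grouped into families by shared parent molecule; only families in
which both compared populations are actually hit enter a denominator. Both
comparisons use strict ">" — ties are not wins.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .chem_io import Library
from .molprops import profile_library
from .screen import Hit


def _family_scores(hits: Sequence[Hit], provenance: Mapping[str, Set[str]]):
    """parent id -> role -> list of fit scores (parents map to themselves)."""
    fam: Dict[str, Dict[str, list]] = {}
    for h in hits:
        if h.role == "NP":
            parents = {h.mol_id}
        else:
            parents = provenance.get(h.mol_id, set())
        for p in parents:
            fam.setdefault(p, {}).setdefault(h.role, []).append(h.fit_score)
    return fam


def compare_ext_vs_non(hits: Sequence[Hit], provenance: Mapping[str, Set[str]]) -> float:
    """Fraction of families (parents with both EXT and NON hits) in which the
    mean fit score of the intermediates beats the mean of the leaves."""
    fam = _family_scores(hits, provenance)
    wins = total = 0
    for scores in fam.values():
        if "EXT" in scores and "NON" in scores:
            total += 1
            if np.mean(scores["NON"]) > np.mean(scores["EXT"]):
                wins += 1
    if total == 0:
        raise ValueError("nothing to compare: no family has both EXT and NON hits")
    return wins / total


def compare_non_vs_parent(hits: Sequence[Hit], provenance: Mapping[str, Set[str]]) -> float:
    """Fraction of families where the parent itself is a hit and at least one
    intermediate fragment out-scores it (existential, strict)."""
    fam = _family_scores(hits, provenance)
    wins = total = 0
    for scores in fam.values():
        if "NP" in scores and "NON" in scores:
            total += 1
            parent_fs = max(scores["NP"])
            if any(s > parent_fs for s in scores["NON"]):
                wins += 1
    if total == 0:
        raise ValueError("nothing to compare: no family has both NP and NON hits")
    return wins / total


def comparison_report(hits: Sequence[Hit], provenance: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Per-family table behind the two headline fractions."""
    fam = _family_scores(hits, provenance)
    rows = []
    for parent in sorted(fam):
        scores = fam[parent]
        mean_ext = float(np.mean(scores["EXT"])) if "EXT" in scores else None
        mean_non = float(np.mean(scores["NON"])) if "NON" in scores else None
        fs_parent = max(scores["NP"]) if "NP" in scores else None
        non_beats_ext = (
            mean_non > mean_ext if mean_ext is not None and mean_non is not None else None
        )
        any_non_beats_parent = (
            any(s > fs_parent for s in scores["NON"])
            if fs_parent is not None and "NON" in scores
            else None
        )
        rows.append(
            {
                "parent_id": parent,
                "mean_fs_ext": mean_ext,
                "mean_fs_non": mean_non,
                "fs_parent": fs_parent,
                "non_beats_ext": non_beats_ext,
                "any_non_beats_parent": any_non_beats_parent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "parent_id", "mean_fs_ext", "mean_fs_non", "fs_parent",
            "non_beats_ext", "any_non_beats_parent",
        ],
    )


def diversity_report(before: Library, after: Library) -> pd.DataFrame:
    """Scaffold counts and property summaries per role, before/after screening.

    One row per (role, stage) with the record count, distinct Murcko skeleton
    count, and five-number summaries of MW, logP and complexity.
    """
    rows = []
    for stage, lib in (("before", before), ("after", after)):
        df = profile_library(lib)
        roles = sorted(df["role"].unique()) if len(df) else []
        for role in roles:
            sub = df[df["role"] == role]
            row = {"role": role, "stage": stage, "n": len(sub)}
            row["n_skeletons"] = sub.loc[sub["murcko_skeleton"] != "", "murcko_skeleton"].nunique()
            for col in ("mw", "logp", "complexity_bertz"):
                q = sub[col].quantile([0.0, 0.25, 0.5, 0.75, 1.0])
                for frac, tag in zip((0.0, 0.25, 0.5, 0.75, 1.0), ("min", "q1", "median", "q3", "max")):
                    row[f"{col}_{tag}"] = round(float(q.loc[frac]), 4)
            rows.append(row)
    cols = ["role", "stage", "n", "n_skeletons"] + [
        f"{c}_{t}"
        for c in ("mw", "logp", "complexity_bertz")
        for t in ("min", "q1", "median", "q3", "max")
    ]
    return pd.DataFrame(rows, columns=cols)


def subset_library(lib: Library, ids: Iterable[str]) -> Library:
    """Library restricted to the given record ids (order preserved)."""
    keep = set(ids)
    return Library(records=[r for r in lib if r.id in keep], name=f"{lib.name}_hits")
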