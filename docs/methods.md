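# Methods

## Retrosynthetic fragmentation

Cleavage sites are acyclic bonds matching one of eleven SMARTS-encoded rule
environments (amide, ester, secondary/tertiary amine, urea, ether, olefin,
quaternary N–C, aromatic N–aliphatic C, lactam N–aliphatic C, biaryl,
sulphonamide; see `recap.RECAP_SMARTS`). Guards follow the usual conventions:
ring bonds are never cut; nitrogens and oxygens adjacent to carbonyl or
sulfonyl groups belong to the dedicated amide/ester/urea/sulphonamide/lactam
environments rather than the amine/ether ones; bonds to single-heavy-atom
terminal caps (D1 atoms) are not cleaved, so methyls and hydroxyls are not
shaved off as one-atom fragments. A bond may satisfy several rules; it is
recorded once per (bond, rule) pair, and fragmentation operates on the unique
bond set.

Two deliberate conventions, where implementations in the wild differ:

- **Ester direction.** We cut the carbonyl-C–O bond (acid side keeps the
  carbonyl, alcohol side keeps the bridging O). RDKit's reaction-based
  decomposition keeps the bridging O with the acid. Either is defensible; the
  choice is applied consistently and the RDKit cross-check in the test suite
  therefore uses amide chemistry, where both agree.
- **Ether rule.** The classic reaction formulation deletes the ether oxygen,
  which has no bond-subset analogue. Here *both* acyclic C–O bonds of a
  dialkyl/aryl ether are sites; cutting both leaves a lone water block.

**Capping.** Severed bonds are hydrogen-capped: each endpoint gains as many
hydrogens as the cut bond's order (two for an olefin). Fragments are therefore
ordinary molecules; for single-bond cuts the leaf masses obey
Σ MW(leaf) = MW(parent) + 2·k·MW(H) exactly.

**Enumeration.** Cutting all sites partitions the heavy atoms into leaf
blocks; sites become edges of a block graph. Non-extensive fragments
correspond one-to-one to connected node subsets with ≥ 2 blocks, excluding
the full set. Subsets are grown breadth-first (each reached exactly once by
adding an adjacent node), realized by cutting the subset's boundary bonds,
and deduplicated on canonical SMILES. Enumeration stops, with an explicit
`truncated` flag, at `max_fragments` (default 10,000) subsets per molecule —
dense block graphs have exponentially many connected subgraphs. A brute-force
path over all 2^k − 1 bond subsets (`recap.bruteforce_fragments`) serves as
the defining oracle in tests and for fixture ground truths; the enumerator is
never validated against itself.

No minimum fragment size is imposed by default (`min_heavy_atoms=1`).

## Descriptors

MW is the average-isotope weight of the H-capped form; logP is the Crippen
atomic-contribution estimate; complexity is Bertz's graph index, reported as
`complexity_bertz` (proprietary complexity scores are not reproducible;
only relative orderings are meaningful, and absolute agreement with other
estimators is not attempted — the same caveat applies to logP). H-bond counts
use the fragment Rule-of-Three convention (donors = N–H/O–H hydrogens,
acceptors = N + O atoms); Ro3 violations are strict exceedances of
MW 300 / logP 3 / HBD 3 / HBA 3 / rotatable bonds 3.

Murcko skeletons retain ring systems and linkers, drop substituents, replace
heteroatoms by carbon and set all bonds single. Because exocyclic
double-bonded atoms (e.g. amide oxygens) survive the first scaffold pass but
become removable side chains once bonds are single, the scaffold/generic
steps are iterated to a fixed point, making the operation idempotent.

## Pharmacophore model and matching

A model is ≥ 3 typed feature spheres (kind, center, tolerance radius,
weight) plus optional exclusion volumes; serialized as JSON (schema
`npvs-phar/1`, units Å). Feature perception is SMARTS-driven (documented in
`pharmacophore.py`): donors at N/O bearing H; acceptors at oxygens,
pyridine-type N and lone-pair sp3/sp2 N (amide and sulfonamide N excluded);
aromatic points at all-aromatic ring centroids; hydrophobic points at
centroids of contiguous carbon/halogen groups with no polar neighbours
(qualifying with ≥ 3 heavy atoms, or ≥ 4 atoms counting hydrogens, so
methane-like caps still register); positive/negative ionizable points at
basic amine / acid group centroids. Direction vectors are not modelled —
tolerance spheres and inter-feature distances only.

Matching enumerates injective kind-compatible assignments, pruning a
candidate pair of model features (i, j) unless
|d_model(i,j) − d_ligand(p,q)| ≤ tol_i + tol_j. Surviving assignments are
rigid-superposed (weighted Kabsch) onto the model centers; a match is
accepted iff every assigned point lies within its tolerance sphere and no
heavy atom falls inside an exclusion volume. The fit score
FS = 10·Σw_matched + max(0, 9 − 3·RMSD) makes one matched unit weight worth
more than any RMSD improvement, so the search runs from the largest feature
subset downward and stops when no smaller subset can beat the incumbent;
ties break by lower RMSD, then lexicographic mapping. With one or two mapped
points the superposition is underdetermined; such matches are accepted as the
degenerate limit (RMSD 0) but only arise when `min_features` < 3.

Conformers come from ETKDG distance-geometry embedding, single-threaded with
a fixed seed (deterministic), RMSD-pruned at 0.5 Å, default ensemble size
100; force-field refinement is off by default. Screening applies a
topological prefilter first: if the ligand's perceivable feature kinds cannot
cover `min_features` model features even in the best case, the molecule is
reported unmatched without embedding. First-match mode stops at the first
accepted conformer; best-match keeps the highest fit score — acceptance is
identical in both modes.

`derive_model_from_reference` is a deliberately simple single-ligand model
builder (one sphere per perceived point, uniform tolerance, no exclusion
volumes); interactive feature editing and receptor-derived volumes are out of
scope.

## Validation statistics

Actives and decoys are pooled and ranked by descending fit score; unmatched
compounds score −∞ and rank below all matched ones. Full AUC is the
average-rank (Mann–Whitney) statistic, equivalent to the trapezoid ROC area
with tied scores traversed diagonally. The early "AUC at top f" is the same
statistic computed over the top ⌈f·N⌉ ranked compounds (window-normalized
partial AUC): bounded in [0, 1] and equal to the full AUC at f = 1. A window
containing a single class is scored 1.0 (all retrieved are actives) or 0.0
(none are); boundary ties are resolved by input order. TPR is the fraction of
actives with at least one matching conformer. Defaults follow fragment-
screening practice: fractions 1, 5, 10, 100 % and 30 decoys per active.

## Population comparisons

Hits are grouped into families by shared parent. The leaf-vs-intermediate
fraction counts families with both populations hit where the intermediate
mean fit score strictly exceeds the leaf mean; the intermediate-vs-parent
fraction counts parent-hit families where at least one intermediate strictly
out-scores the parent. Ties are not wins; families with only one population
hit are excluded from denominators; families are pooled across the model pair
(per-model counting would be a trivial variant). Diversity reports give
per-role, before/after-screening record counts, distinct Murcko skeleton
counts and five-number summaries of MW/logP/complexity.

## Synthetic fixture world

The generator assembles molecules from ~20 cleavage-inert blocks (rings and
short chains with no internal cleavable bond) joined by cleavable linkages,
so detected sites are exactly the planted bonds and fragment ground truths
can be brute-forced at build time. Defaults — 3–5 blocks per molecule, a
linkage mix dominated by amide/ester with ether/olefin/biaryl/sulphonamide
minorities, path topology — give molecules with 2–8 sites, the regime where
exhaustive oracles are cheap. What the fixtures do *not* emulate: real
natural-product ring fusion, stereochemical density, or linkage statistics;
a green oracle test establishes combinatorial correctness of the
enumeration, not chemical realism.

The screening fixture derives its model from a rigid 4-aminophenol reference
(2 HBD + 2 HBA + aromatic ring, all feature atoms ring-attached and hence
conformation-independent; tolerance 1.5 Å). Actives are para-donor/donor
benzenes with inert ring decorations, verified to self-match at build time;
decoys are substituted aromatics/alkanes carrying no H-bond donor, so a model
requiring donors rejects them on feature kinds alone. The 30:1 decoy ratio is
the stated world; with this construction separation is essentially perfect,
so the recovery test certifies the ranking/acceptance plumbing, not a hard
discrimination problem. The acceptance run uses 50 conformers per molecule
(rather than the screening default of 100) to stay within its time budget;
the rigid actives make the ensemble size non-limiting.

## Determinism

All randomness flows through explicit integer seeds (numpy `default_rng` for
sampling, RDKit embedding seeds for conformers); iteration orders are sorted;
reports contain no timestamps or paths. Two pipeline runs with the same seed
are byte-identical.
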