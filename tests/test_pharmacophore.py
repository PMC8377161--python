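"""Feature perception, conformers, matching geometry, and fit scoring."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from npvs import pharmacophore as ph


def kinds_of(smiles):
    return sorted(k for k, _ in ph.perceive_feature_groups(Chem.MolFromSmiles(smiles)))


def embedded(smiles, n=1, seed=7):
    mol = ph.generate_conformers(Chem.MolFromSmiles(smiles), n=n, seed=seed)
    assert mol.GetNumConformers() >= 1
    return mol


def rigid_copy(mol, conf_id=0, seed=0):
    """Copy of mol with one conformer under a random rigid motion."""
    rng = np.random.default_rng(seed)
    out = Chem.Mol(mol)
    conf = out.GetConformer(conf_id)
    R = Rotation.random(random_state=int(rng.integers(2**31 - 1))).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    pos = conf.GetPositions() @ R.T + t
    for i, p in enumerate(pos):
        conf.SetAtomPosition(i, p.tolist())
    return out


class TestPerception:
    def test_benzene_single_aromatic_point_at_centroid(self):
        mol = embedded("c1ccccc1")
        pts = [p for k, p in ph.perceive_features(mol, 0) if k == "AR"]
        assert len(pts) == 1
        centroid = mol.GetConformer(0).GetPositions().mean(axis=0)
        assert np.allclose(pts[0], centroid, atol=1e-6)

    def test_methanol_donor_and_acceptor_at_oxygen(self):
        assert kinds_of("CO") == ["HBA", "HBD"]

    def test_methane_hydrophobic_only(self):
        assert kinds_of("C") == ["HY"]

    @pytest.mark.parametrize(
        "smiles,kind",
        [
            ("CC(=O)[O-]", "NI"),  # carboxylate
            ("CCCC[NH3+]", "PI"),  # protonated amine
            ("c1ccncc1", "HBA"),  # pyridine N lone pair
        ],
    )
    def test_ionizable_and_acceptor_kinds(self, smiles, kind):
        assert kind in kinds_of(smiles)

    def test_amide_nitrogen_is_not_an_acceptor(self):
        groups = ph.perceive_feature_groups(Chem.MolFromSmiles("CC(=O)NC"))
        n_idx = 3
        assert ("HBA", (n_idx,)) not in groups


class TestConformers:
    def test_rigid_molecule_prunes_to_one(self):
        assert embedded("c1ccccc1", n=20).GetNumConformers() == 1

    def test_same_seed_identical_coordinates(self):
        a = embedded("CCCCO", n=10, seed=3)
        b = embedded("CCCCO", n=10, seed=3)
        assert a.GetNumConformers() == b.GetNumConformers()
        for i in range(a.GetNumConformers()):
            assert np.allclose(
                a.GetConformer(i).GetPositions(), b.GetConformer(i).GetPositions()
            )

    def test_flexible_chain_pruned_ensemble(self):
        mol = ph.generate_conformers(
            Chem.MolFromSmiles("NCC(=O)NCC(=O)NCC(=O)O"), n=30, seed=5, prune_rms=0.5
        )
        n = mol.GetNumConformers()
        assert 1 < n <= 30
        molh = Chem.AddHs(mol, addCoords=True)
        for i, j in itertools.combinations(range(n), 2):
            assert AllChem.GetConformerRMS(molh, i, j, prealigned=False) > 0.4


@pytest.fixture(scope="module")
def ref_and_model():
    ref = embedded("Nc1ccc(O)cc1")
    model = ph.derive_model_from_reference(
        ref, conf_id=0, kinds_filter=("AR", "HBD", "HBA"), name="ref"
    )
    return ref, model


class TestMatch:
    def test_identity_geometry_zero_rmsd(self, ref_and_model):
        ref, model = ref_and_model
        res = ph.match(model, ref, conf_id=0)
        assert res is not None
        assert res.n_matched == len(model.features) == 5
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert res.fit_score == pytest.approx(10 * 5 + 9, abs=1e-6)

    def test_rigid_motion_invariance(self, ref_and_model):
        ref, model = ref_and_model
        base = ph.match(model, ref, conf_id=0)
        for seed in range(10):
            res = ph.match(model, rigid_copy(ref, seed=seed), conf_id=0)
            assert res is not None
            assert res.fit_score == pytest.approx(base.fit_score, abs=1e-6)
            assert res.rmsd == pytest.approx(base.rmsd, abs=1e-6)

    def test_exclusion_volume_clash_rejects(self, ref_and_model):
        ref, model = ref_and_model
        atom0 = ref.GetConformer(0).GetPositions()[0]
        clashing = ph.PharmacophoreModel(
            name="xv", features=model.features,
            xvols=[ph.ExclusionVolume(center=atom0, radius=1.0)],
        )
        assert ph.match(clashing, ref, conf_id=0) is None

    def test_far_exclusion_volume_harmless(self, ref_and_model):
        ref, model = ref_and_model
        far = ph.PharmacophoreModel(
            name="xv", features=model.features,
            xvols=[ph.ExclusionVolume(center=[100.0, 100.0, 100.0], radius=2.0)],
        )
        res = ph.match(far, ref, conf_id=0)
        assert res is not None and res.n_matched == 5

    def test_min_features_threshold_semantics(self, ref_and_model):
        ref, model = ref_and_model
        # 4-methoxyphenol offers only one donor: 4 of 5 features matchable
        lig = embedded("COc1ccc(O)cc1")
        assert ph.match(model, lig, conf_id=0) is None  # requires all 5
        relaxed = ph.PharmacophoreModel(
            name="m4", features=model.features, min_features=4
        )
        res = ph.match(relaxed, lig, conf_id=0)
        assert res is not None and res.n_matched == 4

    def test_tolerance_monotonicity(self, ref_and_model):
        ref, model = ref_and_model
        lig = embedded("Nc1cc(C)c(O)cc1")  # decorated analogue
        for scale in (1.0, 1.5, 2.0):
            bigger = ph.PharmacophoreModel(
                name="s",
                features=[
                    ph.Feature(kind=f.kind, center=f.center,
                               tolerance=f.tolerance * scale, weight=f.weight)
                    for f in model.features
                ],
            )
            res = ph.match(bigger, lig, conf_id=0)
            if scale == 1.0:
                matched_at_base = res is not None
            elif matched_at_base:
                assert res is not None  # enlarging spheres never loses a match


class TestFitScore:
    def test_declared_formula_values(self):
        assert ph.fit_score_value(3.0, 0.0) == pytest.approx(39.0)
        assert ph.fit_score_value(3.0, 3.0) == pytest.approx(30.0)
        # count dominance: 4 matched at poor rmsd beats 3 matched perfect
        assert ph.fit_score_value(4.0, 2.9) == pytest.approx(40.3)
        assert ph.fit_score_value(4.0, 2.9) > ph.fit_score_value(3.0, 0.0)

    def test_recompute_from_match(self, ref_and_model):
        ref, model = ref_and_model
        res = ph.match(model, ref, conf_id=0)
        assert ph.fit_score(res, model) == pytest.approx(res.fit_score)


def brute_force_best(model, mol, conf_id=0):
    """Exhaustive oracle over all injective kind-compatible mappings."""
    points = ph.perceive_features(mol, conf_id)
    pos = mol.GetConformer(conf_id).GetPositions()
    centers = np.array([f.center for f in model.features])
    tols = np.array([f.tolerance for f in model.features])
    weights = np.array([f.weight for f in model.features])
    lig = np.array([p for _, p in points])
    best = None
    nf = len(model.features)
    for size in range(model.min_features, nf + 1):
        for subset in itertools.combinations(range(nf), size):
            cands = [
                [j for j, (k, _) in enumerate(points) if k == model.features[i].kind]
                for i in subset
            ]
            for choice in itertools.product(*cands):
                if len(set(choice)) < size:
                    continue
                amap = dict(zip(subset, choice))
                res = ph._evaluate(amap, model, centers, tols, weights, lig, pos)
                if res is None:
                    continue
                if best is None or (res.fit_score, -res.rmsd) > (best.fit_score, -best.rmsd):
                    best = res
    return best


@pytest.mark.parametrize("lig_smiles", ["Nc1ccc(O)cc1", "Oc1ccc(O)cc1", "COc1ccc(N)cc1"])
def test_pruned_search_agrees_with_exhaustive_oracle(ref_and_model, lig_smiles):
    _, model = ref_and_model
    relaxed = ph.PharmacophoreModel(name="m3", features=model.features, min_features=3)
    lig = embedded(lig_smiles)
    fast = ph.match(relaxed, lig, conf_id=0)
    slow = brute_force_best(relaxed, lig, conf_id=0)
    if slow is None:
        assert fast is None
    else:
        assert fast is not None
        assert fast.fit_score == pytest.approx(slow.fit_score, abs=1e-9)
        assert fast.rmsd == pytest.approx(slow.rmsd, abs=1e-9)


class TestDeriveModel:
    def test_reference_with_five_points(self, ref_and_model):
        ref, model = ref_and_model
        assert len(model.features) == 5

    def test_too_few_features_is_error(self):
        with pytest.raises(ValueError, match="model too small"):
            ph.derive_model_from_reference(embedded("c1ccccc1"), conf_id=0,
                                           kinds_filter=("AR",))

    def test_json_round_trip(self, tmp_path, ref_and_model):
        _, model = ref_and_model
        path = tmp_path / "m.json"
        model.save(path)
        back = ph.PharmacophoreModel.load(path)
        assert back.name == model.name
        assert back.min_features == model.min_features
        assert len(back.features) == len(model.features)
        for f, g in zip(back.features, model.features):
            assert f.kind == g.kind and f.tolerance == g.tolerance
            assert np.allclose(f.center, g.center, atol=1e-6)

    def test_model_pair_requires_overlap(self, ref_and_model):
        _, model = ref_and_model
        shifted = ph.PharmacophoreModel(
            name="far",
            features=[
                ph.Feature(kind=f.kind, center=f.center + 50.0, tolerance=f.tolerance)
                for f in model.features
            ],
        )
        with pytest.raises(ValueError, match="overlap"):
            ph.ModelPair.build(model, shifted)
        pair = ph.ModelPair.build(model, model)
        assert pair.overlap
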