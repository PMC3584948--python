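import numpy as np
import pytest

from proqa.features import (
    BURIAL_THRESHOLD,
    FeatureConfig,
    ModelInputs,
    atom_contact_features,
    build_feature_vector,
    exposure_features,
    feature_names,
    global_features,
    ipp_feature,
    residue_contact_features,
    ss_agreement_features,
    surface_agreement_features,
)
from proqa.fixtures import make_native, make_sequence_inputs
from proqa.sequence_inputs import AA_ORDER, ExposurePrediction, SequenceProfile, SSPrediction
from proqa.structure_io import (
    N_ATOM_CLASSES,
    N_RESIDUE_GROUPS,
    Atom,
    ProteinModel,
    Residue,
    assign_residue_group,
)

from conftest import ca_model, ca_residue


# ---------- independent brute-force oracles ----------

def brute_atom_block(model, center_pos, cutoff=4.0, half=10):
    """O(n^2) pair scan over all atoms, plain python."""
    atoms = [(a, r.residue_index) for r in model.residues for a in r.atoms]
    counts = np.zeros((N_ATOM_CLASSES, N_ATOM_CLASSES))
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            (ai, ri), (aj, rj) = atoms[i], atoms[j]
            if abs(ri - rj) <= 1:
                continue
            if np.linalg.norm(ai.coords - aj.coords) > cutoff:
                continue
            if abs(ri - center_pos) > half and abs(rj - center_pos) > half:
                continue
            a, b = sorted((ai.atom_class - 1, aj.atom_class - 1))
            counts[a, b] += 1
    vec = np.array([counts[i, j] for i in range(13) for j in range(i, 13)])
    return vec / vec.sum() if vec.sum() else vec


def brute_residue_block(model, center_pos, cutoff=6.0, min_sep=5, half=10):
    counts = np.zeros((N_RESIDUE_GROUPS, N_RESIDUE_GROUPS))
    res = model.residues
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            if abs(res[i].residue_index - res[j].residue_index) <= min_sep:
                continue
            ai = [a for a in res[i].atoms if a.is_sidechain or a.name == "CA"]
            aj = [a for a in res[j].atoms if a.is_sidechain or a.name == "CA"]
            dmin = min(
                (np.linalg.norm(x.coords - y.coords) for x in ai for y in aj),
                default=np.inf,
            )
            if dmin > cutoff:
                continue
            if (abs(res[i].residue_index - center_pos) > half
                    and abs(res[j].residue_index - center_pos) > half):
                continue
            a, b = sorted((res[i].group - 1, res[j].group - 1))
            counts[a, b] += 1
    vec = np.array([counts[i, j] for i in range(6) for j in range(i, 6)])
    return vec / vec.sum() if vec.sum() else vec


def tri13_index(c1, c2):
    a, b = sorted((c1 - 1, c2 - 1))
    pairs = [(i, j) for i in range(13) for j in range(i, 13)]
    return pairs.index((a, b))


def tri6_index(g1, g2):
    a, b = sorted((g1 - 1, g2 - 1))
    pairs = [(i, j) for i in range(6) for j in range(i, 6)]
    return pairs.index((a, b))


def one_hot_profile(model):
    L = model.target_length
    freqs = np.zeros((L, 20))
    seq = ["A"] * L
    for r in model.residues:
        freqs[r.residue_index, AA_ORDER.index(r.aa)] = 1.0
        seq[r.residue_index] = r.aa
    for i in range(L):
        if freqs[i].sum() == 0:
            freqs[i, 0] = 1.0
    return SequenceProfile("".join(seq), freqs, np.zeros((L, 20)), np.zeros(L))


# ---------- atom contacts ----------

class TestAtomContacts:
    def test_beyond_cutoff_gives_zero_block(self):
        model = ca_model([("A", 0, (0, 0, 0)), ("A", 3, (4.5, 0, 0))])
        block = atom_contact_features(model, 0)
        assert np.all(block == 0)

    def test_single_pair_normalizes_to_one(self):
        # CA (class 2) and CB-like sidechain of class 5, 3.9 A apart, 3 apart in sequence
        r0 = Residue("A", 0, [Atom("CB", "C", 0, np.zeros(3), 5, True)])
        r3 = ca_residue("A", 3, (3.9, 0, 0))
        model = ProteinModel("m", [r0, r3])
        block = atom_contact_features(model, 0)
        assert block.sum() == pytest.approx(1.0)
        assert block[tri13_index(5, 2)] == pytest.approx(1.0)

    def test_adjacent_residue_contacts_excluded(self):
        model = ca_model([("A", 0, (0, 0, 0)), ("A", 1, (3.0, 0, 0))])
        assert np.all(atom_contact_features(model, 0) == 0)

    def test_matches_brute_force_on_fixture(self, two_domain_native):
        cfg = FeatureConfig()
        for center in (0, 17, 30, 59):
            fast = atom_contact_features(two_domain_native, center, cfg)
            slow = brute_atom_block(
                two_domain_native, two_domain_native.residues[center].residue_index
            )
            assert np.allclose(fast, slow, atol=1e-12)


# ---------- residue contacts ----------

class TestResidueContacts:
    def test_arg_glu_pair(self):
        entries = [("G", i, (0, 60.0 * (i + 1), 0)) for i in range(1, 8)]
        model = ca_model([("R", 0, (0, 0, 0))] + entries + [("E", 8, (5.0, 0, 0))])
        block = residue_contact_features(model, 0)
        assert block[tri6_index(1, 2)] == pytest.approx(1.0)
        assert block.sum() == pytest.approx(1.0)

    def test_separation_must_exceed_five(self):
        model = ca_model([("R", 0, (0, 0, 0)), ("E", 4, (5.0, 0, 0))])
        assert np.all(residue_contact_features(model, 0) == 0)
        model6 = ca_model([("R", 0, (0, 0, 0)), ("E", 6, (5.0, 0, 0))])
        assert residue_contact_features(model6, 0).sum() == pytest.approx(1.0)

    def test_profile_weighting_splits_mass(self):
        model = ca_model([("R", 0, (0, 0, 0)), ("A", 8, (5.0, 0, 0))],
                         target_length=9)
        prof = one_hot_profile(model)
        # position 8: 40% alanine (group 5), 60% serine (group 4)
        prof.freqs[8] = 0.0
        prof.freqs[8, AA_ORDER.index("A")] = 0.4
        prof.freqs[8, AA_ORDER.index("S")] = 0.6
        block = residue_contact_features(model, 0, profile=prof)
        assert block[tri6_index(1, 5)] == pytest.approx(0.4)
        assert block[tri6_index(1, 4)] == pytest.approx(0.6)

    def test_matches_brute_force_on_fixture(self, two_domain_native):
        for center in (0, 25, 59):
            fast = residue_contact_features(two_domain_native, center)
            slow = brute_residue_block(
                two_domain_native, two_domain_native.residues[center].residue_index
            )
            assert np.allclose(fast, slow, atol=1e-12)

    def test_profile_weighting_is_linear(self, helix_native):
        # features under a mixed profile equal the frequency-weighted
        # average of pure-residue features
        model = helix_native
        L = model.target_length
        rng = np.random.default_rng(0)
        mixed = one_hot_profile(model)
        w = rng.dirichlet(np.ones(20))
        pos = 12
        mixed.freqs[pos] = w
        got = residue_contact_features(model, 12, profile=mixed)
        acc = np.zeros_like(got)
        for k, aa in enumerate(AA_ORDER):
            pure = one_hot_profile(model)
            pure.freqs[pos] = 0.0
            pure.freqs[pos, k] = 1.0
            acc += w[k] * residue_contact_features(model, 12, profile=pure)
        assert np.allclose(got, acc, atol=1e-10)


# ---------- exposure ----------

class TestExposureFeatures:
    def test_single_residue_window(self):
        model = ca_model([("R", 0, (0, 0, 0))])
        block = exposure_features(model, 0, np.array([0.30]))
        block = block.reshape(6, 4)
        assert block[0, 1] == pytest.approx(1.0)  # group 1, bin 2
        assert block.sum() == pytest.approx(1.0)

    def test_boundary_goes_to_lower_bin(self):
        model = ca_model([("R", 0, (0, 0, 0))])
        block = exposure_features(model, 0, np.array([0.25])).reshape(6, 4)
        assert block[0, 0] == pytest.approx(1.0)

    def test_uniform_profile_equals_average_of_pure_blocks(self):
        model = ca_model([("R", 0, (0, 0, 0))], target_length=1)
        exposures = np.array([0.6])
        uni = one_hot_profile(model)
        uni.freqs[0] = 1.0 / 20
        got = exposure_features(model, 0, exposures, profile=uni)
        acc = np.zeros_like(got)
        for k in range(20):
            pure = one_hot_profile(model)
            pure.freqs[0] = 0.0
            pure.freqs[0, k] = 1.0
            acc += exposure_features(model, 0, exposures, profile=pure) / 20
        assert np.allclose(got, acc)


# ---------- agreement features ----------

def _uniform_ss(seq, cls):
    probs = np.full((len(seq), 3), 0.05)
    probs[:, "HEC".index(cls)] = 0.9
    return SSPrediction(seq, probs)


class TestSSAgreement:
    def test_perfect_agreement(self):
        seq = "A" * 11
        pred = _uniform_ss(seq, "H")
        positions = np.arange(11)
        central, frac, onehot = ss_agreement_features("H" * 11, pred, 5, positions)
        assert frac == pytest.approx(1.0)
        assert central.argmax() == 0
        assert onehot.reshape(5, 3)[:, 0].sum() == pytest.approx(5.0)

    def test_total_disagreement(self):
        seq = "A" * 11
        pred = _uniform_ss(seq, "E")
        _, frac, _ = ss_agreement_features("H" * 11, pred, 5, np.arange(11))
        assert frac == pytest.approx(0.0)

    def test_truncated_window_denominator(self):
        # model of 10 residues, center at position 2: window covers 0..9
        seq = "A" * 10
        assigned = "HHHHHCCCCC"
        pred = _uniform_ss(seq, "H")
        _, frac, _ = ss_agreement_features(assigned, pred, 2, np.arange(10))
        assert frac == pytest.approx(0.5)  # 5 H of 10 actual residues


class TestSurfaceAgreement:
    def test_all_buried_and_predicted_buried(self):
        seq = "A" * 9
        pred = ExposurePrediction(seq, np.zeros(9, bool))
        frac, _ = surface_agreement_features(np.full(9, 0.1), pred, 4, np.arange(9))
        assert frac == pytest.approx(1.0)

    def test_mean_area_window(self):
        seq = "A" * 9
        pred = ExposurePrediction(seq, np.zeros(9, bool))
        _, mean_area = surface_agreement_features(np.full(9, 0.5), pred, 4, np.arange(9))
        assert mean_area == pytest.approx(0.5)

    def test_matches_independent_loop(self):
        rng = np.random.default_rng(5)
        n = 30
        seq = "A" * n
        exposures = rng.uniform(0, 1, n)
        pred = ExposurePrediction(seq, rng.random(n) < 0.5)
        positions = np.arange(n)
        center = 13
        frac, mean_area = surface_agreement_features(exposures, pred, center, positions)
        lo, hi = max(0, center - 10), min(n, center + 11)
        expect_frac = np.mean([
            (exposures[i] >= BURIAL_THRESHOLD) == pred.exposed[i] for i in range(lo, hi)
        ])
        lo13, hi13 = max(0, center - 6), min(n, center + 7)
        assert frac == pytest.approx(expect_frac)
        assert mean_area == pytest.approx(exposures[lo13:hi13].mean())


class TestIppFeature:
    def test_constant_ipp(self):
        model = ca_model([("A", i, (4.0 * i, 0, 0)) for i in range(5)])
        prof = one_hot_profile(model)
        prof.ipp[:] = 1.2
        assert ipp_feature(prof, 2) == pytest.approx(1.2)

    def test_terminus_truncation(self):
        model = ca_model([("A", i, (4.0 * i, 0, 0)) for i in range(5)])
        prof = one_hot_profile(model)
        prof.ipp[:] = [1.0, 3.0, 5.0, 7.0, 9.0]
        assert ipp_feature(prof, 0) == pytest.approx(2.0)  # mean of positions 0,1
        assert ipp_feature(prof, 2) == pytest.approx(5.0)


class TestGlobalFeatures:
    def test_perfect_model(self):
        n = 9
        seq = "A" * n
        pred = _uniform_ss(seq, "C")
        exp_pred = ExposurePrediction(seq, np.ones(n, bool))
        g_ss, g_surf = global_features("C" * n, np.full(n, 0.9), pred, exp_pred, np.arange(n))
        assert (g_ss, g_surf) == (1.0, 1.0)

    def test_half_agreement(self):
        n = 10
        seq = "A" * n
        pred = _uniform_ss(seq, "H")
        exp_pred = ExposurePrediction(seq, np.ones(n, bool))
        assigned = "H" * 5 + "E" * 5
        g_ss, _ = global_features(assigned, np.full(n, 0.9), pred, exp_pred, np.arange(n))
        assert g_ss == pytest.approx(0.5)

    def test_equals_windowed_value_for_short_model(self, helix_native, helix_inputs):
        profile, ss_pred, exp_pred = helix_inputs
        short = ProteinModel("short", helix_native.residues[:21], 21)
        inputs = ModelInputs(short, profile, ss_pred, exp_pred)
        _, w21, _ = ss_agreement_features(inputs.assigned, ss_pred, 10, inputs.positions)
        g_ss, _ = inputs._global
        assert g_ss == pytest.approx(w21)


# ---------- assembled vector ----------

class TestFeatureVector:
    def test_constant_length_and_determinism(self, helix_native, helix_inputs):
        profile, ss_pred, exp_pred = helix_inputs
        inputs = ModelInputs(helix_native, profile, ss_pred, exp_pred)
        vecs = [build_feature_vector(inputs, i) for i in range(len(helix_native))]
        assert {len(v) for v in vecs} == {len(feature_names())}
        inputs2 = ModelInputs(helix_native, profile, ss_pred, exp_pred)
        vecs2 = [build_feature_vector(inputs2, i) for i in range(len(helix_native))]
        assert np.array_equal(np.array(vecs), np.array(vecs2))

    def test_one_hot_profile_reduces_to_unweighted(self, helix_native):
        prof = one_hot_profile(helix_native)
        weighted = residue_contact_features(helix_native, 10, profile=prof)
        plain = residue_contact_features(helix_native, 10, profile=None)
        assert np.allclose(weighted, plain)

    def test_histogram_blocks_normalized(self, two_domain_native):
        profile, ss_pred, exp_pred = None, _uniform_ss("A" * 60, "H"), \
            ExposurePrediction("A" * 60, np.ones(60, bool))
        inputs = ModelInputs(two_domain_native, profile, ss_pred, exp_pred)
        for i in range(0, 60, 7):
            v = build_feature_vector(inputs, i)
            atom_block, res_block, exp_block = v[:91], v[91:112], v[112:136]
            for block in (atom_block, res_block):
                assert block.sum() == pytest.approx(1.0) or np.all(block == 0)
            assert exp_block.sum() == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, helix_native, helix_inputs):
        profile, ss_pred, exp_pred = helix_inputs
        a = np.radians(33.0)
        R = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
        moved = helix_native.transformed(R, np.array([5.0, 6.0, -7.0]))
        X0 = np.array([
            build_feature_vector(ModelInputs(helix_native, profile, ss_pred, exp_pred), i)
            for i in range(0, 30, 5)
        ])
        X1 = np.array([
            build_feature_vector(ModelInputs(moved, profile, ss_pred, exp_pred), i)
            for i in range(0, 30, 5)
        ])
        assert np.allclose(X0, X1, atol=5e-3)  # SASA point sampling rotates with the frame
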