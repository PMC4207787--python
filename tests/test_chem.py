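import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimerstab.chem import (
    DEFAULT_LIABILITY_SMARTS, DEFAULT_PPI_RULES, FilterRule, MoleculeRecord,
    MoleculeParseError, bioavailability_radar, compute_descriptors,
    diversity_cluster, fingerprint, liability_flags, ppi_druglike_filter,
    scaffold_cluster, tanimoto,
)
from dimerstab.synth import SynthSpec, make_library

from oracles import leader_cluster_reference, tanimoto_bit_loop


def record(**kwargs):
    defaults = dict(id="X", smiles="CCO", mw=350.0, logp=2.0, tpsa=80.0,
                    hbd=2, hba=5, rotb=6)
    defaults.update(kwargs)
    return MoleculeRecord(**defaults)


class TestDescriptors:
    def test_ethanol(self):
        rec = compute_descriptors("CCO")
        assert rec.mw == pytest.approx(46.07, abs=0.01)
        assert rec.hbd == 1
        # Ertl fragment value for an aliphatic hydroxyl
        assert rec.tpsa == pytest.approx(20.23, abs=0.01)

    def test_benzene_is_apolar_and_rigid(self):
        rec = compute_descriptors("c1ccccc1")
        assert rec.hbd == 0
        assert rec.hba == 0
        assert rec.rotb == 0
        assert rec.tpsa == 0.0

    def test_unparseable_smiles(self):
        with pytest.raises(MoleculeParseError):
            compute_descriptors("not-a-molecule((")

    def test_deterministic(self):
        a = compute_descriptors("CC(=O)Nc1ccc(O)cc1")
        b = compute_descriptors("CC(=O)Nc1ccc(O)cc1")
        assert (a.mw, a.logp, a.tpsa, a.hbd, a.hba, a.rotb) == \
               (b.mw, b.logp, b.tpsa, b.hbd, b.hba, b.rotb)


class TestPpiFilter:
    @pytest.mark.parametrize("override, violated", [
        ({"mw": 750.0}, "mw"),       # 100 < MW < 700
        ({"logp": -5.0}, "logp"),    # -4 < logP < 6
        ({"tpsa": 200.0}, "tpsa"),
        ({"hbd": 5}, "hbd"),
        ({"hba": 10}, "hba"),
        ({"rotb": 15}, "rotb"),
    ])
    def test_out_of_range_fails_with_named_rule(self, override, violated):
        res = ppi_druglike_filter(record(**override))
        assert not res.passed
        assert violated in res.violations

    def test_interior_point_passes(self):
        res = ppi_druglike_filter(record())
        assert res.passed and res.violations == ()

    def test_bounds_are_exclusive(self):
        assert not ppi_druglike_filter(record(mw=700.0)).passed
        assert not ppi_druglike_filter(record(hbd=0)).passed
        assert ppi_druglike_filter(record(mw=699.99)).passed

    def test_all_violations_listed(self):
        res = ppi_druglike_filter(record(mw=800.0, logp=9.0))
        assert set(res.violations) == {"mw", "logp"}

    def test_missing_descriptor_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            ppi_druglike_filter(record(tpsa=None))

    def test_idempotent_on_synthetic_library(self):
        lib = make_library(SynthSpec(seed=3, library_size=200))
        def run(df):
            keep = []
            for row in df.itertuples(index=False):
                rec = record(id=row.id, mw=row.mw, logp=row.logp,
                             tpsa=row.tpsa, hbd=row.hbd, hba=row.hba,
                             rotb=row.rotb)
                keep.append(ppi_druglike_filter(rec).passed)
            return df[np.array(keep)]
        once = run(lib)
        twice = run(once)
        assert list(once["id"]) == list(twice["id"])

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            FilterRule("mw", 700, 100)


class TestFingerprint:
    def test_deterministic(self):
        a = fingerprint("CC(=O)Oc1ccccc1C(=O)O")
        b = fingerprint("CC(=O)Oc1ccccc1C(=O)O")
        assert np.array_equal(a, b)

    def test_different_molecules_differ(self):
        assert not np.array_equal(fingerprint("C"), fingerprint("CCCCCCCCCC"))

    @pytest.mark.parametrize("smi1, smi2", [
        ("CCO", "OCC"),
        ("c1ccccc1O", "Oc1ccccc1"),
        ("N(C)C", "CNC"),
    ])
    def test_canonical_form_invariance(self, smi1, smi2):
        assert np.array_equal(fingerprint(smi1), fingerprint(smi2))


class TestTanimoto:
    def test_identical_nonempty_is_one(self, rng):
        a = rng.random(2048) < 0.1
        assert tanimoto(a, a) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros(64, dtype=bool)
        b = np.zeros(64, dtype=bool)
        a[:10] = True
        b[20:30] = True
        assert tanimoto(a, b) == 0.0

    def test_both_empty_defined_as_one(self):
        z = np.zeros(32, dtype=bool)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(8, dtype=bool), np.zeros(16, dtype=bool))

    def test_matches_bit_loop_and_is_symmetric(self, rng):
        for _ in range(50):
            a = rng.random(128) < 0.2
            b = rng.random(128) < 0.2
            assert tanimoto(a, b) == pytest.approx(tanimoto_bit_loop(a, b))
            assert tanimoto(a, b) == tanimoto(b, a)

    def test_one_iff_equal_nonempty(self, rng):
        a = rng.random(128) < 0.2
        b = a.copy()
        b[np.argmax(a)] = False  # remove one set bit
        assert tanimoto(a, b) < 1.0


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(1, 64).flatmap(
    lambda n: st.tuples(st.lists(st.booleans(), min_size=n, max_size=n),
                        st.lists(st.booleans(), min_size=n, max_size=n))))
def test_tanimoto_is_a_bounded_symmetric_similarity(pair):
    """0 <= T <= 1, T(a,b) = T(b,a), and T = 1 exactly when the bitsets are
    equal (the all-empty pair counts as equal by convention)."""
    a = np.array(pair[0], dtype=bool)
    b = np.array(pair[1], dtype=bool)
    t = tanimoto(a, b)
    assert 0.0 <= t <= 1.0
    assert t == tanimoto(b, a)
    assert (t == 1.0) == bool(np.array_equal(a, b))


def _records_with_fps(smiles_list):
    recs = []
    for i, smi in enumerate(smiles_list):
        r = MoleculeRecord(id=f"M{i:03d}", smiles=smi)
        r.fingerprint = fingerprint(smi)
        recs.append(r)
    return recs


class TestDiversityCluster:
    def test_identical_molecules_one_representative(self):
        recs = _records_with_fps(["CCO"] * 5)
        reps, assignment = diversity_cluster(recs)
        assert len(reps) == 1
        assert set(assignment.values()) == set(reps)

    def test_dissimilar_pair_two_clusters(self):
        recs = _records_with_fps(["CCO", "c1ccc2ccccc2c1"])
        d = 1 - tanimoto(recs[0].fingerprint, recs[1].fingerprint)
        assert d > 0.3  # precondition of the scenario
        reps, _ = diversity_cluster(recs)
        assert len(reps) == 2

    def test_representatives_pairwise_distant(self):
        lib = make_library(SynthSpec(seed=5, library_size=60))
        recs = _records_with_fps(lib["smiles"].tolist()[:60])
        for i, r in enumerate(recs):
            r.id = f"M{i:03d}"
        reps, assignment = diversity_cluster(recs, max_distance=0.3)
        by_id = {r.id: r for r in recs}
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                d = 1 - tanimoto(by_id[a].fingerprint, by_id[b].fingerprint)
                assert d > 0.3
        # every member within 0.3 of its representative
        for mid, rid in assignment.items():
            d = 1 - tanimoto(by_id[mid].fingerprint, by_id[rid].fingerprint)
            assert d <= 0.3 or mid == rid

    def test_matches_quadratic_reference(self):
        lib = make_library(SynthSpec(seed=11, library_size=100))
        recs = _records_with_fps(lib["smiles"].tolist())
        reps, assignment = diversity_cluster(recs, max_distance=0.3)
        ref_reps, ref_assignment = leader_cluster_reference(
            [r.id for r in recs], [r.fingerprint for r in recs], 0.3)
        assert reps == ref_reps
        assert assignment == ref_assignment

    def test_empty_library_errors(self):
        with pytest.raises(ValueError):
            diversity_cluster([])


def _synthetic_fp(blocks, nbits=100):
    fp = np.zeros(nbits, dtype=bool)
    for lo, hi in blocks:
        fp[lo:hi] = True
    return fp


class TestScaffoldCluster:
    def test_all_dissimilar_gives_singletons(self):
        recs = _records_with_fps(["CCO", "c1ccc2ccccc2c1", "CC(=O)OCC(N)=O"])
        clusters = scaffold_cluster(recs, min_similarity=0.99)
        assert len(clusters) == 3

    def test_single_linkage_chains(self):
        """a~b and b~c above threshold, a-c far below: one cluster {a,b,c}."""
        a = MoleculeRecord(id="a", smiles="")
        b = MoleculeRecord(id="b", smiles="")
        c = MoleculeRecord(id="c", smiles="")
        a.fingerprint = _synthetic_fp([(0, 40)])
        b.fingerprint = _synthetic_fp([(10, 50)])
        c.fingerprint = _synthetic_fp([(20, 60)])
        assert tanimoto(a.fingerprint, b.fingerprint) >= 0.6
        assert tanimoto(b.fingerprint, c.fingerprint) >= 0.6
        assert tanimoto(a.fingerprint, c.fingerprint) < 0.6
        clusters = scaffold_cluster([a, b, c], min_similarity=0.6)
        assert clusters == [{"a", "b", "c"}]

    def test_matches_graph_components(self, rng):
        import networkx as nx
        recs = []
        for i in range(20):
            r = MoleculeRecord(id=f"S{i:02d}", smiles="")
            r.fingerprint = rng.random(100) < 0.3
            recs.append(r)
        clusters = scaffold_cluster(recs, min_similarity=0.5)
        g = nx.Graph()
        g.add_nodes_from(r.id for r in recs)
        for i in range(20):
            for j in range(i + 1, 20):
                if tanimoto_bit_loop(recs[i].fingerprint,
                                     recs[j].fingerprint) >= 0.5:
                    g.add_edge(recs[i].id, recs[j].id)
        expected = sorted((set(c) for c in nx.connected_components(g)),
                          key=lambda c: sorted(c)[0])
        assert clusters == expected


LIABILITY_EXEMPLARS = {
    "reactive_acyl_halide": "CC(=O)Cl",
    "reactive_aldehyde": "CC=O",
    "reactive_michael_acceptor": "C=CC(C)=O",
    "reactive_isocyanate": "CN=C=O",
    "reactive_epoxide": "CC1CO1",
    "reactive_alkyl_halide": "CCBr",
    "pains_quinone": "O=C1C=CC(=O)C=C1",
    "pains_catechol": "Oc1ccccc1O",
    "pains_hydrazone": "CC=NNC",
    "pains_nitroaromatic": "O=[N+]([O-])c1ccccc1",
}


class TestLiabilityFlags:
    def test_clean_molecule_unflagged(self):
        assert liability_flags("CCO") == []

    @pytest.mark.parametrize("rule", sorted(DEFAULT_LIABILITY_SMARTS))
    def test_each_rule_hits_its_exemplar(self, rule):
        assert rule in liability_flags(LIABILITY_EXEMPLARS[rule])

    def test_malformed_smarts_rejected(self):
        with pytest.raises(ValueError):
            liability_flags("CCO", {"bad": "((("})


class TestRadarEquivalence:
    def test_radar_inside_iff_filter_passes(self):
        """The radar-polygon predicate and the interval filter are the same
        test in two renderings, across a planted library."""
        lib = make_library(SynthSpec(seed=9, library_size=300))
        for row in lib.itertuples(index=False):
            rec = record(id=row.id, mw=row.mw, logp=row.logp, tpsa=row.tpsa,
                         hbd=row.hbd, hba=row.hba, rotb=row.rotb)
            _, inside = bioavailability_radar(rec)
            assert inside == ppi_druglike_filter(rec).passed
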