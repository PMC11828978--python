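import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echomap import (
    FeatureConfig,
    Ontology,
    OntologyTerm,
    assemble_features,
    char_ngrams,
    detect_negation,
    embed_entities,
    fit_entity_projection,
    jaccard,
    jaccard_block,
    lexicon_recognizer,
)
from echomap.features import EntityProjection


class TestNegation:
    @pytest.mark.parametrize(
        "sentence,flag",
        [
            ("there is no aortic valve mass present", 1),
            ("normal left ventricular systolic function", 0),
            ("without pericardial effusion", 1),
            ("patient is free of effusion", 1),
            ("non coronary cusp is calcified", 0),  # "non" is not a cue
            ("nothing notable", 0),  # whole-token match only
        ],
    )
    def test_cue_matching(self, sentence, flag):
        assert detect_negation(sentence) == flag


class TestCharNgrams:
    def test_enumeration(self):
        assert char_ngrams("aorta", 3) == {"aor", "ort", "rta"}

    def test_short_string_yields_itself(self):
        assert char_ngrams("ab", 3) == {"ab"}

    def test_empty_string(self):
        assert char_ngrams("", 3) == frozenset()

    def test_spaces_included(self):
        assert "c v" in char_ngrams("aortic valve", 3)


class TestJaccard:
    def test_identical_nonempty(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_both_empty(self):
        assert jaccard(set(), set()) == 0.0

    def test_aorta_vs_aortic(self):
        # {aor,ort,rta} vs {aor,ort,rti,tic}: intersection 2, union 5
        assert jaccard(char_ngrams("aorta"), char_ngrams("aortic")) == pytest.approx(0.4)

    @given(
        st.text(alphabet="abcde ", max_size=20),
        st.text(alphabet="abcde ", max_size=20),
    )
    def test_matches_brute_force_and_is_symmetric(self, s, t):
        A, B = char_ngrams(s), char_ngrams(t)
        inter = sum(1 for g in A if g in B)
        union = len(set(list(A) + list(B)))
        expected = inter / union if union else 0.0
        assert jaccard(A, B) == pytest.approx(expected)
        assert jaccard(A, B) == jaccard(B, A)
        assert 0.0 <= jaccard(A, B) <= 1.0
        if A or B:
            assert (jaccard(A, B) == 1.0) == (A == B)

    def test_equals_one_iff_sets_equal(self):
        A, B = char_ngrams("aorta"), char_ngrams("aortb")
        assert jaccard(A, A) == 1.0
        assert jaccard(A, B) < 1.0


class TestJaccardBlock:
    def test_sentence_equal_to_term_scores_one(self):
        terms = ["aorta", "mitral valve", "left ventricle"]
        v = jaccard_block("mitral valve", terms)
        assert v[1] == 1.0 and len(v) == 3

    def test_empty_sentence_all_zero(self):
        assert np.all(jaccard_block("", ["aorta", "mitral"]) == 0.0)


def _entity_ontology(n_terms: int) -> Ontology:
    terms = [OntologyTerm(f"term{i:02d}", 1) for i in range(n_terms)]
    return Ontology(terms, [])


class TestEntityProjection:
    def test_output_dimension_is_requested_dim(self):
        o = _entity_ontology(40)
        rec = lexicon_recognizer(o)
        train = [f"term{i:02d} is here" for i in range(40)]
        proj = fit_entity_projection(train, rec, dim=25)
        assert proj.dim == 25
        assert embed_entities(train[0], proj, rec).shape == (25,)

    def test_rank_deficient_vocabulary_zero_padded(self):
        o = _entity_ontology(10)
        rec = lexicon_recognizer(o)
        train = [f"term{i:02d} present" for i in range(10)]
        proj = fit_entity_projection(train, rec, dim=25)
        assert proj.dim == 25
        assert np.allclose(proj.components[10:], 0.0)

    def test_identical_entity_sets_identical_embeddings(self):
        o = _entity_ontology(6)
        rec = lexicon_recognizer(o)
        train = [f"term{i:02d} seen" for i in range(6)]
        proj = fit_entity_projection(train, rec, dim=4)
        a = embed_entities("the term03 is dilated", proj, rec)
        b = embed_entities("term03 appears small", proj, rec)
        np.testing.assert_array_equal(a, b)

    def test_no_entities_embeds_centered_zero(self):
        o = _entity_ontology(6)
        rec = lexicon_recognizer(o)
        train = [f"term{i:02d}" for i in range(6)]
        proj = fit_entity_projection(train, rec, dim=3)
        v = embed_entities("nothing recognizable", proj, rec)
        np.testing.assert_allclose(v, proj.components @ (-proj.mean_vector))

    def test_deterministic_fit(self):
        o = _entity_ontology(8)
        rec = lexicon_recognizer(o)
        train = [f"term{i:02d} and term{(i + 1) % 8:02d}" for i in range(8)]
        p1 = fit_entity_projection(train, rec, dim=5)
        p2 = fit_entity_projection(train, rec, dim=5)
        np.testing.assert_array_equal(p1.components, p2.components)

    def test_agrees_with_reference_pca_subspace(self):
        """Components must span the same leading subspace as sklearn PCA."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(0)
        o = _entity_ontology(12)
        rec = lexicon_recognizer(o)
        train = [
            " ".join(f"term{j:02d}" for j in rng.choice(12, size=4, replace=False))
            for _ in range(30)
        ]
        k = 5
        proj = fit_entity_projection(train, rec, dim=k)
        X = np.stack(
            [
                np.isin(np.arange(12), [int(e[4:]) for e in rec(s)]).astype(float)
                for s in train
            ]
        )
        ref = PCA(n_components=k, random_state=0).fit(X)
        # compare up to sign, component by component
        for r in range(k):
            dot = abs(float(ref.components_[r] @ proj.components[r]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_zero_entity_corpus_rejected(self):
        o = _entity_ontology(3)
        rec = lexicon_recognizer(o)
        with pytest.raises(ValueError):
            fit_entity_projection(["nothing here"], rec, dim=2)

    def test_json_round_trip(self, tmp_path):
        o = _entity_ontology(5)
        rec = lexicon_recognizer(o)
        proj = fit_entity_projection([f"term{i:02d}" for i in range(5)], rec, dim=3)
        p = tmp_path / "proj.json"
        proj.save(p)
        loaded = EntityProjection.load(p)
        np.testing.assert_array_equal(loaded.components, proj.components)
        assert loaded.entity_vocabulary == proj.entity_vocabulary


class TestLexiconRecognizer:
    def test_longest_match_wins(self, toy_ontology):
        rec = lexicon_recognizer(toy_ontology)
        assert rec("the left ventricle function is normal") == [
            "left ventricle",
            "function",
        ]

    def test_synonym_recognized(self, toy_ontology):
        rec = lexicon_recognizer(toy_ontology)
        assert rec("lv appears hyperdynamic") == ["lv", "hyperdynamic"]


def _blocks(n_l1, n_l23, dim):
    return dict(
        negation=1,
        entity_embedding=np.zeros(dim),
        jaccard_l1=np.zeros(n_l1),
        jaccard_l23=np.zeros(n_l23),
    )


class TestAssembleFeatures:
    def test_reference_configuration_lengths(self):
        """27 L1 terms + 230 distinct L2/L3 terms + 25 entity components
        give per-level input lengths 53, 284 and 285."""
        cfg = FeatureConfig()
        b = _blocks(27, 230, 25)
        l1 = assemble_features(1, **{**b, "jaccard_l23": None}, cfg=cfg)
        l2 = assemble_features(2, **b, pred_l1=3.0, cfg=cfg)
        l3 = assemble_features(3, **b, pred_l1=3.0, pred_l2=7.0, cfg=cfg)
        assert (len(l1), len(l2), len(l3)) == (53, 284, 285)
        assert l2.block_layout["pred_l1"] == (283, 284)

    @given(
        st.integers(1, 40), st.integers(1, 60), st.integers(1, 30),
        st.booleans(), st.booleans(), st.booleans(),
    )
    def test_length_identities_any_configuration(
        self, n_l1, n_l23, dim, use_neg, use_hier, use_ent
    ):
        cfg = FeatureConfig(
            entity_dim=dim,
            use_negation=use_neg,
            use_hierarchy=use_hier,
            use_entities=use_ent,
        )
        b = _blocks(n_l1, n_l23, dim)
        l1 = assemble_features(1, **{**b, "jaccard_l23": None}, cfg=cfg)
        l2 = assemble_features(2, **b, pred_l1=0.0, cfg=cfg)
        l3 = assemble_features(3, **b, pred_l1=0.0, pred_l2=0.0, cfg=cfg)
        hier = 1 if use_hier else 0
        assert len(l2) == len(l1) + n_l23 + hier
        assert len(l3) == len(l2) + hier

    def test_disabling_negation_shortens_every_vector_by_one(self):
        b = _blocks(27, 230, 25)
        for level, extra in ((1, {}), (2, {"pred_l1": 0.0}), (3, {"pred_l1": 0.0, "pred_l2": 0.0})):
            kw = {**b, "jaccard_l23": None} if level == 1 else b
            on = assemble_features(level, **kw, **extra, cfg=FeatureConfig())
            off = assemble_features(
                level, **kw, **extra, cfg=FeatureConfig(use_negation=False)
            )
            assert len(on) - len(off) == 1

    def test_missing_required_prediction_rejected(self):
        b = _blocks(5, 7, 3)
        cfg = FeatureConfig(entity_dim=3)
        with pytest.raises(ValueError):
            assemble_features(2, **b, cfg=cfg)
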