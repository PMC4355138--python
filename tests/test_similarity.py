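"""simGIC, query translation, and corpus ranking."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenosearch import (
    EmptyQueryError,
    FixtureSpec,
    MappingTable,
    SearchIndex,
    UnknownTermError,
    build_query,
    compute_ic,
    load_mapping,
    oracle_search,
    random_corpus,
    random_ontology,
    random_queries,
    search,
    simgic,
    translate_query,
)

ROOT, A, B, C, D = (f"XP:000000{i}" for i in range(5))

# Hand-derived worked-example values (entity-level IC, natural log):
# sim(Cl(e1), Cl(e2)) = (ln2 + ln(4/3)) / (ln2 + 2 ln(4/3))
# sim(Cl(e3), Cl(e4)) = ln(4/3) / (2 ln2 + 2 ln(4/3))
SIM_E1_E2 = (math.log(2) + math.log(4 / 3)) / (math.log(2) + 2 * math.log(4 / 3))
SIM_E3_E4 = math.log(4 / 3) / (2 * math.log(2) + 2 * math.log(4 / 3))


class TestTranslateQuery:
    @pytest.fixture
    def mapping(self, canonical_graph):
        return MappingTable(
            pairs={
                "YP:0000001": frozenset({C}),
                "YP:0000002": frozenset({A, B}),
            },
            provenance="synthetic",
        )

    def test_canonical_terms_pass_through(self, canonical_graph, mapping):
        effective, skipped = translate_query([C], canonical_graph, mapping)
        assert effective == [C] and skipped == []

    def test_foreign_term_replaced_by_targets(self, canonical_graph, mapping):
        effective, skipped = translate_query(["YP:0000001"], canonical_graph, mapping)
        assert effective == [C] and skipped == []
        # one-to-many rows contribute their whole target set
        effective, _ = translate_query(["YP:0000002"], canonical_graph, mapping)
        assert set(effective) == {A, B}

    def test_unmappable_term_dropped_and_recorded_or_strict_error(
        self, canonical_graph, mapping
    ):
        effective, skipped = translate_query(
            ["YP:0009999", C], canonical_graph, mapping
        )
        assert effective == [C]
        assert skipped == [("YP:0009999", "not in ontology or mapping")]
        with pytest.raises(UnknownTermError):
            translate_query(["YP:0009999"], canonical_graph, mapping, strict=True)

    def test_mapping_tsv_round_trip_and_bad_target(self, canonical_graph, tmp_path):
        path = tmp_path / "mapping.tsv"
        path.write_text(
            "source_term\ttarget_term\nYP:0000001\tXP:0000003\nYP:0000001\tXP:0000004\n"
        )
        table = load_mapping(path, canonical_graph)
        assert table.targets("YP:0000001") == {C, D}
        bad = tmp_path / "bad.tsv"
        bad.write_text("source_term\ttarget_term\nYP:0000001\tXP:7777777\n")
        with pytest.raises(UnknownTermError):
            load_mapping(bad, canonical_graph)

    def test_empty_effective_query_is_an_error(self, canonical_graph):
        with pytest.raises(EmptyQueryError):
            build_query(["YP:0009999"], canonical_graph)


class TestSimgic:
    def test_identity_profile_scores_one(self, canonical_corpus, canonical_ic):
        closed = canonical_corpus.profiles["e1"].closed_terms
        assert simgic(closed, closed, canonical_ic) == 1.0

    def test_worked_example_pairs(self, canonical_corpus, canonical_ic):
        p = canonical_corpus.profiles
        assert simgic(
            p["e1"].closed_terms, p["e2"].closed_terms, canonical_ic
        ) == pytest.approx(SIM_E1_E2, abs=1e-12)
        assert simgic(
            p["e3"].closed_terms, p["e4"].closed_terms, canonical_ic
        ) == pytest.approx(SIM_E3_E4, abs=1e-12)

    def test_zero_information_denominator_returns_zero(
        self, canonical_graph, canonical_ic
    ):
        # root alone carries IC 0 on both sides
        assert simgic({ROOT}, {ROOT}, canonical_ic) == 0.0


class TestSearch:
    def test_query_c_ranking_matches_brute_force(self, canonical):
        graph, corpus = canonical
        ic = compute_ic(corpus)
        result = search(build_query([C], graph), corpus, ic)
        assert result.entity_ids() == ["e1", "e2", "e3", "e4"]
        scores = dict(zip(result.entity_ids(), result.scores()))
        assert scores["e1"] == 1.0  # query equals e1's profile
        assert scores["e4"] == 0.0  # shares only the zero-IC root
        assert scores["e1"] > scores["e2"] > scores["e3"]

    def test_identity_query_attains_rank_one(self, canonical):
        graph, corpus = canonical
        ic = compute_ic(corpus)
        for eid, profile in corpus.profiles.items():
            result = search(
                build_query(sorted(profile.annotated_terms), graph), corpus, ic
            )
            assert result.scores()[0] == pytest.approx(1.0)
            top = {e for e, _, _, s in result.entries if s == result.scores()[0]}
            assert eid in top

    def test_type_filter_with_no_matches_is_empty_not_error(self, canonical):
        graph, corpus = canonical
        ic = compute_ic(corpus)
        result = search(build_query([C], graph), corpus, ic, entity_type="disease")
        assert len(result) == 0

    def test_top_k_truncates_after_sorting(self, canonical):
        graph, corpus = canonical
        ic = compute_ic(corpus)
        result = search(build_query([C], graph), corpus, ic, top_k=2)
        assert result.entity_ids() == ["e1", "e2"]

    def test_result_tsv_has_six_decimal_scores(self, canonical, tmp_path):
        graph, corpus = canonical
        ic = compute_ic(corpus)
        result = search(build_query([C], graph), corpus, ic)
        out = tmp_path / "result.tsv"
        with open(out, "w") as handle:
            result.write_tsv(handle)
        lines = out.read_text().splitlines()
        assert lines[0] == "rank\tentity_id\tentity_type\tspecies\tscore"
        assert lines[1].split("\t") == ["1", "e1", "gene", "synthetic", "1.000000"]


def _random_instance(seed, n_terms=40, n_entities=30):
    spec = FixtureSpec(
        n_terms=n_terms, n_entities=n_entities, profile_size_range=(1, 5), seed=seed
    )
    graph = random_ontology(spec)
    corpus = random_corpus(spec, graph)
    return spec, graph, corpus


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000))
def test_simgic_symmetry_and_bounds_on_random_profiles(seed):
    _, graph, corpus = _random_instance(seed)
    ic = compute_ic(corpus)
    profiles = list(corpus)
    for i, p in enumerate(profiles):
        for r in profiles[i:]:
            forward = simgic(p.closed_terms, r.closed_terms, ic)
            assert forward == simgic(r.closed_terms, p.closed_terms, ic)
            assert 0.0 <= forward <= 1.0


@settings(deadline=None, derandomize=True, max_examples=10)
@given(seed=st.integers(0, 10_000), base=st.sampled_from([2.0, 10.0, math.e, 1.5]))
def test_simgic_is_log_base_invariant(seed, base):
    _, graph, corpus = _random_instance(seed, n_entities=15)
    ic = compute_ic(corpus)
    rebased = ic.with_base(base)
    profiles = list(corpus)[:8]
    for p in profiles:
        for r in profiles:
            assert simgic(p.closed_terms, r.closed_terms, ic) == pytest.approx(
                simgic(p.closed_terms, r.closed_terms, rebased), abs=1e-12
            )


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000))
def test_adding_a_shared_informative_term_strictly_increases_simgic(seed):
    _, graph, corpus = _random_instance(seed)
    ic = compute_ic(corpus)
    profiles = list(corpus)
    p, r = profiles[0].closed_terms, profiles[-1].closed_terms
    current = simgic(p, r, ic)
    fresh = [t for t in ic.values if t not in (p | r) and ic[t] > 0]
    if current < 1.0 and fresh:
        t = fresh[0]
        assert simgic(p | {t}, r | {t}, ic) > current


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000))
def test_search_matches_naive_reference_on_random_instances(seed):
    """The inverted-index engine must reproduce the no-cache reference
    ranking exactly (same order, scores within 1e-12)."""
    spec, graph, corpus = _random_instance(seed, n_terms=50, n_entities=40)
    ic = compute_ic(corpus)
    index = SearchIndex(corpus, ic)
    for terms in random_queries(
        FixtureSpec(n_terms=spec.n_terms, n_queries=3, terms_per_query=5, seed=seed),
        graph,
    ):
        fast = index.search(build_query(terms, graph))
        slow = oracle_search(terms, corpus, graph)
        assert fast.entity_ids() == slow.entity_ids()
        for a, b in zip(fast.scores(), slow.scores()):
            assert a == pytest.approx(b, abs=1e-12)
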