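"""Database joins, exclusive set intersections, heatmap input, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from math import comb

from hlatarget.annotation import (
    annotate,
    enrich_terms,
    set_intersections,
    top_shared_matrix,
    zscore_rows,
)
from hlatarget.filtering import RetainedPeptide
from hlatarget.io import AnnotationDb
from hlatarget.synthetic import make_annotation_fixtures


def _entry(seq, proteins=("P1",), intensities=None):
    return RetainedPeptide(
        sequence=seq,
        score=1.0,
        q_value=0.0,
        proteins=frozenset(proteins),
        samples=frozenset({"s1"}),
        sample_intensity=dict(intensities or {}),
    )


class TestAnnotate:
    def test_flags_match_generator_truth(self):
        peptides = [f"AAAAAAAA{a}" for a in "CDEFGHIKLMNPQRSTVWY"]
        proteins = [f"P{i:02d}" for i in range(20)]
        dbs, truth = make_annotation_fixtures(
            peptides, proteins, {"TANTIGEN": 0.2, "HBPA": 0.3}, seed=5
        )
        entries = [
            _entry(pep, proteins=[proteins[i % len(proteins)]])
            for i, pep in enumerate(peptides)
        ]
        annotated, counts = annotate(entries, dbs)
        for a, e in zip(annotated, entries):
            assert a.flags["TANTIGEN"] == (e.sequence in truth.db_members["TANTIGEN"])
            assert a.flags["HBPA"] == bool(e.proteins & truth.db_members["HBPA"])
        assert counts["TANTIGEN"] == sum(a.flags["TANTIGEN"] for a in annotated)

    def test_protein_level_flag_from_any_source_accession(self):
        db = AnnotationDb("CSPA", "protein", frozenset({"P2"}))
        annotated, counts = annotate([_entry("AAAAAAAA", proteins=["P1", "P2"])], [db])
        assert annotated[0].flags["CSPA"] is True and counts["CSPA"] == 1

    def test_empty_database_set_gives_no_flags(self):
        annotated, counts = annotate([_entry("AAAAAAAA")], [])
        assert annotated[0].flags == {} and counts == {"multi": 0}


class TestSetIntersections:
    def test_two_set_enumeration(self):
        counts = set_intersections({"A": {"x", "y"}, "B": {"y", "z"}})
        assert counts[("A",)] == 1 and counts[("B",)] == 1 and counts[("A", "B")] == 1

    def test_identical_sets_fill_only_full_intersection(self):
        counts = set_intersections({"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x", "y"}})
        assert counts[("A", "B", "C")] == 2
        assert sum(v for k, v in counts.items() if k != ("A", "B", "C")) == 0

    def test_exclusive_counts_conserve_union(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 6))
            universe = [f"e{i}" for i in range(100)]
            sets = {
                f"S{j}": set(rng.choice(universe, size=50, replace=False))
                for j in range(k)
            }
            counts = set_intersections(sets)
            assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_matches_membership_vector_oracle(self, rng):
        universe = [f"e{i}" for i in range(100)]
        sets = {
            f"S{j}": set(rng.choice(universe, size=50, replace=False)) for j in range(4)
        }
        counts = set_intersections(sets)
        names = list(sets)
        for r in range(1, 5):
            for combo in itertools.combinations(names, r):
                expected = sum(
                    1
                    for e in universe
                    if all(e in sets[n] for n in combo)
                    and not any(e in sets[n] for n in set(names) - set(combo))
                )
                assert counts[combo] == expected

    def test_no_sets_is_error(self):
        with pytest.raises(ValueError):
            set_intersections({})


class TestTopSharedMatrix:
    def test_ordering_and_k_selection(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.normal(20, 2, (50, 4)),
            index=[f"pep{i}" for i in range(50)],
            columns=list("abcd"),
        )
        top, shortfall = top_shared_matrix(df, k=40)
        assert top.shape == (40, 4) and shortfall == 0
        means = df.mean(axis=1)
        assert list(top.index) == list(means.sort_values(ascending=False).index[:40])

    def test_constant_row_zscores_to_zero(self):
        df = pd.DataFrame({"a": [5.0, 1.0], "b": [5.0, 2.0], "c": [5.0, 3.0]}, index=["p1", "p2"])
        top, _ = top_shared_matrix(df, k=2)
        assert (top.loc["p1"] == 0).all()

    def test_zscore_hand_computation(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["p"])
        z = zscore_rows(df)
        assert list(z.loc["p"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_shortfall_warns_and_returns_all(self):
        df = pd.DataFrame(np.ones((3, 2)), index=list("xyz"), columns=list("ab"))
        with pytest.warns(UserWarning):
            top, shortfall = top_shared_matrix(df, k=40)
        assert len(top) == 3 and shortfall == 37


def hypergeom_tail_oracle(x, N, K, n):
    """Exhaustive right tail P(X >= x) from binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(x, min(K, n) + 1)) / total


class TestEnrichment:
    def test_worked_example(self):
        background = {f"P{i}" for i in range(20)}
        term = {f"P{i}" for i in range(5)}
        query = {"P0", "P1", "P2", "P3", "P10"}
        out = enrich_terms(query, {"T": term}, background)
        assert out.p_value[0] == pytest.approx(76 / 15504, rel=1e-9)
        assert out.p_adjusted[0] == out.p_value[0]  # single term tested

    def test_disjoint_query_has_p_one(self):
        background = {f"P{i}" for i in range(10)}
        out = enrich_terms({"P9"}, {"T": {"P0", "P1"}}, background)
        assert out.p_value[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_exhaustively(self, rng):
        for _ in range(30):
            N = int(rng.integers(5, 26))
            background = {f"P{i}" for i in range(N)}
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(rng.choice(sorted(background), size=K, replace=False))
            query = set(rng.choice(sorted(background), size=n, replace=False))
            out = enrich_terms(query, {"T": term}, background)
            x = len(term & query)
            assert out.p_value[0] == pytest.approx(
                hypergeom_tail_oracle(x, N, K, n), rel=1e-9
            )

    def test_bonferroni_multiplies_by_number_of_terms(self):
        background = {f"P{i}" for i in range(20)}
        terms = {"T1": {"P0", "P1"}, "T2": {"P2", "P3"}, "T3": {"P4"}}
        out = enrich_terms({"P0", "P1"}, terms, background)
        assert np.allclose(out.p_adjusted, np.minimum(1.0, out.p_value * 3))

    def test_term_without_background_members_is_skipped_with_warning(self):
        background = {"P0", "P1"}
        with pytest.warns(UserWarning, match="skipped"):
            out = enrich_terms({"P0"}, {"T": {"X9"}}, background)
        assert out.empty

    def test_query_outside_background_is_error(self):
        with pytest.raises(ValueError):
            enrich_terms({"Q"}, {"T": {"P0"}}, {"P0"})
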