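import math

import numpy as np
import pytest

from specsample import (
    BinaryRealization,
    CooccurrenceStats,
    ScorerSpec,
    cooccurrence_stats,
    hart_hypergeometric_score,
    hart_poisson_score,
    hypergeom_tail_score,
    pe_score,
    poisson_tail_score,
    presence_sets,
    sai_score,
    score_realization,
    spectral_sum_baseline,
)
from specsample.data import SpectralCountMatrix

from .oracles import (
    hypergeom_upper_tail_exact,
    pe_reference,
    poisson_upper_tail_series,
    sai_reference,
)


def _random_sets(rng, n_prot, n_exp, with_baits=False):
    prots = [f"P{i}" for i in range(n_prot)]
    sets = {}
    baits = {}
    for e in range(n_exp):
        k = int(rng.integers(0, n_prot + 1))
        members = set(rng.choice(prots, size=k, replace=False))
        bait = prots[int(rng.integers(n_prot))]
        if with_baits:
            members.add(bait)
            baits[f"E{e}"] = bait
        sets[f"E{e}"] = frozenset(members)
    return sets, baits


class TestCooccurrenceStats:
    def test_single_experiment_triplet(self):
        stats = cooccurrence_stats({"e1": frozenset(["A", "B", "C"])})
        assert stats.x_of("A", "B") == stats.x_of("A", "C") == stats.x_of("B", "C") == 1
        assert stats.N_of == {"A": 2, "B": 2, "C": 2}
        assert stats.N_total == 3
        assert stats.lambda_of("A", "B") == pytest.approx(4 / 3)

    def test_disjoint_experiments(self):
        stats = cooccurrence_stats(
            {"e1": frozenset(["A", "B"]), "e2": frozenset(["C", "D"])}
        )
        assert stats.x_of("A", "C") == 0
        assert stats.N_total == 2
        assert stats.lambda_of("A", "C") == pytest.approx(0.5)

    def test_empty_input(self):
        stats = cooccurrence_stats({})
        assert stats.N_total == 0
        assert stats.lambda_of("A", "B") == 0.0

    def test_pair_sum_matches_per_experiment_pairs(self):
        rng = np.random.default_rng(0)
        sets, _ = _random_sets(rng, 7, 5)
        stats = cooccurrence_stats(sets)
        assert sum(stats.X.values()) == stats.N_total
        for p in stats.proteins:
            assert stats.N_of[p] == sum(
                len(s) - 1 for s in sets.values() if p in s
            )


class TestHartScores:
    def test_poisson_triplet_value(self):
        stats = cooccurrence_stats({"e1": frozenset(["A", "B", "C"])})
        expected = -math.log(1 - math.exp(-4 / 3) * (1 + 4 / 3))
        assert hart_poisson_score(stats, ("A", "B")) == pytest.approx(
            expected, abs=1e-12
        )

    def test_degenerate_null_scores_zero(self):
        stats = CooccurrenceStats(proteins=["A", "B"], X={}, N_of={}, N_total=0)
        assert hart_poisson_score(stats, ("A", "B")) == 0.0
        assert hart_hypergeometric_score(stats, ("A", "B")) == 0.0

    def test_poisson_monotone_in_x(self):
        scores = [float(poisson_tail_score(x, 2.5)) for x in range(8)]
        assert scores == sorted(scores)

    def test_poisson_matches_series_oracle(self):
        for tail in ("gt", "ge"):
            for x in range(11):
                for lam in (0.1, 0.5, 4 / 3, 2.0, 5.0, 10.0):
                    got = float(poisson_tail_score(x, lam, tail))
                    want = -math.log(
                        max(poisson_upper_tail_series(x, lam, tail), 1e-300)
                    )
                    assert got == pytest.approx(want, abs=1e-10)

    def test_hypergeom_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(40):
            sets, _ = _random_sets(rng, int(rng.integers(2, 9)), int(rng.integers(1, 7)))
            stats = cooccurrence_stats(sets)
            for (a, b), x in stats.X.items():
                got = hart_hypergeometric_score(stats, (a, b))
                tail = hypergeom_upper_tail_exact(
                    x, stats.N_of[a], stats.N_of[b], stats.N_total
                )
                want = -math.log(max(float(tail), 1e-300))
                assert got == pytest.approx(want, abs=1e-10)
                checked += 1
        assert checked > 50

    def test_hypergeom_zero_overlap_ge_tail_scores_zero(self):
        assert float(hypergeom_tail_score(0, 3, 4, 10, tail="ge")) == 0.0

    def test_hypergeom_symmetric_in_marginals(self):
        a = float(hypergeom_tail_score(2, 3, 7, 20))
        b = float(hypergeom_tail_score(2, 7, 3, 20))
        assert a == pytest.approx(b, abs=1e-12)

    def test_hypergeom_rejects_incidence_above_total(self):
        with pytest.raises(ValueError, match="exceeds"):
            hypergeom_tail_score(1, 11, 2, 10)


class TestSpokeScorers:
    def _instance(self, seed=5):
        rng = np.random.default_rng(seed)
        sets, baits = _random_sets(rng, 8, 10, with_baits=True)
        return sets, baits

    def test_sai_matches_reference(self):
        sets, baits = self._instance()
        got = sai_score(sets, baits).scores
        want = sai_reference(sets, baits)
        assert set(got) == set(want)
        for pair in want:
            assert got[pair] == pytest.approx(want[pair], abs=1e-12)

    def test_pe_matches_reference(self):
        sets, baits = self._instance(seed=6)
        got = pe_score(sets, baits).scores
        want = pe_reference(sets, baits)
        assert set(got) == set(want)
        for pair in want:
            assert got[pair] == pytest.approx(want[pair], abs=1e-10)

    def test_never_observed_pair_nonpositive_sai(self):
        # A and B never co-purify and never retrieve each other: every SAI
        # term has zero observed evidence
        sets = {
            "E0": frozenset(["A", "C"]),
            "E1": frozenset(["B", "D"]),
            "E2": frozenset(["C", "D"]),
        }
        baits = {"E0": "A", "E1": "B", "E2": "C"}
        scores = sai_score(sets, baits).scores
        assert ("A", "B") not in scores  # not even a candidate
        full = sai_reference(sets, baits)
        assert all(math.isfinite(v) for v in full.values())

    def test_degenerate_single_experiment_finite(self):
        sets = {"E0": frozenset(["A", "B", "C"])}
        baits = {"E0": "A"}
        for table in (sai_score(sets, baits), pe_score(sets, baits)):
            assert all(math.isfinite(v) for v in table.scores.values())

    def test_experiment_order_invariance(self):
        sets, baits = self._instance(seed=7)
        reordered = dict(reversed(list(sets.items())))
        for fn in (sai_score, lambda s, b: pe_score(s, b)):
            assert fn(sets, baits).scores == fn(reordered, baits).scores

    def test_pe_rejects_bad_params(self):
        sets, baits = self._instance()
        with pytest.raises(ValueError, match="r must be"):
            pe_score(sets, baits, r=1.5)
        with pytest.raises(ValueError, match="n_pseudo"):
            pe_score(sets, baits, n_pseudo=-1)
        with pytest.raises(ValueError, match="unknown parameter"):
            ScorerSpec("pe", params={"bogus": 1})
        with pytest.raises(ValueError, match="unknown scorer"):
            ScorerSpec("hgscore")

    def test_pe_additional_cooccurrence_does_not_decrease_score(self):
        # sparse study (20 purifications, A and B rare): an experiment that
        # contained only A now also pulls down B
        others = ["U", "V", "W", "S", "T"]
        base = {}
        baits = {}
        for e in range(20):
            bait = others[e % 5]
            base[f"E{e}"] = frozenset({bait, others[(e + 1) % 5]})
            baits[f"E{e}"] = bait
        base["E0"] = base["E0"] | {"A", "B"}
        base["E1"] = base["E1"] | {"A"}
        more = dict(base)
        more["E1"] = base["E1"] | {"B"}
        s0 = pe_score(base, baits).scores[("A", "B")]
        s1 = pe_score(more, baits).scores[("A", "B")]
        assert s1 >= s0
        # and the reference implementation agrees on both instances
        assert s0 == pytest.approx(pe_reference(base, baits)[("A", "B")], abs=1e-10)
        assert s1 == pytest.approx(pe_reference(more, baits)[("A", "B")], abs=1e-10)

    def test_missing_bait_metadata_errors(self):
        sets = {"E0": frozenset(["A", "B"])}
        with pytest.raises(ValueError, match="bait"):
            sai_score(sets, {})
        with pytest.raises(ValueError, match="bait"):
            pe_score(sets, {})


class TestPresenceSets:
    def _realization(self):
        return BinaryRealization(
            prey_ids=["A", "B", "C"],
            experiment_ids=["e1", "e2"],
            cells=np.array([[1, 0], [1, 0], [1, 0]]),
            bait_of={"e1": "C", "e2": "D"},
            is_control={"e2": True},
        )

    def test_bait_added_without_double_count(self):
        sets = presence_sets(self._realization(), use_controls=True)
        assert sets["e1"] == frozenset(["A", "B", "C"])  # bait C already a prey
        assert sets["e2"] == frozenset(["D"])  # all-zero column: bait only

    def test_all_zero_column_without_bait_is_empty(self):
        r = self._realization()
        sets = presence_sets(r, include_bait=False, use_controls=True)
        assert sets["e2"] == frozenset()

    def test_controls_excluded_by_default(self):
        assert "e2" not in presence_sets(self._realization())

    def test_include_bait_requires_metadata(self):
        r = self._realization()
        r.bait_of = {}
        with pytest.raises(ValueError, match="bait"):
            presence_sets(r, include_bait=True)


class TestBaselineAndDispatch:
    def test_spectral_sum_over_replicates(self):
        m = SpectralCountMatrix(
            prey_ids=["P", "Q"],
            experiment_ids=["r1", "r2", "c1"],
            counts=np.array([[3, 2, 9], [0, 0, 1]]),
            bait_of={"r1": "B", "r2": "B", "c1": "B"},
            is_control={"c1": True},
        )
        scores = spectral_sum_baseline(m).scores
        assert scores[("B", "P")] == 5.0  # control column ignored
        assert ("B", "Q") not in scores  # all-zero under non-control columns

    def test_spectral_sum_distinct_baits_distinct_pairs(self):
        m = SpectralCountMatrix(
            prey_ids=["P"],
            experiment_ids=["e1", "e2"],
            counts=np.array([[2, 4]]),
            bait_of={"e1": "B1", "e2": "B2"},
        )
        scores = spectral_sum_baseline(m).scores
        assert scores == {("B1", "P"): 2.0, ("B2", "P"): 4.0}

    def test_spectral_sum_requires_baits(self):
        m = SpectralCountMatrix(["P"], ["e1"], np.array([[2]]))
        with pytest.raises(ValueError, match="bait"):
            spectral_sum_baseline(m)

    def test_score_realization_universe_and_determinism(self):
        r = BinaryRealization(
            prey_ids=["A", "B", "C"],
            experiment_ids=["e1"],
            cells=np.array([[1], [1], [1]]),
        )
        spec = ScorerSpec("hart_poisson")
        t1 = score_realization(r, spec, include_bait=False)
        t2 = score_realization(r, spec, include_bait=False)
        assert set(t1.scores) == {("A", "B"), ("A", "C"), ("B", "C")}
        assert t1.scores == t2.scores

    def test_all_zero_realization_empty_table(self):
        r = BinaryRealization(
            prey_ids=["A"], experiment_ids=["e1"], cells=np.array([[0]])
        )
        assert score_realization(r, ScorerSpec("hart_poisson"),
                                 include_bait=False).scores == {}

    def test_cooccurrence_count_scores_are_x(self):
        r = BinaryRealization(
            prey_ids=["A", "B"],
            experiment_ids=["e1", "e2"],
            cells=np.array([[1, 1], [1, 1]]),
        )
        table = score_realization(r, ScorerSpec("cooccurrence_count"),
                                  include_bait=False)
        assert table.scores == {("A", "B"): 2.0}
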