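"""Binary-matrix PPI scoring methods applied to a single 0/1 realization.

All scorers here consume binary presence data (one :class:`BinaryRealization`)
and produce a confidence score per unordered protein pair.  The workhorse is
the null-model score of Hart et al.: under the null, interaction partners are
paired at random in proportion to how often each protein co-purifies, so the
expected number of co-purifications of proteins A and B is

    lambda_AB = N_A / N * N_B / N * N,

where ``X_AB`` is the number of experiments in which A and B co-purify,
``N_A`` is the number of co-purifying pairs protein A takes part in
(sum over experiments containing A of ``s_e - 1`` with ``s_e`` the number of
proteins present in experiment e), and ``N`` is the total number of
co-purifying pairs (sum of ``C(s_e, 2)``).  The score is the negative log of
an upper-tail probability of X_AB under the null — hypergeometric in the
original method, or its Poisson approximation ``-log(1 - PoissonCDF(X; λ))``
which becomes accurate for large studies.

Socio-affinity (SAI) and purification-enrichment (PE) style scores combine
spoke evidence (bait retrieves prey) with matrix evidence (two preys
co-purify under other baits) as log-odds against frequency-based null rates;
see docs/methods.md for the exact forms used here.

Scores are in natural log throughout; tail probabilities are floored at
1e-300 before the log so every score is finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats as _stats

from .data import (
    BinaryRealization,
    Pair,
    PairScoreTable,
    SpectralCountMatrix,
    canonical_pair,
)

TAIL_FLOOR = 1e-300

KNOWN_SCORERS = (
    "hart_poisson",
    "hart_hypergeometric",
    "sai",
    "pe",
    "cooccurrence_count",
)
#: Scorers that use direct bait->prey (spoke) evidence and therefore need
#: bait metadata and a bait-prey candidate universe.
SPOKE_AWARE = frozenset({"sai", "pe"})

_DEFAULT_PARAMS = {
    "hart_poisson": {"tail": "gt"},
    "hart_hypergeometric": {"tail": "gt"},
    "sai": {},
    "pe": {"r": 0.3, "n_pseudo": 10},
    "cooccurrence_count": {},
}


@dataclass
class ScorerSpec:
    """A scorer name plus its parameter record, validated and defaulted."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in KNOWN_SCORERS:
            raise ValueError(
                f"unknown scorer {self.name!r}; valid options: "
                + ", ".join(KNOWN_SCORERS)
            )
        merged = dict(_DEFAULT_PARAMS[self.name])
        for key, value in self.params.items():
            if key not in merged:
                raise ValueError(f"unknown parameter {key!r} for scorer {self.name}")
            merged[key] = value
        if self.name == "pe":
            r = float(merged["r"])
            if not (0.0 < r < 1.0):
                raise ValueError(f"PE parameter r must be in (0, 1), got {r}")
            n_pseudo = merged["n_pseudo"]
            if n_pseudo < 0:
                raise ValueError(f"PE parameter n_pseudo must be >= 0, got {n_pseudo}")
            merged["r"] = r
        if self.name.startswith("hart") and merged["tail"] not in ("gt", "ge"):
            raise ValueError(f"tail must be 'gt' or 'ge', got {merged['tail']!r}")
        self.params = merged

    @property
    def spoke_aware(self) -> bool:
        return self.name in SPOKE_AWARE


# ---------------------------------------------------------------------------
# Presence sets and co-occurrence statistics
# ---------------------------------------------------------------------------

def presence_sets(
    realization: BinaryRealization,
    include_bait: bool = True,
    use_controls: bool = False,
) -> dict:
    """Per-experiment protein sets from a binary realization.

    Experiment ``e`` maps to the set of preys with a 1 in column ``e``,
    plus the bait of ``e`` when ``include_bait`` is set (a purification
    physically contains its bait).  Control columns are dropped unless
    ``use_controls`` is set.
    """
    if include_bait and not realization.bait_of:
        raise ValueError("include_bait requires bait metadata")
    preys = np.asarray(realization.prey_ids, dtype=object)
    out = {}
    for j, exp in enumerate(realization.experiment_ids):
        if realization.control_flag(exp) and not use_controls:
            continue
        members = set(preys[realization.cells[:, j] > 0])
        if include_bait and exp in realization.bait_of:
            members.add(realization.bait_of[exp])
        out[exp] = frozenset(members)
    return out


def _presence_matrix(sets: Mapping) -> tuple:
    """Dense boolean proteins x experiments matrix for a set-of-sets input.

    Returns ``(B, proteins)`` with proteins sorted for determinism.
    """
    proteins = sorted(set().union(*sets.values())) if sets else []
    index = {p: i for i, p in enumerate(proteins)}
    exp_ids = list(sets)
    B = np.zeros((len(proteins), len(exp_ids)), dtype=np.float64)
    for j, e in enumerate(exp_ids):
        for p in sets[e]:
            B[index[p], j] = 1.0
    return B, proteins


def _pair_stats_arrays(B: np.ndarray) -> tuple:
    """Co-occurrence arrays from a boolean presence matrix.

    Returns ``(i_idx, j_idx, x, n_of, n_total)`` where ``(i_idx, j_idx)``
    index the upper-triangle pairs with at least one co-occurrence, ``x``
    their co-purification counts, ``n_of`` the per-protein co-purifying pair
    incidences and ``n_total`` the total number of co-purifying pairs.
    """
    if B.size == 0:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty, empty, np.zeros(B.shape[0], dtype=np.int64), 0
    s = B.sum(axis=0)
    X = B @ B.T
    n_of = (B * np.maximum(s - 1.0, 0.0)).sum(axis=1)
    n_total = int(round((s * (s - 1.0) / 2.0).sum()))
    iu, ju = np.triu_indices(B.shape[0], k=1)
    x = X[iu, ju]
    keep = x >= 1
    return (
        iu[keep].astype(np.int64),
        ju[keep].astype(np.int64),
        np.rint(x[keep]).astype(np.int64),
        np.rint(n_of).astype(np.int64),
        n_total,
    )


@dataclass
class CooccurrenceStats:
    """Co-occurrence statistics of one binary realization.

    ``X`` stores only pairs with at least one co-occurrence; ``lambda_of``
    is computable on demand for any pair of observed proteins.
    """

    proteins: list
    X: dict
    N_of: dict
    N_total: int

    def x_of(self, a: str, b: str) -> int:
        return self.X.get(canonical_pair(a, b), 0)

    def lambda_of(self, a: str, b: str) -> float:
        if self.N_total <= 0:
            return 0.0
        return self.N_of.get(a, 0) * self.N_of.get(b, 0) / self.N_total


def cooccurrence_stats(sets: Mapping) -> CooccurrenceStats:
    """Compute X_AB, N_A, N and lambda machinery from per-experiment sets."""
    B, proteins = _presence_matrix(sets)
    i_idx, j_idx, x, n_of, n_total = _pair_stats_arrays(B)
    X = {
        (proteins[i], proteins[j]): int(v)
        for i, j, v in zip(i_idx, j_idx, x)
    }
    return CooccurrenceStats(
        proteins=proteins,
        X=X,
        N_of={p: int(n) for p, n in zip(proteins, n_of)},
        N_total=n_total,
    )


# ---------------------------------------------------------------------------
# Hart null-model scores
# ---------------------------------------------------------------------------

def poisson_tail_score(x, lam, tail: str = "gt"):
    """-log upper-tail Poisson probability, vectorized.

    ``tail='gt'`` scores P[Poisson(lam) > x] (the printed 1 - CDF(x) form);
    ``tail='ge'`` scores P[Poisson(lam) >= x].  Pairs with a degenerate null
    (lam == 0) score 0.
    """
    x = np.asarray(x, dtype=np.int64)
    lam = np.asarray(lam, dtype=np.float64)
    k = x if tail == "gt" else x - 1
    p = _stats.poisson.sf(k, np.where(lam > 0, lam, 1.0))
    score = -np.log(np.maximum(p, TAIL_FLOOR))
    score = np.where(lam > 0, score, 0.0)
    return score if score.ndim else float(score)


def hypergeom_tail_score(x, n_a, n_b, n_total, tail: str = "gt"):
    """-log upper-tail hypergeometric probability, vectorized.

    The null draws ``n_b`` of ``n_total`` co-purifying pair slots with
    ``n_a`` of them marked; the observed overlap is ``x``.  Symmetric in
    (n_a, n_b).  Degenerate nulls (any marginal 0) score 0.
    """
    x = np.asarray(x, dtype=np.int64)
    n_a = np.asarray(n_a, dtype=np.int64)
    n_b = np.asarray(n_b, dtype=np.int64)
    n_tot = np.asarray(n_total, dtype=np.int64)
    if np.any(n_a > n_tot) or np.any(n_b > n_tot):
        raise ValueError("per-protein incidence N_A exceeds total pairs N")
    ok = (n_a > 0) & (n_b > 0) & (n_tot > 0)
    k = x if tail == "gt" else x - 1
    p = _stats.hypergeom.sf(
        k,
        np.where(ok, n_tot, 1),
        np.where(ok, n_a, 0),
        np.where(ok, n_b, 0),
    )
    score = -np.log(np.maximum(p, TAIL_FLOOR))
    score = np.where(ok, score, 0.0)
    return score if score.ndim else float(score)


def hart_poisson_score(stats: CooccurrenceStats, pair: Pair, tail: str = "gt") -> float:
    """Hart score via the Poisson approximation for one pair."""
    a, b = canonical_pair(*pair)
    return float(poisson_tail_score(stats.x_of(a, b), stats.lambda_of(a, b), tail))


def hart_hypergeometric_score(
    stats: CooccurrenceStats, pair: Pair, tail: str = "gt"
) -> float:
    """Original hypergeometric Hart score for one pair."""
    a, b = canonical_pair(*pair)
    return float(
        hypergeom_tail_score(
            stats.x_of(a, b),
            stats.N_of.get(a, 0),
            stats.N_of.get(b, 0),
            stats.N_total,
            tail,
        )
    )


# ---------------------------------------------------------------------------
# SAI and PE
# ---------------------------------------------------------------------------

def _spoke_matrix_counts(sets: Mapping, bait_of: Mapping):
    """Shared bookkeeping for the spoke/matrix scorers.

    Returns per-protein experiment sets, per-bait experiment lists, retrieval
    frequencies f_i, and the list of experiments used.
    """
    if not bait_of:
        raise ValueError("spoke-aware scorers require bait metadata")
    exp_ids = list(sets)
    missing = [e for e in exp_ids if e not in bait_of]
    if missing:
        raise ValueError(f"experiments without bait metadata: {missing[:5]}")
    exps_of: dict = {}
    for e in exp_ids:
        for p in sets[e]:
            exps_of.setdefault(p, set()).add(e)
    bait_exps: dict = {}
    for e in exp_ids:
        bait_exps.setdefault(bait_of[e], []).append(e)
    n_purif = len(exp_ids)
    f = {p: len(es) / n_purif for p, es in exps_of.items()}
    return exps_of, bait_exps, f, exp_ids


def _candidate_pairs(sets: Mapping, bait_of: Mapping) -> set:
    """Co-occurring pairs plus observed bait-prey pairs."""
    pairs = set()
    exps_of: dict = {}
    for e, members in sets.items():
        ms = sorted(members)
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                pairs.add((a, b))
        bait = bait_of.get(e)
        if bait is not None:
            for p in members:
                if p != bait:
                    pairs.add(canonical_pair(bait, p))
    return pairs


def sai_score(sets: Mapping, bait_of: Mapping) -> PairScoreTable:
    """Socio-affinity-style index over candidate pairs.

    SAI(i, j) = S(i|j) + S(j|i) + M(i, j), each term a log-odds of observed
    versus expected retrievals under independence:

    - spoke S(i|j) = log(o / (f_i * n_j)) where o is the number of bait-j
      purifications retrieving i, n_j the number of bait-j purifications and
      f_i the overall retrieval frequency of i;
    - matrix M(i, j) = log(m / (f_i * f_j * n_purif)) where m counts
      purifications (bait neither i nor j) containing both.

    A term with zero observed retrievals contributes 0, keeping every score
    finite; a pair never seen together and never retrieved by each other
    therefore scores 0 (<= 0 per the finiteness/sign contract).
    """
    exps_of, bait_exps, f, exp_ids = _spoke_matrix_counts(sets, bait_of)
    n_purif = len(exp_ids)

    def spoke(i: str, j: str) -> float:
        exps_j = bait_exps.get(j, ())
        if not exps_j:
            return 0.0
        o = sum(1 for e in exps_j if i in sets[e])
        if o == 0:
            return 0.0
        return math.log(o / (f[i] * len(exps_j)))

    def matrix_term(i: str, j: str) -> float:
        both = exps_of.get(i, set()) & exps_of.get(j, set())
        m = sum(1 for e in both if bait_of[e] not in (i, j))
        if m == 0:
            return 0.0
        return math.log(m / (f[i] * f[j] * n_purif))

    scores = {}
    for (a, b) in _candidate_pairs(sets, bait_of):
        scores[(a, b)] = spoke(a, b) + spoke(b, a) + matrix_term(a, b)
    return PairScoreTable(scores=scores, scorer="sai")


def pe_score(
    sets: Mapping,
    bait_of: Mapping,
    r: float = 0.3,
    n_pseudo: float = 10,
) -> PairScoreTable:
    """Purification-enrichment-style log-likelihood-ratio score.

    ``r`` is the probability of detecting a true association in a
    purification; ``n_pseudo`` pseudo-observations at the average retrieval
    rate regularize each prey's frequency estimate.  Spoke terms accumulate
    log(r / f_i) per bait-j purification retrieving i and
    log((1-r) / (1-f_i)) per bait-j purification missing it; matrix terms
    treat purifications of third-party baits where at least one of the pair
    appears, comparing co-retrieval against the independence rate f_i * f_j.
    """
    if not (0.0 < r < 1.0):
        raise ValueError(f"r must be in (0, 1), got {r}")
    if n_pseudo < 0:
        raise ValueError(f"n_pseudo must be >= 0, got {n_pseudo}")
    exps_of, bait_exps, f_raw, exp_ids = _spoke_matrix_counts(sets, bait_of)
    n_purif = len(exp_ids)
    proteins = sorted(exps_of)
    f0 = (
        sum(len(es) for es in exps_of.values()) / (len(proteins) * n_purif)
        if proteins
        else 0.0
    )
    def f(p: str) -> float:
        # pseudocount-regularized retrieval frequency; a protein never seen
        # as prey (e.g. a bait outside the presence sets) gets the
        # pseudocount-only rate
        raw = len(exps_of.get(p, ()))
        return min(max((raw + n_pseudo * f0) / (n_purif + n_pseudo), 1e-9), 1.0 - 1e-9)

    def spoke(i: str, j: str) -> float:
        exps_j = bait_exps.get(j, ())
        if not exps_j:
            return 0.0
        o = sum(1 for e in exps_j if i in sets[e])
        return o * math.log(r / f(i)) + (len(exps_j) - o) * math.log(
            (1.0 - r) / (1.0 - f(i))
        )

    def matrix_term(i: str, j: str) -> float:
        ei = {e for e in exps_of.get(i, set()) if bait_of[e] not in (i, j)}
        ej = {e for e in exps_of.get(j, set()) if bait_of[e] not in (i, j)}
        both = len(ei & ej)
        only_i = len(ei - ej)
        only_j = len(ej - ei)
        f_max = max(f(i), f(j))
        total = 0.0
        if both:
            total += both * math.log(r * f_max / (f(i) * f(j)))
        if only_i:
            total += only_i * math.log((1.0 - r) / (1.0 - f(j)))
        if only_j:
            total += only_j * math.log((1.0 - r) / (1.0 - f(i)))
        return total

    scores = {}
    for (a, b) in _candidate_pairs(sets, bait_of):
        scores[(a, b)] = spoke(a, b) + spoke(b, a) + matrix_term(a, b)
    return PairScoreTable(
        scores=scores, scorer="pe", params={"r": r, "n_pseudo": n_pseudo}
    )


# ---------------------------------------------------------------------------
# Baseline and dispatch
# ---------------------------------------------------------------------------

def spectral_sum_baseline(matrix: SpectralCountMatrix) -> PairScoreTable:
    """Rank bait-prey pairs by summed spectral counts.

    For each bait-prey pair observed with a positive count, the score is the
    sum of that prey's counts over all non-control experiments of that bait.
    """
    if not matrix.bait_of:
        raise ValueError("spectral-count baseline requires bait metadata")
    scores: dict = {}
    for j, exp in enumerate(matrix.experiment_ids):
        if matrix.control_flag(exp) or exp not in matrix.bait_of:
            continue
        bait = matrix.bait_of[exp]
        col = matrix.counts[:, j]
        for i in np.nonzero(col)[0]:
            prey = matrix.prey_ids[i]
            if prey == bait:
                continue
            pair = canonical_pair(bait, prey)
            scores[pair] = scores.get(pair, 0.0) + float(col[i])
    return PairScoreTable(scores=scores, scorer="spectral_sum_baseline")


def _score_binary_arrays(B: np.ndarray, spec: ScorerSpec) -> tuple:
    """Vectorized Hart/co-occurrence scoring of a presence matrix.

    Returns ``(i_idx, j_idx, scores)`` over pairs with X >= 1.
    """
    i_idx, j_idx, x, n_of, n_total = _pair_stats_arrays(B)
    if spec.name == "cooccurrence_count":
        return i_idx, j_idx, x.astype(np.float64)
    if spec.name == "hart_poisson":
        lam = (
            n_of[i_idx] * n_of[j_idx] / n_total
            if n_total > 0
            else np.zeros(len(i_idx))
        )
        return i_idx, j_idx, np.atleast_1d(
            poisson_tail_score(x, lam, spec.params["tail"])
        )
    if spec.name == "hart_hypergeometric":
        return i_idx, j_idx, np.atleast_1d(
            hypergeom_tail_score(
                x, n_of[i_idx], n_of[j_idx], n_total, spec.params["tail"]
            )
        )
    raise ValueError(f"no array path for scorer {spec.name}")


def score_realization(
    realization: BinaryRealization,
    spec: ScorerSpec,
    include_bait: bool = True,
    use_controls: bool = False,
) -> PairScoreTable:
    """Apply one binary scorer to one realization.

    The candidate universe is every pair co-purifying at least once in the
    realization, plus observed bait-prey pairs for the spoke-aware scorers.
    Deterministic for fixed input.
    """
    sets = presence_sets(
        realization,
        include_bait=include_bait and bool(realization.bait_of),
        use_controls=use_controls,
    )
    if spec.name == "sai":
        return sai_score(sets, realization.bait_of)
    if spec.name == "pe":
        return pe_score(
            sets,
            realization.bait_of,
            r=spec.params["r"],
            n_pseudo=spec.params["n_pseudo"],
        )
    B, proteins = _presence_matrix(sets)
    i_idx, j_idx, scores = _score_binary_arrays(B, spec)
    table = {
        (proteins[i], proteins[j]): float(s)
        for i, j, s in zip(i_idx, j_idx, scores)
    }
    return PairScoreTable(scores=table, scorer=spec.name, params=dict(spec.params))
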