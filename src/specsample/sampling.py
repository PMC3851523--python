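"""Ensemble sampling of binary realizations from spectral counts.

Spectral counts span a huge dynamic range, and collapsing them to 0/1 —
required by most co-occurrence scorers — discards the information that a
count of 40 is far stronger evidence than a count of 1.  The sampling
framework keeps the binary scorers untouched and instead represents the
quantitative matrix by an ensemble of binary matrices:

1. each count ``n`` becomes a probability ``1 - (1 - p)**n`` that the
   observation is real, where ``p`` is the reliability of a single spectral
   count (default 0.3);
2. each ensemble member is drawn by independent Bernoulli sampling of every
   cell at its probability;
3. the chosen binary scorer runs on every member;
4. per-pair scores are averaged over the ensemble (optionally clamped from
   below first, which matters for scorers with unbounded negative values
   such as SAI).

With ``p = 1`` the ensemble degenerates to the direct binarization (every
positive count becomes 1), the comparator the framework improves upon.

Randomness is counter-based: trial ``t`` uses a Philox stream keyed by
``(seed, t)``, and cell ``(i, j)`` consumes the draw at flat position
``i * n_cols + j`` of that stream.  Each cell's draw is therefore a pure
function of (seed, trial, row, column), so serial and parallel execution —
and any evaluation order — give identical ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats as _stats

from .data import BinaryRealization, PairScoreTable, SpectralCountMatrix
from .scorers import (
    ScorerSpec,
    _presence_matrix,
    _score_binary_arrays,
    presence_sets,
    pe_score,
    sai_score,
)

logger = logging.getLogger(__name__)


def count_to_probability(n, p: float):
    """Probability that a spectral count of ``n`` reflects a true observation.

    Each of the ``n`` counts independently has probability ``p`` of being a
    true observation, so the cell is real with probability ``1 - (1-p)**n``.
    Accepts scalars or arrays; strictly increasing in ``n`` for ``p < 1``
    and 0 at ``n = 0``.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    n_arr = np.asarray(n)
    if n_arr.size and (np.any(n_arr < 0) or not np.all(n_arr == np.floor(n_arr))):
        raise ValueError("spectral counts must be non-negative integers")
    if p == 1.0:
        out = (n_arr > 0).astype(np.float64)
    else:
        # -expm1(n*log1p(-p)) evaluates 1-(1-p)^n without cancellation
        out = -np.expm1(n_arr * np.log1p(-p))
    return float(out) if np.isscalar(n) else out


@dataclass
class ProbabilityMatrix:
    """Per-cell true-observation probabilities, same shape/ids as the source."""

    prey_ids: list
    experiment_ids: list
    probs: np.ndarray
    bait_of: dict = field(default_factory=dict)
    is_control: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.shape != (len(self.prey_ids), len(self.experiment_ids)):
            raise ValueError("probs shape does not match identifier lists")
        if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        self.probs = probs


def build_probability_matrix(
    matrix: SpectralCountMatrix, p: float
) -> ProbabilityMatrix:
    """Elementwise count->probability conversion preserving shape and ids."""
    return ProbabilityMatrix(
        prey_ids=list(matrix.prey_ids),
        experiment_ids=list(matrix.experiment_ids),
        probs=count_to_probability(matrix.counts, p)
        if matrix.counts.size
        else np.zeros_like(matrix.counts, dtype=np.float64),
        bait_of=dict(matrix.bait_of),
        is_control=dict(matrix.is_control),
    )


def _uniforms(seed: int, trial_index: int, shape: tuple) -> np.ndarray:
    """Counter-based uniform draws for one trial (pure in seed and trial)."""
    if seed < 0 or trial_index < 0:
        raise ValueError("seed and trial_index must be non-negative")
    gen = np.random.Generator(np.random.Philox(key=[seed, trial_index]))
    return gen.random(shape)


def sample_realization(
    probs: ProbabilityMatrix, seed: int, trial_index: int
) -> BinaryRealization:
    """Draw one binary realization by independent per-cell Bernoulli sampling."""
    u = _uniforms(seed, trial_index, probs.probs.shape)
    return BinaryRealization(
        prey_ids=list(probs.prey_ids),
        experiment_ids=list(probs.experiment_ids),
        cells=(u < probs.probs).astype(np.int8),
        trial_index=trial_index,
        bait_of=dict(probs.bait_of),
        is_control=dict(probs.is_control),
    )


def binarize(matrix: SpectralCountMatrix) -> BinaryRealization:
    """Direct binarization: every positive count becomes 1."""
    return BinaryRealization(
        prey_ids=list(matrix.prey_ids),
        experiment_ids=list(matrix.experiment_ids),
        cells=(matrix.counts > 0).astype(np.int8),
        trial_index=0,
        bait_of=dict(matrix.bait_of),
        is_control=dict(matrix.is_control),
    )


@dataclass
class EnsembleConfig:
    """Configuration of one ensemble run.

    ``clamp_floor="auto"`` resolves to 0 for SAI (whose scores are unbounded
    below, so a single realization could otherwise dominate the mean) and to
    no clamping for every other scorer.  ``trial_offset`` shifts the trial
    indices, giving disjoint randomness for independent ensembles under one
    seed.
    """

    scorer: ScorerSpec
    p: float = 0.3
    trials: int = 120
    seed: int = 0
    clamp_floor: object = "auto"
    include_bait: bool = True
    use_controls: bool = False
    trial_offset: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.trials < 1:
            raise ValueError(f"trials must be >= 1, got {self.trials}")

    def resolved_clamp(self) -> Optional[float]:
        if self.clamp_floor == "auto":
            return 0.0 if self.scorer.name == "sai" else None
        return self.clamp_floor


def _realization_scores(
    realization: BinaryRealization, config: EnsembleConfig
) -> dict:
    """Name-keyed per-pair scores of one realization under the config scorer."""
    spec = config.scorer
    sets = presence_sets(
        realization,
        include_bait=config.include_bait and bool(realization.bait_of),
        use_controls=config.use_controls,
    )
    if spec.name == "sai":
        return sai_score(sets, realization.bait_of).scores
    if spec.name == "pe":
        return pe_score(
            sets,
            realization.bait_of,
            r=spec.params["r"],
            n_pseudo=spec.params["n_pseudo"],
        ).scores
    B, proteins = _presence_matrix(sets)
    i_idx, j_idx, scores = _score_binary_arrays(B, spec)
    return {
        (proteins[i], proteins[j]): float(s)
        for i, j, s in zip(i_idx, j_idx, scores)
    }


def ensemble_score(
    matrix: SpectralCountMatrix, config: EnsembleConfig
) -> PairScoreTable:
    """Sample, score and aggregate an ensemble of binary realizations.

    The candidate universe is fixed up front from the direct binarization of
    the raw counts (a superset of every realization's co-occurrences), plus
    observed bait-prey pairs for spoke-aware scorers; a universe pair absent
    from a realization's score table contributes 0 for that trial.  The
    aggregate is the arithmetic mean over trials, computed as the first
    trial's score plus the mean deviation from it (numerically this removes
    the common magnitude before summing, and makes a deterministic ensemble
    — e.g. ``p = 1`` — reproduce the single-realization scores exactly).
    """
    spec = config.scorer
    base = binarize(matrix)
    base_sets = presence_sets(
        base,
        include_bait=config.include_bait and bool(base.bait_of),
        use_controls=config.use_controls,
    )
    universe = _universe_pairs(base_sets, base.bait_of if spec.spoke_aware else {})
    universe = sorted(universe)
    if not universe:
        return PairScoreTable(scores={}, scorer=spec.name, params=dict(spec.params))
    key_of = {pair: k for k, pair in enumerate(universe)}

    probs = build_probability_matrix(matrix, config.p)
    clamp = config.resolved_clamp()
    first = None
    dev_sum = np.zeros(len(universe), dtype=np.float64)
    for t in range(config.trials):
        realization = sample_realization(
            probs, config.seed, config.trial_offset + t
        )
        table = _realization_scores(realization, config)
        vec = np.zeros(len(universe), dtype=np.float64)
        for pair, s in table.items():
            if clamp is not None and s < clamp:
                s = clamp
            vec[key_of[pair]] = s
        if first is None:
            first = vec
        else:
            dev_sum += vec - first
        if (t + 1) % 10 == 0 or t + 1 == config.trials:
            logger.info(
                "ensemble %s: trial %d/%d", spec.name, t + 1, config.trials
            )
    mean = first + dev_sum / config.trials
    return PairScoreTable(
        scores={pair: float(s) for pair, s in zip(universe, mean)},
        scorer=spec.name,
        params={
            **spec.params,
            "p": config.p,
            "trials": config.trials,
            "seed": config.seed,
            "clamp_floor": clamp,
        },
    )


def _universe_pairs(sets, bait_of) -> set:
    """Pairs with X >= 1 in the base binarization, plus bait-prey pairs."""
    from .scorers import _candidate_pairs

    return _candidate_pairs(sets, bait_of)


def ensemble_stability(
    matrix: SpectralCountMatrix, config: EnsembleConfig, factor: int
) -> float:
    """Spearman rank agreement between an ensemble and one ``factor`` x larger.

    The larger ensemble uses disjoint trial indices, so the two rankings are
    independent given the data.  Returns 1.0 exactly when the two score
    vectors are identical (e.g. the deterministic ``p = 1`` ensemble).
    """
    if factor < 2:
        raise ValueError(f"factor must be >= 2, got {factor}")
    small = ensemble_score(matrix, config)
    big_cfg = replace(
        config,
        trials=config.trials * factor,
        trial_offset=config.trial_offset + config.trials,
    )
    big = ensemble_score(matrix, big_cfg)
    pairs = sorted(small.scores)
    x = np.array([small.scores[p] for p in pairs])
    y = np.array([big.scores[p] for p in pairs])
    if np.array_equal(x, y):
        return 1.0
    rho = _stats.spearmanr(x, y).statistic
    return float(rho)
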