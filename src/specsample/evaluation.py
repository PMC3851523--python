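"""Top-K validation of ranked PPI predictions against gold standards.

The protocol compares the highest-confidence K predictions against
reference-pair subsets at increasingly stringent thresholds on the number
of supporting evidence sources, and reports validated counts absolutely and
relative to the spectral-count-ranking baseline.  Predicted pairs absent
from every gold source count as non-validated; gold pairs are matched
orientation-insensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .data import GoldStandard, PairScoreTable
from .sampling import EnsembleConfig, binarize, ensemble_score
from .scorers import ScorerSpec, score_realization


@dataclass
class EvaluationCurve:
    """Validated counts of the top-K predictions at one support threshold."""

    threshold: int
    cutoffs: list
    validated: list
    truncated: bool = False  # ranked list shorter than the largest cutoff

    def __post_init__(self) -> None:
        if list(self.cutoffs) != sorted(set(self.cutoffs)) or any(
            c <= 0 for c in self.cutoffs
        ):
            raise ValueError("cutoffs must be strictly increasing and positive")


def evaluate_topk(
    ranked: PairScoreTable,
    gold: GoldStandard,
    cutoffs: Sequence[int],
    thresholds: Sequence[int],
) -> list:
    """Count validated predictions among the top K, per support threshold.

    Returns one :class:`EvaluationCurve` per threshold.  If the ranked list
    is shorter than a cutoff the full list is used and the curve is flagged
    as truncated.
    """
    if len(ranked) == 0:
        raise ValueError("ranked table is empty")
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be positive integers")
    order = ranked.ranked()
    curves = []
    for t in thresholds:
        reference = gold.pairs_at(t)
        validated = []
        hits = 0
        pos = 0
        for cutoff in sorted(set(cutoffs)):
            top = min(cutoff, len(order))
            while pos < top:
                if order[pos] in reference:
                    hits += 1
                pos += 1
            validated.append(hits)
        curves.append(
            EvaluationCurve(
                threshold=t,
                cutoffs=sorted(set(cutoffs)),
                validated=validated,
                truncated=len(order) < max(cutoffs),
            )
        )
    return curves


def relative_to_baseline(curves: Iterable, baseline: Iterable) -> list:
    """Elementwise validated-count differences (method - baseline).

    Both curve lists must share thresholds and cutoff grids.
    """
    curves = list(curves)
    baseline = list(baseline)
    if len(curves) != len(baseline):
        raise ValueError("mismatched number of curves")
    out = []
    for c, b in zip(curves, baseline):
        if c.threshold != b.threshold or c.cutoffs != b.cutoffs:
            raise ValueError("mismatched threshold/cutoff grids")
        out.append(
            replace(c, validated=[x - y for x, y in zip(c.validated, b.validated)])
        )
    return out


def average_precision(
    ranked: PairScoreTable, gold: GoldStandard, threshold: int = 1
) -> float:
    """Average precision of a ranking against gold pairs at a threshold.

    Normalized by the number of gold pairs at the threshold (full-recall
    convention), so reference pairs the ranking never reaches count against
    it.  Returns 0 when the reference set is empty.
    """
    reference = gold.pairs_at(threshold)
    if not reference:
        return 0.0
    hits = 0
    total = 0.0
    for rank, pair in enumerate(ranked.ranked(), start=1):
        if pair in reference:
            hits += 1
            total += hits / rank
    return total / len(reference)


def sweep_p(
    matrix,
    scorer: ScorerSpec,
    p_values: Sequence[float],
    gold: GoldStandard,
    cutoff: int,
    threshold: int = 1,
    trials: int = 120,
    seed: int = 0,
    include_bait: bool = True,
    use_controls: bool = False,
) -> list:
    """Improvement of the sampled ensemble over direct binarization vs ``p``.

    For each reliability value, improvement = validated count of the
    ensemble's top ``cutoff`` predictions minus that of the same scorer on
    the direct binarization (the ``p = 1`` path).  Returns a list of
    ``(p, improvement)`` tuples.
    """
    if any(not (0.0 < p <= 1.0) for p in p_values):
        raise ValueError("p values must lie in (0, 1]")
    direct = score_realization(
        binarize(matrix), scorer, include_bait=include_bait, use_controls=use_controls
    )
    base_count = evaluate_topk(direct, gold, [cutoff], [threshold])[0].validated[0]
    out = []
    for p in p_values:
        config = EnsembleConfig(
            scorer=scorer,
            p=p,
            trials=trials,
            seed=seed,
            include_bait=include_bait,
            use_controls=use_controls,
        )
        table = ensemble_score(matrix, config)
        count = evaluate_topk(table, gold, [cutoff], [threshold])[0].validated[0]
        out.append((p, count - base_count))
    return out


def curves_table(method_curves: dict, baseline_curves: list) -> list:
    """Flatten per-method curves into rows for TSV output.

    Rows are ``(method, threshold, cutoff, validated, baseline_validated,
    difference)``.
    """
    rows = []
    base_by_t = {c.threshold: c for c in baseline_curves}
    for method in sorted(method_curves):
        for c in method_curves[method]:
            b = base_by_t.get(c.threshold)
            for cutoff, v in zip(c.cutoffs, c.validated):
                bv = (
                    b.validated[b.cutoffs.index(cutoff)]
                    if b is not None and cutoff in b.cutoffs
                    else 0
                )
                rows.append((method, c.threshold, cutoff, v, bv, v - bv))
    return rows
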