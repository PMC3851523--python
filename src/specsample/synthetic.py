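"""Synthetic AP-MS spectral-count generator with known ground truth.

The generator plants disjoint protein complexes, runs simulated bait
purifications against them and overlays a sticky-contaminant background, so
that every pipeline stage — and the central claim that sampling an ensemble
beats direct binarization — is testable without external data.

The model reproduces two robust qualitative features of real AP-MS count
matrices: positive contaminant counts concentrate at 1-2 (a geometric count
distribution), and the contaminant background is approximately rank-1 —
each protein has a fixed stickiness propensity (Dirichlet-distributed) that
applies across all purifications.  True co-complex preys are pulled down
with higher counts (shifted Poisson around ``mu_true``).

It does not attempt peptide-level realism: protein length and detectability
effects, MS1 intensities, and control purifications are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import GoldStandard, SpectralCountMatrix, canonical_pair


@dataclass
class GenerativeParams:
    """Parameters of the synthetic AP-MS study.

    The default preset is a contaminant-heavy regime: 300 proteins of which
    200 form 40 five-member complexes (100 background-only), 150 bait
    purifications, true-prey detection probability 0.7 with mean true count
    6, and on average 8 sticky contaminants per purification with counts
    mostly 1-2 (geometric with success 0.6).
    """

    n_proteins: int = 300
    n_complexes: int = 40
    complex_size: object = 5  # int, or (lo, hi) range sampled per complex
    n_experiments: int = 150
    baits_per_complex: int = 3
    p_detect_true: float = 0.7
    mu_true: float = 6.0
    stickiness_dirichlet_alpha: float = 0.5
    contaminant_rate: float = 8.0
    contaminant_geom_p: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_complexes", "n_experiments", "baits_per_complex"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("p_detect_true", "contaminant_geom_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.mu_true < 1.0:
            raise ValueError("mu_true must be >= 1 (counts are 1 + Poisson)")
        if self.contaminant_rate < 0:
            raise ValueError("contaminant_rate must be >= 0")
        if self.stickiness_dirichlet_alpha <= 0:
            raise ValueError("stickiness_dirichlet_alpha must be > 0")

    def sizes(self, rng: np.random.Generator) -> list:
        if isinstance(self.complex_size, int):
            sizes = [self.complex_size] * self.n_complexes
        else:
            lo, hi = self.complex_size
            sizes = list(rng.integers(lo, hi + 1, size=self.n_complexes))
        if any(s < 2 for s in sizes):
            raise ValueError("complexes must have at least 2 members")
        return sizes


@dataclass
class GroundTruth:
    """Planted complex membership, true co-complex pairs, experiment baits."""

    complex_of: dict
    true_pairs: set
    bait_list: list  # bait protein per experiment, in experiment order


def _protein_names(n: int) -> list:
    width = len(str(n))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def generate_truth(params: GenerativeParams) -> GroundTruth:
    """Plant disjoint complexes and pick baits; deterministic given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    sizes = params.sizes(rng)
    if sum(sizes) > params.n_proteins:
        raise ValueError(
            f"complexes need {sum(sizes)} proteins but only "
            f"{params.n_proteins} available"
        )
    proteins = _protein_names(params.n_proteins)
    order = list(rng.permutation(params.n_proteins))
    complex_of: dict = {}
    true_pairs: set = set()
    bait_pool: list = []
    start = 0
    for cid, size in enumerate(sizes):
        members = [proteins[k] for k in order[start : start + size]]
        start += size
        for m in members:
            complex_of[m] = cid
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                true_pairs.add(canonical_pair(a, b))
        n_baits = min(params.baits_per_complex, size)
        picked = rng.choice(len(members), size=n_baits, replace=False)
        bait_pool.extend(members[k] for k in sorted(picked))
    # cycle the bait pool until every experiment has a bait (extra passes are
    # replicate purifications of the same bait)
    bait_list = [bait_pool[e % len(bait_pool)] for e in range(params.n_experiments)]
    return GroundTruth(
        complex_of=complex_of, true_pairs=true_pairs, bait_list=bait_list
    )


@dataclass
class SyntheticDataset:
    """A simulated study: counts + metadata, planted truth, and provenance."""

    matrix: SpectralCountMatrix
    truth: GroundTruth
    gold: GoldStandard
    true_cell_counts: list = field(default_factory=list)
    contaminant_cell_counts: list = field(default_factory=list)


def simulate_counts(
    truth: GroundTruth,
    params: GenerativeParams,
    _collect: Optional[SyntheticDataset] = None,
) -> SpectralCountMatrix:
    """Simulate a prey x experiment count matrix over the planted truth.

    Per experiment with bait b, each co-complex partner of b is detected
    with probability ``p_detect_true`` and contributes ``1 + Poisson(mu_true
    - 1)`` counts; a Poisson(``contaminant_rate``) number of contaminant
    preys is drawn (without replacement) in proportion to protein-specific
    stickiness weights, each contributing ``Geometric(contaminant_geom_p)``
    counts.  Colliding contributions add.  Baits get no count in their own
    row; their presence travels via the bait metadata.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    proteins = _protein_names(params.n_proteins)
    index = {p: i for i, p in enumerate(proteins)}
    members_of: dict = {}
    for p, cid in truth.complex_of.items():
        members_of.setdefault(cid, []).append(p)
    stickiness = rng.dirichlet(
        np.full(params.n_proteins, params.stickiness_dirichlet_alpha)
    )
    counts = np.zeros((params.n_proteins, params.n_experiments), dtype=np.int64)
    exp_ids = [f"E{j + 1:03d}" for j in range(params.n_experiments)]
    bait_of: dict = {}
    replicate_group: dict = {}
    for j, bait in enumerate(truth.bait_list):
        bait_of[exp_ids[j]] = bait
        replicate_group[exp_ids[j]] = bait
        partners = [
            m for m in sorted(members_of.get(truth.complex_of.get(bait, -1), []))
            if m != bait
        ]
        for m in partners:
            if rng.random() < params.p_detect_true:
                c = 1 + rng.poisson(params.mu_true - 1.0)
                counts[index[m], j] += c
                if _collect is not None:
                    _collect.true_cell_counts.append(int(c))
        k = rng.poisson(params.contaminant_rate)
        if k > 0:
            picked = rng.choice(
                params.n_proteins,
                size=min(k, params.n_proteins),
                replace=False,
                p=stickiness,
            )
            for i in picked:
                if proteins[i] == bait:
                    continue
                c = rng.geometric(params.contaminant_geom_p)
                counts[i, j] += c
                if _collect is not None:
                    _collect.contaminant_cell_counts.append(int(c))
    return SpectralCountMatrix(
        prey_ids=proteins,
        experiment_ids=exp_ids,
        counts=counts,
        bait_of=bait_of,
        replicate_group=replicate_group,
        is_control={e: False for e in exp_ids},
    )


def labels_as_gold(truth: GroundTruth) -> GoldStandard:
    """Planted co-complex pairs as a single-source gold standard."""
    return GoldStandard(support={pair: 1 for pair in truth.true_pairs})


def simulate(params: Optional[GenerativeParams] = None) -> SyntheticDataset:
    """Generate a full synthetic study (truth, counts, gold) in one call."""
    params = params if params is not None else GenerativeParams()
    truth = generate_truth(params)
    dataset = SyntheticDataset(
        matrix=None, truth=truth, gold=labels_as_gold(truth)
    )
    dataset.matrix = simulate_counts(truth, params, _collect=dataset)
    return dataset
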