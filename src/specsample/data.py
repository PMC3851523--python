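"""Core data model and TSV I/O for AP-MS protein-interaction analysis.

The central object is the spectral-count matrix: rows are prey proteins,
columns are purification experiments, and entries are non-negative integer
spectral counts.  Experiment metadata attaches a bait protein, a replicate
group and a control flag to each column.  Gold standards map unordered
protein pairs to the number of independent evidence sources supporting
them; ranked prediction lists are written as deterministic TSV.

Protein identifiers are opaque, case-sensitive strings compared exactly.
Zero is a stored count, not "missing": the TSV dialect has no NA token, so
absent data must be encoded as 0 by the producer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: An unordered protein pair in canonical form: a 2-tuple (a, b) with a < b.
Pair = tuple


class ParseError(ValueError):
    """A malformed input file (bad cell, bad line, duplicate identifier)."""


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical (lexicographically sorted) form of a protein pair.

    Self-pairs are forbidden: a protein cannot be its own interaction partner.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ParseError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class SpectralCountMatrix:
    """Prey x experiment matrix of spectral counts with experiment metadata.

    Parameters
    ----------
    prey_ids:
        Row identifiers (prey proteins), unique.
    experiment_ids:
        Column identifiers (purification experiments), unique.
    counts:
        Integer array of shape ``(len(prey_ids), len(experiment_ids))``,
        all entries >= 0.
    bait_of:
        Optional map experiment id -> bait protein id.
    is_control:
        Optional map experiment id -> bool; experiments absent from the map
        are treated as non-control.
    replicate_group:
        Optional map experiment id -> replicate-group label.  Replicate
        columns are treated as independent experiments by every scorer; the
        grouping is carried only for bookkeeping.
    """

    prey_ids: list
    experiment_ids: list
    counts: np.ndarray
    bait_of: dict = field(default_factory=dict)
    is_control: dict = field(default_factory=dict)
    replicate_group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prey_ids = list(self.prey_ids)
        self.experiment_ids = list(self.experiment_ids)
        _check_unique(self.prey_ids, "prey")
        _check_unique(self.experiment_ids, "experiment")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.prey_ids), len(self.experiment_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.prey_ids)} preys x {len(self.experiment_ids)} experiments"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integral")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at prey {self.prey_ids[i]!r}, "
                f"experiment {self.experiment_ids[j]!r}"
            )
        self.counts = counts
        known = set(self.experiment_ids)
        for name, mapping in (
            ("bait_of", self.bait_of),
            ("is_control", self.is_control),
            ("replicate_group", self.replicate_group),
        ):
            for e in mapping:
                if e not in known:
                    raise ValueError(f"{name} references unknown experiment {e!r}")

    @property
    def n_preys(self) -> int:
        return len(self.prey_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def control_flag(self, experiment_id: str) -> bool:
        return bool(self.is_control.get(experiment_id, False))


@dataclass
class BinaryRealization:
    """One 0/1 matrix of the same shape as its source count matrix.

    A realization is either the direct binarization of the counts or one
    member of the sampled ensemble (``trial_index`` records which).
    Cells are 0 wherever the source count was 0.
    """

    prey_ids: list
    experiment_ids: list
    cells: np.ndarray
    trial_index: int = 0
    bait_of: dict = field(default_factory=dict)
    is_control: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.shape != (len(self.prey_ids), len(self.experiment_ids)):
            raise ValueError("cells shape does not match identifier lists")
        if cells.size and not np.isin(cells, (0, 1)).all():
            raise ValueError("realization cells must be 0 or 1")
        self.cells = cells.astype(np.int8)

    def control_flag(self, experiment_id: str) -> bool:
        return bool(self.is_control.get(experiment_id, False))


@dataclass
class PairScoreTable:
    """Map from canonical protein pairs to finite real confidence scores."""

    scores: dict
    scorer: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, s in self.scores.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for pair {pair}: {s}")

    def ranked(self) -> list:
        """Pairs sorted by descending score; ties broken by (a, b) ascending."""
        return sorted(self.scores, key=lambda pr: (-self.scores[pr], pr))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class GoldStandard:
    """Unordered reference pairs with their number of supporting sources."""

    support: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, k in self.support.items():
            if k < 1:
                raise ValueError(f"support must be >= 1, got {k} for {pair}")

    def pairs_at(self, threshold: int) -> set:
        """Pairs supported by at least ``threshold`` distinct sources."""
        return {p for p, k in self.support.items() if k >= threshold}

    def __len__(self) -> int:
        return len(self.support)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path, metadata_path=None) -> SpectralCountMatrix:
    """Read a spectral-count matrix from TSV.

    The first row holds experiment ids (its first cell is a corner label and
    is ignored); the first column holds prey ids; every body cell must be a
    non-negative integer — a missing cell is an error, not a zero.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    experiment_ids = header[1:]
    prey_ids = []
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(experiment_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(experiment_ids) + 1} cells, "
                f"got {len(cells)}"
            )
        prey = cells[0]
        row = []
        for j, cell in enumerate(cells[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer count {cell!r} at prey "
                    f"{prey!r}, experiment {experiment_ids[j]!r}"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{path}:{lineno}: negative count {value} at prey "
                    f"{prey!r}, experiment {experiment_ids[j]!r}"
                )
            row.append(value)
        prey_ids.append(prey)
        rows.append(row)
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(experiment_ids)), dtype=np.int64)
    )
    bait_of: dict = {}
    is_control: dict = {}
    replicate_group: dict = {}
    if metadata_path is not None:
        bait_of, replicate_group, is_control = read_experiment_metadata(metadata_path)
    return SpectralCountMatrix(
        prey_ids=prey_ids,
        experiment_ids=experiment_ids,
        counts=counts,
        bait_of=bait_of,
        is_control=is_control,
        replicate_group=replicate_group,
    )


def read_experiment_metadata(path):
    """Read experiment metadata TSV.

    Columns: ``experiment_id``, ``bait_id``, ``replicate_group``,
    ``is_control`` (0/1).  Returns ``(bait_of, replicate_group, is_control)``
    dictionaries; an empty ``bait_id`` cell leaves the experiment unmapped.
    """
    expected = ["experiment_id", "bait_id", "replicate_group", "is_control"]
    bait_of: dict = {}
    replicate_group: dict = {}
    is_control: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != expected:
            raise ParseError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 cells, got {len(cells)}")
            exp, bait, group, ctrl = cells
            if exp in bait_of or exp in is_control:
                raise ParseError(f"{path}:{lineno}: duplicate experiment {exp!r}")
            if ctrl not in ("0", "1"):
                raise ParseError(
                    f"{path}:{lineno}: is_control must be 0 or 1, got {ctrl!r}"
                )
            if bait:
                bait_of[exp] = bait
            if group:
                replicate_group[exp] = group
            is_control[exp] = ctrl == "1"
    return bait_of, replicate_group, is_control


def write_count_matrix(matrix: SpectralCountMatrix, path) -> None:
    """Write a count matrix as deterministic TSV (stored order, LF endings)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(["prey"] + matrix.experiment_ids) + "\n")
        for i, prey in enumerate(matrix.prey_ids):
            row = "\t".join(str(int(c)) for c in matrix.counts[i])
            fh.write(prey + ("\t" + row if matrix.n_experiments else "") + "\n")


def write_experiment_metadata(matrix: SpectralCountMatrix, path) -> None:
    """Write the experiment metadata of ``matrix`` as TSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("experiment_id\tbait_id\treplicate_group\tis_control\n")
        for e in matrix.experiment_ids:
            fh.write(
                "\t".join(
                    [
                        e,
                        matrix.bait_of.get(e, ""),
                        matrix.replicate_group.get(e, ""),
                        "1" if matrix.control_flag(e) else "0",
                    ]
                )
                + "\n"
            )


def read_gold_standard(paths: Iterable) -> GoldStandard:
    """Read gold-standard edge lists and count distinct supporting sources.

    Each file is either a two-column edge list (the whole file is one
    source) or a three-column list whose third column is a source label.
    Pairs are canonicalized, duplicates within one source count once, and
    self-pairs are dropped with a logged warning.
    """
    sources_of: dict = {}
    for file_index, path in enumerate(paths):
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                cells = line.split("\t")
                if len(cells) == 2:
                    a, b = cells
                    source = f"file:{file_index}"
                elif len(cells) == 3:
                    a, b, source = cells
                else:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 or 3 columns, got {len(cells)}"
                    )
                if not a or not b:
                    raise ParseError(f"{path}:{lineno}: empty protein identifier")
                if a == b:
                    logger.warning(
                        "%s:%d: dropping self-pair (%s, %s)", path, lineno, a, b
                    )
                    continue
                sources_of.setdefault(canonical_pair(a, b), set()).add(source)
    return GoldStandard(support={p: len(s) for p, s in sources_of.items()})


def write_gold_standard(gold: GoldStandard, path) -> None:
    """Write a gold standard as a three-column TSV with synthetic source tags.

    A pair supported by k sources is emitted on k lines with source labels
    ``s1..sk`` so that re-reading recovers the same support counts.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for (a, b) in sorted(gold.support):
            for k in range(gold.support[(a, b)]):
                fh.write(f"{a}\t{b}\ts{k + 1}\n")


def write_ranked_pairs(table: PairScoreTable, path) -> None:
    """Write a score table as ranked TSV: protein_a, protein_b, score, rank.

    Rows are sorted by descending score with ties broken by (a, b)
    lexicographic ascending; output bytes are deterministic.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("protein_a\tprotein_b\tscore\trank\n")
        for rank, (a, b) in enumerate(table.ranked(), start=1):
            fh.write(f"{a}\t{b}\t{table.scores[(a, b)]!r}\t{rank}\n")


def read_ranked_pairs(path) -> PairScoreTable:
    """Read a ranked-pairs TSV back into a :class:`PairScoreTable`."""
    scores: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_a", "protein_b", "score"]:
            raise ParseError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            scores[canonical_pair(cells[0], cells[1])] = float(cells[2])
    return PairScoreTable(scores=scores)
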