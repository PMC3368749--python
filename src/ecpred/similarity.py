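"""Reaction and mechanism similarity.

Two of the five descriptor sets are similarity matrices: each entry is
described by its similarity to every reference entry.  *Overall reaction
similarity* is the count-vector Tanimoto coefficient between overall
bond-change vectors, computed in the stored (canonical) direction only.
*Mechanistic similarity* aligns the ordered steps of two mechanisms with a
global Needleman-Wunsch procedure — step-vs-step Tanimoto as the match
score — and takes the better of the as-stored and one-reversed direction.

The column-deletion rule used during cross-validation (drop reference
columns belonging to the held-out entries before training) is implemented
here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .reaction_model import BondChangeVector, ReactionEntry, reverse_entry

__all__ = [
    "AlignmentResult",
    "tanimoto",
    "overall_reaction_similarity",
    "align_mechanisms",
    "mechanism_similarity",
    "similarity_matrix",
    "delete_test_columns",
]


def tanimoto(a: BondChangeVector, b: BondChangeVector) -> float:
    """Count-vector Tanimoto: sum of min counts over sum of max counts.

    Reduces to the binary Tanimoto coefficient on 0/1 vectors.  Two empty
    vectors score 1 (identity of nothing); empty vs non-empty scores 0.
    """
    inter = sum(min(c, b.get(t)) for t, c in a.items())
    union = a.total() + b.total() - inter
    if union == 0:
        return 1.0
    return inter / union


def overall_reaction_similarity(a: ReactionEntry, b: ReactionEntry) -> float:
    """Tanimoto of overall bond changes, canonical direction only."""
    return tanimoto(a.overall_changes, b.overall_changes)


@dataclass
class AlignmentResult:
    """Outcome of a global step alignment.

    ``pairs`` lists aligned step indices, with ``None`` marking a gap;
    ``normalized_similarity`` is the optimal score divided by the longer
    mechanism's step count, which keeps it in [0, 1] for any non-negative
    gap penalty.
    """

    score: float
    pairs: List[Tuple[Optional[int], Optional[int]]]
    normalized_similarity: float


def align_mechanisms(steps_a: Sequence[BondChangeVector],
                     steps_b: Sequence[BondChangeVector],
                     gap_penalty: float = 0.0) -> AlignmentResult:
    """Global Needleman-Wunsch alignment of two step sequences.

    Match score for a step pair is their Tanimoto similarity; gaps incur a
    linear penalty of ``gap_penalty`` per unaligned step.
    """
    if not steps_a or not steps_b:
        raise ValueError("cannot align an empty mechanism")
    if gap_penalty < 0:
        raise ValueError("gap penalty must be non-negative")
    n, m = len(steps_a), len(steps_b)
    sim = np.array([[tanimoto(sa, sb) for sb in steps_b] for sa in steps_a])

    score = np.zeros((n + 1, m + 1))
    score[1:, 0] = -gap_penalty * np.arange(1, n + 1)
    score[0, 1:] = -gap_penalty * np.arange(1, m + 1)
    # 0 = diagonal (match), 1 = up (gap in b), 2 = left (gap in a)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            options = (score[i - 1, j - 1] + sim[i - 1, j - 1],
                       score[i - 1, j] - gap_penalty,
                       score[i, j - 1] - gap_penalty)
            best = int(np.argmax(options))
            score[i, j] = options[best]
            move[i, j] = best

    pairs: List[Tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if move[i, j] == 0:
            pairs.append((i - 1, j - 1)); i -= 1; j -= 1
        elif move[i, j] == 1:
            pairs.append((i - 1, None)); i -= 1
        else:
            pairs.append((None, j - 1)); j -= 1
    pairs.reverse()

    final = float(score[n, m])
    return AlignmentResult(score=final, pairs=pairs,
                           normalized_similarity=max(final, 0.0) / max(n, m))


def mechanism_similarity(a: ReactionEntry, b: ReactionEntry,
                         gap_penalty: float = 0.0) -> float:
    """Normalized mechanism alignment score, best over reaction direction.

    The alignment is computed with both mechanisms as stored, then
    recomputed with one reversed; the higher similarity is selected, so the
    measure is insensitive to the arbitrary direction of annotation.
    """
    forward = align_mechanisms(a.mechanism, b.mechanism, gap_penalty)
    flipped = align_mechanisms(a.mechanism, reverse_entry(b).mechanism, gap_penalty)
    return max(forward.normalized_similarity, flipped.normalized_similarity)


_MODES = ("overall", "mechanism")


def similarity_matrix(entries: Sequence[ReactionEntry],
                      reference_entries: Sequence[ReactionEntry],
                      mode: str = "overall",
                      gap_penalty: float = 0.0) -> DescriptorMatrix:
    """Entries x reference-entries similarity table.

    Columns are named by reference entry ids so that cross-validation can
    delete the columns of held-out entries.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if not entries or not reference_entries:
        raise ValueError("need non-empty entry and reference lists")
    if mode == "overall":
        fn = overall_reaction_similarity
    else:
        fn = lambda a, b: mechanism_similarity(a, b, gap_penalty)
    # Cache symmetric values when rows and columns share entries.
    cache: dict = {}
    data = np.empty((len(entries), len(reference_entries)))
    for i, e in enumerate(entries):
        for j, r in enumerate(reference_entries):
            key = (e.entry_id, r.entry_id) if e.entry_id <= r.entry_id \
                else (r.entry_id, e.entry_id)
            if key not in cache:
                cache[key] = fn(e, r)
            data[i, j] = cache[key]
    return DescriptorMatrix(pd.DataFrame(
        data, index=[e.entry_id for e in entries],
        columns=[r.entry_id for r in reference_entries], dtype=float))


def delete_test_columns(matrix: DescriptorMatrix,
                        test_ids: Sequence[str]) -> DescriptorMatrix:
    """Drop similarity columns that belong to held-out entries.

    Leaves the row set unchanged; raises if deletion would remove every
    column.
    """
    drop = set(test_ids)
    keep = [c for c in matrix.feature_names if c not in drop]
    if not keep:
        raise ValueError("deleting test columns would leave an empty matrix")
    return DescriptorMatrix(matrix.df[keep], scaling=None)
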