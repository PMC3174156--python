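"""De-duplication, ranking and hot-spot mapping of probe locations."""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["jaccard", "merge_locations", "rank_locations", "hotspot_count"]


def jaccard(a, b) -> float:
    """|a∩b| / |a∪b|; two empty sets are defined as similarity 0."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _similarity_matrix(residue_sets: list[frozenset]) -> np.ndarray:
    m = len(residue_sets)
    universe = sorted(set().union(*residue_sets)) if residue_sets else []
    index = {r: c for c, r in enumerate(universe)}
    member = np.zeros((m, len(universe)), dtype=bool)
    for i, s in enumerate(residue_sets):
        for r in s:
            member[i, index[r]] = True
    inter = (member.astype(np.int32) @ member.T.astype(np.int32)).astype(float)
    sizes = member.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(sim, 0.0)
    return sim


def merge_locations(
    locations: Sequence, lc_scores: Sequence[float], threshold: float = 0.7
) -> tuple[list, list[float]]:
    """Greedy de-duplication of probe locations by Jaccard similarity.

    Repeatedly finds the most similar pair above ``threshold`` and drops the
    member with the lower LC score (most similar pairs first), until no pair
    exceeds the threshold.  Returns surviving (locations, lc_scores) ordered
    by LC score descending.  Residue sets are read from ``.residues`` when
    present, else each location is treated as a residue set itself.
    """
    if len(locations) != len(lc_scores):
        raise ValueError("one LC score per location required")
    if not locations:
        return [], []
    residue_sets = [
        frozenset(getattr(loc, "residues", loc)) for loc in locations
    ]
    sim = _similarity_matrix(residue_sets)
    lc = np.asarray(lc_scores, dtype=float)
    alive = np.ones(len(locations), dtype=bool)
    while True:
        masked = np.where(alive[:, None] & alive[None, :], sim, -1.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        # drop the lower-LC member; ties resolved toward the later index
        drop = i if (lc[i] < lc[j]) or (lc[i] == lc[j] and i > j) else j
        alive[drop] = False
    survivors = np.flatnonzero(alive)
    order = survivors[np.lexsort((survivors, -lc[survivors]))]
    return [locations[k] for k in order], [float(lc[k]) for k in order]


def rank_locations(
    locations: Sequence, scores: Sequence[float], lc_scores: Sequence[float] | None = None
) -> list[int]:
    """Indices sorting locations by score descending; ties broken by LC score
    then by insertion order, for determinism."""
    scores = np.asarray(scores, dtype=float)
    lc = (
        np.zeros_like(scores)
        if lc_scores is None
        else np.asarray(lc_scores, dtype=float)
    )
    idx = np.arange(len(scores))
    return list(np.lexsort((idx, -lc, -scores)))


def hotspot_count(
    ranked_locations: Sequence, x: float, n_residues: int
) -> np.ndarray:
    """Per-residue count f_i(x): appearances in the top ⌈x·M⌉ ranked locations.

    f_i(1) is the plain distribution of probe locations over residues.
    """
    if not 0.0 < x <= 1.0:
        raise ValueError("x must be in (0, 1]")
    m = len(ranked_locations)
    top = int(np.ceil(x * m))
    counts = np.zeros(n_residues, dtype=int)
    for loc in ranked_locations[:top]:
        for r in set(getattr(loc, "residues", loc)):
            counts[int(r)] += 1
    return counts
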