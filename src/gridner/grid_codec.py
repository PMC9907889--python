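"""Encoding entity mentions as a word-pair relation grid and decoding back.

The grid replaces per-token sequence tags: for every ordered word pair
``(i, j)`` of an ``n``-token sentence, one relation label is stored.

* ``NNW`` (next-neighboring-word) at ``(i, j)`` with ``i < j``: the two words
  are successive members of the same entity (upper triangle).
* ``THW-t`` (tail-head-word, carrying entity type ``t``) at ``(i, j)`` with
  ``i >= j``: word ``i`` is the last and word ``j`` the first word of an
  entity of type ``t`` (lower triangle; single-token entities sit on the
  diagonal).
* ``NONE`` everywhere else.

Decoding treats NNW cells as directed edges of a graph and emits a mention
``(s, e, t)`` whenever the cell ``(e, s)`` holds ``THW-t`` and some increasing
NNW path leads from ``s`` to ``e`` (depth-first search); THW cells with no
such path are dropped and counted in the diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import EntityMention, LabeledSentence

__all__ = [
    "NONE",
    "NNW",
    "RelationSet",
    "RelationGrid",
    "GridDiagnostics",
    "encode_grid",
    "decode_grid",
    "validate_grid",
    "grid_to_json",
    "grid_from_json",
]

NONE = "NONE"
NNW = "NNW"


class RelationSet:
    """Ordered label set: NONE at 0, NNW at 1, then THW-<type> per entity type."""

    def __init__(self, entity_types: Sequence[str]):
        types = list(dict.fromkeys(entity_types))
        if not types:
            raise ValueError("at least one entity type is required")
        self.entity_types = types
        self.labels = [NONE, NNW] + [f"THW-{t}" for t in types]
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown relation label {label!r}") from None

    def thw_index(self, etype: str) -> int:
        return self.index(f"THW-{etype}")

    def type_of(self, label_index: int) -> str:
        label = self.labels[label_index]
        if not label.startswith("THW-"):
            raise ValueError(f"label {label} carries no entity type")
        return label[4:]

    @classmethod
    def from_corpus(cls, sentences: Iterable[LabeledSentence]) -> "RelationSet":
        types = sorted({t for s in sentences for t in s.entity_types})
        return cls(types or ["Entity"])


@dataclass
class RelationGrid:
    """n x n grid of relation-label indices into a RelationSet."""

    n: int
    cells: np.ndarray  # (n, n) int array

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (self.n, self.n):
            raise ValueError(f"cells must be {self.n}x{self.n}, got {self.cells.shape}")

    @classmethod
    def empty(cls, n: int) -> "RelationGrid":
        return cls(n, np.zeros((n, n), dtype=np.int64))


@dataclass
class GridDiagnostics:
    triangle_violations: int = 0
    unreachable_thw: int = 0
    uncovered_nnw: int = 0
    dropped_mentions: list[EntityMention] = field(default_factory=list)


def encode_grid(sentence: LabeledSentence, rset: RelationSet) -> RelationGrid:
    """Encode flat mentions: a k-token mention yields k-1 NNW cells on the
    adjacent upper off-diagonal and one THW cell at (end, start)."""
    n = len(sentence)
    grid = RelationGrid.empty(n)
    nnw = rset.index(NNW)
    for m in sorted(sentence.mentions):
        thw = rset.thw_index(m.etype)  # KeyError -> unknown type, hard error
        for k in range(m.start, m.end):
            grid.cells[k, k + 1] = nnw
        grid.cells[m.end, m.start] = thw
    return grid


def _nnw_adjacency(grid: RelationGrid, nnw_index: int) -> list[list[int]]:
    succ: list[list[int]] = [[] for _ in range(grid.n)]
    rows, cols = np.nonzero(grid.cells == nnw_index)
    for i, j in zip(rows.tolist(), cols.tolist()):
        if i < j:
            succ[i].append(j)
    return succ


def _path_exists(succ: list[list[int]], s: int, e: int) -> bool:
    if s == e:
        return True
    stack = [s]
    seen = {s}
    while stack:
        u = stack.pop()
        for v in succ[u]:
            if v == e:
                return True
            if v < e and v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def decode_grid(
    grid: RelationGrid,
    rset: RelationSet,
    thw_probs: np.ndarray | None = None,
    resolve_overlaps: bool | None = None,
    diagnostics: GridDiagnostics | None = None,
) -> frozenset[EntityMention]:
    """Decode a relation grid to entity mentions.

    Candidates are all (s, e, t) with ``THW-t`` at cell (e, s) and an NNW path
    from s to e. When ``thw_probs`` (an n x n array of the predicted THW cell
    probabilities) is given, overlapping candidates are resolved greedily:
    highest THW probability wins, ties broken by smaller start then longer
    span. Without probabilities all path-valid candidates are returned
    (encoded gold grids never conflict).
    """
    nnw = rset.index(NNW)
    succ = _nnw_adjacency(grid, nnw)
    candidates: list[EntityMention] = []
    rows, cols = np.nonzero(grid.cells >= 2)
    for e, s in zip(rows.tolist(), cols.tolist()):
        if e < s:
            continue  # triangle violation; ignored here, counted by validate_grid
        etype = rset.type_of(int(grid.cells[e, s]))
        if _path_exists(succ, s, e):
            candidates.append(EntityMention(s, e, etype))
        elif diagnostics is not None:
            diagnostics.unreachable_thw += 1
    if resolve_overlaps is None:
        resolve_overlaps = thw_probs is not None
    if not resolve_overlaps:
        return frozenset(candidates)

    def priority(m: EntityMention):
        p = float(thw_probs[m.end, m.start]) if thw_probs is not None else 1.0
        return (-p, m.start, -(m.end - m.start))

    chosen: list[EntityMention] = []
    for m in sorted(candidates, key=priority):
        if not any(m.overlaps(c) for c in chosen):
            chosen.append(m)
        elif diagnostics is not None:
            diagnostics.dropped_mentions.append(m)
    return frozenset(chosen)


def validate_grid(grid: RelationGrid, rset: RelationSet) -> GridDiagnostics:
    """Count structural violations: NNW outside the strict upper triangle or
    THW above the diagonal; THW cells without an NNW path; NNW edges not used
    by any decodable mention."""
    diag = GridDiagnostics()
    nnw = rset.index(NNW)
    n = grid.n
    succ = _nnw_adjacency(grid, nnw)
    covered: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(n):
            lab = int(grid.cells[i, j])
            if lab == nnw and i >= j:
                diag.triangle_violations += 1
            elif lab >= 2 and i < j:
                diag.triangle_violations += 1
    rows, cols = np.nonzero(grid.cells >= 2)
    for e, s in zip(rows.tolist(), cols.tolist()):
        if e < s:
            continue
        if not _path_exists(succ, s, e):
            diag.unreachable_thw += 1
        else:
            for u in range(s, e):
                for v in succ[u]:
                    if v <= e:
                        covered.add((u, v))
    for i in range(n):
        for j in succ[i]:
            if i < j and (i, j) not in covered:
                diag.uncovered_nnw += 1
    return diag


def grid_to_json(grid: RelationGrid, rset: RelationSet) -> str:
    cells = [
        [int(i), int(j), rset.labels[int(grid.cells[i, j])]]
        for i, j in zip(*np.nonzero(grid.cells))
    ]
    return json.dumps({"n": grid.n, "cells": cells})


def grid_from_json(text: str, rset: RelationSet) -> RelationGrid:
    obj = json.loads(text)
    grid = RelationGrid.empty(int(obj["n"]))
    for i, j, lab in obj["cells"]:
        grid.cells[int(i), int(j)] = rset.index(lab)
    return grid
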