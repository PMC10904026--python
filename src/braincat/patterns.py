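"""Stimulus battery generation.

The study's inputs are not images or sounds but binary activity patterns on
25x25 grids of excitatory cells: "grounding patterns" injected into the two
extrasylvian primary areas (V1, M1_L) stand for the perceptuomotor experience
of one object/action instance, and "word-form patterns" injected into the two
perisylvian primary areas (A1, M1_i) stand for spoken labels.

Battery design (defaults): 10 categories x 6 instances (3 trained + 3 novel).
Each instance activates 12 cells per grounding area: 6 cells shared by every
instance of its category (category-critical features) and 6 cells unique to
that instance (idiosyncratic features). Hence within-category instance pairs
overlap in exactly 50% of their cells and between-category pairs overlap in
none, each category occupies 6 + 36 = 42 distinct cells per area, and all
cells of one category are pairwise non-adjacent (Moore 8-neighbourhood) so
that co-activation cannot arise from mere spatial proximity. Word forms are
12-cell patterns per perisylvian area obeying the same rules: category terms
(CT) map 1-to-1 onto categories, proper names (PN) 1-to-1 onto trained
instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

GRID = 25
N_CELLS = GRID * GRID

GROUNDING_AREAS = ("V1", "M1_L")
WORDFORM_AREAS = ("A1", "M1_i")

CELLS_PER_PATTERN = 12
SHARED_PER_CATEGORY = 6
UNIQUE_PER_INSTANCE = 6
INSTANCES_PER_CATEGORY = 6
TRAINED_PER_CATEGORY = 3

_MAX_TRIES_PER_CELL = 10_000
_MAX_RESTARTS = 200


def cell_rc(idx: int) -> tuple[int, int]:
    """Flat cell index -> (row, col) on the 25x25 grid."""
    return divmod(int(idx), GRID)


def adjacent(a: int, b: int) -> bool:
    """Moore (8-neighbourhood) adjacency on the grid; a cell is not adjacent to itself."""
    ra, ca = cell_rc(a)
    rb, cb = cell_rc(b)
    return (a != b) and max(abs(ra - rb), abs(ca - cb)) <= 1


@dataclass(frozen=True)
class CellSet:
    """A set of cell indices in one model area."""

    area: str
    cells: frozenset[int]

    def __post_init__(self) -> None:
        if any(not (0 <= c < N_CELLS) for c in self.cells):
            raise ValueError("cell index outside the 25x25 grid")


@dataclass(frozen=True)
class GroundingPattern:
    instance_id: int          # 0..59
    category_id: int          # 0..9
    trained: bool
    shared: dict[str, frozenset[int]]   # area -> 6 category-shared cells
    unique: dict[str, frozenset[int]]   # area -> 6 instance-unique cells

    def cells(self, area: str) -> frozenset[int]:
        return self.shared[area] | self.unique[area]


@dataclass(frozen=True)
class WordFormPattern:
    symbol_id: int
    symbol_type: str          # "category-term" | "proper-name"
    target: int               # category_id for CT, instance_id for PN
    cells_by_area: dict[str, frozenset[int]]

    def cells(self, area: str) -> frozenset[int]:
        return self.cells_by_area[area]


@dataclass
class StimulusSet:
    """The full designed battery for one study."""

    seed: int
    n_categories: int
    grounding: list[GroundingPattern] = field(default_factory=list)
    ct_words: list[WordFormPattern] = field(default_factory=list)
    pn_words: dict[int, WordFormPattern] = field(default_factory=dict)  # instance_id -> PN

    @property
    def n_instances(self) -> int:
        return len(self.grounding)

    def instance(self, instance_id: int) -> GroundingPattern:
        return self.grounding[instance_id]

    def category_instances(self, category_id: int) -> list[GroundingPattern]:
        return [g for g in self.grounding if g.category_id == category_id]

    def trained_instances(self) -> list[GroundingPattern]:
        return [g for g in self.grounding if g.trained]


def _sample_disjoint_groups(
    rng: np.random.Generator,
    n_groups: int,
    cells_per_group: int,
) -> list[list[int]]:
    """Sample n_groups disjoint cell groups, each internally pairwise non-adjacent.

    Groups are filled round-robin (one cell per group per sweep) so late groups
    are not starved; a group whose candidate set empties triggers a restart of
    the whole draw with fresh randomness.
    """
    for _ in range(_MAX_RESTARTS):
        free = np.ones(N_CELLS, dtype=bool)
        blocked = np.zeros((n_groups, N_CELLS), dtype=bool)  # adjacency halo per group
        groups: list[list[int]] = [[] for _ in range(n_groups)]
        ok = True
        for _sweep in range(cells_per_group):
            order = rng.permutation(n_groups)
            for g in order:
                cand = np.flatnonzero(free & ~blocked[g])
                if cand.size == 0:
                    ok = False
                    break
                c = int(cand[rng.integers(cand.size)])
                groups[g].append(c)
                free[c] = False
                r, col = cell_rc(c)
                r0, r1 = max(0, r - 1), min(GRID, r + 2)
                c0, c1 = max(0, col - 1), min(GRID, col + 2)
                halo = np.zeros((GRID, GRID), dtype=bool)
                halo[r0:r1, c0:c1] = True
                blocked[g] |= halo.ravel()
            if not ok:
                break
        if ok:
            return groups
    raise RuntimeError(
        f"pattern generation failed after {_MAX_RESTARTS} restarts "
        f"({n_groups} groups x {cells_per_group} cells) — generator bug"
    )


def generate_stimulus_set(seed: int, n_categories: int = 10) -> StimulusSet:
    """Generate the complete battery, reproducibly from a seed.

    Grounding patterns for V1 and M1_L are drawn independently; the same holds
    for word forms in A1 and M1_i. CT and PN word forms are drawn jointly as
    disjoint symbols per area (they are never co-present in one condition, but
    disjointness keeps the batteries maximally controlled).
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBC]))
    n_cat = int(n_categories)
    cells_per_cat = SHARED_PER_CATEGORY + UNIQUE_PER_INSTANCE * INSTANCES_PER_CATEGORY
    if n_cat * cells_per_cat > N_CELLS:
        raise ValueError("battery does not fit on the grid")

    # --- grounding patterns: one independent draw per grounding area ---
    per_area_groups = {
        area: _sample_disjoint_groups(rng, n_cat, cells_per_cat)
        for area in GROUNDING_AREAS
    }
    grounding: list[GroundingPattern] = []
    for cat in range(n_cat):
        shared = {
            area: frozenset(per_area_groups[area][cat][:SHARED_PER_CATEGORY])
            for area in GROUNDING_AREAS
        }
        for k in range(INSTANCES_PER_CATEGORY):
            lo = SHARED_PER_CATEGORY + k * UNIQUE_PER_INSTANCE
            unique = {
                area: frozenset(per_area_groups[area][cat][lo:lo + UNIQUE_PER_INSTANCE])
                for area in GROUNDING_AREAS
            }
            grounding.append(
                GroundingPattern(
                    instance_id=cat * INSTANCES_PER_CATEGORY + k,
                    category_id=cat,
                    trained=k < TRAINED_PER_CATEGORY,
                    shared=shared,
                    unique=unique,
                )
            )

    # --- word forms: CT (one per category) + PN (one per trained instance) ---
    n_ct = n_cat
    n_pn = n_cat * TRAINED_PER_CATEGORY
    wf_groups = {
        area: _sample_disjoint_groups(rng, n_ct + n_pn, CELLS_PER_PATTERN)
        for area in WORDFORM_AREAS
    }
    ct_words = [
        WordFormPattern(
            symbol_id=c,
            symbol_type="category-term",
            target=c,
            cells_by_area={a: frozenset(wf_groups[a][c]) for a in WORDFORM_AREAS},
        )
        for c in range(n_ct)
    ]
    pn_words: dict[int, WordFormPattern] = {}
    trained_ids = [g.instance_id for g in grounding if g.trained]
    for k, inst_id in enumerate(trained_ids):
        pn_words[inst_id] = WordFormPattern(
            symbol_id=n_ct + k,
            symbol_type="proper-name",
            target=inst_id,
            cells_by_area={a: frozenset(wf_groups[a][n_ct + k]) for a in WORDFORM_AREAS},
        )

    return StimulusSet(seed=int(seed), n_categories=n_cat,
                       grounding=grounding, ct_words=ct_words, pn_words=pn_words)


def _check_group(cells: Iterable[int], label: str, out: list[str]) -> None:
    cells = sorted(cells)
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            if adjacent(a, b):
                out.append(f"adjacency: {label}: cells {a} and {b} are Moore-adjacent")


def validate_constraints(s: StimulusSet) -> list[str]:
    """Report every violated battery constraint (empty list means valid).

    Checks, per grounding area: 6+6 cell counts, identical shared cells within
    a category, unique cells globally unique, zero between-category overlap,
    pairwise non-adjacency of each category's full cell set, and V1/M1_L
    patterns not identical for any instance. Word forms are checked with the
    same rules (12 cells, cross-symbol disjointness, within-symbol
    non-adjacency, A1/M1_i not identical). Never raises.
    """
    out: list[str] = []
    cats = sorted({g.category_id for g in s.grounding})
    for area in GROUNDING_AREAS:
        union_by_cat: dict[int, set[int]] = {}
        seen_unique: dict[int, int] = {}
        for g in s.grounding:
            if len(g.shared[area]) != SHARED_PER_CATEGORY:
                out.append(f"count: instance {g.instance_id} {area}: "
                           f"{len(g.shared[area])} shared cells (expected {SHARED_PER_CATEGORY})")
            if len(g.unique[area]) != UNIQUE_PER_INSTANCE:
                out.append(f"count: instance {g.instance_id} {area}: "
                           f"{len(g.unique[area])} unique cells (expected {UNIQUE_PER_INSTANCE})")
            if g.shared[area] & g.unique[area]:
                out.append(f"overlap: instance {g.instance_id} {area}: shared and unique cells intersect")
            for c in g.unique[area]:
                if c in seen_unique and seen_unique[c] != g.instance_id:
                    out.append(f"unique-cell reuse: {area} cell {c} appears in instances "
                               f"{seen_unique[c]} and {g.instance_id}")
                seen_unique[c] = g.instance_id
            union_by_cat.setdefault(g.category_id, set()).update(g.cells(area))
        for cat in cats:
            members = [g for g in s.grounding if g.category_id == cat]
            ref = members[0].shared[area]
            for g in members[1:]:
                if g.shared[area] != ref:
                    out.append(f"shared-cell mismatch: category {cat} {area}: "
                               f"instance {g.instance_id} has different shared cells")
            _check_group(union_by_cat[cat], f"category {cat} {area}", out)
        for i, a_cat in enumerate(cats):
            for b_cat in cats[i + 1:]:
                ov = union_by_cat[a_cat] & union_by_cat[b_cat]
                if ov:
                    out.append(f"between-category overlap: {area}: categories {a_cat} and {b_cat} "
                               f"share {len(ov)} cell(s)")
    for g in s.grounding:
        if g.cells("V1") == g.cells("M1_L"):
            out.append(f"identical areas: instance {g.instance_id}: V1 and M1_L patterns coincide")

    symbols = list(s.ct_words) + list(s.pn_words.values())
    for area in WORDFORM_AREAS:
        for w in symbols:
            if len(w.cells(area)) != CELLS_PER_PATTERN:
                out.append(f"count: symbol {w.symbol_id} {area}: "
                           f"{len(w.cells(area))} cells (expected {CELLS_PER_PATTERN})")
            _check_group(w.cells(area), f"symbol {w.symbol_id} {area}", out)
        for i, wa in enumerate(symbols):
            for wb in symbols[i + 1:]:
                if wa.cells(area) & wb.cells(area):
                    out.append(f"between-symbol overlap: {area}: symbols "
                               f"{wa.symbol_id} and {wb.symbol_id} share cells")
    for w in symbols:
        if w.cells("A1") == w.cells("M1_i"):
            out.append(f"identical areas: symbol {w.symbol_id}: A1 and M1_i patterns coincide")
    return out


def category_cell_census(s: StimulusSet, category_id: int, area: str) -> tuple[int, int]:
    """(distinct shared cells, distinct union-of-unique cells) for one category/area."""
    members = s.category_instances(category_id)
    if not members:
        raise KeyError(f"unknown category {category_id}")
    if area not in GROUNDING_AREAS:
        raise KeyError(f"{area} is not a grounding area")
    shared: set[int] = set()
    unique: set[int] = set()
    for g in members:
        shared |= g.shared[area]
        unique |= g.unique[area]
    return len(shared), len(unique)


# --- plain-text serialization -------------------------------------------------

def to_text(s: StimulusSet) -> str:
    """Serialize to a line-oriented text record (bit-identical reload)."""
    rec: dict = {"seed": s.seed, "n_categories": s.n_categories,
                 "grounding": [], "ct_words": [], "pn_words": []}
    for g in s.grounding:
        rec["grounding"].append({
            "instance_id": g.instance_id, "category_id": g.category_id,
            "trained": g.trained,
            "shared": {a: sorted(g.shared[a]) for a in GROUNDING_AREAS},
            "unique": {a: sorted(g.unique[a]) for a in GROUNDING_AREAS},
        })
    for w in s.ct_words:
        rec["ct_words"].append({
            "symbol_id": w.symbol_id, "target": w.target,
            "cells": {a: sorted(w.cells(a)) for a in WORDFORM_AREAS},
        })
    for inst_id in sorted(s.pn_words):
        w = s.pn_words[inst_id]
        rec["pn_words"].append({
            "symbol_id": w.symbol_id, "target": w.target,
            "cells": {a: sorted(w.cells(a)) for a in WORDFORM_AREAS},
        })
    return json.dumps(rec, indent=1, sort_keys=True)


def from_text(text: str) -> StimulusSet:
    rec = json.loads(text)
    grounding = [
        GroundingPattern(
            instance_id=g["instance_id"], category_id=g["category_id"],
            trained=bool(g["trained"]),
            shared={a: frozenset(g["shared"][a]) for a in GROUNDING_AREAS},
            unique={a: frozenset(g["unique"][a]) for a in GROUNDING_AREAS},
        )
        for g in rec["grounding"]
    ]
    ct_words = [
        WordFormPattern(symbol_id=w["symbol_id"], symbol_type="category-term",
                        target=w["target"],
                        cells_by_area={a: frozenset(w["cells"][a]) for a in WORDFORM_AREAS})
        for w in rec["ct_words"]
    ]
    pn_words = {
        w["target"]: WordFormPattern(symbol_id=w["symbol_id"], symbol_type="proper-name",
                                     target=w["target"],
                                     cells_by_area={a: frozenset(w["cells"][a]) for a in WORDFORM_AREAS})
        for w in rec["pn_words"]
    }
    return StimulusSet(seed=rec["seed"], n_categories=rec["n_categories"],
                       grounding=grounding, ct_words=ct_words, pn_words=pn_words)


def save(s: StimulusSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_text(s))


def load(path) -> StimulusSet:
    with open(path) as fh:
        return from_text(fh.read())
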