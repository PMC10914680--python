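"""Building blocks, silhouettes and the silhouette algebra.

Elementary building blocks are small polyomino shapes on an integer grid.
Compound stimuli ("silhouettes") are formed by placing one block on top of /
below / beside another so that the shapes touch but do not overlap.  The
module provides the geometric composition rule, the visual overlap metrics
used as confound regressors elsewhere, the conjunctive (block-in-relational-
position) code of a silhouette, role assignment for the four-block task
variant, and enumeration of silhouette-algebra triplets
(``WX - YX + YZ = WZ``) with their target/reference contrasts.

Grid convention: 0-based ``(row, col)``, row increases downward, so "on top"
means smaller row indices.  Every shape and silhouette is normalised so that
its minimum row and column are 0.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

Cell = tuple[int, int]


class CompositionError(ValueError):
    """Raised when two shapes cannot be legally composed."""


class InvalidInput(ValueError):
    """Raised for degenerate geometric inputs (e.g. an empty silhouette)."""


class InsufficientStimuli(ValueError):
    """Raised when a stimulus set is too small for triplet enumeration."""


class RoleError(ValueError):
    """Raised for inconsistent role assignments."""


class Relation(Enum):
    """Spatial relation between two blocks; on-top/below and left/right are
    mutual inverses."""

    ON_TOP = "on_top"
    BELOW = "below"
    LEFT_OF = "left_of"
    RIGHT_OF = "right_of"

    @property
    def inverse(self) -> "Relation":
        return _INVERSE[self]

    @property
    def axis(self) -> str:
        """'vertical' for on-top/below, 'horizontal' for left/right."""
        return "vertical" if self in (Relation.ON_TOP, Relation.BELOW) else "horizontal"

    @property
    def role_labels(self) -> tuple[str, str]:
        """(label of the first block, label of the second block)."""
        return _ROLES[self]


_INVERSE = {
    Relation.ON_TOP: Relation.BELOW,
    Relation.BELOW: Relation.ON_TOP,
    Relation.LEFT_OF: Relation.RIGHT_OF,
    Relation.RIGHT_OF: Relation.LEFT_OF,
}

_ROLES = {
    Relation.ON_TOP: ("top", "bottom"),
    Relation.BELOW: ("bottom", "top"),
    Relation.LEFT_OF: ("left", "right"),
    Relation.RIGHT_OF: ("right", "left"),
}

TEXTURES = ("bricks", "concrete", "steel", "wood")


def _normalize(cells: Iterable[Cell]) -> frozenset[Cell]:
    cells = list(cells)
    if not cells:
        raise InvalidInput("shape has no cells")
    rmin = min(r for r, _ in cells)
    cmin = min(c for _, c in cells)
    return frozenset((r - rmin, c - cmin) for r, c in cells)


def _connected(cells: frozenset[Cell]) -> bool:
    todo = [next(iter(cells))]
    seen = set(todo)
    while todo:
        r, c = todo.pop()
        for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if nb in cells and nb not in seen:
                seen.add(nb)
                todo.append(nb)
    return len(seen) == len(cells)


@dataclass(frozen=True)
class BlockShape:
    """An elementary building block: a connected polyomino with a label.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"W"``.
    cells : frozenset of (row, col)
        Grid cells, normalised so min row = min col = 0.
    texture : str or None
        Optional texture label (four-block task variant).
    """

    id: str
    cells: frozenset[Cell]
    texture: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", _normalize(self.cells))
        if not _connected(self.cells):
            raise InvalidInput(f"block {self.id!r} is not 4-connected")
        if self.texture is not None and self.texture not in TEXTURES:
            raise InvalidInput(f"unknown texture {self.texture!r}")

    @property
    def height(self) -> int:
        return max(r for r, _ in self.cells) + 1

    @property
    def width(self) -> int:
        return max(c for _, c in self.cells) + 1


@dataclass(frozen=True)
class Silhouette:
    """A compound stimulus: blocks placed on the grid plus a composition graph.

    ``placements`` maps block id -> grid offset of the block's normalised
    cells; ``edges`` records the relational structure as
    ``(block_a, relation, block_b)`` meaning "a is <relation> b".
    """

    blocks: Mapping[str, BlockShape]
    placements: tuple[tuple[str, Cell], ...]
    edges: tuple[tuple[str, Relation, str], ...]

    def __post_init__(self) -> None:
        ids = [bid for bid, _ in self.placements]
        if len(ids) != len(set(ids)):
            raise CompositionError("every building block may be used only once")
        cells: set[Cell] = set()
        for bid, (dr, dc) in self.placements:
            placed = {(r + dr, c + dc) for r, c in self.blocks[bid].cells}
            if cells & placed:
                raise CompositionError("overlapping block cells")
            cells |= placed
        # renormalise the whole silhouette to the origin
        rmin = min(r for r, _ in cells)
        cmin = min(c for _, c in cells)
        if (rmin, cmin) != (0, 0):
            shifted = tuple(
                (bid, (dr - rmin, dc - cmin)) for bid, (dr, dc) in self.placements
            )
            object.__setattr__(self, "placements", shifted)

    @property
    def block_ids(self) -> frozenset[str]:
        return frozenset(bid for bid, _ in self.placements)

    def block_cells(self, bid: str) -> frozenset[Cell]:
        off = dict(self.placements)[bid]
        return frozenset((r + off[0], c + off[1]) for r, c in self.blocks[bid].cells)

    @property
    def occupancy(self) -> frozenset[Cell]:
        cells: set[Cell] = set()
        for bid, _ in self.placements:
            cells |= self.block_cells(bid)
        return frozenset(cells)

    @property
    def height(self) -> int:
        return max(r for r, _ in self.occupancy) + 1

    @property
    def width(self) -> int:
        return max(c for _, c in self.occupancy) + 1

    def relation_classes(self) -> tuple[str, ...]:
        """Sorted multiset of edge axis classes ('vertical'/'horizontal')."""
        return tuple(sorted(r.axis for _, r, _ in self.edges))

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "blocks": {
                    bid: {"cells": sorted(b.cells), "texture": b.texture}
                    for bid, b in self.blocks.items()
                    if bid in self.block_ids
                },
                "placements": [[bid, list(off)] for bid, off in self.placements],
                "edges": [[a, r.value, b] for a, r, b in self.edges],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Silhouette":
        d = json.loads(text)
        blocks = {
            bid: BlockShape(bid, frozenset(map(tuple, spec["cells"])), spec["texture"])
            for bid, spec in d["blocks"].items()
        }
        return cls(
            blocks=blocks,
            placements=tuple((bid, tuple(off)) for bid, off in d["placements"]),
            edges=tuple((a, Relation(r), b) for a, r, b in d["edges"]),
        )

    def ascii_art(self) -> str:
        grid = [["."] * self.width for _ in range(self.height)]
        for bid, _ in self.placements:
            for r, c in self.block_cells(bid):
                grid[r][c] = bid[0]
        return "\n".join("".join(row) for row in grid)


def _drop_offset(
    a_cells: frozenset[Cell], b_cells: frozenset[Cell], r: Relation, contact_offset: int
) -> Cell:
    """Offset of a's cells relative to b's absolute cells so that a abuts b in
    the direction of `r`, with lateral shift `contact_offset` (columns for
    vertical relations, rows for horizontal ones)."""
    if r == Relation.BELOW:
        dr, dc = _drop_offset(b_cells, a_cells, Relation.ON_TOP, -contact_offset)
        return (-dr, -dc)
    if r == Relation.RIGHT_OF:
        dr, dc = _drop_offset(b_cells, a_cells, Relation.LEFT_OF, -contact_offset)
        return (-dr, -dc)
    if r == Relation.ON_TOP:
        a_by_col: dict[int, int] = {}
        for rr, cc in a_cells:
            a_by_col[cc] = max(a_by_col.get(cc, rr), rr)
        b_by_col: dict[int, int] = {}
        for rr, cc in b_cells:
            b_by_col[cc] = min(b_by_col.get(cc, rr), rr)
        shared = [c for c in b_by_col if (c - contact_offset) in a_by_col]
        if not shared:
            raise CompositionError("no touching cells at this contact offset")
        dr = min(b_by_col[c] - 1 - a_by_col[c - contact_offset] for c in shared)
        return (dr, contact_offset)
    # LEFT_OF: transpose of ON_TOP
    at = frozenset((c, r_) for r_, c in a_cells)
    bt = frozenset((c, r_) for r_, c in b_cells)
    dc, dr = _drop_offset(at, bt, Relation.ON_TOP, contact_offset)
    return (dr, dc)


def compose(
    a: BlockShape, b: BlockShape, r: Relation, contact_offset: int = 0
) -> Silhouette:
    """Place block ``a`` in relation ``r`` to block ``b``.

    The blocks are slid together along the relation's axis until they touch
    ("drop" contact rule: at least one cell of ``a`` shares an edge with a
    cell of ``b`` in the direction of the relation); ``contact_offset``
    shifts ``a`` laterally before the drop.

    Raises
    ------
    CompositionError
        If the two blocks share an id (every block may be used only once) or
        the contact offset produces no touching cell pair.
    """
    if a.id == b.id:
        raise CompositionError("a block can be used only once per silhouette")
    off = _drop_offset(a.cells, b.cells, r, contact_offset)
    return Silhouette(
        blocks={a.id: a, b.id: b},
        placements=((a.id, off), (b.id, (0, 0))),
        edges=((a.id, r, b.id),),
    )


def attach(
    s: Silhouette,
    block: BlockShape,
    r: Relation,
    anchor_id: str,
    contact_offset: int = 0,
) -> Silhouette:
    """Attach a further block to ``s`` in relation ``r`` to block ``anchor_id``.

    Contact is established against the anchor block's cells; a collision with
    any other already-placed block raises :class:`CompositionError`.
    """
    if block.id in s.block_ids:
        raise CompositionError("a block can be used only once per silhouette")
    if anchor_id not in s.block_ids:
        raise CompositionError(f"anchor {anchor_id!r} not in silhouette")
    off = _drop_offset(block.cells, s.block_cells(anchor_id), r, contact_offset)
    placed = {(rr + off[0], cc + off[1]) for rr, cc in block.cells}
    if placed & s.occupancy:
        raise CompositionError("new block collides with existing silhouette")
    return Silhouette(
        blocks={**dict(s.blocks), block.id: block},
        placements=s.placements + ((block.id, off),),
        edges=s.edges + ((block.id, r, anchor_id),),
    )


def chain(
    blocks: Sequence[BlockShape],
    relations: Sequence[Relation],
    offsets: Sequence[int] | None = None,
) -> Silhouette:
    """Build a chain silhouette: ``blocks[i]`` related to ``blocks[i+1]`` by
    ``relations[i]`` (e.g. A on top of B on top of C)."""
    if len(relations) != len(blocks) - 1:
        raise InvalidInput("need one relation per adjacent block pair")
    offsets = offsets if offsets is not None else [0] * len(relations)
    s = compose(blocks[-2], blocks[-1], relations[-1], offsets[-1])
    for i in range(len(blocks) - 3, -1, -1):
        s = attach(s, blocks[i], relations[i], blocks[i + 1].id, offsets[i])
    return s


# ---------------------------------------------------------------------------
# conjunctive code
# ---------------------------------------------------------------------------


def conjunctions(s: Silhouette) -> frozenset[tuple[str, tuple[str, ...]]]:
    """The conjunctive code of a silhouette: one ``(block id, position
    signature)`` conjunction per placed block, where the position signature is
    the sorted tuple of the block's directed role labels over its incident
    edges (e.g. a middle block in a tower has signature ``('bottom', 'top')``).
    """
    labels: dict[str, list[str]] = {bid: [] for bid in s.block_ids}
    for a, r, b in s.edges:
        la, lb = r.role_labels
        labels[a].append(la)
        labels[b].append(lb)
    return frozenset((bid, tuple(sorted(ls))) for bid, ls in labels.items())


def conjunctive_overlap(s1: Silhouette, s2: Silhouette) -> int:
    """Number of (block, relational-position) conjunctions shared by the two
    silhouettes; symmetric."""
    return len(conjunctions(s1) & conjunctions(s2))


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------


def _max_pixel_overlap(c1: frozenset[Cell], c2: frozenset[Cell], norm: str) -> float:
    best = 0.0
    r1 = [r for r, _ in c1]
    r2 = [r for r, _ in c2]
    k1 = [c for _, c in c1]
    k2 = [c for _, c in c2]
    for dr in range(min(r1) - max(r2), max(r1) - min(r2) + 1):
        for dc in range(min(k1) - max(k2), max(k1) - min(k2) + 1):
            shifted = {(r + dr, c + dc) for r, c in c2}
            inter = len(c1 & shifted)
            if inter == 0:
                continue
            if norm == "jaccard":
                val = inter / len(c1 | shifted)
            elif norm == "total":
                val = 2 * inter / (len(c1) + len(c2))
            else:
                raise InvalidInput(f"unknown pixel normalisation {norm!r}")
            best = max(best, val)
    return best


def _size_nonoverlap(s1: Silhouette, s2: Silhouette, combine: str) -> float:
    dh = abs(s1.height - s2.height)
    dw = abs(s1.width - s2.width)
    if combine == "sum":
        return float(dh + dw)
    if combine == "max":
        return float(max(dh, dw))
    if combine == "l2":
        return math.hypot(dh, dw)
    raise InvalidInput(f"unknown size combination {combine!r}")


def block_overlap(
    s1: Silhouette,
    s2: Silhouette,
    decompositions: Mapping[int, Sequence[frozenset[str]]] | None = None,
    weights: Mapping[int, Sequence[float]] | None = None,
) -> float:
    """Jaccard overlap of block-id sets, averaged over alternative
    decompositions (equal weights unless given).

    ``decompositions[i]`` lists the candidate block-id sets of silhouette
    ``i`` (1 or 2); defaults to the single placement-derived set.
    """
    decompositions = decompositions or {}
    weights = weights or {}
    sols1 = list(decompositions.get(1, [s1.block_ids]))
    sols2 = list(decompositions.get(2, [s2.block_ids]))
    w1 = list(weights.get(1, [1.0] * len(sols1)))
    w2 = list(weights.get(2, [1.0] * len(sols2)))
    total, wsum = 0.0, 0.0
    for a, wa in zip(sols1, w1):
        for b, wb in zip(sols2, w2):
            a, b = frozenset(a), frozenset(b)
            total += wa * wb * (len(a & b) / len(a | b))
            wsum += wa * wb
    return total / wsum


def overlap_metrics(
    s1: Silhouette,
    s2: Silhouette,
    pixel_norm: str = "jaccard",
    size_combine: str = "sum",
    decompositions: Mapping[int, Sequence[frozenset[str]]] | None = None,
) -> dict[str, float]:
    """Visual/compositional overlap metrics between two silhouettes.

    Returns
    -------
    dict with keys
        ``pixel_overlap`` — maximum shape overlap over all integer
        translations (Jaccard by default; ``pixel_norm='total'`` normalises
        by the summed pixel sizes instead);
        ``size_nonoverlap`` — combined absolute height/width difference;
        ``block_overlap`` — block-set Jaccard (solution-averaged when
        alternative decompositions are given);
        ``relation_same`` — 1.0 iff both silhouettes use the same multiset of
        relation classes (on-top vs beside).
    """
    if not s1.placements or not s2.placements:
        raise InvalidInput("empty silhouette")
    return {
        "pixel_overlap": _max_pixel_overlap(s1.occupancy, s2.occupancy, pixel_norm),
        "size_nonoverlap": _size_nonoverlap(s1, s2, size_combine),
        "block_overlap": block_overlap(s1, s2, decompositions),
        "relation_same": float(s1.relation_classes() == s2.relation_classes()),
    }


# ---------------------------------------------------------------------------
# roles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoleAssignment:
    """Trial roles of the four blocks: the always-present anchor (stable), the
    two blocks in the current silhouette (present), the present block not
    connected to the anchor (distant present, when the anchor is not in the
    middle), and the unused block (absent)."""

    stable: str
    present: frozenset[str]
    absent: str
    distant_present: str | None = None

    def __post_init__(self) -> None:
        if len(self.present) != 2:
            raise RoleError("exactly two present blocks required")
        ids = {self.stable, self.absent} | self.present
        if len(ids) != 4:
            raise RoleError("roles must partition four distinct blocks")
        if self.distant_present is not None and self.distant_present not in self.present:
            raise RoleError("distant_present must be a present block")

    @property
    def stable_middle(self) -> bool:
        return self.distant_present is None


def assign_roles(
    s: Silhouette, block_universe: Sequence[BlockShape | str], stable_id: str
) -> RoleAssignment:
    """Derive the trial roles of the four-block universe from a silhouette.

    The absent block is the universe member missing from ``s``; the distant
    present block is defined iff exactly one present block touches the stable
    block (stable not in the middle of the chain).
    """
    universe = {b if isinstance(b, str) else b.id for b in block_universe}
    if len(universe) != 4:
        raise RoleError("block universe must contain four blocks")
    in_s = s.block_ids
    if len(in_s) != 3 or not in_s <= universe:
        raise RoleError("silhouette must contain exactly 3 universe blocks")
    if stable_id not in in_s:
        raise RoleError("stable block missing from silhouette")
    absent = next(iter(universe - in_s))
    present = frozenset(in_s - {stable_id})
    neighbours = {
        (b if a == stable_id else a)
        for a, _, b in s.edges
        if stable_id in (a, b)
    }
    linked = present & neighbours
    if len(linked) == 2:
        distant = None  # stable in the middle
    elif len(linked) == 1:
        distant = next(iter(present - linked))
    else:
        raise RoleError("stable block is disconnected from the present blocks")
    return RoleAssignment(
        stable=stable_id, present=present, absent=absent, distant_present=distant
    )


# ---------------------------------------------------------------------------
# silhouette algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlgebraTriplet:
    """A silhouette-algebra trial: signed terms ``+WX - YX + YZ`` whose
    conjunctive code formally cancels to the target ``WZ``; the reference
    ``ZW`` uses the same blocks in swapped relational positions."""

    terms: tuple[tuple[int, Silhouette], ...]
    target: Silhouette
    reference: Silhouette

    def __post_init__(self) -> None:
        if tuple(sign for sign, _ in self.terms) != (1, -1, 1):
            raise InvalidInput("terms must be signed (+1, -1, +1)")
        if not self.cancels():
            raise InvalidInput("terms do not cancel to the target")
        if self.target.block_ids != self.reference.block_ids:
            raise InvalidInput("target and reference must share their block set")

    def cancels(self) -> bool:
        """Signed multiset of term conjunctions equals the target's."""
        counts: dict = {}
        for sign, s in self.terms:
            for conj in conjunctions(s):
                counts[conj] = counts.get(conj, 0) + sign
        expected = {conj: 1 for conj in conjunctions(self.target)}
        return {k: v for k, v in counts.items() if v != 0} == expected

    @property
    def block_labels(self) -> tuple[str, str, str, str]:
        """(W, X, Y, Z) of the canonical +WX - YX + YZ = WZ form."""
        (s1, _), (_, s2), (_, s3) = (
            (self.terms[0][1], None),
            (None, self.terms[1][1]),
            (None, self.terms[2][1]),
        )
        (w, _, x) = s1.edges[0]
        (y, _, _) = s2.edges[0]
        (_, _, z) = s3.edges[0]
        return (w, x, y, z)


def _canonical_pair(s: Silhouette) -> tuple[str, str, Relation] | None:
    """(active block, passive block, canonical relation) of a 2-block
    silhouette, folding below/right_of onto on_top/left_of."""
    if len(s.block_ids) != 2 or len(s.edges) != 1:
        return None
    a, r, b = s.edges[0]
    if r in (Relation.BELOW, Relation.RIGHT_OF):
        a, r, b = b, r.inverse, a
    return (a, b, r)


def enumerate_algebra_triplets(
    stimulus_set: Sequence[Silhouette],
) -> list[AlgebraTriplet]:
    """Enumerate all silhouette-algebra triplets supported by a set of
    two-block compounds.

    For every ordered quadruple of distinct blocks (W, X, Y, Z) and relation
    class such that WX, YX and YZ are all in the stimulus set, the triplet
    ``+WX - YX + YZ`` is returned with target WZ and reference ZW (taken from
    the stimulus set when present, otherwise composed with zero offset).
    Output is sorted, independent of input order, and free of duplicates.
    """
    index: dict[tuple[str, str, Relation], Silhouette] = {}
    blocks: dict[str, BlockShape] = {}
    for s in stimulus_set:
        key = _canonical_pair(s)
        if key is not None:
            index[key] = s
            for bid in s.block_ids:
                blocks[bid] = s.blocks[bid]
    if len(blocks) < 4:
        raise InsufficientStimuli("need two-block compounds over >= 4 blocks")

    def lookup(a: str, b: str, r: Relation) -> Silhouette | None:
        if (a, b, r) in index:
            return index[(a, b, r)]
        try:
            return compose(blocks[a], blocks[b], r)
        except CompositionError:
            return None

    out: list[tuple[tuple, AlgebraTriplet]] = []
    relations = sorted({r for (_, _, r) in index}, key=lambda r: r.value)
    for r in relations:
        for w, x, y, z in itertools.permutations(sorted(blocks), 4):
            wx = index.get((w, x, r))
            yx = index.get((y, x, r))
            yz = index.get((y, z, r))
            if wx is None or yx is None or yz is None:
                continue
            target = lookup(w, z, r)
            reference = lookup(z, w, r)
            if target is None or reference is None:
                continue
            trip = AlgebraTriplet(
                terms=((1, wx), (-1, yx), (1, yz)), target=target, reference=reference
            )
            out.append(((r.value, w, x, y, z), trip))
    out.sort(key=lambda kv: kv[0])
    return [trip for _, trip in out]


def brick_ordering_count(n_bricks: int) -> int:
    """Number of distinct orderings in which ``n_bricks`` bricks can be
    stacked: n! (3,628,800 for a 10-brick tower)."""
    return math.factorial(n_bricks)


# ---------------------------------------------------------------------------
# stock shapes
# ---------------------------------------------------------------------------


def default_blocks(textured: bool = True) -> list[BlockShape]:
    """Four distinct polyomino blocks (W, X, Y, Z) used throughout the
    synthetic experiments; textured for the four-block task variant."""
    shapes = {
        "W": {(0, 0), (0, 1)},
        "X": {(0, 0), (1, 0)},
        "Y": {(0, 0), (0, 1), (1, 0)},
        "Z": {(0, 0), (0, 1), (1, 1)},
    }
    tex = dict(zip(shapes, TEXTURES)) if textured else {}
    return [BlockShape(bid, frozenset(cells), tex.get(bid)) for bid, cells in shapes.items()]


def stimulus_index(stimuli: Mapping[str, Silhouette]) -> "object":
    """Index table of a stimulus set (one row per silhouette) as a pandas
    DataFrame with columns stim_id, blocks, relation, height, width."""
    import pandas as pd

    rows = []
    for sid, s in stimuli.items():
        rows.append(
            {
                "stim_id": sid,
                "blocks": "+".join(sorted(s.block_ids)),
                "relation": ",".join(r.value for _, r, _ in s.edges),
                "height": s.height,
                "width": s.width,
            }
        )
    return pd.DataFrame(rows).sort_values("stim_id").reset_index(drop=True)
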