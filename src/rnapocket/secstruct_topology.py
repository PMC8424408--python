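"""Dot-bracket secondary structure, loop elements and tandem-loop relations.

The secondary structure is supplied as a dot-bracket string (pseudoknots in
secondary bracket alphabets ``[] {} <>`` are parsed and retained but do not
enter loop classification).  Loop elements follow the usual taxonomy:

* hairpin — unpaired run closed by a single pair,
* bulge — one-sided unpaired run between two stacked helices,
* internal — two-sided unpaired region between two helices,
* multibranch — loop bounded by three or more helices,
* exterior — unpaired positions not enclosed by any pair,
* stem — a maximal helix (stack of pairs), carried for distance queries.

Each pocket is tagged with the loop kinds of its lining nucleotides; two
loops separated along the helix tree by fewer than six base pairs are
"tandem", and tandem loops whose pockets share a shape class are labelled
TS (same topology), otherwise TD.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .pocket_detection import Pocket
from .rpdescriptor import ShapeDescriptor
from .structure_io import MolecularModel

__all__ = [
    "SecondaryStructure",
    "LoopElement",
    "PocketPattern",
    "ParseError",
    "parse_dotbracket",
    "loop_elements",
    "pocket_pattern",
    "tandem_relation",
    "ts_td_label",
]

_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_PRIMARY = "("

TANDEM_MAX_BP = 6  # tandem iff separating helix has fewer base pairs


class ParseError(ValueError):
    """Malformed dot-bracket input."""


@dataclass(frozen=True)
class LoopElement:
    """One secondary-structure element.

    ``positions`` are the unpaired member positions (0-based) for loops, or
    the paired positions for a stem.  ``closing`` is the outermost pair
    bounding the element (None for the exterior loop).
    """

    kind: str  # hairpin | bulge | internal | multibranch | exterior | stem
    positions: tuple[int, ...]
    closing: tuple[int, int] | None = None
    inner: tuple[tuple[int, int], ...] = ()


@dataclass
class SecondaryStructure:
    sequence: str
    pairs: dict[int, int]  # primary (nested) pairs, both directions
    pseudoknot_pairs: dict[int, int] = field(default_factory=dict)
    elements: list[LoopElement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def is_paired(self, i: int) -> bool:
        return i in self.pairs

    def loop_of(self, i: int) -> LoopElement | None:
        """The loop element containing unpaired position ``i``."""
        for el in self.elements:
            if el.kind != "stem" and i in el.positions:
                return el
        return None


def parse_dotbracket(sequence: str, structure: str) -> SecondaryStructure:
    """Parse a dot-bracket string; one stack per bracket alphabet.

    Pairs from the primary ``()`` alphabet define the nested structure and
    loop elements; pairs from other alphabets are kept in
    ``pseudoknot_pairs`` and excluded from loop classification.
    """
    if len(sequence) != len(structure):
        raise ParseError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    stacks: dict[str, list[int]] = {op: [] for op in _BRACKETS}
    closers = {cl: op for op, cl in _BRACKETS.items()}
    primary: dict[int, int] = {}
    pseudo: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == ".":
            continue
        if ch in _BRACKETS:
            stacks[ch].append(i)
        elif ch in closers:
            op = closers[ch]
            if not stacks[op]:
                raise ParseError(f"unbalanced {ch!r} at position {i}")
            j = stacks[op].pop()
            target = primary if op == _PRIMARY else pseudo
            target[i] = j
            target[j] = i
        else:
            raise ParseError(f"unexpected character {ch!r} at position {i}")
    for op, stack in stacks.items():
        if stack:
            raise ParseError(f"unbalanced {op!r} at position {stack[-1]}")
    ss = SecondaryStructure(sequence=sequence, pairs=primary, pseudoknot_pairs=pseudo)
    ss.elements = loop_elements(ss)
    return ss


def _children(pairs: dict[int, int], i: int, j: int) -> list[tuple[int, int]]:
    """Maximal pairs directly nested inside (i, j), plus unpaired positions."""
    kids = []
    k = i + 1
    while k < j:
        if k in pairs and pairs[k] > k:
            kids.append((k, pairs[k]))
            k = pairs[k] + 1
        else:
            k += 1
    return kids


def loop_elements(ss: SecondaryStructure) -> list[LoopElement]:
    """Partition the structure into stems and loop elements.

    Every unpaired position lands in exactly one loop element; every paired
    (primary) position lands in exactly one stem.
    """
    n = len(ss.sequence)
    pairs = ss.pairs
    elements: list[LoopElement] = []

    # stems: maximal stacks (i, j), (i+1, j-1), ...
    opening = sorted(p for p in pairs if pairs[p] > p)
    in_stem: set[int] = set()
    for i in opening:
        if i in in_stem:
            continue
        j = pairs[i]
        run = [(i, j)]
        while (i + 1) in pairs and pairs[i + 1] == j - 1 and i + 1 < j - 1:
            i, j = i + 1, j - 1
            run.append((i, j))
        positions = tuple(sorted(p for ij in run for p in ij))
        in_stem.update(positions)
        elements.append(
            LoopElement(kind="stem", positions=positions, closing=run[0], inner=(run[-1],))
        )

    # exterior: unpaired positions not enclosed by any primary pair
    top_level = _children(pairs, -1, n)
    enclosed: set[int] = set()
    for a, b in top_level:
        enclosed.update(range(a, b + 1))
    exterior = tuple(p for p in range(n) if p not in pairs and p not in enclosed)
    if exterior or top_level:
        elements.append(
            LoopElement(kind="exterior", positions=exterior, closing=None,
                        inner=tuple(top_level))
        )

    # loops closed by each pair
    for i in opening:
        j = pairs[i]
        kids = _children(pairs, i, j)
        unpaired = tuple(
            p
            for p in range(i + 1, j)
            if p not in pairs and not any(a <= p <= b for a, b in kids)
        )
        if len(kids) == 0:
            kind = "hairpin"
        elif len(kids) == 1:
            a, b = kids[0]
            left = a - i - 1
            right = j - b - 1
            if left == 0 and right == 0:
                continue  # stacked pair, part of a stem
            kind = "bulge" if (left == 0 or right == 0) else "internal"
        else:
            kind = "multibranch"
        elements.append(
            LoopElement(kind=kind, positions=unpaired, closing=(i, j),
                        inner=tuple(kids))
        )
    return elements


@dataclass
class PocketPattern:
    pocket_id: str
    lining: list[tuple[str, int, str]]  # (chain, residue_index, base)
    loop_kinds: tuple[str, ...]
    label: str


def pocket_pattern(
    pocket: Pocket,
    model: MolecularModel,
    ss: SecondaryStructure,
    lining_cutoff: float = 4.0,
) -> PocketPattern:
    """Label a pocket by the loop kinds of its lining nucleotides.

    Lining nucleotides have a heavy atom within ``lining_cutoff`` Å of an
    occupied pocket voxel center.  The label joins the sorted unique loop
    kinds of the *unpaired* lining nucleotides with hyphens and appends
    " loop"; a pocket lining only paired positions is "stem-only".
    """
    residues = model.polymer_residues()
    if len(residues) != len(ss):
        raise ValueError(
            f"model has {len(residues)} nucleotides but structure has {len(ss)}"
        )
    pos_of = {(c, idx): k for k, (c, idx, _name) in enumerate(residues)}
    centers = pocket.mask.voxel_centers()
    tree = cKDTree(centers)
    lining_keys: set[tuple[str, int, str]] = set()
    for a in model.heavy_polymer_atoms():
        d, _ = tree.query(a.coords)
        if d <= lining_cutoff:
            lining_keys.add((a.chain_id, a.residue_index, a.residue_name))
    lining = sorted(lining_keys, key=lambda k: (k[0], k[1]))

    kinds: set[str] = set()
    for c, idx, _name in lining:
        p = pos_of[(c, idx)]
        if ss.is_paired(p):
            continue
        el = ss.loop_of(p)
        if el is not None and el.kind != "stem":
            kinds.add(el.kind)
    if not kinds:
        return PocketPattern(pocket.pocket_id, lining, (), "stem-only")
    ordered = tuple(sorted(kinds))
    return PocketPattern(pocket.pocket_id, lining, ordered, "-".join(ordered) + " loop")


# ---------------------------------------------------------------------------
# tandem-loop relations


def _element_graph(ss: SecondaryStructure):
    """Adjacency between loop elements through the stems that join them.

    Each stem of ``k`` base pairs is an edge of weight ``k`` between the
    loop above it (the element whose ``inner`` pairs include the stem's
    outermost pair) and the loop below it (the element closed by the stem's
    innermost pair).
    """
    loops = [el for el in ss.elements if el.kind != "stem"]
    stems = [el for el in ss.elements if el.kind == "stem"]
    by_closing = {el.closing: el for el in loops if el.closing is not None}
    adj: dict[int, list[tuple[int, int]]] = {k: [] for k in range(len(loops))}
    index = {id(el): k for k, el in enumerate(loops)}
    for stem in stems:
        outer = stem.closing
        inner = stem.inner[0]
        above = next((el for el in loops if outer in el.inner), None)
        below = by_closing.get(inner)
        if above is None or below is None:
            continue
        w = len(stem.positions) // 2  # base pairs in the helix
        a, b = index[id(above)], index[id(below)]
        adj[a].append((b, w))
        adj[b].append((a, w))
    return loops, adj


def tandem_relation(
    a: LoopElement, b: LoopElement, ss: SecondaryStructure
) -> tuple[int | None, bool]:
    """Base-pair distance between two loops along the helix tree.

    Returns ``(bp_distance, tandem)`` where the distance sums the base pairs
    of the helices on the path between the loops; for directly adjacent
    loops this is the length of the single separating helix.  Loops are
    tandem when the distance is strictly below six base pairs.  Returns
    ``(None, False)`` when no helix path connects the loops.
    """
    if a is b:
        raise ValueError("tandem_relation needs two distinct loops")
    loops, adj = _element_graph(ss)
    try:
        ia = next(k for k, el in enumerate(loops) if el is a or el == a)
        ib = next(k for k, el in enumerate(loops) if el is b or el == b)
    except StopIteration:
        raise ValueError("both arguments must be loop elements of this structure")
    # Dijkstra over the (tiny) loop graph
    dist = {ia: 0}
    queue = [(0, ia)]
    while queue:
        d, u = heapq.heappop(queue)
        if u == ib:
            return d, d < TANDEM_MAX_BP
        if d > dist.get(u, np.inf):
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(queue, (nd, v))
    return None, False


def ts_td_label(desc_a: ShapeDescriptor, desc_b: ShapeDescriptor) -> str:
    """TS when two tandem-loop pockets share a shape class, else TD."""
    for d in (desc_a, desc_b):
        if not getattr(d, "shape_class", None):
            raise ValueError("both pockets need a shape class")
    return "TS" if desc_a.shape_class == desc_b.shape_class else "TD"
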