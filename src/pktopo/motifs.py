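"""Secondary-structure parsing and motif decomposition.

A secondary structure with tertiary (crossing) base pairs is decomposed into
three kinds of motifs: tertiary motifs whose helices cross (the H-type
pseudoknot PK, two helices H1/H2 joined by loops L1-L3, and the
hairpin-hairpin kissing motif KISS, three helices H1/H2/H3 joined by loops
L1-L6), secondary motifs (internal/bulge loops and multibranch junctions),
and single-stranded loops (hairpin loops, tails and inter-helix joints).
Substructures hanging off a tertiary motif's loops are reduced to their
terminal base pair, contributing two effective nucleotides to the host loop;
this yields the irreducible topology of the structure.

Indices are 1-based throughout, matching PDB residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SecondaryStructure",
    "MotifSpec",
    "ReducedTopology",
    "Helix2D",
    "UnsupportedTopologyError",
    "parse_structure",
    "detect_crossings",
    "classify_motifs",
    "effective_l6",
    "parse_size_string",
]

BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
MOTIF_TYPES = ("PK", "KISS", "HAIRPIN", "INTERNAL", "BULGE", "JUNCTION",
               "HELIX", "HELIX2", "TAIL")


class UnsupportedTopologyError(ValueError):
    """Raised for crossing patterns beyond H-type PK / three-helix KISS."""


# ---------------------------------------------------------------------------
# secondary structure container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondaryStructure:
    """Base-pair set of an RNA 2D structure (possibly with crossings)."""

    length: int
    pairs: frozenset

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) outside 1..{self.length}")
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"index {k} appears in multiple pairs")
                seen.add(k)

    @property
    def paired(self) -> set:
        return {k for ij in self.pairs for k in ij}

    def to_dotbracket(self) -> str:
        """Dot-bracket string, assigning bracket families greedily so that
        crossing pairs land in different families."""
        chars = ["."] * self.length
        families: list[list[tuple[int, int]]] = []
        for i, j in sorted(self.pairs):
            placed = False
            for fam_idx, fam in enumerate(families):
                if not any(a < i < b < j or i < a < j < b for a, b in fam):
                    fam.append((i, j))
                    placed = True
                    break
            if not placed:
                if len(families) >= len(BRACKETS):
                    raise UnsupportedTopologyError(
                        "structure needs more than four bracket families")
                families.append([(i, j)])
                fam_idx = len(families) - 1
            op = list(BRACKETS)[fam_idx]
            chars[i - 1], chars[j - 1] = op, BRACKETS[op]
        return "".join(chars)


def parse_structure(source, length: int | None = None) -> SecondaryStructure:
    """Parse a multi-bracket dot-bracket string or an explicit pair list.

    Bracket families ``() [] {} <>`` may cross each other (pseudoknot
    dialect).  A pair list is any iterable of (i, j) 1-based index pairs.
    """
    if isinstance(source, str):
        stacks: dict[str, list[int]] = {op: [] for op in BRACKETS}
        closing = {v: k for k, v in BRACKETS.items()}
        pairs = set()
        for pos, ch in enumerate(source.strip(), start=1):
            if ch in BRACKETS:
                stacks[ch].append(pos)
            elif ch in closing:
                op = closing[ch]
                if not stacks[op]:
                    raise ValueError(
                        f"unbalanced {ch!r} at position {pos}")
                pairs.add((stacks[op].pop(), pos))
            elif ch not in ".-_,:":
                raise ValueError(f"unknown character {ch!r} at position {pos}")
        for op, stack in stacks.items():
            if stack:
                raise ValueError(
                    f"unbalanced {op!r} opened at position {stack[-1]}")
        return SecondaryStructure(len(source.strip()), frozenset(pairs))
    pairs = frozenset((min(i, j), max(i, j)) for i, j in source)
    if length is None:
        length = max((j for _, j in pairs), default=0)
    return SecondaryStructure(length, pairs)


# ---------------------------------------------------------------------------
# helices and crossings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Helix2D:
    """A maximal stack of nested pairs (i, j), (i+1, j-1), ..."""

    pairs: tuple  # ((i, j), ...) ordered outside-in

    @property
    def n_bp(self) -> int:
        return len(self.pairs)

    @property
    def seg1(self) -> tuple[int, int]:
        """5' strand segment (start, end), inclusive."""
        return self.pairs[0][0], self.pairs[-1][0]

    @property
    def seg2(self) -> tuple[int, int]:
        """3' strand segment (start, end), inclusive."""
        return self.pairs[-1][1], self.pairs[0][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.pairs[0][0], self.pairs[0][1]


def find_helices(ss: SecondaryStructure) -> list[Helix2D]:
    """Maximal stacks of nested pairs; 1-bp helices are allowed."""
    pairs = sorted(ss.pairs)
    pairset = set(pairs)
    helices = []
    used = set()
    for p in pairs:
        if p in used:
            continue
        run = [p]
        i, j = p
        while (i + 1, j - 1) in pairset:
            i, j = i + 1, j - 1
            run.append((i, j))
        used.update(run)
        helices.append(Helix2D(tuple(run)))
    return helices


def _cross(a: Helix2D, b: Helix2D) -> bool:
    (ai, aj), (bi, bj) = a.span, b.span
    return ai < bi < aj < bj or bi < ai < bj < aj


def detect_crossings(ss: SecondaryStructure
                     ) -> list[tuple[Helix2D, Helix2D]]:
    """All pairs of helices whose base pairs interleave (i < k < j < l)."""
    helices = find_helices(ss)
    out = []
    for x in range(len(helices)):
        for y in range(x + 1, len(helices)):
            if _cross(helices[x], helices[y]):
                out.append((helices[x], helices[y]))
    return out


# ---------------------------------------------------------------------------
# motif specifications
# ---------------------------------------------------------------------------

@dataclass
class MotifSpec:
    """Size description of a structural motif.

    PK: helices (H1, H2), loops (L1, L2, L3).
    KISS: helices (H1, H2, H3), loops (L1..L6); ``l6_closed`` marks whether
    the effective L6 loop actually closes the H1-H3 circuit (it does not for
    a free two-strand kissing complex).
    ``residue_map`` maps element labels to the covered sequence positions.
    """

    motif_type: str
    helix_sizes: list[int] = field(default_factory=list)
    loop_sizes: list[int] = field(default_factory=list)
    residue_map: dict = field(default_factory=dict)
    l6_closed: bool = True
    name: str = ""

    def __post_init__(self):
        if self.motif_type not in MOTIF_TYPES:
            raise ValueError(f"unknown motif type {self.motif_type!r}")
        if self.motif_type == "PK":
            if len(self.helix_sizes) != 2 or len(self.loop_sizes) != 3:
                raise ValueError("PK needs 2 helices and 3 loops")
        if self.motif_type == "KISS":
            if len(self.helix_sizes) != 3 or len(self.loop_sizes) != 6:
                raise ValueError("KISS needs 3 helices and 6 loops")
        if any(h < 1 for h in self.helix_sizes):
            raise ValueError("helix sizes must be >= 1")
        if any(l < 0 for l in self.loop_sizes):
            raise ValueError("loop sizes must be >= 0")

    @property
    def size_string(self) -> str:
        h = self.helix_sizes
        l = self.loop_sizes
        if self.motif_type == "PK":
            return f"{h[0]}-{l[0]}-{l[1]}-{l[2]}-{h[1]}"
        if self.motif_type == "KISS":
            return ("(" + "-".join(map(str, h)) + ")-(" +
                    "-".join(map(str, l)) + ")")
        parts = list(map(str, h + l))
        return "-".join(parts) if parts else "-"

    def positions(self) -> set:
        return {p for v in self.residue_map.values() for p in v}


def parse_size_string(text: str) -> MotifSpec:
    """Parse ``"H1-L1-L2-L3-H2"`` (PK) or ``"(H1-H2-H3)-(L1-...-L6)"``
    (KISS) size notation into a synthetic MotifSpec."""
    text = text.strip()
    if text.startswith("("):
        try:
            hpart, lpart = text.split(")-(")
            h = [int(v) for v in hpart.lstrip("(").split("-")]
            l = [int(v) for v in lpart.rstrip(")").split("-")]
        except ValueError:
            raise ValueError(f"malformed KISS size string {text!r}") from None
        if len(h) != 3 or len(l) != 6:
            raise ValueError(f"KISS size string needs 3 helices and 6 loops,"
                             f" got {text!r}")
        return MotifSpec("KISS", h, l)
    vals = text.split("-")
    if len(vals) != 5:
        raise ValueError(f"malformed PK size string {text!r} "
                         "(expected H1-L1-L2-L3-H2)")
    try:
        h1, l1, l2, l3, h2 = (int(v) for v in vals)
    except ValueError:
        raise ValueError(f"malformed PK size string {text!r}") from None
    return MotifSpec("PK", [h1, h2], [l1, l2, l3])


def effective_l6(la: int, lb: int) -> int:
    """Effective L6 loop length when the enclosing helix is reduced to its
    terminal base pair (two nucleotides): L6 = La + Lb + 2."""
    if la < 0 or lb < 0:
        raise ValueError("loop lengths must be >= 0")
    return la + lb + 2


@dataclass
class ReducedTopology:
    """Motif decomposition plus the record of reduced substructures."""

    motifs: list
    substitutions: list = field(default_factory=list)
    length: int = 0

    def by_type(self, motif_type: str) -> list:
        return [m for m in self.motifs if m.motif_type == motif_type]

    def coverage(self) -> dict:
        cover: dict[int, int] = {}
        for m in self.motifs:
            for p in m.positions():
                cover[p] = cover.get(p, 0) + 1
        return cover


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class _Unit:
    kind: str                  # "helix" or "tertiary"
    helices: list
    span: tuple[int, int]
    parent: "._Unit | None" = None
    children: list = field(default_factory=list)
    motif: MotifSpec | None = None

    @property
    def segments(self) -> list[tuple[int, int]]:
        segs = []
        for h in self.helices:
            segs.extend([h.seg1, h.seg2])
        return sorted(segs)


def _components(helices: list[Helix2D]) -> list[list[Helix2D]]:
    n = len(helices)
    adj = [[] for _ in range(n)]
    for x in range(n):
        for y in range(x + 1, n):
            if _cross(helices[x], helices[y]):
                adj[x].append(y)
                adj[y].append(x)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, stack = [], [s]
        seen.add(s)
        while stack:
            u = stack.pop()
            comp.append(helices[u])
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


def _gap_content(lo: int, hi: int, paired: set, units: list[_Unit]):
    """Unpaired count and directly-contained units in the open interval
    (lo, hi)."""
    inside = [u for u in units if lo < u.span[0] and u.span[1] < hi]
    # keep only top-level units in the interval (a stem with a bulge is two
    # nested helix units but one substructure)
    inside = [u for u in inside if u.parent not in inside]
    covered = set()
    for u in inside:
        covered.update(range(u.span[0], u.span[1] + 1))
    free = [p for p in range(lo + 1, hi)
            if p not in paired and p not in covered]
    return free, inside


def classify_motifs(ss: SecondaryStructure,
                    drop_isolated_pairs: bool = False) -> ReducedTopology:
    """Decompose a structure into tertiary, secondary and single-stranded
    motifs, reducing substructures on tertiary-motif loops to their terminal
    base pairs.

    Crossing components must match the H-type PK wiring (segments ordered
    H1a, H2a, H1b, H2b) or the hairpin-hairpin KISS wiring (H1a, H2a, H1b,
    H3a, H2b, H3b); anything else raises
    :class:`UnsupportedTopologyError`.
    """
    if drop_isolated_pairs:
        keep = {p for p in ss.pairs
                if (p[0] + 1, p[1] - 1) in ss.pairs
                or (p[0] - 1, p[1] + 1) in ss.pairs}
        ss = SecondaryStructure(ss.length, frozenset(keep))
    helices = find_helices(ss)
    paired = ss.paired

    units: list[_Unit] = []
    for comp in _components(helices):
        if len(comp) == 1:
            h = comp[0]
            units.append(_Unit("helix", [h], h.span))
        else:
            lo = min(h.span[0] for h in comp)
            hi = max(h.span[1] for h in comp)
            units.append(_Unit("tertiary", sorted(comp, key=lambda h: h.seg1),
                               (lo, hi)))

    # containment forest (smallest strictly-containing unit is the parent)
    for u in units:
        best = None
        for v in units:
            if v is u:
                continue
            if v.span[0] < u.span[0] and u.span[1] < v.span[1]:
                if best is None or (v.span[1] - v.span[0] <
                                    best.span[1] - best.span[0]):
                    best = v
        u.parent = best
        if best is not None:
            best.children.append(u)
    for u in units:
        u.children.sort(key=lambda v: v.span[0])

    motifs: list[MotifSpec] = []
    substitutions: list[dict] = []

    def reduce_gap(lo, hi, host_label, host_elem):
        """Loop size over interval (lo, hi) with substructure reduction."""
        free, inside = _gap_content(lo, hi, paired, units)
        for u in inside:
            substitutions.append({
                "span": u.span,
                "replaced_by": "terminal base pair (2 nt)",
                "host": host_label,
                "element": host_elem,
            })
        return len(free) + 2 * len(inside), free

    counter = {"n": 0}

    def label(mt):
        counter["n"] += 1
        return f"{mt.lower()}{counter['n']}"

    # --- tertiary motifs -------------------------------------------------
    for u in units:
        if u.kind != "tertiary":
            continue
        segs = u.segments
        hs = u.helices
        if len(hs) == 2:
            A, B = hs
            if segs != [A.seg1, B.seg1, A.seg2, B.seg2]:
                raise UnsupportedTopologyError(
                    f"two-helix crossing with segment order {segs} is not an "
                    "H-type pseudoknot")
            name = label("PK")
            l1, f1 = reduce_gap(A.seg1[1], B.seg1[0], name, "L1")
            l2, f2 = reduce_gap(B.seg1[1], A.seg2[0], name, "L2")
            l3, f3 = reduce_gap(A.seg2[1], B.seg2[0], name, "L3")
            rm = {
                "H1": tuple(_seg_positions(A)),
                "H2": tuple(_seg_positions(B)),
                "L1": tuple(f1), "L2": tuple(f2), "L3": tuple(f3),
            }
            m = MotifSpec("PK", [A.n_bp, B.n_bp], [l1, l2, l3],
                          residue_map=rm, name=name)
        elif len(hs) == 3:
            A, B, C = hs
            expected = [A.seg1, B.seg1, A.seg2, C.seg1, B.seg2, C.seg2]
            if segs != sorted(expected) or segs != expected or \
                    not (_cross(A, B) and _cross(B, C)) or _cross(A, C):
                raise UnsupportedTopologyError(
                    f"three-helix crossing with segment order {segs} is not "
                    "a hairpin-hairpin kissing wiring")
            name = label("KISS")
            l1, f1 = reduce_gap(A.seg1[1], B.seg1[0], name, "L1")
            l2, f2 = reduce_gap(B.seg1[1], A.seg2[0], name, "L2")
            l3, f3 = reduce_gap(A.seg2[1], C.seg1[0], name, "L3")
            l4, f4 = reduce_gap(C.seg1[1], B.seg2[0], name, "L4")
            l5, f5 = reduce_gap(B.seg2[1], C.seg2[0], name, "L5")
            # effective L6 from the enclosing helix, if any
            f6: list[int] = []
            if u.parent is not None and u.parent.kind == "helix":
                ph = u.parent.helices[0]
                la, fa = reduce_gap(ph.seg1[1], u.span[0], name, "L6")
                lb, fb = reduce_gap(u.span[1], ph.seg2[0], name, "L6")
                l6 = effective_l6(la, lb)
                f6 = fa + fb
                closed = True
            else:
                l6, closed = 0, False
            rm = {
                "H1": tuple(_seg_positions(A)),
                "H2": tuple(_seg_positions(B)),
                "H3": tuple(_seg_positions(C)),
                "L1": tuple(f1), "L2": tuple(f2), "L3": tuple(f3),
                "L4": tuple(f4), "L5": tuple(f5), "L6": tuple(f6),
            }
            m = MotifSpec("KISS", [A.n_bp, B.n_bp, C.n_bp],
                          [l1, l2, l3, l4, l5, l6],
                          residue_map=rm, l6_closed=closed, name=name)
        else:
            raise UnsupportedTopologyError(
                f"crossing component with {len(hs)} helices; only H-type PK "
                "(2) and hairpin-hairpin KISS (3) wirings are supported")
        u.motif = m
        motifs.append(m)

    # --- secondary helices and their inner loops -------------------------
    for u in units:
        if u.kind != "helix":
            continue
        h = u.helices[0]
        name = label("HELIX")
        motifs.append(MotifSpec(
            "HELIX", [h.n_bp], [],
            residue_map={"H": tuple(_seg_positions(h))}, name=name))
        tert_children = [c for c in u.children if c.kind == "tertiary"]
        if tert_children:
            if len(tert_children) > 1:
                raise UnsupportedTopologyError(
                    "more than one tertiary component inside a single helix")
            continue  # inner region absorbed into the KISS/PK reduction
        lo, hi = h.seg1[1], h.seg2[0]
        kids = u.children
        if not kids:
            free = [p for p in range(lo + 1, hi) if p not in paired]
            motifs.append(MotifSpec(
                "HAIRPIN", [], [len(free)],
                residue_map={"L": tuple(free)}, name=label("HAIRPIN")))
        elif len(kids) == 1:
            k = kids[0]
            g1 = [p for p in range(lo + 1, k.span[0]) if p not in paired]
            g2 = [p for p in range(k.span[1] + 1, hi) if p not in paired]
            mt = "INTERNAL" if (g1 and g2) else "BULGE"
            if not g1 and not g2:
                mt = "INTERNAL"  # degenerate 0x0 joint between stacks
            motifs.append(MotifSpec(
                mt, [], [len(g1), len(g2)],
                residue_map={"L1": tuple(g1), "L2": tuple(g2)},
                name=label(mt)))
        else:
            sizes, rm = [], {}
            edges = [(lo, kids[0].span[0])]
            for a, b in zip(kids[:-1], kids[1:]):
                edges.append((a.span[1], b.span[0]))
            edges.append((kids[-1].span[1], hi))
            for idx, (a, b) in enumerate(edges, start=1):
                free = [p for p in range(a + 1, b) if p not in paired]
                sizes.append(len(free))
                rm[f"L{idx}"] = tuple(free)
            motifs.append(MotifSpec(
                "JUNCTION", [], sizes, residue_map=rm, name=label("JUNCTION")))

    # --- exterior single strands -----------------------------------------
    roots = sorted((u for u in units if u.parent is None),
                   key=lambda u: u.span[0])
    if not roots:
        if ss.length:
            motifs.append(MotifSpec(
                "TAIL", [], [ss.length],
                residue_map={"L": tuple(range(1, ss.length + 1))},
                name=label("TAIL")))
    else:
        lead = list(range(1, roots[0].span[0]))
        if lead:
            motifs.append(MotifSpec(
                "TAIL", [], [len(lead)], residue_map={"L": tuple(lead)},
                name=label("TAIL")))
        for a, b in zip(roots[:-1], roots[1:]):
            mid = [p for p in range(a.span[1] + 1, b.span[0])
                   if p not in paired]
            motifs.append(MotifSpec(
                "HELIX2", [], [len(mid)], residue_map={"L": tuple(mid)},
                name=label("HELIX2")))
        trail = list(range(roots[-1].span[1] + 1, ss.length + 1))
        if trail:
            motifs.append(MotifSpec(
                "TAIL", [], [len(trail)], residue_map={"L": tuple(trail)},
                name=label("TAIL")))

    return ReducedTopology(motifs=motifs, substitutions=substitutions,
                           length=ss.length)


def _seg_positions(h: Helix2D) -> list[int]:
    out = []
    for a, b in (h.seg1, h.seg2):
        out.extend(range(a, b + 1))
    return sorted(out)
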