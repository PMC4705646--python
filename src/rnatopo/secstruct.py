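"""Pseudoknotted RNA secondary structures and their derived topology.

A secondary structure is a sequence plus a set of base pairs.  Pairs are
either ``canonical`` (enforced as rigid A-form helix members downstream) or
``noncanonical_internal`` (internal-loop pairs held together by soft
restraints instead of rigid grouping).  From a validated structure we derive
the topology objects the rest of the package consumes: maximal helices,
unpaired runs, named regions, linker classifications between helix pairs,
and flexible-pivot counts along the secondary-structure graph.

Positions are 1-based and inclusive throughout.  An optional numbering map
carries author/crystal residue numbers (e.g. ``A39``) so restraint rosters
written in crystal numbering can be used verbatim.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import networkx as nx

CANONICAL = "canonical"
NONCANONICAL = "noncanonical_internal"

# bracket alphabets for pseudoknotted dot-bracket, by nesting level
_OPEN = "([{<"
_CLOSE = ")]}>"

VALID_LETTERS = set("ACGUN")


class StructureError(ValueError):
    """Raised for malformed or inconsistent secondary-structure input."""


@dataclass(frozen=True)
class Pair:
    i: int
    j: int
    pair_class: str = CANONICAL

    def __post_init__(self):
        if not self.i < self.j:
            raise StructureError(f"pair must have i < j, got ({self.i}, {self.j})")
        if self.pair_class not in (CANONICAL, NONCANONICAL):
            raise StructureError(f"unknown pair class {self.pair_class!r}")


@dataclass
class SecondaryStructure:
    """Validated sequence + pair table (+ optional crystal numbering)."""

    sequence: str
    pairs: list[Pair]
    numbering_map: dict[int, str] | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("T", "U")
        bad = set(self.sequence) - VALID_LETTERS
        if bad:
            raise StructureError(f"invalid residue letters {sorted(bad)}")
        n = len(self.sequence)
        seen: dict[int, Pair] = {}
        for p in self.pairs:
            if not (1 <= p.i <= n and 1 <= p.j <= n):
                raise StructureError(f"pair ({p.i},{p.j}) outside 1..{n}")
            for pos in (p.i, p.j):
                if pos in seen:
                    raise StructureError(
                        f"position {pos} has duplicate pairing partner"
                    )
                seen[pos] = p
        self.pairs = sorted(self.pairs, key=lambda p: (p.i, p.j))
        if self.numbering_map is not None:
            vals = list(self.numbering_map.values())
            if len(set(vals)) != len(vals):
                raise StructureError("numbering_map is not injective")

    # -- basic queries ----------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.sequence)

    def partner(self) -> dict[int, int]:
        """Map position -> paired position (absent if unpaired)."""
        out: dict[int, int] = {}
        for p in self.pairs:
            out[p.i] = p.j
            out[p.j] = p.i
        return out

    def pair_class_of(self, i: int, j: int) -> str:
        for p in self.pairs:
            if (p.i, p.j) == (min(i, j), max(i, j)):
                return p.pair_class
        raise KeyError((i, j))

    def crystal_name(self, pos: int) -> str:
        if self.numbering_map and pos in self.numbering_map:
            return self.numbering_map[pos]
        return f"{self.sequence[pos - 1]}{pos}"

    def position_of(self, crystal: str) -> int:
        """Inverse numbering lookup, e.g. ``'A39' -> 28``."""
        if self.numbering_map:
            for pos, name in self.numbering_map.items():
                if name == crystal:
                    return pos
        m = re.fullmatch(r"[ACGUN]?(\d+)", crystal)
        if m:
            pos = int(m.group(1))
            if 1 <= pos <= self.length:
                return pos
        raise KeyError(f"residue {crystal!r} not found in numbering map")

    def has_pseudoknot(self) -> bool:
        return len(crossing_pairs(self.pairs)) > 0

    # -- serialization ----------------------------------------------------
    def to_dotbracket(self) -> str:
        """Serialize pairs to multi-level dot-bracket (pair classes lost)."""
        chars = ["."] * self.length
        levels: list[list[Pair]] = []
        for p in self.pairs:
            for lv, members in enumerate(levels):
                if not any(_cross(p, q) for q in members):
                    members.append(p)
                    break
            else:
                levels.append([p])
        if len(levels) > len(_OPEN):
            raise StructureError("more crossing levels than bracket alphabets")
        for lv, members in enumerate(levels):
            for p in members:
                chars[p.i - 1] = _OPEN[lv]
                chars[p.j - 1] = _CLOSE[lv]
        return "".join(chars)

    def to_pairlist(self) -> str:
        """TSV with columns ``i  j  class``."""
        buf = io.StringIO()
        buf.write("i\tj\tclass\n")
        for p in self.pairs:
            buf.write(f"{p.i}\t{p.j}\t{p.pair_class}\n")
        return buf.getvalue()


def _cross(p: Pair, q: Pair) -> bool:
    return (p.i < q.i < p.j < q.j) or (q.i < p.i < q.j < p.j)


def crossing_pairs(pairs: list[Pair]) -> list[tuple[Pair, Pair]]:
    """All crossing (pseudoknotted) pair combinations, brute force."""
    out = []
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            if _cross(pairs[a], pairs[b]):
                out.append((pairs[a], pairs[b]))
    return out


# ---------------------------------------------------------------------------
# parsing


def parse_structure(
    text: str,
    sequence: str | None = None,
    numbering_map: dict[int, str] | None = None,
) -> SecondaryStructure:
    """Parse dot-bracket or a pair-list TSV into a SecondaryStructure.

    Dot-bracket supports four nesting levels ``()[]{}<>``; every pair parsed
    this way is canonical (the notation cannot carry pair classes).
    Noncanonical internal-loop pairs can only be declared through the
    pair-list channel (TSV columns ``i  j  class``).
    """
    stripped = text.strip()
    if set(stripped.split("\n")[0].split("\t")) >= {"i", "j"} or "\t" in stripped:
        pairs = _parse_pairlist(stripped)
        if sequence is None:
            raise StructureError("pair-list input requires an explicit sequence")
    else:
        if sequence is not None and len(sequence) != len(stripped):
            raise StructureError(
                f"sequence length {len(sequence)} != structure length {len(stripped)}"
            )
        pairs = _parse_dotbracket(stripped)
        if sequence is None:
            sequence = "N" * len(stripped)
    return SecondaryStructure(sequence, pairs, numbering_map)


def _parse_dotbracket(db: str) -> list[Pair]:
    stacks: dict[int, list[int]] = {lv: [] for lv in range(len(_OPEN))}
    pairs: list[Pair] = []
    for pos, ch in enumerate(db, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(pos)
        elif ch in _CLOSE:
            lv = _CLOSE.index(ch)
            if not stacks[lv]:
                raise StructureError(
                    f"unbalanced bracket: unmatched {ch!r} at position {pos}"
                )
            pairs.append(Pair(stacks[lv].pop(), pos))
        else:
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    for lv, st in stacks.items():
        if st:
            raise StructureError(
                f"unbalanced bracket: unmatched {_OPEN[lv]!r} at position {st[0]}"
            )
    return pairs


def _parse_pairlist(text: str) -> list[Pair]:
    pairs = []
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if lines and lines[0].split("\t")[0].strip() == "i":
        lines = lines[1:]
    for ln in lines:
        cols = ln.split("\t")
        if len(cols) < 2:
            raise StructureError(f"malformed pair-list row {ln!r}")
        i, j = int(cols[0]), int(cols[1])
        cls = cols[2].strip() if len(cols) > 2 and cols[2].strip() else CANONICAL
        pairs.append(Pair(min(i, j), max(i, j), cls))
    return pairs


def parse_regions(text: str) -> dict[str, list[int]]:
    """Parse a regions TSV (``name  positions``) with comma/range syntax.

    Example row: ``J5\t40,41,42,60-64``.  Positions are 1-based inclusive.
    """
    regions: dict[str, list[int]] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.lower().startswith("name\t"):
            continue
        name, spec = ln.split("\t")[:2]
        out: list[int] = []
        for tok in spec.split(","):
            tok = tok.strip()
            if "-" in tok:
                a, b = tok.split("-")
                out.extend(range(int(a), int(b) + 1))
            elif tok:
                out.append(int(tok))
        regions[name] = sorted(set(out))
    return regions


def format_regions(regions: dict[str, list[int]]) -> str:
    def compact(positions: list[int]) -> str:
        runs, start, prev = [], None, None
        for p in sorted(positions):
            if start is None:
                start = prev = p
            elif p == prev + 1:
                prev = p
            else:
                runs.append((start, prev))
                start = prev = p
        if start is not None:
            runs.append((start, prev))
        return ",".join(f"{a}-{b}" if a != b else str(a) for a, b in runs)

    lines = ["name\tpositions"]
    for name, pos in regions.items():
        lines.append(f"{name}\t{compact(pos)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# topology decomposition


@dataclass
class Helix:
    """A maximal stack of consecutive pairs (i..i+k paired with j-k..j)."""

    name: str
    pairs: list[Pair]

    @property
    def strand1(self) -> tuple[int, int]:
        return (self.pairs[0].i, self.pairs[-1].i)

    @property
    def strand2(self) -> tuple[int, int]:
        return (self.pairs[-1].j, self.pairs[0].j)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def outer(self) -> tuple[int, int]:
        return (self.pairs[0].i, self.pairs[0].j)

    def residues(self) -> list[int]:
        out = []
        for p in self.pairs:
            out.extend((p.i, p.j))
        return sorted(out)


LINKER_TWO_WAY = "two_way"
LINKER_SINGLE = "single_linker"
LINKER_PSEUDOKNOT = "pseudoknot"
LINKER_INDIRECT = "indirect"


@dataclass
class TopologyGraph:
    """Helices + unpaired runs + named regions derived from a structure."""

    structure: SecondaryStructure
    helices: list[Helix]
    loops: list[tuple[int, int]]  # maximal unpaired runs, inclusive
    regions: dict[str, list[int]] = field(default_factory=dict)

    def helix_by_name(self, name: str) -> Helix:
        for h in self.helices:
            if h.name == name:
                return h
        raise KeyError(f"no helix named {name!r}")

    def helix_of(self, pos: int) -> Helix | None:
        for h in self.helices:
            for p in h.pairs:
                if pos in (p.i, p.j):
                    return h
        return None

    # -- linker classification -------------------------------------------
    def _connections(self, a: Helix, b: Helix) -> list[int]:
        """Lengths of unpaired runs directly connecting helix a and helix b.

        A run connects a and b if its flanking paired residues belong to a
        and b (either order).  Zero-length (coaxial) connections are
        detected from strand-end adjacency and reported as 0.
        """
        ends_a = _strand_ends(a)
        ends_b = _strand_ends(b)
        conns: list[int] = []
        partner = self.structure.partner()
        n = self.structure.length
        for lo, hi in self.loops:
            left = lo - 1 if lo > 1 else None
            right = hi + 1 if hi < n else None
            if left is None or right is None:
                continue
            if left not in partner or right not in partner:
                continue
            la, lb = left in ends_a, left in ends_b
            ra, rb = right in ends_a, right in ends_b
            if (la and rb) or (lb and ra):
                conns.append(hi - lo + 1)
        # direct (coaxial) adjacency: consecutive positions in different helices
        for pos in ends_a:
            for nxt in (pos - 1, pos + 1):
                if nxt in ends_b:
                    conns.append(0)
        return conns

    def linker_class(self, name_a: str, name_b: str) -> str:
        """Classify how two helices are linked (Figure-2-style categories).

        ``pseudoknot`` if their pairs cross; ``two_way`` if they are joined
        through a junction by two strand connections (including 0-nt coaxial
        sides, i.e. standard two-way junctions, bulges and internal loops);
        ``single_linker`` if a single unpaired strand of <= 3 nt attaches
        one of them (peripheral attachment); ``indirect`` otherwise.
        """
        a, b = self.helix_by_name(name_a), self.helix_by_name(name_b)
        for p in a.pairs:
            for q in b.pairs:
                if _cross(p, q):
                    return LINKER_PSEUDOKNOT
        conns = self._connections(a, b)
        if len(conns) >= 2:
            return LINKER_TWO_WAY
        if len(conns) == 1:
            if conns[0] == 0:
                # directly stacked: a degenerate (0-nt) two-way junction
                return LINKER_TWO_WAY
            if conns[0] <= 3:
                return LINKER_SINGLE
        return LINKER_INDIRECT

    # -- articulation graph ----------------------------------------------
    def _junction_graph(self) -> nx.Graph:
        """Graph whose nodes are rigid helices and flexible joints.

        Each maximal unpaired run (plus each zero-length coaxial contact
        between distinct helices) becomes one *joint* node connecting the
        helices it abuts; joints carry ``flexible=True`` except zero-length
        coaxial contacts, which are geometric articulation points but are
        counted as flexible joints too (a 0-nt two-way junction still
        permits interhelical bending in this model).
        """
        g = nx.Graph()
        for h in self.helices:
            g.add_node(("helix", h.name))
        partner = self.structure.partner()
        n = self.structure.length
        jid = 0
        for lo, hi in self.loops:
            left = lo - 1 if lo > 1 else None
            right = hi + 1 if hi < n else None
            hl = self.helix_of(left) if left in partner else None
            hr = self.helix_of(right) if right in partner else None
            node = ("joint", jid, lo, hi)
            g.add_node(node, flexible=True, length=hi - lo + 1)
            jid += 1
            if hl is not None:
                g.add_edge(("helix", hl.name), node)
            if hr is not None:
                g.add_edge(("helix", hr.name), node)
        # coaxial adjacencies (0-nt junction sides)
        for a in self.helices:
            for b in self.helices:
                if a.name >= b.name:
                    continue
                for pos in _strand_ends(a):
                    for nxt in (pos - 1, pos + 1):
                        if nxt in _strand_ends(b):
                            node = ("joint", jid, pos, nxt)
                            if node not in g:
                                g.add_node(node, flexible=True, length=0)
                                g.add_edge(("helix", a.name), node)
                                g.add_edge(("helix", b.name), node)
                                jid += 1
        return g

    def count_flexible_pivots(self, region_a: str, region_b: str) -> int:
        """Number of flexible joints on the shortest structure path A -> B.

        Helices are rigid segments; every unpaired junction/linker crossed
        between the rigid unit holding A and the rigid unit holding B counts
        as one pivot.  A region adjacent to the destination's rigid unit
        contributes no pivot of its own (entering the destination region is
        not a crossing), so a hairpin loop queried against its own closing
        helix yields 0.
        """
        ra = self.regions.get(region_a)
        rb = self.regions.get(region_b)
        if ra is None or rb is None:
            missing = region_a if ra is None else region_b
            raise KeyError(f"region {missing!r} not defined")
        g = self._junction_graph()
        anchors_a = self._anchor_nodes(ra, g)
        anchors_b = self._anchor_nodes(rb, g)
        best = None
        for na in anchors_a:
            for nb in anchors_b:
                try:
                    path = nx.shortest_path(g, na, nb)
                except nx.NetworkXNoPath:
                    continue
                pivots = sum(
                    1
                    for node in path[1:-1]
                    if node[0] == "joint" and g.nodes[node].get("flexible")
                )
                if best is None or pivots < best:
                    best = pivots
        if best is None:
            raise StructureError("regions are disconnected in the topology graph")
        return best

    def _anchor_nodes(self, residues: list[int], g: nx.Graph) -> list:
        """Graph nodes a region touches: its helices, and for unpaired
        residues the helices flanking the loop run(s) containing them."""
        anchors = set()
        for pos in residues:
            h = self.helix_of(pos)
            if h is not None:
                anchors.add(("helix", h.name))
                continue
            for lo, hi in self.loops:
                if lo <= pos <= hi:
                    for nb, flank in ((lo - 1, "l"), (hi + 1, "r")):
                        hf = self.helix_of(nb) if 1 <= nb <= self.structure.length else None
                        if hf is not None:
                            anchors.add(("helix", hf.name))
                    break
        if not anchors:
            raise StructureError("region touches no helix (fully detached)")
        return sorted(anchors)

    def pseudoknot_linkages(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.helices)):
            for j in range(i + 1, len(self.helices)):
                a, b = self.helices[i], self.helices[j]
                if any(_cross(p, q) for p in a.pairs for q in b.pairs):
                    out.append((a.name, b.name))
        return out


def _strand_ends(h: Helix) -> set[int]:
    s1, s2 = h.strand1, h.strand2
    return set(range(s1[0], s1[1] + 1)) | set(range(s2[0], s2[1] + 1))


def find_helices(pairs: list[Pair]) -> list[list[Pair]]:
    """Maximal ladders of consecutive pairs: (i,j) stacks on (i+1, j-1)."""
    canon = sorted((p for p in pairs if p.pair_class == CANONICAL), key=lambda p: p.i)
    bykey = {(p.i, p.j): p for p in canon}
    used: set[tuple[int, int]] = set()
    out: list[list[Pair]] = []
    for p in canon:
        if (p.i, p.j) in used:
            continue
        if (p.i - 1, p.j + 1) in bykey:
            continue  # not the outermost pair of its ladder
        ladder = [p]
        used.add((p.i, p.j))
        q = p
        while (q.i + 1, q.j - 1) in bykey:
            q = bykey[(q.i + 1, q.j - 1)]
            ladder.append(q)
            used.add((q.i, q.j))
        out.append(ladder)
    return out


def decompose_topology(
    ss: SecondaryStructure,
    regions: dict[str, list[int]] | None = None,
    helix_names: dict[int, str] | None = None,
) -> TopologyGraph:
    """Derive helices, loops and (optionally named) regions from ``ss``.

    Helices are maximal stacks of consecutive *canonical* pairs; a helix
    name can be supplied per outer-pair 5' position via ``helix_names``,
    or is auto-assigned ``H1, H2, ...`` in 5'->3' order.  When a regions
    dict is given, any region name matching a helix strand-set renames the
    helix (so fixture files control the P1..P9 naming).
    """
    ladders = find_helices(ss.pairs)
    helices = []
    for k, ladder in enumerate(sorted(ladders, key=lambda l: l[0].i)):
        name = f"H{k + 1}"
        if helix_names and ladder[0].i in helix_names:
            name = helix_names[ladder[0].i]
        helices.append(Helix(name, ladder))

    if regions:
        residues_of = {
            h.name: set(h.residues()) for h in helices
        }
        for rname, rpos in regions.items():
            rset = set(rpos)
            for h in helices:
                if residues_of[h.name] == rset:
                    h.name = rname
                    residues_of[rname] = rset
                    break

    partner = ss.partner()
    loops: list[tuple[int, int]] = []
    pos = 1
    while pos <= ss.length:
        if pos not in partner:
            start = pos
            while pos + 1 <= ss.length and (pos + 1) not in partner:
                pos += 1
            loops.append((start, pos))
        pos += 1

    return TopologyGraph(ss, helices, loops, dict(regions or {}))


def count_flexible_pivots(tg: TopologyGraph, region_a: str, region_b: str) -> int:
    """Module-level convenience wrapper (see TopologyGraph method)."""
    return tg.count_flexible_pivots(region_a, region_b)
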