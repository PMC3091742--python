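"""Circular gene-order comparison and junction (overlap/spacer) accounting.

A gene order is a circular signed permutation of gene labels.  Two orders
are equal up to rotation and up to reading the circle in the opposite
direction with all orientations flipped (strand relabelling): both are
normalised away by canonicalisation.  A *boundary* is a circular adjacency
between consecutive elements; adjacency ``(X+, Y+)`` and its
reverse-complement reading ``(Y-, X-)`` are the same boundary.

Junction accounting works on J-strand coordinates regardless of feature
strands: for each consecutive feature pair around the circle it reports the
signed gap (negative = overlap), and the totals satisfy the conservation
identity ``sum(spacers) + sum(gene lengths) - sum(overlaps) = genome length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .genome_io import MitoGenomeRecord

__all__ = [
    "GeneOrder",
    "OrderComparison",
    "JunctionTable",
    "Junction",
    "gene_order",
    "parse_order",
    "format_order",
    "ground_pattern_order",
    "conserved_boundaries",
    "classify_rearrangements",
    "junction_accounting",
]

Element = tuple[str, str]  # (gene name, "+" | "-")


@dataclass(frozen=True)
class GeneOrder:
    """Rotation-canonicalised circular signed gene order."""

    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.elements]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene names without suffixes: {dup}")

    @staticmethod
    def from_elements(elements: list[Element], anchor: str | None = "cox1") -> "GeneOrder":
        return GeneOrder(tuple(_canonicalize(list(elements), anchor)))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.elements)

    def restricted(self, keep: set[str], anchor: str | None = None) -> "GeneOrder":
        """Adjacency closure over a gene subset (dropped genes excised)."""
        kept = [e for e in self.elements if e[0] in keep]
        return GeneOrder.from_elements(kept, anchor=anchor)

    def adjacencies(self) -> set[frozenset]:
        """Canonical circular adjacency set; (X+,Y+) == (Y-,X-)."""
        out = set()
        n = len(self.elements)
        for i in range(n):
            out.add(_canonical_adjacency(self.elements[i], self.elements[(i + 1) % n]))
        return out

    def __eq__(self, other) -> bool:  # rotation/reflection handled at construction
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.elements == other.elements

    def __hash__(self) -> int:
        return hash(self.elements)


def _flip(e: Element) -> Element:
    return (e[0], "-" if e[1] == "+" else "+")


def _canonicalize(elements: list[Element], anchor: str | None = "cox1") -> list[Element]:
    """Rotate to the anchor gene on '+'; reflect+complement first if the
    anchor is on '-'.  Without an anchor (or if absent) the lexicographically
    smallest rotation over both readings is used."""
    if not elements:
        return elements
    readings = [elements, [_flip(e) for e in reversed(elements)]]
    if anchor is not None:
        for reading in readings:
            for i, e in enumerate(reading):
                if e[0] == anchor and e[1] == "+":
                    return reading[i:] + reading[:i]
    best = None
    for reading in readings:
        n = len(reading)
        for i in range(n):
            rot = reading[i:] + reading[:i]
            if best is None or rot < best:
                best = rot
    return best


def _canonical_adjacency(a: Element, b: Element) -> frozenset:
    """Orientation-aware boundary: {(X,sx)->(Y,sy)} == {(Y,-sy)->(X,-sx)}."""
    fwd = (a, b)
    rev = (_flip(b), _flip(a))
    return frozenset({("adj",) + fwd, ("adj",) + rev})


def gene_order(
    record: MitoGenomeRecord, include_trnas: bool = True, include_cr: bool = True
) -> GeneOrder:
    """Canonical circular signed order of a record's features."""
    elems: list[Element] = []
    for f in record.features:  # features are begin-sorted
        if f.kind == "tRNA" and not include_trnas:
            continue
        if f.kind == "control_region" and not include_cr:
            continue
        if f.kind == "other":
            continue
        elems.append((f.name, "+" if f.strand == "J" else "-"))
    return GeneOrder.from_elements(elems)


def parse_order(text: str) -> GeneOrder:
    """Parse whitespace-separated tokens; '-' prefix marks the N strand."""
    elems = []
    for tok in text.split():
        if tok.startswith("#"):
            break
        if tok.startswith("-"):
            elems.append((tok[1:], "-"))
        else:
            elems.append((tok, "+"))
    return GeneOrder.from_elements(elems)


def format_order(order: GeneOrder) -> str:
    return " ".join(n if s == "+" else "-" + n for n, s in order.elements)


def ground_pattern_order() -> GeneOrder:
    """The arthropod mitochondrial ground pattern (Limulus polyphemus),
    37 genes + control region = 38 circular boundaries."""
    text = (
        resources.files("mitocomp").joinpath("data/ground_pattern_order.txt").read_text()
    )
    tokens = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return parse_order(" ".join(tokens))


@dataclass
class OrderComparison:
    conserved_boundary_count: int
    conserved_boundary_list: list
    labels: dict[str, str]
    dropped_genes: tuple[str, ...] = ()


def conserved_boundaries(order_a: GeneOrder, order_b: GeneOrder) -> OrderComparison:
    """Count circular adjacencies shared by two orders (orientation-aware).

    Genes absent from either order are excised from both (adjacency closure)
    and reported as dropped.
    """
    shared = set(order_a.names) & set(order_b.names)
    dropped = tuple(sorted((set(order_a.names) | set(order_b.names)) - shared))
    a = order_a.restricted(shared)
    b = order_b.restricted(shared)
    common = a.adjacencies() & b.adjacencies()
    return OrderComparison(
        conserved_boundary_count=len(common),
        conserved_boundary_list=sorted(
            tuple(sorted(adj)) for adj in common
        ),
        labels={},
        dropped_genes=dropped,
    )


def classify_rearrangements(order: GeneOrder, reference: GeneOrder) -> dict[str, str]:
    """Per-gene rearrangement labels against a reference order.

    ``same_position``: both circular neighbours (with relative orientation)
    match the reference; ``translocated_and_inverted``: the gene's
    orientation in the canonicalised order differs from the reference;
    ``translocated`` otherwise.
    """
    shared = set(order.names) & set(reference.names)
    # orientation is only meaningful relative to a shared anchor gene
    anchor = "cox1" if "cox1" in shared else sorted(shared)[0]
    a = order.restricted(shared, anchor=anchor)
    r = reference.restricted(shared, anchor=anchor)
    a_or = dict(a.elements)
    r_or = dict(r.elements)
    ref_adj = r.adjacencies()
    n = len(a.elements)
    labels: dict[str, str] = {}
    for i, (name, orient) in enumerate(a.elements):
        if orient != r_or[name]:
            labels[name] = "translocated_and_inverted"
            continue
        left_ok = _canonical_adjacency(a.elements[(i - 1) % n], a.elements[i]) in ref_adj
        right_ok = _canonical_adjacency(a.elements[i], a.elements[(i + 1) % n]) in ref_adj
        labels[name] = "same_position" if (left_ok and right_ok) else "translocated"
    return labels


@dataclass
class Junction:
    upstream: str
    downstream: str
    gap: int  # >0 spacer, <0 overlap, 0 abutting
    strands: tuple[str, str]


@dataclass
class JunctionTable:
    junctions: list[Junction]
    genome_length: int
    inconsistencies: list[str] = field(default_factory=list)

    @property
    def n_overlap_junctions(self) -> int:
        return sum(1 for j in self.junctions if j.gap < 0)

    @property
    def total_overlap_bp(self) -> int:
        return sum(-j.gap for j in self.junctions if j.gap < 0)

    @property
    def n_spacers(self) -> int:
        return sum(1 for j in self.junctions if j.gap > 0)

    @property
    def spacer_sizes(self) -> list[int]:
        return sorted(j.gap for j in self.junctions if j.gap > 0)

    @property
    def largest_spacer(self) -> Junction | None:
        spacers = [j for j in self.junctions if j.gap > 0]
        return max(spacers, key=lambda j: j.gap) if spacers else None

    @property
    def longest_overlap(self) -> Junction | None:
        ovl = [j for j in self.junctions if j.gap < 0]
        return min(ovl, key=lambda j: j.gap) if ovl else None

    def summary(self) -> dict:
        big = self.largest_spacer
        long_ovl = self.longest_overlap
        return {
            "n_overlap_junctions": self.n_overlap_junctions,
            "total_overlap_bp": self.total_overlap_bp,
            "n_spacers": self.n_spacers,
            "spacer_size_range": (
                (min(self.spacer_sizes), max(self.spacer_sizes))
                if self.spacer_sizes
                else (0, 0)
            ),
            "largest_noncoding": (
                {"length": big.gap, "between": (big.upstream, big.downstream)}
                if big
                else None
            ),
            "longest_overlap": (
                {"length": -long_ovl.gap, "between": (long_ovl.upstream, long_ovl.downstream)}
                if long_ovl
                else None
            ),
        }


def junction_accounting(
    record: MitoGenomeRecord, include_cr: bool = True
) -> JunctionTable:
    """Signed gap at every consecutive feature junction around the circle.

    Computed on J-strand coordinates regardless of feature strands.  Features
    overlapping a *non*-adjacent feature are flagged in ``inconsistencies``.
    """
    feats = [
        f
        for f in record.features
        if f.kind != "other" and (include_cr or f.kind != "control_region")
    ]
    if not feats:
        raise ValueError("record has no features to account")
    L = record.length
    feats = sorted(feats, key=lambda f: (f.begin, f.end))
    junctions = []
    n = len(feats)
    for i in range(n):
        cur, nxt = feats[i], feats[(i + 1) % n]
        if i + 1 < n:
            gap = nxt.begin - cur.end
        else:  # wrap junction back to the first feature
            gap = (nxt.begin + L) - cur.end
        junctions.append(
            Junction(cur.name, nxt.name, gap, (cur.strand, nxt.strand))
        )
    table = JunctionTable(junctions, L)
    # non-adjacent overlap check
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # those are circular neighbours
            a, b = feats[i], feats[j]
            if _spans_overlap(a.begin, a.end, b.begin, b.end, L):
                table.inconsistencies.append(
                    f"non-adjacent features overlap: {a.name} and {b.name}"
                )
    return table


def _spans_overlap(ab, ae, bb, be, L):
    segs_a = [(ab, min(ae, L))] + ([(0, ae - L)] if ae > L else [])
    segs_b = [(bb, min(be, L))] + ([(0, be - L)] if be > L else [])
    return any(s1 < e2 and s2 < e1 for (s1, e1) in segs_a for (s2, e2) in segs_b)
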