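"""Base composition, strand skews, and control-region motif scans.

Strand asymmetry follows the standard conventions
``AT-skew = (A - T) / (A + T)`` and ``GC-skew = (G - C) / (G + C)``, computed
on the J strand.  Signed values and magnitudes are both reported: AT-rich
mitogenomes are often quoted by skew magnitude, and the sign convention in
the literature is not uniform.

The control-region scans replace thermodynamic folding with direct motif
searches: maximal T homopolymer runs (replication-initiation signals) and
inverted-repeat stem-loops found by pure Watson-Crick (optionally G·U)
complementarity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GeneFeature, MitoGenomeRecord

__all__ = [
    "BaseComposition",
    "SkewPair",
    "TStretch",
    "StemLoopCandidate",
    "base_composition",
    "skews",
    "codon_position_composition",
    "find_t_stretches",
    "find_stem_loops",
]


@dataclass
class BaseComposition:
    """Counts and percentage fractions of A/T/G/C over unambiguous bases."""

    a: int
    t: int
    g: int
    c: int
    n_ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.a + self.t + self.g + self.c

    def fraction(self, base: str) -> float:
        return 100.0 * getattr(self, base.lower()) / self.total

    @property
    def at_percent(self) -> float:
        return 100.0 * (self.a + self.t) / self.total

    @property
    def gc_percent(self) -> float:
        return 100.0 * (self.g + self.c) / self.total


@dataclass
class SkewPair:
    at_skew_signed: float | None
    gc_skew_signed: float | None

    @property
    def at_skew_magnitude(self) -> float | None:
        return None if self.at_skew_signed is None else abs(self.at_skew_signed)

    @property
    def gc_skew_magnitude(self) -> float | None:
        return None if self.gc_skew_signed is None else abs(self.gc_skew_signed)


@dataclass
class TStretch:
    """Maximal run of thymines on one strand (N-strand runs are J-strand A runs)."""

    strand: str
    begin: int  # J-strand coordinates, 0-based half-open
    end: int
    nearest_feature: str | None = None
    distance: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.begin


@dataclass
class StemLoopCandidate:
    """Inverted repeat: arms reverse-complementary up to allowed mismatches."""

    arm5_begin: int
    arm5_end: int
    arm3_begin: int
    arm3_end: int
    stem_length: int
    mismatches: int
    upstream_flank: str = ""
    downstream_flank: str = ""
    has_tata_upstream: bool = False
    has_gaat_downstream: bool = False

    @property
    def loop_begin(self) -> int:
        return self.arm5_end

    @property
    def loop_end(self) -> int:
        return self.arm3_begin

    @property
    def loop_length(self) -> int:
        return self.arm3_begin - self.arm5_end


def base_composition(seq: str) -> BaseComposition:
    """Exact base counts; fractions are over unambiguous bases only."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, t, g, c = s.count("A"), s.count("T") + s.count("U"), s.count("G"), s.count("C")
    return BaseComposition(a, t, g, c, n_ambiguous=len(s) - a - t - g - c)


def skews(comp: BaseComposition) -> SkewPair:
    """Signed AT/GC skews; a zero denominator yields None, never NaN."""
    at = comp.a + comp.t
    gc = comp.g + comp.c
    return SkewPair(
        at_skew_signed=(comp.a - comp.t) / at if at else None,
        gc_skew_signed=(comp.g - comp.c) / gc if gc else None,
    )


def codon_position_composition(cds_seqs: list[str]) -> tuple[float, float, float]:
    """A+T percentage at codon positions 1, 2, 3 over concatenated in-frame CDS.

    Trailing incomplete codons (1-2 nt) are dropped per sequence.
    """
    if not cds_seqs:
        raise ValueError("no CDS sequences given")
    buckets = ["", "", ""]
    for seq in cds_seqs:
        trimmed = seq[: len(seq) - len(seq) % 3].upper()
        for k in range(3):
            buckets[k] += trimmed[k::3]
    out = []
    for b in buckets:
        comp = base_composition(b)
        out.append(comp.at_percent)
    return tuple(out)


# ---------------------------------------------------------------------------
# T-stretches
# ---------------------------------------------------------------------------

def _maximal_runs(seq: str, base: str, min_len: int):
    runs, i, n = [], 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def find_t_stretches(
    record: MitoGenomeRecord,
    region: GeneFeature | tuple[int, int] | None = None,
    min_len: int = 4,
    strand: str = "both",
) -> list[TStretch]:
    """Maximal T runs in *region* on the requested strand(s).

    N-strand stretches are runs of A on the J strand, reported in J
    coordinates with ``strand="N"``.  Each run is annotated with the nearest
    named feature outside the region and its distance (nt between the run
    edge and the feature edge).
    """
    if region is None:
        begin, end = 0, record.length
    elif isinstance(region, GeneFeature):
        begin, end = region.begin, region.end
    else:
        begin, end = region
    L = record.length
    sub = (
        record.sequence[begin:end]
        if end <= L
        else record.sequence[begin:] + record.sequence[: end - L]
    )
    wanted = ["J", "N"] if strand == "both" else [strand]
    out: list[TStretch] = []
    for st in wanted:
        base = "T" if st == "J" else "A"
        for i, j in _maximal_runs(sub.upper(), base, min_len):
            ts = TStretch(strand=st, begin=(begin + i) % L, end=(begin + j - 1) % L + 1)
            ts.nearest_feature, ts.distance = _nearest_feature(record, ts.begin, ts.end)
            out.append(ts)
    out.sort(key=lambda r: (r.begin, r.strand))
    return out


def _nearest_feature(record: MitoGenomeRecord, begin: int, end: int):
    """Closest non-CR feature edge to the run, circular distance."""
    L = record.length
    best_name, best_d = None, None
    for f in record.features:
        if f.kind == "control_region":
            continue
        for d in ((begin - f.end) % L, (f.begin - end) % L):
            if best_d is None or d < best_d:
                best_name, best_d = f.name, d
    return best_name, best_d


# ---------------------------------------------------------------------------
# Stem-loop (inverted repeat) scan
# ---------------------------------------------------------------------------

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _pairs(x: str, y: str, allow_gu: bool) -> bool:
    return (x, y) in _WC or (allow_gu and (x, y) in _GU)


def find_stem_loops(
    seq: str,
    min_stem: int = 4,
    max_mismatch: int = 0,
    loop_bounds: tuple[int, int] = (3, 20),
    allow_gu: bool = False,
    flank: int = 4,
) -> list[StemLoopCandidate]:
    """All maximal inverted repeats in *seq* satisfying the bounds.

    A candidate has two arms of ``stem_length`` bases whose sequences are
    reverse-complementary up to ``max_mismatch`` non-pairing positions,
    separated by a loop within ``loop_bounds``.  Candidates are maximal (the
    stem cannot be extended outward within the mismatch budget) and are
    sorted by stem length (desc) then mismatches (asc) then position.  The
    four bases flanking each arm are checked for the conserved TATA (5') and
    GA(A)T (3') control-region motifs.
    """
    s = seq.upper()
    n = len(s)
    lo, hi = loop_bounds
    out = []
    for loop_start in range(1, n):
        for loop_len in range(lo, hi + 1):
            i = loop_start - 1          # last base of 5' arm
            j = loop_start + loop_len   # first base of 3' arm
            stem = mism = 0
            best = None
            while i >= 0 and j < n:
                if _pairs(s[i], s[j], allow_gu):
                    stem += 1
                    if stem >= min_stem:
                        # outermost counted base must pair
                        best = (stem, mism)
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                    stem += 1
                i -= 1
                j += 1
            if best is None:
                continue
            stem_len, m = best
            a5b = loop_start - stem_len
            ls, ll = loop_start, loop_len
            arm3_begin = ls + ll
            arm3_end = arm3_begin + stem_len
            up = s[max(0, a5b - flank) : a5b]
            down = s[arm3_end : arm3_end + flank]
            out.append(
                StemLoopCandidate(
                    arm5_begin=a5b,
                    arm5_end=ls,
                    arm3_begin=arm3_begin,
                    arm3_end=arm3_end,
                    stem_length=stem_len,
                    mismatches=m,
                    upstream_flank=up,
                    downstream_flank=down,
                    has_tata_upstream="TATA" in up,
                    has_gaat_downstream=("GAAT" in down or "GAT" in down),
                )
            )
    out.sort(key=lambda c: (-c.stem_length, c.mismatches, c.arm5_begin))
    return out
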