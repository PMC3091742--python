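"""Constraint-based detection of (possibly extremely truncated) mito tRNAs.

Acariform mite mitochondrial tRNA genes are too short and too degenerate for
covariance-model scanners; the reliable landmarks are the anticodon stem-loop
(the most conserved region), a 7-bp aminoacyl acceptor stem that tolerates
1-3 mispairings, and at most one of the D- and T-arms — the other being
replaced by an unpaired loop, or both missing in the extreme ("armless")
case.  The search implemented here mirrors that manual procedure:

1. anchor on every possible anticodon loop (7 nt, anticodon at loop
   positions 3-5 drawn from the expected isoacceptor anticodon set; an 8-nt
   loop is permitted for trnI) flanked by a 5-bp anticodon stem within a
   mismatch budget;
2. extend outward to a 7-bp acceptor stem within its own mismatch budget and
   the gene length bounds;
3. infer D-/T-arm presence between the stems (an arm needs >= 2 contiguous
   base pairs closing a loop; anything less is a replacement loop);
4. emit candidates scored by (fewest stem mismatches, most arms, shortest
   gene, leftmost start).

Isoacceptor assignment then aligns candidates against reference tRNAs from
related taxa and assigns one locus per isoacceptor, best alignment first.
Overlap with adjacent genes never disqualifies a candidate: the most
truncated mite tRNAs overlap their neighbours by 10-14 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import mean, stdev

from Bio import Align, SeqIO

from .genome_io import MitoGenomeRecord, revcomp

__all__ = [
    "TrnaSearchParams",
    "TrnaAnnotation",
    "ReferenceTrnaSet",
    "EXPECTED_ANTICODONS",
    "find_trna_candidates",
    "assign_isoacceptors",
    "classify_structure",
    "trna_size_summary",
]

#: expected anticodon(s) per isoacceptor, DNA alphabet, read 5'->3' on the
#: tRNA sense strand (invertebrate mitochondrial wobble set; trnK and trnS1
#: occur with either anticodon in arthropod mitogenomes)
EXPECTED_ANTICODONS: dict[str, tuple[str, ...]] = {
    "trnA": ("TGC",),
    "trnR": ("TCG",),
    "trnN": ("GTT",),
    "trnD": ("GTC",),
    "trnC": ("GCA",),
    "trnQ": ("TTG",),
    "trnE": ("TTC",),
    "trnG": ("TCC",),
    "trnH": ("GTG",),
    "trnI": ("GAT",),
    "trnL1": ("TAG",),
    "trnL2": ("TAA",),
    "trnK": ("TTT", "CTT"),
    "trnM": ("CAT",),
    "trnF": ("GAA",),
    "trnP": ("TGG",),
    "trnS1": ("TCT", "GCT"),
    "trnS2": ("TGA",),
    "trnT": ("TGT",),
    "trnW": ("TCA",),
    "trnY": ("GTA",),
    "trnV": ("TAC",),
}

_ANTICODON_TO_ISO: dict[str, list[str]] = {}
for _iso, _acs in EXPECTED_ANTICODONS.items():
    for _ac in _acs:
        _ANTICODON_TO_ISO.setdefault(_ac, []).append(_iso)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _pairs(x: str, y: str, allow_gu: bool = True) -> bool:
    return (x, y) in _WC or (allow_gu and (x, y) in _GU)


@dataclass(frozen=True)
class TrnaSearchParams:
    """Structural constraints for the candidate search (lengths in nt)."""

    acceptor_stem_len: int = 7
    max_acceptor_mismatch: int = 3
    anticodon_stem_len: int = 5
    max_anticodon_mismatch: int = 1
    arm_min_stem: int = 2
    arm_min_loop: int = 3
    max_arm_region: int = 16
    min_len: int = 40
    max_len: int = 75
    allow_gu: bool = True
    top_k_per_anchor: int = 5

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if min(self.acceptor_stem_len, self.anticodon_stem_len, self.arm_min_stem) < 1:
            raise ValueError("stem lengths must be positive")


@dataclass
class TrnaAnnotation:
    """A located tRNA (candidate or assigned isoacceptor)."""

    name: str | None
    strand: str
    begin: int  # J-strand 0-based half-open; end may wrap (> genome length)
    end: int
    anticodon: str  # RNA alphabet, 5'->3'
    acceptor_mismatches: int
    anticodon_mismatches: int
    d_arm_present: bool
    t_arm_present: bool
    anticodon_loop_len: int = 7
    sequence: str = ""
    structure: str = ""
    alignment_identity: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.begin

    @property
    def total_mismatches(self) -> int:
        return self.acceptor_mismatches + self.anticodon_mismatches

    @property
    def n_arms(self) -> int:
        return int(self.d_arm_present) + int(self.t_arm_present)

    @property
    def structure_class(self) -> str:
        return classify_structure(self)

    def sort_key(self):
        return (self.total_mismatches, -self.n_arms, self.length, self.begin)


def classify_structure(ann: TrnaAnnotation) -> str:
    """Structure class from the arm flags.

    cloverleaf: both arms form stems; TV_replacement: the T-arm is replaced
    by a loop (D present); D_replacement: the D-arm is replaced (T present);
    armless_candidate: neither region forms a stem of the required length.
    """
    if ann.d_arm_present and ann.t_arm_present:
        return "cloverleaf"
    if ann.d_arm_present:
        return "TV_replacement"
    if ann.t_arm_present:
        return "D_replacement"
    return "armless_candidate"


def _find_arm(region: str, params: TrnaSearchParams):
    """Best hairpin inside an inter-stem region.

    Returns (stem_len, p, q) for the longest run of >= arm_min_stem
    contiguous pairs closing a loop of >= arm_min_loop nt, or None.  p/q are
    the indices of the outermost pair.
    """
    n = len(region)
    best = None
    for p in range(n):
        for q in range(n - 1, p + params.arm_min_loop, -1):
            k = 0
            while (
                p + k < q - k
                and (q - k) - (p + k) - 1 >= params.arm_min_loop
                and _pairs(region[p + k], region[q - k], params.allow_gu)
            ):
                k += 1
            if k >= params.arm_min_stem and (best is None or k > best[0]):
                best = (k, p, q)
    return best


def _structure_string(seq: str, params: TrnaSearchParams, d_region: tuple[int, int],
                      ac_stem_start: int, loop_len: int, t_region: tuple[int, int]) -> str:
    """Dot-bracket over acceptor, D, anticodon and T regions."""
    dots = ["."] * len(seq)
    a = params.acceptor_stem_len
    for k in range(a):
        dots[k] = "("
        dots[len(seq) - 1 - k] = ")"
    s = params.anticodon_stem_len
    for k in range(s):
        dots[ac_stem_start + k] = "("
        dots[ac_stem_start + s + loop_len + k] = ")"
    for (rb, re_) in (d_region, t_region):
        region = seq[rb:re_]
        arm = _find_arm(region, params)
        if arm:
            k, p, q = arm
            for m in range(k):
                dots[rb + p + m] = "("
                dots[rb + q - m] = ")"
    return "".join(dots)


def _stem_mismatches(arm5: str, arm3: str, allow_gu: bool) -> int:
    n = len(arm5)
    return sum(0 if _pairs(arm5[k], arm3[n - 1 - k], allow_gu) else 1 for k in range(n))


def _scan_strand(s: str, L: int, strand: str, params: TrnaSearchParams):
    """Scan one reading of the (extended) genome; yields candidates with
    coordinates local to *s*; caller maps them back to J coordinates."""
    p = params
    ac5, acc = p.anticodon_stem_len, p.acceptor_stem_len
    out = []
    n = len(s)
    for loop_len in (7, 8):
        for i in range(ac5 + acc, n - loop_len - ac5 - acc):
            ac = s[i + 2 : i + 5]
            isos = _ANTICODON_TO_ISO.get(ac)
            if isos is None:
                continue
            if loop_len == 8 and ac != "GAT":
                continue  # the 8-nt anticodon loop is a trnI peculiarity
            arm5 = s[i - ac5 : i]
            arm3 = s[i + loop_len : i + loop_len + ac5]
            ac_mm = _stem_mismatches(arm5, arm3, p.allow_gu)
            if ac_mm > p.max_anticodon_mismatch:
                continue
            # extend outward to the acceptor stem; geometry first (cheap),
            # arm inference and structure strings only for the short-listed
            # geometries (arms are the *second* tie-break criterion, so a
            # shortlist ordered by mismatches then length retains the best)
            geoms = []
            for dl in range(0, p.max_arm_region + 1):
                a5_end = i - ac5 - dl
                a5_begin = a5_end - acc
                if a5_begin < 0:
                    break
                arm5_acc = s[a5_begin:a5_end]
                for dr in range(0, p.max_arm_region + 1):
                    b = i + loop_len + ac5 + dr
                    gene_len = (b + acc) - a5_begin
                    if gene_len > p.max_len:
                        break
                    if gene_len < p.min_len or b + acc > n:
                        continue
                    acc_mm = _stem_mismatches(arm5_acc, s[b : b + acc], p.allow_gu)
                    if acc_mm > p.max_acceptor_mismatch:
                        continue
                    geoms.append((acc_mm + ac_mm, gene_len, a5_begin, b, dl, dr, acc_mm))
            if not geoms:
                continue
            geoms.sort(key=lambda g: (g[0], g[1], g[2]))
            anchor_cands = []
            for _mm, gene_len, a5_begin, b, dl, dr, acc_mm in geoms[: max(12, 3 * p.top_k_per_anchor)]:
                d_region = (acc, acc + dl)
                t_region = (acc + dl + ac5 + loop_len + ac5,
                            acc + dl + ac5 + loop_len + ac5 + dr)
                gene_seq = s[a5_begin : b + acc]
                d_arm = _find_arm(gene_seq[d_region[0]:d_region[1]], p) is not None
                t_arm = _find_arm(gene_seq[t_region[0]:t_region[1]], p) is not None
                anchor_cands.append(TrnaAnnotation(
                    name=None,
                    strand=strand,
                    begin=a5_begin,
                    end=b + acc,
                    anticodon=ac.replace("T", "U"),
                    acceptor_mismatches=acc_mm,
                    anticodon_mismatches=ac_mm,
                    d_arm_present=d_arm,
                    t_arm_present=t_arm,
                    anticodon_loop_len=loop_len,
                    sequence=gene_seq,
                    structure=_structure_string(
                        gene_seq, p, d_region, acc + dl, loop_len, t_region
                    ),
                ))
            anchor_cands.sort(key=TrnaAnnotation.sort_key)
            out.extend(anchor_cands[: p.top_k_per_anchor])
    return out


def find_trna_candidates(
    seq: str | MitoGenomeRecord,
    params: TrnaSearchParams = TrnaSearchParams(),
    circular: bool = True,
) -> list[TrnaAnnotation]:
    """Scan both strands of a (circular) sequence for tRNA candidates.

    Coordinates are reported on the J strand (0-based half-open, wrap
    encoded as end > genome length).  Per anticodon anchor at most
    ``params.top_k_per_anchor`` geometries are kept, best score first.
    """
    if isinstance(seq, MitoGenomeRecord):
        circular = seq.circular
        seq = seq.sequence
    s = seq.upper()
    L = len(s)
    if L < params.min_len:
        return []
    W = params.max_len + 5 if circular else 0
    ext = s + s[:W]
    candidates: list[TrnaAnnotation] = []
    seen: set[tuple] = set()
    for strand, reading in (("J", ext), ("N", revcomp(ext))):
        for cand in _scan_strand(reading, L, strand, params):
            if strand == "J":
                begin, end = cand.begin, cand.end
            else:
                begin, end = len(ext) - cand.end, len(ext) - cand.begin
            begin_mod = begin % L
            key = (strand, begin_mod, end - begin, cand.anticodon)
            if key in seen:
                continue
            seen.add(key)
            cand = replace(cand, begin=begin_mod, end=begin_mod + (end - begin))
            candidates.append(cand)
    candidates.sort(key=TrnaAnnotation.sort_key)
    return candidates


# ---------------------------------------------------------------------------
# Isoacceptor assignment against reference tRNAs
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTrnaSet:
    """Per-isoacceptor reference sequences (reading direction, DNA)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(EXPECTED_ANTICODONS) - set(self.sequences)
        if missing:
            raise ValueError(f"reference set missing isoacceptors: {sorted(missing)}")
        self.sequences = {k: v.upper().replace("U", "T") for k, v in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceTrnaSet":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    return al


def _identity(aligner, a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / max(len(a), len(b))


def assign_isoacceptors(
    candidates: list[TrnaAnnotation],
    refs: ReferenceTrnaSet,
    min_identity: float = 0.60,
    genome_length: int | None = None,
) -> dict:
    """One-to-one assignment of candidates to the 22 isoacceptors.

    Candidates are ranked per isoacceptor by (anticodon match, global
    alignment identity to the reference, structural score) and assigned
    greedily, best first; a locus (>=50% span overlap on the same strand)
    can be kept by only one isoacceptor — the higher-scoring one, with the
    conflict reported.  Isoacceptors with no candidate above *min_identity*
    are reported missing.
    """
    aligner = _aligner()
    scored: list[tuple[float, int, int, str, TrnaAnnotation]] = []
    for cand in candidates:
        ac_dna = cand.anticodon.replace("U", "T")
        for iso in _ANTICODON_TO_ISO.get(ac_dna, []):
            ident = _identity(aligner, cand.sequence, refs.sequences[iso])
            if ident < min_identity:
                continue
            scored.append((ident, -cand.total_mismatches, cand.n_arms, iso, cand))
    scored.sort(key=lambda t: (-t[0], -t[1] - 0, -t[2], t[4].begin))
    assigned: dict[str, TrnaAnnotation] = {}
    taken_spans: list[tuple[str, int, int, str]] = []
    conflicts: list[str] = []
    for ident, _negmm, _arms, iso, cand in scored:
        if iso in assigned:
            continue
        clash = None
        for (strand, b, e, owner) in taken_spans:
            if strand == cand.strand and _span_overlap_frac(b, e, cand.begin, cand.end,
                                                            genome_length) >= 0.5:
                clash = owner
                break
        if clash:
            conflicts.append(f"{iso} candidate at [{cand.begin},{cand.end}) lost locus to {clash}")
            continue
        ann = replace(cand, name=iso, alignment_identity=ident)
        assigned[iso] = ann
        taken_spans.append((cand.strand, cand.begin, cand.end, iso))
    missing = sorted(set(EXPECTED_ANTICODONS) - set(assigned))
    return {"assigned": assigned, "missing": missing, "conflicts": conflicts}


def _span_overlap_frac(b1, e1, b2, e2, L=None) -> float:
    def segs(b, e):
        if L and e > L:
            return [(b, L), (0, e - L)]
        return [(b, e)]

    ovl = 0
    for s1, t1 in segs(b1, e1):
        for s2, t2 in segs(b2, e2):
            ovl += max(0, min(t1, t2) - max(s1, s2))
    return ovl / min(e1 - b1, e2 - b2)


def trna_size_summary(annotations) -> dict:
    """Arithmetic mean, sample sd and range of tRNA gene lengths."""
    anns = list(annotations.values()) if isinstance(annotations, dict) else list(annotations)
    if not anns:
        raise ValueError("no tRNA annotations")
    lengths = [a.length for a in anns]
    return {
        "n": len(lengths),
        "mean": mean(lengths),
        "sd": stdev(lengths) if len(lengths) > 1 else 0.0,
        "min": min(lengths),
        "max": max(lengths),
    }
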