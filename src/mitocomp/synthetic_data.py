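"""Synthetic circular mitogenomes with ground-truth manifests.

The generator emulates the statistical structure of an acariform mite
mitogenome — the conditions every analysis module here assumes: a ~13 kb
circular molecule carrying the 37 canonical metazoan genes plus one control
region, ~85% A+T with configurable signed strand skews, overlapping gene
junctions, extremely truncated tRNAs (44-65 nt, planted with a declared
structure class), and an A+T-only control region containing T-stretches and
an inverted-repeat hairpin.  Background sequence is drawn i.i.d. from the
target base composition; no higher-order structure is simulated.

Every planted object is recorded in a :class:`TruthManifest` so recovery by
the analysis modules can be scored exactly.  All randomness flows from one
master seed; the same config + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    GENE_VOCABULARY,
    GeneFeature,
    MitoGenomeRecord,
    PCG_NAMES,
    revcomp,
)
from .gene_order import GeneOrder, ground_pattern_order
from .trna_struct import EXPECTED_ANTICODONS, TrnaSearchParams, _find_arm
from .codon_usage import INVERTEBRATE_MITO_CODE

__all__ = [
    "GenomeSimConfig",
    "TruthManifest",
    "generate_mitogenome",
    "permute_order",
    "mutate_cds",
    "random_cds",
    "DEFAULT_PCG_LENGTHS",
    "DEFAULT_TRNA_PLAN",
]

# protein gene lengths (bp) summing to 10,196; non-multiples of 3 end in the
# truncated stop codons (T / TA) completed by polyadenylation in vivo
DEFAULT_PCG_LENGTHS: dict[str, int] = {
    "cox1": 1539, "cox2": 660, "cox3": 771, "cob": 1000,
    "nad1": 870, "nad2": 840, "nad3": 330, "nad4": 1260, "nad4L": 270,
    "nad5": 1436, "nad6": 420, "atp6": 650, "atp8": 150,
}

_START_CODONS = {
    "cox1": "ATC", "nad3": "ATA", "nad4L": "ATA", "nad1": "ATA",
    "cox2": "ATG", "cox3": "ATG", "atp6": "ATG", "nad4": "ATG",
}

#: per-isoacceptor (length, structure class); lengths sum to 1190
#: (mean 54.1, range 44-65) and the class census mirrors a mite genome:
#: 3 cloverleaf, 6 D-replacement, 13 TV-replacement
DEFAULT_TRNA_PLAN: dict[str, tuple[int, str]] = {
    "trnN": (60, "cloverleaf"), "trnL2": (61, "cloverleaf"), "trnK": (62, "cloverleaf"),
    "trnD": (54, "D_replacement"), "trnE": (55, "D_replacement"),
    "trnQ": (50, "D_replacement"), "trnS1": (56, "D_replacement"),
    "trnS2": (57, "D_replacement"), "trnV": (52, "D_replacement"),
    "trnA": (52, "TV_replacement"), "trnR": (54, "TV_replacement"),
    "trnC": (53, "TV_replacement"), "trnG": (53, "TV_replacement"),
    "trnH": (54, "TV_replacement"), "trnI": (44, "TV_replacement"),
    "trnL1": (55, "TV_replacement"), "trnM": (56, "TV_replacement"),
    "trnF": (53, "TV_replacement"), "trnP": (52, "TV_replacement"),
    "trnT": (54, "TV_replacement"), "trnW": (55, "TV_replacement"),
    "trnY": (48, "TV_replacement"),
}

# 11 overlapping junctions totalling 55 bp (keyed by (upstream, downstream)
# in the ground-pattern template).  The three large overlaps put a tRNA over
# an rRNA or control-region neighbour — the tRNA keeps its planted structure
# and the unconstrained neighbour donates the shared bases; small overlaps
# (<= 3 bp) at tRNA/tRNA junctions cost the upstream tRNA at most the
# acceptor-stem mismatch budget.
DEFAULT_OVERLAPS: dict[tuple[str, str], int] = {
    ("rrnL", "trnV"): 14, ("trnV", "rrnS"): 10, ("rrnS", "CR"): 13,
    ("trnK", "trnD"): 3, ("trnA", "trnR"): 3,
    ("trnN", "trnS1"): 2, ("trnS1", "trnE"): 2, ("trnI", "trnQ"): 2,
    ("trnQ", "trnM"): 2, ("trnC", "trnY"): 2, ("trnL2", "rrnL"): 2,
}

# ten intergenic spacers, 1-16 bp, totalling 52 bp
DEFAULT_SPACERS: dict[tuple[str, str], int] = {
    ("cox1", "cox2"): 16, ("cox2", "trnK"): 8, ("atp6", "cox3"): 6,
    ("nad3", "trnA"): 5, ("trnE", "trnF"): 4, ("nad4L", "trnT"): 3,
    ("trnT", "trnP"): 3, ("trnP", "nad6"): 3, ("nad6", "cob"): 2,
    ("CR", "trnI"): 2,
}


@dataclass
class GenomeSimConfig:
    target_length: int = 13077
    at_content: float = 0.85
    at_skew: float = -0.071  # signed (A-T)/(A+T) on the J strand
    gc_skew: float = 0.03
    order: GeneOrder | None = None  # default: arthropod ground pattern
    pcg_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    rrnl_length: int = 989
    rrns_length: int = 648
    cr_length: int = 57
    cr_t_stretch_j: tuple[int, int] = (6, 4)   # (offset from CR start, run length)
    cr_t_stretch_n: tuple[int, int] = (17, 6)  # (gap to CR end, A-run length)
    cr_hairpin: tuple[int, int] = (5, 5)       # (stem, loop), A/T-only arms
    trna_plan: dict[str, tuple[int, str]] = field(
        default_factory=lambda: dict(DEFAULT_TRNA_PLAN)
    )
    trna_acceptor_mismatches: int = 0
    overlaps: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_OVERLAPS)
    )
    spacers: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_SPACERS)
    )
    code_id: int = INVERTEBRATE_MITO_CODE
    seed: int = 0


@dataclass
class TruthManifest:
    features: list[dict]
    overlaps: dict
    spacers: dict
    trna_classes: dict[str, str]
    trna_anticodons: dict[str, str]
    realized_at_percent: float
    genome_length: int
    seed: int


def _base_probs(cfg: GenomeSimConfig) -> dict[str, float]:
    at, gc = cfg.at_content, 1.0 - cfg.at_content
    return {
        "A": at * (1 + cfg.at_skew) / 2,
        "T": at * (1 - cfg.at_skew) / 2,
        "G": gc * (1 + cfg.gc_skew) / 2,
        "C": gc * (1 - cfg.gc_skew) / 2,
    }


def _random_bases(rng, probs: dict[str, float], n: int) -> str:
    bases = np.array(list(probs))
    p = np.array(list(probs.values()))
    p = p / p.sum()
    return "".join(rng.choice(bases, size=n, p=p))


def _codon_weights(probs: dict[str, float], code_id: int):
    """Sense-codon sampling weights whose base *marginals* match ``probs``.

    Excluding the (A/T-rich) stop codons from a naive product distribution
    depresses the realized A+T content; a short fixed-point iteration on the
    per-base weights restores the target marginal composition.
    """
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[code_id]
    codons = [c for c in table.forward_table
              if len(c) == 3 and set(c) <= set("ACGT")]
    target = np.array([probs[b] for b in "ACGT"])
    target = target / target.sum()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.array([[idx[b] for b in c] for c in codons])
    q = target.copy()
    for _ in range(40):
        w = q[mat].prod(axis=1)
        w = w / w.sum()
        marginal = np.zeros(4)
        for k in range(4):
            marginal[k] = (w[:, None] * (mat == k)).sum() / 3.0
        q = q * np.where(marginal > 0, target / marginal, 1.0)
        q = q / q.sum()
    w = q[mat].prod(axis=1)
    return codons, w / w.sum()


def random_cds(
    rng, n_codons: int, probs: dict[str, float] | None = None,
    code_id: int = INVERTEBRATE_MITO_CODE, start: str = "ATT", stop: str = "TAA",
) -> str:
    """Random in-frame CDS: start codon + AT-biased sense codons + stop."""
    if probs is None:
        probs = {"A": 0.425, "T": 0.425, "G": 0.075, "C": 0.075}
    codons, w = _codon_weights(probs, code_id)
    body = rng.choice(codons, size=max(n_codons - 2, 0), p=w)
    return start + "".join(body) + stop


def _make_pcg(rng, name: str, length: int, probs, code_id: int) -> str:
    start = _START_CODONS.get(name, "ATT")
    rem = length % 3
    n_full = length // 3
    codons, w = _codon_weights(probs, code_id)
    body = "".join(rng.choice(codons, size=n_full - 2, p=w))
    if rem == 0:
        stop = "TAG" if name == "cob" else "TAA"
        return start + body + stop
    # truncated stop: one more body codon, then T / TA
    extra = rng.choice(codons, p=w)
    return start + body + extra + ("T" if rem == 1 else "TA")


# ---------------------------------------------------------------------------
# tRNA construction (stem-first, guaranteeing the declared structure class)
# ---------------------------------------------------------------------------

_NONPAIRING_FILL = "A"  # A·A never pairs, even with G·U wobble allowed


def _paired_stem(rng, k: int) -> tuple[str, str]:
    # AT-rich stems as in real mite tRNAs; A-T pairs are as detectable as G-C
    left = "".join(rng.choice(list("ACGT"), size=k, p=[0.35, 0.1, 0.2, 0.35]))
    return left, revcomp(left)


def _arm_region(rng, length: int, arm_min_loop: int = 3) -> str:
    """Region folding into a hairpin: >=2-bp stem closing a >=3-nt loop."""
    if length < 7:
        raise ValueError("arm region needs >= 7 nt")
    k = min(3, (length - arm_min_loop) // 2)
    left, right = _paired_stem(rng, k)
    return left + _NONPAIRING_FILL * (length - 2 * k) + right


def _loop_region(length: int) -> str:
    return _NONPAIRING_FILL * length


def _make_trna(rng, iso: str, length: int, klass: str,
               params: TrnaSearchParams, acceptor_mismatches: int = 0) -> dict:
    """Build one tRNA gene sequence with the declared structure class.

    Geometry: acceptor5(7) D-region acstem5(5) loop(7|8) acstem3(5) T-region
    acceptor3(7).
    """
    anticodon = EXPECTED_ANTICODONS[iso][0]
    loop_len = 8 if iso == "trnI" else 7
    core = 7 + 5 + loop_len + 5 + 7
    remaining = length - core
    if remaining < 0:
        raise ValueError(f"{iso}: length {length} below the structural minimum {core}")
    need_d = klass in ("cloverleaf", "TV_replacement")
    need_t = klass in ("cloverleaf", "D_replacement")
    min_d = 7 if need_d else 0
    min_t = 7 if need_t else 0
    if remaining < min_d + min_t:
        raise ValueError(f"{iso}: length {length} cannot host class {klass}")
    d_len = max(min_d, remaining // 2) if need_d else (remaining - min_t if need_t else remaining // 2)
    d_len = min(d_len, remaining - min_t, params.max_arm_region)
    t_len = remaining - d_len
    if t_len > params.max_arm_region:
        raise ValueError(f"{iso}: T region {t_len} exceeds search bound")
    acc5, acc3 = _paired_stem(rng, 7)
    for _ in range(acceptor_mismatches):
        pos = rng.integers(0, 7)
        cur = acc5[pos]
        acc5 = acc5[:pos] + str(rng.choice([b for b in "ACGT" if b != cur])) + acc5[pos + 1:]
    ac5, ac3 = _paired_stem(rng, 5)
    loop = ("CT" + anticodon + "AA") if loop_len == 7 else ("CT" + anticodon + "AAA")
    d_region = _arm_region(rng, d_len) if need_d else _loop_region(d_len)
    t_region = _arm_region(rng, t_len) if need_t else _loop_region(t_len)
    seq = acc5 + d_region + ac5 + loop + ac3 + t_region + acc3
    assert len(seq) == length
    # post-hoc structural self-check against the search constraints
    assert (_find_arm(d_region, params) is not None) == need_d, iso
    assert (_find_arm(t_region, params) is not None) == need_t, iso
    return {"sequence": seq, "anticodon": anticodon.replace("T", "U"),
            "class": klass, "length": length}


def _make_cr(cfg: GenomeSimConfig) -> str:
    """A+T-only control region with planted T-stretches and hairpin."""
    n = cfg.cr_length
    j_off, j_len = cfg.cr_t_stretch_j
    n_gap, n_len = cfg.cr_t_stretch_n
    stem, loop = cfg.cr_hairpin
    filler = ("AAT" * (n // 3 + 2))  # A-runs of 2, T-runs of 1: inert
    buf = list(filler[:n])
    # J-strand T-stretch at j_off
    for k in range(j_len):
        buf[j_off + k] = "T"
    if j_off > 0:
        buf[j_off - 1] = "A"
    buf[j_off + j_len] = "A"
    # hairpin (A/T arms) right after the T-stretch
    hp_start = j_off + j_len + 2
    arm = "TTATA"[:stem].ljust(stem, "T")
    hp = arm + "A" * loop + revcomp(arm)
    for k, ch in enumerate(hp):
        buf[hp_start + k] = ch
    # N-strand T-stretch = J-strand A-run ending n_gap before the CR end
    a_end = n - n_gap
    for k in range(n_len):
        buf[a_end - n_len + k] = "A"
    if a_end - n_len - 1 >= 0:
        buf[a_end - n_len - 1] = "T"
    if a_end < n:
        buf[a_end] = "T"
    out = "".join(buf[:n])
    if len(out) != n or set(out) - set("AT"):
        raise ValueError("control region construction failed")
    return out


def generate_mitogenome(
    config: GenomeSimConfig | None = None, seed: int | None = None
) -> tuple[MitoGenomeRecord, TruthManifest]:
    """Generate a circular annotated mitogenome plus its truth manifest.

    Features are laid out along the configured gene order with the declared
    junction overlaps/spacers; tRNA sequences are written last so an overlap
    never corrupts a planted tRNA (the overlapped neighbour donates the
    shared bases, mimicking truncated stops and abutting genes).
    """
    cfg = config or GenomeSimConfig()
    if seed is not None:
        cfg.seed = seed
    rng = np.random.default_rng(cfg.seed)
    probs = _base_probs(cfg)
    # reading-direction composition of an N-strand gene is the complement of
    # the J-strand target: strand asymmetry belongs to the molecule, not to
    # the reading frame
    probs_n = {"A": probs["T"], "T": probs["A"], "G": probs["C"], "C": probs["G"]}
    order = cfg.order or ground_pattern_order()
    params = TrnaSearchParams()

    seqs: dict[str, str] = {}
    kinds: dict[str, str] = {}
    trna_meta: dict[str, dict] = {}
    for name, orient in order.elements:
        p = probs if orient == "+" else probs_n
        if name in cfg.pcg_lengths:
            seqs[name] = _make_pcg(rng, name, cfg.pcg_lengths[name], p, cfg.code_id)
            kinds[name] = "PCG"
        elif name == "rrnL":
            seqs[name] = _random_bases(rng, p, cfg.rrnl_length)
            kinds[name] = "rRNA"
        elif name == "rrnS":
            seqs[name] = _random_bases(rng, p, cfg.rrns_length)
            kinds[name] = "rRNA"
        elif name == "CR":
            seqs[name] = _make_cr(cfg)
            kinds[name] = "control_region"
        elif name in cfg.trna_plan:
            length, klass = cfg.trna_plan[name]
            meta = _make_trna(rng, name, length, klass, params,
                              cfg.trna_acceptor_mismatches)
            seqs[name] = meta["sequence"]
            trna_meta[name] = meta
            kinds[name] = "tRNA"
        else:
            raise ValueError(f"no length specification for gene {name}")

    # --- layout along the circle ---
    elements = list(order.elements)
    begins: dict[str, int] = {}
    pos = 0
    for idx, (name, _orient) in enumerate(elements):
        if idx > 0:
            prev = elements[idx - 1][0]
            pos += cfg.spacers.get((prev, name), 0)
            pos -= cfg.overlaps.get((prev, name), 0)
            if pos < 0:
                raise ValueError(f"overlap before origin at junction {prev}/{name}")
        begins[name] = pos
        pos += len(seqs[name])
    last = elements[-1][0]
    first = elements[0][0]
    wrap_gap = cfg.spacers.get((last, first), 0) - cfg.overlaps.get((last, first), 0)
    layout_len = pos + wrap_gap
    if layout_len > cfg.target_length:
        raise ValueError(
            f"planted features ({layout_len} bp) exceed target length {cfg.target_length}"
        )
    # pad any deficit into the wrap junction
    L = cfg.target_length

    buf = list(_random_bases(rng, probs, L))
    # non-tRNA first; tRNAs written last keep their planted structure intact
    writing_order = [e for e in elements if kinds[e[0]] != "tRNA"] + [
        e for e in elements if kinds[e[0]] == "tRNA"
    ]
    for name, orient in writing_order:
        s = seqs[name] if orient == "+" else revcomp(seqs[name])
        b = begins[name]
        for k, ch in enumerate(s):
            buf[(b + k) % L] = ch
    sequence = "".join(buf)

    features = [
        GeneFeature(
            name=name,
            kind=kinds[name],
            strand="J" if orient == "+" else "N",
            begin=begins[name],
            end=begins[name] + len(seqs[name]),
            anticodon=trna_meta[name]["anticodon"] if name in trna_meta else None,
        )
        for name, orient in elements
    ]
    record = MitoGenomeRecord(
        id=f"SYN-{cfg.seed}",
        sequence=sequence,
        circular=True,
        features=features,
        source_taxon="synthetic mite-like mitogenome",
    )
    comp_at = 100.0 * sum(sequence.count(b) for b in "AT") / L
    manifest = TruthManifest(
        features=[
            {
                "name": f.name, "kind": f.kind, "strand": f.strand,
                "begin": f.begin, "end": f.end, "anticodon": f.anticodon,
            }
            for f in record.features
        ],
        overlaps={f"{a}/{b}": v for (a, b), v in cfg.overlaps.items()},
        spacers={f"{a}/{b}": v for (a, b), v in cfg.spacers.items()},
        trna_classes={k: v["class"] for k, v in trna_meta.items()},
        trna_anticodons={k: v["anticodon"] for k, v in trna_meta.items()},
        realized_at_percent=comp_at,
        genome_length=L,
        seed=cfg.seed,
    )
    return record, manifest


# ---------------------------------------------------------------------------
# Gene-order permutation with truth labels
# ---------------------------------------------------------------------------

def permute_order(
    reference: GeneOrder, n_translocations: int = 0, n_inversions: int = 0,
    seed: int = 0,
) -> tuple[GeneOrder, dict[str, str]]:
    """Apply seeded random block translocations and inversions.

    The anchor gene (cox1) is never moved or inverted, keeping orientations
    comparable after canonicalisation.  Truth labels follow the boundary
    definition: a gene is ``same_position`` iff both circular neighbours
    (with relative orientation) match the reference; inverted genes are
    ``translocated_and_inverted``.
    """
    rng = np.random.default_rng(seed)
    elems = list(reference.elements)
    inverted: set[str] = set()

    def pick_block(max_len=3):
        n = len(elems)
        while True:
            start = int(rng.integers(0, n))
            blen = int(rng.integers(1, max_len + 1))
            block = [elems[(start + k) % n] for k in range(blen)]
            if all(e[0] != "cox1" for e in block):
                return start, blen, block

    for _ in range(n_inversions):
        start, blen, block = pick_block()
        flipped = [(nm, "-" if s == "+" else "+") for nm, s in reversed(block)]
        for k in range(blen):
            elems[(start + k) % len(elems)] = flipped[k]
        inverted ^= {nm for nm, _s in block}  # double inversion cancels

    for _ in range(n_translocations):
        start, blen, block = pick_block()
        idxs = sorted(((start + k) % len(elems) for k in range(blen)), reverse=True)
        for i in idxs:
            del elems[i]
        dest = int(rng.integers(0, len(elems) + 1))
        elems[dest:dest] = block

    new_order = GeneOrder.from_elements(elems)
    labels = _truth_labels(new_order, reference)
    return new_order, labels


def _truth_labels(order: GeneOrder, reference: GeneOrder) -> dict[str, str]:
    """Independent neighbour-based labelling (same definition, direct code)."""
    ref_adj = reference.adjacencies()
    ref_orient = dict(reference.elements)
    from .gene_order import _canonical_adjacency  # shared canonical form

    labels = {}
    n = len(order.elements)
    for i, (name, orient) in enumerate(order.elements):
        if orient != ref_orient[name]:
            labels[name] = "translocated_and_inverted"
            continue
        left = _canonical_adjacency(order.elements[(i - 1) % n], order.elements[i])
        right = _canonical_adjacency(order.elements[i], order.elements[(i + 1) % n])
        labels[name] = (
            "same_position" if (left in ref_adj and right in ref_adj) else "translocated"
        )
    return labels


# ---------------------------------------------------------------------------
# CDS mutator with target substitution densities
# ---------------------------------------------------------------------------

def mutate_cds(
    cds: str, ks_target: float, ka_target: float,
    code_id: int = INVERTEBRATE_MITO_CODE, seed: int = 0,
) -> str:
    """Mutate an in-frame CDS towards target Ks/Ka (JC-corrected scales).

    Per codon position, a synonymous change is applied with probability
    ``fs * ps`` and a nonsynonymous (never stop-creating) change with
    probability ``fn * pn``, where fs/fn are the position's NG site
    fractions and ps/pn invert the Jukes-Cantor correction of the targets.
    """
    import math

    from Bio.Data import CodonTable

    if ks_target < 0 or ka_target < 0:
        raise ValueError("targets must be non-negative")
    ps = 0.75 * (1.0 - math.exp(-4.0 * ks_target / 3.0))
    pn = 0.75 * (1.0 - math.exp(-4.0 * ka_target / 3.0))
    if ps >= 0.75 or pn >= 0.75:
        raise ValueError("target rate saturates the JC correction")
    table = CodonTable.unambiguous_dna_by_id[code_id]
    rng = np.random.default_rng(seed)
    s = cds.upper().replace("U", "T")
    if len(s) % 3:
        raise ValueError("CDS length must be a codon multiple")
    out = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        aa0 = table.forward_table.get(codon)
        if aa0 is None:
            if i + 3 == len(s):
                out.append(codon)  # terminal stop untouched
                continue
            raise ValueError(f"internal stop codon at {i}")
        for pos in range(3):
            syn, non = [], []
            aa_cur = table.forward_table.get(codon)
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                aa1 = table.forward_table.get(alt)
                if aa1 is None:
                    continue  # rejection: never introduce a stop
                (syn if aa1 == aa_cur else non).append(alt)
            total = len(syn) + len(non)
            if not total:
                continue
            fs = len(syn) / total
            u = rng.random()
            if syn and u < fs * ps:
                codon = syn[int(rng.integers(0, len(syn)))]
            elif non and u < fs * ps + (1 - fs) * pn:
                codon = non[int(rng.integers(0, len(non)))]
        out.append(codon)
    return "".join(out)
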