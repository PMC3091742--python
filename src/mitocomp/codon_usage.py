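"""Codon counting and relative synonymous codon usage (RSCU).

RSCU for codon *i* in a synonymous family of size *k* with member counts
``n_j`` is ``RSCU_i = n_i * k / sum_j n_j``: the observed count divided by
the count expected if every codon in the family were used equally.  Within
each used family the RSCU values therefore sum to *k*.

Two synonymous-family maps over the invertebrate mitochondrial code (NCBI
table 5) are provided.  The default "paper" map splits leucine into the
CUN (L1, k=4) and UUR (L2, k=2) families while keeping all eight serine
codons (AGN + UCN, which are all Ser under table 5) as a single k=8 family —
the arithmetic used by the published mite codon-usage tables.  The
"standard" map groups every codon strictly by amino acid (Leu as one k=6
family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources

from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "SynonymousFamilyMap",
    "CodonCountTable",
    "RscuTable",
    "paper_family_map",
    "standard_family_map",
    "count_codons",
    "rscu",
    "codon_percent_report",
    "unused_codons",
    "codon_at_correlation",
    "load_table1",
    "display_round",
    "INVERTEBRATE_MITO_CODE",
]

INVERTEBRATE_MITO_CODE = 5

_BASES = "UCAG"


def display_round(numerator: int, denominator: int, scale: int = 1, dp: int = 2) -> float:
    """Round ``scale * numerator / denominator`` to *dp* decimals, half-up.

    Published codon-usage tables round the exact fraction half-up (2.125 ->
    2.13); binary floats round-half-even would disagree on such ties, so the
    ratio is carried exactly until rounding.
    """
    frac = Fraction(scale) * Fraction(numerator, denominator)
    return float(
        Decimal(frac.numerator).scaleb(dp)
        .__truediv__(Decimal(frac.denominator))
        .quantize(Decimal(1), rounding=ROUND_HALF_UP)
        .scaleb(-dp)
    )


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def _code_table(code_id: int):
    return CodonTable.unambiguous_rna_by_id[code_id]


@dataclass
class SynonymousFamilyMap:
    """codon -> (amino acid, family id) plus family id -> member codons."""

    code_id: int
    codon_to_family: dict[str, tuple[str, str]]
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.families:
            fams: dict[str, list[str]] = {}
            for codon, (_aa, fam) in self.codon_to_family.items():
                fams.setdefault(fam, []).append(codon)
            self.families = {f: tuple(sorted(c)) for f, c in fams.items()}

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, (_aa, f) in self.codon_to_family.items() if f != "stop")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c, (_aa, f) in self.codon_to_family.items() if f == "stop")

    def family_of(self, codon: str) -> str:
        return self.codon_to_family[_rna(codon)][1]


def _base_map(code_id: int) -> dict[str, tuple[str, str]]:
    table = _code_table(code_id)
    mapping = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                if codon in table.stop_codons:
                    mapping[codon] = ("*", "stop")
                else:
                    mapping[codon] = (table.forward_table[codon], table.forward_table[codon])
    return mapping


def standard_family_map(code_id: int = INVERTEBRATE_MITO_CODE) -> SynonymousFamilyMap:
    """Families strictly by amino acid (Leu is one six-codon family)."""
    return SynonymousFamilyMap(code_id, _base_map(code_id))


def paper_family_map(code_id: int = INVERTEBRATE_MITO_CODE) -> SynonymousFamilyMap:
    """The mite-table convention: Leu split into L1=CUN and L2=UUR, Ser kept
    as one eight-codon AGN+UCN family."""
    mapping = _base_map(code_id)
    for codon, (aa, _fam) in list(mapping.items()):
        if aa == "L":
            mapping[codon] = ("L", "L1" if codon.startswith("CU") else "L2")
    return SynonymousFamilyMap(code_id, mapping)


@dataclass
class CodonCountTable:
    """Per-codon counts over sense codons; stops tallied separately."""

    counts: dict[str, int]
    stop_counts: dict[str, int] = field(default_factory=dict)
    dropped_trailing_nt: int = 0
    skipped_ambiguous: int = 0
    code_id: int = INVERTEBRATE_MITO_CODE

    @property
    def total(self) -> int:
        """N: total sense codons."""
        return sum(self.counts.values())

    def percent(self, codon: str) -> float:
        return 100.0 * self.counts.get(_rna(codon), 0) / self.total


def count_codons(
    cds_seqs: list[str], code_id: int = INVERTEBRATE_MITO_CODE
) -> CodonCountTable:
    """Count codons over reading-direction CDS sequences.

    Trailing incomplete codons are dropped (and tallied); codons containing
    ambiguity symbols are excluded (and tallied); stop codons are counted
    separately and excluded from N.
    """
    table = _code_table(code_id)
    stops = set(table.stop_codons)
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    dropped = skipped = 0
    for seq in cds_seqs:
        s = _rna(seq)
        rem = len(s) % 3
        if rem:
            dropped += rem
            s = s[: len(s) - rem]
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if any(b not in "ACGU" for b in codon):
                skipped += 1
            elif codon in stops:
                stop_counts[codon] = stop_counts.get(codon, 0) + 1
            else:
                counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(counts, stop_counts, dropped, skipped, code_id)


@dataclass
class RscuTable:
    values: dict[str, float]
    undefined_families: tuple[str, ...] = ()
    family_map: SynonymousFamilyMap | None = None

    def __getitem__(self, codon: str) -> float:
        return self.values[_rna(codon)]


def rscu(counts: CodonCountTable, fam: SynonymousFamilyMap | None = None) -> RscuTable:
    """RSCU per sense codon under the declared family map.

    Families with zero total are flagged undefined (their codons get 0.0,
    matching how published tables print empty families).
    """
    if fam is None:
        fam = paper_family_map(counts.code_id)
    if fam.code_id != counts.code_id:
        raise ValueError("family map and counts use different genetic codes")
    values: dict[str, float] = {}
    undefined = []
    for fam_id, members in fam.families.items():
        if fam_id == "stop":
            continue
        total = sum(counts.counts.get(c, 0) for c in members)
        k = len(members)
        if total == 0:
            undefined.append(fam_id)
            for c in members:
                values[c] = 0.0
        else:
            for c in members:
                values[c] = counts.counts.get(c, 0) * k / total
    return RscuTable(values, tuple(undefined), fam)


def codon_percent_report(
    counts: CodonCountTable, top_codons: tuple[str, ...] = ("UUU", "UUA", "AUU", "AUA")
) -> dict:
    """Ranked per-codon percentages and the combined share of a named set.

    The default named set is the four AT-rich codons that dominate usage in
    AT-biased mitogenomes (Phe-UUU, Leu-UUA, Ile-AUU, Met-AUA).
    """
    if counts.total == 0:
        raise ValueError("empty codon count table")
    ranked = sorted(counts.counts, key=lambda c: (-counts.counts[c], c))
    return {
        "percent": {c: counts.percent(c) for c in ranked},
        "ranked": ranked,
        "named_set": tuple(_rna(c) for c in top_codons),
        "named_set_share": sum(counts.percent(c) for c in top_codons),
    }


def unused_codons(
    counts: CodonCountTable, code_id: int | None = None
) -> tuple[str, ...]:
    """Sense codons with zero observed count."""
    fam = standard_family_map(code_id or counts.code_id)
    return tuple(sorted(c for c in fam.sense_codons if counts.counts.get(c, 0) == 0))


def codon_at_correlation(per_genome: list[tuple[float, float]]):
    """Pearson correlation between top-codon share and genome A+T%, across genomes."""
    if len(per_genome) < 3:
        raise ValueError("need at least 3 genomes")
    xs = [p[0] for p in per_genome]
    ys = [p[1] for p in per_genome]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return {"r": None, "p": None, "undefined": True}
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "undefined": False}


def load_table1():
    """The published citrus-red-mite codon-usage table shipped as package data.

    Returns (CodonCountTable, printed) where printed maps codon ->
    (family label, printed percent, printed RSCU).
    """
    text = (
        resources.files("mitocomp").joinpath("data/table1_codon_usage.tsv").read_text()
    )
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    printed: dict[str, tuple[str, float, float]] = {}
    for line in text.strip().splitlines()[1:]:
        aa, codon, n, percent, rs = line.split("\t")
        n = int(n)
        if aa == "Stop":
            stop_counts[codon] = n
        else:
            counts[codon] = n
        printed[codon] = (aa, float(percent), float(rs))
    return CodonCountTable(counts, stop_counts), printed
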