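"""Annotated mitogenome I/O and circular-coordinate plumbing.

A mitochondrial genome is held as a :class:`MitoGenomeRecord`: the J-strand
nucleotide sequence plus an ordered feature table over the canonical 37-gene
metazoan vocabulary (13 protein-coding genes, 2 rRNAs, 22 tRNA isoacceptors)
and the control region.  Coordinates are 0-based half-open on the J strand;
GenBank's 1-based inclusive convention is converted at the I/O boundary.
Features on a circular molecule may wrap the origin, encoded as
``end > len(sequence)`` with all arithmetic modulo the genome length.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GENE_VOCABULARY",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "GeneFeature",
    "MitoGenomeRecord",
    "GeneNameMap",
    "DEFAULT_NAME_MAP",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "feature_table",
    "write_feature_table",
    "extract_gene_seq",
    "delimit_rrna_boundaries",
    "audit_start_stop",
    "revcomp",
    "GenomeParseError",
]

PCG_NAMES = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)
TRNA_NAMES = tuple(
    "trn" + x
    for x in ("A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
              "L1", "L2", "K", "M", "F", "P", "S1", "S2", "T", "W", "Y", "V")
)
RRNA_NAMES = ("rrnL", "rrnS")
CONTROL_REGION = "CR"
#: the 37 canonical metazoan mitochondrial genes plus the control region
GENE_VOCABULARY = PCG_NAMES + RRNA_NAMES + TRNA_NAMES + (CONTROL_REGION,)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeParseError(ValueError):
    """Raised for malformed or internally inconsistent genome records."""


@dataclass
class GeneFeature:
    """One annotated gene on the J-strand reference frame.

    ``begin``/``end`` are 0-based half-open; ``end`` may exceed the genome
    length to encode a feature wrapping the origin of a circular molecule.
    ``strand`` is ``"J"`` (majority) or ``"N"`` (minority, i.e. the feature is
    read as the reverse complement of the J-strand slice).
    """

    name: str
    kind: str  # PCG | rRNA | tRNA | control_region | other
    strand: str
    begin: int
    end: int
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.begin:
            raise GenomeParseError(
                f"feature {self.name}: end ({self.end}) must exceed begin ({self.begin})"
            )
        if self.strand not in ("J", "N"):
            raise GenomeParseError(f"feature {self.name}: strand must be J or N")

    @property
    def length(self) -> int:
        return self.end - self.begin

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class MitoGenomeRecord:
    """Circular (or linear) mitogenome: sequence + ordered feature table."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    source_taxon: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeParseError(f"record {self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        self.sort_features()

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.begin, f.end))

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def length(self) -> int:
        return len(self.sequence)


class GeneNameMap:
    """Alias -> canonical gene-name dictionary.

    Lookups are case-insensitive and whitespace/punctuation tolerant; unknown
    aliases are reported to the caller, never silently dropped.
    """

    def __init__(self, aliases: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        for name in GENE_VOCABULARY:
            self._map[self._key(name)] = name
        if aliases:
            for alias, canon in aliases.items():
                self.add(alias, canon)

    @staticmethod
    def _key(label: str) -> str:
        return "".join(c for c in label.lower() if c.isalnum())

    def add(self, alias: str, canonical: str) -> None:
        base = canonical.rstrip("_0123456789") if canonical not in GENE_VOCABULARY else canonical
        if canonical not in GENE_VOCABULARY and base not in GENE_VOCABULARY:
            raise ValueError(f"{canonical!r} is not in the 37-gene vocabulary")
        self._map[self._key(alias)] = canonical

    def resolve(self, label: str) -> str | None:
        """Canonical name for *label*, or None if unmappable."""
        return self._map.get(self._key(label))


_DEFAULT_ALIASES = {
    # protein-coding genes
    "COI": "cox1", "COII": "cox2", "COIII": "cox3", "CO1": "cox1",
    "CO2": "cox2", "CO3": "cox3", "COX-1": "cox1", "COX-2": "cox2",
    "COX-3": "cox3", "cytochrome c oxidase subunit I": "cox1",
    "cytochrome c oxidase subunit II": "cox2",
    "cytochrome c oxidase subunit III": "cox3",
    "cytb": "cob", "cob": "cob", "CYTB": "cob", "cytochrome b": "cob",
    "ND1": "nad1", "ND2": "nad2", "ND3": "nad3", "ND4": "nad4",
    "ND4L": "nad4L", "ND5": "nad5", "ND6": "nad6",
    "NADH dehydrogenase subunit 1": "nad1",
    "NADH dehydrogenase subunit 2": "nad2",
    "NADH dehydrogenase subunit 3": "nad3",
    "NADH dehydrogenase subunit 4": "nad4",
    "NADH dehydrogenase subunit 4L": "nad4L",
    "NADH dehydrogenase subunit 5": "nad5",
    "NADH dehydrogenase subunit 6": "nad6",
    "ATP6": "atp6", "ATP8": "atp8", "ATPase6": "atp6", "ATPase8": "atp8",
    "ATP synthase F0 subunit 6": "atp6", "ATP synthase F0 subunit 8": "atp8",
    # rRNAs
    "l-rRNA": "rrnL", "s-rRNA": "rrnS", "16S": "rrnL", "12S": "rrnS",
    "16S ribosomal RNA": "rrnL", "12S ribosomal RNA": "rrnS",
    "large subunit ribosomal RNA": "rrnL",
    "small subunit ribosomal RNA": "rrnS",
    "lrRNA": "rrnL", "srRNA": "rrnS",
    # control region
    "D-loop": "CR", "control region": "CR", "A+T-rich region": "CR",
    "AT-rich region": "CR", "putative control region": "CR",
    # tRNAs: tRNA-Xxx three-letter forms
    "tRNA-Ala": "trnA", "tRNA-Arg": "trnR", "tRNA-Asn": "trnN",
    "tRNA-Asp": "trnD", "tRNA-Cys": "trnC", "tRNA-Gln": "trnQ",
    "tRNA-Glu": "trnE", "tRNA-Gly": "trnG", "tRNA-His": "trnH",
    "tRNA-Ile": "trnI", "tRNA-Lys": "trnK", "tRNA-Met": "trnM",
    "tRNA-Phe": "trnF", "tRNA-Pro": "trnP", "tRNA-Thr": "trnT",
    "tRNA-Trp": "trnW", "tRNA-Tyr": "trnY", "tRNA-Val": "trnV",
    "tRNA-Leu(CUN)": "trnL1", "tRNA-Leu(UUR)": "trnL2",
    "tRNA-Ser(AGN)": "trnS1", "tRNA-Ser(UCN)": "trnS2",
    "tRNA-Leu (CUN)": "trnL1", "tRNA-Leu (UUR)": "trnL2",
    "tRNA-Ser (AGN)": "trnS1", "tRNA-Ser (UCN)": "trnS2",
}

DEFAULT_NAME_MAP = GeneNameMap(_DEFAULT_ALIASES)


def _kind_for(name: str, gb_type: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name.startswith("trn"):
        return "tRNA"
    if name == CONTROL_REGION:
        return "control_region"
    return {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "control_region"}.get(
        gb_type, "other"
    )


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature")


def _feature_label(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def read_genbank(path, name_map: GeneNameMap = DEFAULT_NAME_MAP) -> MitoGenomeRecord:
    """Read a single-locus GenBank flat file into a :class:`MitoGenomeRecord`.

    The circular flag is taken from the LOCUS topology; complement locations
    map to strand N; origin-spanning ``join`` locations collapse to a single
    wrap-encoded feature.  Gene labels run through *name_map*; unmappable
    labels are kept verbatim and reported in ``record.warnings``.
    """
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenomeParseError(f"malformed GenBank record {path}: {exc}") from exc
    length = len(seqrec.seq)
    circular = seqrec.annotations.get("topology", "linear") == "circular"
    rec = MitoGenomeRecord(
        id=seqrec.id or seqrec.name,
        sequence=str(seqrec.seq),
        circular=circular,
        source_taxon=seqrec.annotations.get("organism", ""),
    )
    for feat in seqrec.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        label = _feature_label(feat)
        if feat.type == "misc_feature" and name_map.resolve(label) != CONTROL_REGION:
            continue
        begin, end = _collapse_location(feat.location, length, circular, label)
        strand = "N" if feat.location.strand == -1 else "J"
        canon = name_map.resolve(label)
        if canon is None:
            rec.warnings.append(f"unmappable gene label kept verbatim: {label!r}")
            canon = label
        anticodon = None
        if "anticodon" in feat.qualifiers:
            ac = str(feat.qualifiers["anticodon"][0])
            anticodon = ac.split("seq:")[-1].strip(")").upper() if "seq:" in ac else ac.upper()
        rec.features.append(
            GeneFeature(canon, _kind_for(canon, feat.type), strand, begin, end, anticodon)
        )
    rec.sort_features()
    return rec


def _collapse_location(loc, length: int, circular: bool, label: str) -> tuple[int, int]:
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end)
    if len(parts) == 2 and circular and int(parts[1].end) == length and int(parts[0].start) == 0:
        # join(X..length, 1..Y): wraps the origin
        return int(parts[1].start), length + int(parts[0].end)
    raise GenomeParseError(f"feature {label!r}: unsupported compound location {loc}")


_GB_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control_region": "D-loop",
            "other": "misc_feature"}


def write_genbank(record: MitoGenomeRecord, path) -> None:
    """Write a record as a GenBank flat file (round-trip safe)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id.split(".")[0][:16],
        description=record.source_taxon or record.id,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.source_taxon,
        },
    )
    L = record.length
    for f in record.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps(L):
            loc = CompoundLocation(
                [SimpleLocation(f.begin, L, strand), SimpleLocation(0, f.end - L, strand)]
            )
        else:
            loc = SimpleLocation(f.begin, f.end, strand)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        seqrec.features.append(SeqFeature(loc, type=_GB_TYPE.get(f.kind, "misc_feature"),
                                          qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


def read_fasta(path, circular: bool = True) -> MitoGenomeRecord:
    """Read an unannotated sequence; features start empty."""
    seqrec = SeqIO.read(str(path), "fasta")
    return MitoGenomeRecord(id=seqrec.id, sequence=str(seqrec.seq), circular=circular)


def write_fasta(record: MitoGenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id} {record.source_taxon}\n")
        for i in range(0, record.length, 70):
            fh.write(record.sequence[i : i + 70] + "\n")


def feature_table(record: MitoGenomeRecord) -> list[dict]:
    """Feature table rows with GenBank-style 1-based inclusive coordinates."""
    return [
        {
            "name": f.name,
            "kind": f.kind,
            "strand": f.strand,
            "begin_1based": f.begin + 1,
            "end_1based": f.end,
            "length": f.length,
        }
        for f in record.features
    ]


def write_feature_table(record: MitoGenomeRecord, path) -> None:
    rows = feature_table(record)
    with open(path, "w") as fh:
        cols = ["name", "kind", "strand", "begin_1based", "end_1based", "length"]
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction and annotation rules
# ---------------------------------------------------------------------------

def extract_gene_seq(record: MitoGenomeRecord, feature: GeneFeature) -> str:
    """Reading-direction sequence of *feature*.

    J-strand slice for strand J, reverse complement for strand N; wraps
    across the origin for circular records.
    """
    L = record.length
    if feature.wraps(L):
        if not record.circular:
            raise GenomeParseError(
                f"feature {feature.name} wraps the origin of a non-circular record"
            )
        seq = record.sequence[feature.begin:] + record.sequence[: feature.end - L]
    else:
        seq = record.sequence[feature.begin : feature.end]
    return revcomp(seq) if feature.strand == "N" else seq


def delimit_rrna_boundaries(record: MitoGenomeRecord) -> MitoGenomeRecord:
    """Reset each rRNA's ends to abut its flanking tRNAs exactly.

    Implements the annotation rule that an rRNA's 5' and 3' ends are the first
    nucleotides downstream/upstream of the neighbouring tRNA genes, i.e. after
    this call gap and overlap between each rRNA and both flanking tRNAs are
    zero.  All other features are untouched; a new record is returned.
    """
    L = record.length
    trnas = [f for f in record.features if f.kind == "tRNA"]
    if not trnas:
        raise GenomeParseError("record has no tRNA features to delimit against")
    new_feats = []
    for f in record.features:
        if f.kind != "rRNA":
            new_feats.append(replace(f))
            continue
        left = _nearest_trna(trnas, f.begin, L, side="left")
        right = _nearest_trna(trnas, f.end, L, side="right")
        if left is None or right is None:
            missing = "5'" if left is None else "3'"
            raise GenomeParseError(f"{f.name}: no flanking tRNA on the {missing} side")
        begin = left.end % L
        end = right.begin % L
        if end <= begin:
            end += L  # wraps the origin
        new_feats.append(replace(f, begin=begin, end=end))
    return MitoGenomeRecord(
        id=record.id,
        sequence=record.sequence,
        circular=record.circular,
        features=new_feats,
        source_taxon=record.source_taxon,
        warnings=list(record.warnings),
    )


def _nearest_trna(trnas, pos: int, L: int, side: str):
    """Closest tRNA ending before (left) or beginning after (right) pos, circularly."""
    best, best_d = None, None
    for t in trnas:
        if side == "left":
            d = (pos - t.end) % L
        else:
            d = (t.begin - pos) % L
        if best_d is None or d < best_d:
            best, best_d = t, d
    return best


def audit_start_stop(record: MitoGenomeRecord) -> list[dict]:
    """Start/stop codon audit for every protein-coding gene.

    Returns one row per PCG: first triplet, terminal stop (TAA/TAG or the
    truncated TA/T completed by polyadenylation), and an incomplete flag when
    the gene length is not a codon multiple or the stop is truncated.
    """
    rows = []
    for f in record.features:
        if f.kind != "PCG":
            continue
        seq = extract_gene_seq(record, f)
        if len(seq) < 6:
            raise GenomeParseError(f"{f.name}: shorter than 2 codons")
        start = seq[:3]
        rem = len(seq) % 3
        if rem == 0:
            tail = seq[-3:]
            if tail in ("TAA", "TAG"):
                stop, complete = tail, True
            else:
                stop, complete = "", False
        else:
            tail = seq[-rem:]
            stop = tail if tail in ("T", "TA") else ""
            complete = False
        rows.append(
            {"gene": f.name, "start_codon": start, "stop_codon": stop,
             "complete_stop": complete}
        )
    if not rows:
        raise GenomeParseError("record has no protein-coding genes")
    return rows
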