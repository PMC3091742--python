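"""Composition, skews, and control-region motif scans."""

import pytest
from hypothesis import given, settings, strategies as st

from mitocomp.composition import (
    BaseComposition,
    base_composition,
    codon_position_composition,
    find_stem_loops,
    find_t_stretches,
    skews,
)
from mitocomp.genome_io import GeneFeature, MitoGenomeRecord, revcomp

# published J-strand composition of the mite genome, scaled to counts
PRINTED = BaseComposition(a=3962, t=4566, g=758, c=714)


class TestPrintedCompositionIdentities:
    def test_at_percent(self):
        assert round(PRINTED.at_percent, 2) == 85.28

    def test_gc_skew_positive(self):
        assert round(skews(PRINTED).gc_skew_signed, 2) == 0.03

    def test_at_skew_magnitude(self):
        sk = skews(PRINTED)
        assert round(sk.at_skew_magnitude, 3) == 0.071
        # the signed value under (A-T)/(A+T) is negative for this composition
        assert sk.at_skew_signed < 0


def test_base_composition_trivials():
    c = base_composition("AATT")
    assert (c.fraction("A"), c.fraction("T"), c.g, c.c) == (50.0, 50.0, 0, 0)
    c = base_composition("ACGTN")
    assert (c.a, c.c, c.g, c.t, c.n_ambiguous) == (1, 1, 1, 1, 1)
    assert c.fraction("A") == 25.0


def test_base_composition_empty_errors():
    with pytest.raises(ValueError):
        base_composition("")


def test_equal_bases_zero_skew():
    sk = skews(base_composition("ATGC"))
    assert sk.at_skew_signed == 0 and sk.gc_skew_signed == 0


def test_zero_denominator_flagged_not_nan():
    sk = skews(base_composition("AT"))
    assert sk.gc_skew_signed is None and sk.gc_skew_magnitude is None


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ACGT", min_size=4, max_size=200))
def test_skews_antisymmetric_under_revcomp(seq):
    sk = skews(base_composition(seq))
    rk = skews(base_composition(revcomp(seq)))
    for a, b in ((sk.at_skew_signed, rk.at_skew_signed),
                 (sk.gc_skew_signed, rk.gc_skew_signed)):
        if a is None:
            assert b is None
        else:
            assert b == pytest.approx(-a, abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
def test_counts_sum_to_length(seq):
    c = base_composition(seq)
    assert c.total + c.n_ambiguous == len(seq)


def test_codon_position_composition_examples():
    assert codon_position_composition(["ATG"]) == (100.0, 100.0, 0.0)
    # hand count: pos1 (A,G)->50, pos2 (T,C)->50, pos3 (G,C)->0
    assert codon_position_composition(["ATGGCC"]) == (50.0, 50.0, 0.0)
    with pytest.raises(ValueError):
        codon_position_composition([])


def test_codon_position_drops_trailing_partial():
    # trailing "AT" dropped: identical to the complete-codon call
    assert codon_position_composition(["ATGGCCAT"]) == codon_position_composition(["ATGGCC"])


# ---------------------------------------------------------------------------
# T-stretches
# ---------------------------------------------------------------------------

def _plain_record(seq):
    return MitoGenomeRecord(id="x", sequence=seq, circular=False,
                            features=[GeneFeature("cox1", "PCG", "J", 0, 1)])


def test_t_stretch_trivials():
    assert find_t_stretches(_plain_record("AAAA"), min_len=2, strand="J") == []
    runs = find_t_stretches(_plain_record("TTTT"), min_len=4, strand="J")
    assert len(runs) == 1 and runs[0].length == 4
    # A-runs are N-strand T-stretches
    runs = find_t_stretches(_plain_record("CAAAAC"), min_len=4, strand="N")
    assert len(runs) == 1 and runs[0].strand == "N" and runs[0].length == 4


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="AT", min_size=1, max_size=150), st.integers(1, 5))
def test_t_stretches_are_maximal(seq, min_len):
    rec = _plain_record(seq)
    for run in find_t_stretches(rec, min_len=min_len, strand="J"):
        assert set(seq[run.begin : run.end]) == {"T"}
        assert run.length >= min_len
        assert run.begin == 0 or seq[run.begin - 1] != "T"
        assert run.end == len(seq) or seq[run.end] != "T"


def test_planted_cr_t_stretches(synthetic_record, synthetic_manifest):
    cr = synthetic_record.feature("CR")
    runs = find_t_stretches(synthetic_record, cr, min_len=4)
    j_runs = [r for r in runs if r.strand == "J"]
    n_runs = [r for r in runs if r.strand == "N"]
    # planted: 4-bp J stretch 6 nt into the CR; 6-bp N stretch 17 nt from its end
    assert any(r.length == 4 and r.begin == cr.begin + 6 for r in j_runs)
    assert any(r.length == 6 and cr.end - r.end == 17 for r in n_runs)


# ---------------------------------------------------------------------------
# Stem-loops vs brute-force oracle
# ---------------------------------------------------------------------------

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _oracle_stem_loops(seq, min_stem, max_mismatch, loop_bounds):
    """O(n^3) enumeration: for every loop placement, the longest stem whose
    outermost base pairs and whose mismatches stay within budget."""
    n = len(seq)
    lo, hi = loop_bounds
    found = set()
    for ls in range(1, n):
        for ll in range(lo, hi + 1):
            best = None
            for k in range(1, min(ls, n - ls - ll) + 1):
                arm5 = seq[ls - k : ls]
                arm3 = seq[ls + ll : ls + ll + k]
                mm = sum(
                    1 for x, y in zip(arm5, reversed(arm3)) if (x, y) not in _PAIR
                )
                outermost_pairs = (arm5[0], arm3[-1]) in _PAIR
                if mm > max_mismatch:
                    break
                if k >= min_stem and outermost_pairs:
                    best = (ls - k, ls, ls + ll, ls + ll + k, mm)
            if best:
                found.add(best)
    return found


def test_stem_loop_worked_example():
    cands = find_stem_loops("GGGCAAAAAGCCC", min_stem=4, max_mismatch=0)
    assert len(cands) == 1
    c = cands[0]
    assert (c.stem_length, c.loop_length, c.mismatches) == (4, 5, 0)
    assert (c.arm5_begin, c.arm5_end, c.arm3_begin, c.arm3_end) == (0, 4, 9, 13)


def test_stem_loop_homopolymer_empty():
    assert find_stem_loops("AAAAAAAA", min_stem=2) == []


@settings(max_examples=60, deadline=None)
@given(st.text(alphabet="ACGT", min_size=10, max_size=60),
       st.integers(2, 4), st.integers(0, 1))
def test_stem_loops_match_bruteforce_oracle(seq, min_stem, max_mismatch):
    loop_bounds = (3, 10)
    got = {
        (c.arm5_begin, c.arm5_end, c.arm3_begin, c.arm3_end, c.mismatches)
        for c in find_stem_loops(seq, min_stem, max_mismatch, loop_bounds)
    }
    assert got == _oracle_stem_loops(seq, min_stem, max_mismatch, loop_bounds)


def test_planted_cr_hairpin_found(synthetic_record, synthetic_manifest):
    cr = synthetic_record.feature("CR")
    sub = synthetic_record.sequence[cr.begin : cr.end]
    cands = find_stem_loops(sub, min_stem=5, max_mismatch=0)
    # the planted hairpin sits right after the 4-bp T-stretch (offset 12)
    assert any(c.arm5_begin <= 12 < c.arm3_end for c in cands)


def test_flanking_motif_annotation():
    seq = "AATATAGGGCAAAAAGCCCGAATAA"
    c = find_stem_loops(seq, min_stem=4, max_mismatch=0)[0]
    assert c.has_tata_upstream and c.has_gaat_downstream
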