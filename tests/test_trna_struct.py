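"""Constraint-based tRNA search, assignment and classification."""

import numpy as np
import pytest

from conftest import mutated_reference_set, trna_truth
from mitocomp.genome_io import extract_gene_seq, revcomp
from mitocomp.trna_struct import (
    EXPECTED_ANTICODONS,
    TrnaAnnotation,
    TrnaSearchParams,
    assign_isoacceptors,
    classify_structure,
    find_trna_candidates,
    trna_size_summary,
    _pairs,
)
from mitocomp.synthetic_data import GenomeSimConfig, generate_mitogenome, _make_trna


def _planted(iso="trnQ", length=52, klass="TV_replacement", seed=5):
    rng = np.random.default_rng(seed)
    return _make_trna(rng, iso, length, klass, TrnaSearchParams())


def _embed(trna_seq, seed=9, flank=450):
    """Plant a tRNA in AT-rich random background (linear)."""
    rng = np.random.default_rng(seed)
    bg = "".join(rng.choice(list("ACGT"), size=2 * flank, p=[0.44, 0.06, 0.08, 0.42]))
    return bg[:flank] + trna_seq + bg[flank:], flank


def test_planted_trna_recovered_with_correct_anticodon():
    meta = _planted()
    seq, off = _embed(meta["sequence"])
    cands = find_trna_candidates(seq, circular=False)
    hits = [
        c for c in cands
        if c.anticodon == meta["anticodon"]
        and max(0, min(c.end, off + meta["length"]) - max(c.begin, off))
        >= 0.9 * meta["length"]
    ]
    assert hits, "planted tRNA not recovered"
    assert any(c.structure_class == "TV_replacement" for c in hits)


def test_candidates_satisfy_their_own_params():
    meta = _planted(iso="trnE", length=55, klass="D_replacement", seed=11)
    seq, _ = _embed(meta["sequence"], seed=12)
    params = TrnaSearchParams()
    for c in find_trna_candidates(seq, params, circular=False):
        assert params.min_len <= c.length <= params.max_len
        assert c.acceptor_mismatches <= params.max_acceptor_mismatch
        assert c.anticodon_mismatches <= params.max_anticodon_mismatch
        # re-validate the acceptor stem directly from the emitted sequence
        s = c.sequence
        mm = sum(
            0 if _pairs(s[k], s[len(s) - 1 - k]) else 1
            for k in range(params.acceptor_stem_len)
        )
        assert mm == c.acceptor_mismatches


def test_strand_reflection_symmetry():
    meta = _planted(iso="trnF", length=53, seed=21)
    seq, _ = _embed(meta["sequence"], seed=22, flank=150)
    # no per-anchor truncation: the emitted sets must mirror exactly
    params = TrnaSearchParams(top_k_per_anchor=10_000)
    fwd = find_trna_candidates(seq, params, circular=False)
    rev = find_trna_candidates(revcomp(seq), params, circular=False)
    L = len(seq)
    fwd_set = {(c.strand, c.begin, c.end, c.anticodon) for c in fwd}
    # reflected: J<->N, coordinates mirrored
    rev_set = {
        ({"J": "N", "N": "J"}[c.strand], L - c.end, L - c.begin, c.anticodon)
        for c in rev
    }
    assert fwd_set == rev_set


def test_trni_eight_nt_anticodon_loop():
    meta = _planted(iso="trnI", length=44, klass="TV_replacement", seed=31)
    seq, off = _embed(meta["sequence"], seed=32)
    cands = find_trna_candidates(seq, circular=False)
    hits = [c for c in cands if c.anticodon == "GAU" and c.anticodon_loop_len == 8
            and abs(c.begin - off) <= 3]
    assert hits


def test_armless_candidate_classified():
    meta = _planted(iso="trnC", length=50, klass="armless_candidate", seed=41)
    seq, off = _embed(meta["sequence"], seed=42)
    cands = [c for c in find_trna_candidates(seq, circular=False)
             if c.anticodon == meta["anticodon"] and abs(c.begin - off) <= 2]
    assert cands and cands[0].structure_class == "armless_candidate"


def test_classify_structure_paths():
    base = dict(name=None, strand="J", begin=0, end=50, anticodon="UUG",
                acceptor_mismatches=0, anticodon_mismatches=0)
    assert classify_structure(TrnaAnnotation(**base, d_arm_present=True,
                                             t_arm_present=True)) == "cloverleaf"
    assert classify_structure(TrnaAnnotation(**base, d_arm_present=True,
                                             t_arm_present=False)) == "TV_replacement"
    assert classify_structure(TrnaAnnotation(**base, d_arm_present=False,
                                             t_arm_present=True)) == "D_replacement"
    assert classify_structure(TrnaAnnotation(**base, d_arm_present=False,
                                             t_arm_present=False)) == "armless_candidate"


def test_full_genome_assignment(synthetic_record, synthetic_manifest):
    refs = mutated_reference_set(synthetic_record, divergence=0.10, seed=3)
    cands = find_trna_candidates(synthetic_record)
    res = assign_isoacceptors(cands, refs, genome_length=synthetic_record.length)
    truth = trna_truth(synthetic_record)
    assert len(res["assigned"]) >= 21
    correct = 0
    for iso, ann in res["assigned"].items():
        st_, b, e = truth[iso]
        ovl = max(0, min(e, ann.end) - max(b, ann.begin))
        if ann.strand == st_ and ovl >= 0.9 * (e - b):
            correct += 1
    assert correct >= 21
    # planted structure classes recovered for correctly located genes
    for iso, ann in res["assigned"].items():
        st_, b, e = truth[iso]
        if ann.strand == st_ and ann.begin == b and ann.end == e:
            assert ann.structure_class == synthetic_manifest.trna_classes[iso]


def test_identical_reference_gets_maximal_identity(synthetic_record):
    from mitocomp.trna_struct import ReferenceTrnaSet

    refs = ReferenceTrnaSet({
        f.name: extract_gene_seq(synthetic_record, f)
        for f in synthetic_record.features if f.kind == "tRNA"
    })
    cands = find_trna_candidates(synthetic_record)
    res = assign_isoacceptors(cands, refs, genome_length=synthetic_record.length)
    idents = [a.alignment_identity for a in res["assigned"].values()]
    assert max(idents) == pytest.approx(1.0)
    assert sum(1 for i in idents if i == pytest.approx(1.0)) >= 20


def test_negative_control_random_sequence():
    """AT-rich random sequence with no planted tRNA: strict parameters leave
    nothing that aligns convincingly to real references."""
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=1000, p=[0.44, 0.06, 0.08, 0.42]))
    strict = TrnaSearchParams(max_acceptor_mismatch=0, max_anticodon_mismatch=0)
    cands = find_trna_candidates(seq, strict, circular=False)
    # references from an unrelated synthetic genome
    rec, _ = generate_mitogenome(seed=77)
    refs = mutated_reference_set(rec, divergence=0.10, seed=78)
    res = assign_isoacceptors(cands, refs, min_identity=0.80)
    assert len(res["assigned"]) == 0


def test_overlap_never_disqualifies(synthetic_record, synthetic_manifest):
    # the genome plants trnI overlapping the control region by 13 nt and
    # trnV overlapping both rRNAs; all three must still be recoverable
    refs = mutated_reference_set(synthetic_record, divergence=0.05, seed=5)
    cands = find_trna_candidates(synthetic_record)
    res = assign_isoacceptors(cands, refs, genome_length=synthetic_record.length)
    truth = trna_truth(synthetic_record)
    for iso in ("trnI", "trnV"):
        ann = res["assigned"].get(iso)
        assert ann is not None
        st_, b, e = truth[iso]
        assert ann.strand == st_ and abs(ann.begin - b) <= 3


def test_size_summary():
    def ann(length):
        return TrnaAnnotation("trnA", "J", 0, length, "UGC", 0, 0, True, False)

    s = trna_size_summary([ann(50), ann(60)])
    assert s["mean"] == 55 and round(s["sd"], 2) == 7.07
    assert (s["min"], s["max"]) == (50, 60)
    s = trna_size_summary([ann(50), ann(50), ann(50)])
    assert s["sd"] == 0.0
    with pytest.raises(ValueError):
        trna_size_summary([])


def test_synthetic_sizes_in_range(synthetic_record):
    anns = [
        TrnaAnnotation(f.name, f.strand, f.begin, f.end, f.anticodon or "",
                       0, 0, False, False)
        for f in synthetic_record.features if f.kind == "tRNA"
    ]
    s = trna_size_summary(anns)
    assert s["n"] == 22
    assert 44 <= s["min"] and s["max"] <= 65
    assert 52 <= s["mean"] <= 56


def test_expected_anticodons_cover_22_isoacceptors():
    assert len(EXPECTED_ANTICODONS) == 22
    assert all(len(a) == 3 for acs in EXPECTED_ANTICODONS.values() for a in acs)
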