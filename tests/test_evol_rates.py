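"""JC distances, NG86 Ka/Ks vs a brute-force pathway oracle, bootstrap."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, seed as hyp_seed, settings, strategies as st

from Bio.Data import CodonTable

from mitocomp.evol_rates import (
    back_translate,
    bootstrap_se,
    jc_distance,
    jc_gamma_distance,
    ng_kaks,
    pearson_p_from_r,
    rate_gc_correlation,
)

TABLE5 = CodonTable.unambiguous_dna_by_id[5]
SENSE = [c for c in TABLE5.forward_table if set(c) <= set("ACGT") and len(c) == 3]


# ---------------------------------------------------------------------------
# Independent brute-force oracle (written first, frozen expected values)
# ---------------------------------------------------------------------------

def oracle_syn_sites(codon):
    """Per-codon synonymous sites by direct enumeration."""
    aa0 = TABLE5.forward_table[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            aa1 = TABLE5.forward_table.get(alt)
            if aa1 is None:
                continue
            valid += 1
            syn += aa1 == aa0
        if valid:
            s += syn / valid
    return s


def oracle_pair(c1, c2):
    """(Sd, Nd) by explicit enumeration of all substitution orderings."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths, stop_free = [], []
    for order in permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            a0 = TABLE5.forward_table.get(cur)
            a1 = TABLE5.forward_table.get(nxt)
            if a1 is None:
                ok = False
            if a0 is not None and a1 is not None and a0 == a1:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd))
        if ok:
            stop_free.append((sd, nd))
    use = stop_free or paths
    return (sum(p[0] for p in use) / len(use), sum(p[1] for p in use) / len(use))


def oracle_kaks(a, b):
    S = Sd = Nd = 0.0
    n = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        S += (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
        sd, nd = oracle_pair(ca, cb)
        Sd += sd
        Nd += nd
        n += 1
    N = 3 * n - S
    ps, pn = Sd / S, Nd / N
    jc = lambda p: None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(ps), jc(pn), S, N, Sd, Nd


# ---------------------------------------------------------------------------
# Distances: closed-form checks
# ---------------------------------------------------------------------------

def _pair_with_p(n_sites, n_diff):
    a = "A" * n_sites
    b = "G" * n_diff + "A" * (n_sites - n_diff)
    return a, b


def test_jc_identical_is_zero():
    d = jc_distance("ACGTACGT", "ACGTACGT")
    assert d.p == 0 and d.d == 0


def test_jc_closed_form_p0075():
    a, b = _pair_with_p(200, 15)  # p = 0.075
    d = jc_distance(a, b)
    assert d.p == pytest.approx(0.075)
    assert d.d == pytest.approx(-0.75 * math.log(0.9))
    assert round(d.d, 4) == 0.0790


def test_jc_saturation():
    a, b = _pair_with_p(100, 75)
    d = jc_distance(a, b)
    assert d.saturated and d.d is None


def test_jc_gamma_closed_forms():
    a, b = _pair_with_p(200, 15)
    d = jc_gamma_distance(a, b, alpha=1.0)
    assert d.d == pytest.approx(0.75 * (1 / 0.9 - 1))
    assert round(d.d, 4) == 0.0833
    big = jc_gamma_distance(a, b, alpha=1e6)
    assert abs(big.d - jc_distance(a, b).d) < 1e-4
    same = jc_gamma_distance("AAAA", "AAAA", alpha=0.3)
    assert same.d == 0


def test_jc_gamma_dominates_jc():
    for diff in (5, 20, 60, 100):
        a, b = _pair_with_p(200, diff)
        assert jc_gamma_distance(a, b, 0.5).d >= jc_distance(a, b).d


def test_jc_monotone_in_p():
    prev = -1.0
    for diff in range(0, 140, 10):
        d = jc_distance(*_pair_with_p(200, diff)).d
        assert d > prev
        prev = d


def test_pairwise_deletion():
    d = jc_distance("ACGTN-", "ACTT-A")
    assert d.n_sites == 4  # two columns dropped
    assert d.p == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# Ka/Ks vs the oracle
# ---------------------------------------------------------------------------

def test_kaks_identical_zero():
    cds = "ATGAAATTTCTT"
    est = ng_kaks(cds, cds)
    assert est.ka == 0 and est.ks == 0
    assert est.S + est.N == pytest.approx(len(cds))


def test_single_synonymous_change_matches_oracle():
    a = "ATGAAATTTCTTGGGCCCAAAATTATTACT" * 2  # 20 codons
    b = a[:5] + "G" + a[6:]  # AAA -> AAG at codon 2 (Lys, synonymous)
    est = ng_kaks(a, b)
    ks_o, ka_o, *_ = oracle_kaks(a, b)
    assert est.ka == 0
    assert est.ks == pytest.approx(ks_o) and est.ks > 0


def test_two_difference_codon_averages_pathways():
    # single codon pair differing at two positions: averages the 2 orderings
    a, b = "TTA", "CTG"  # Leu -> Leu via CTA(L) or TTG(L): both syn paths
    est = ng_kaks(a, b)
    sd_o, nd_o = oracle_pair(a, b)
    assert (est.Sd, est.Nd) == (pytest.approx(sd_o), pytest.approx(nd_o))
    assert est.Sd == pytest.approx(2.0) and est.Nd == pytest.approx(0.0)


def test_internal_stop_rejected():
    with pytest.raises(ValueError):
        ng_kaks("ATGTAAAAA", "ATGTAAAAA")


@settings(max_examples=200, deadline=None)
@hyp_seed(1234)
@given(st.data())
def test_ng_kaks_equals_bruteforce_oracle(data):
    n = data.draw(st.integers(2, 30))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    a = "".join(rng.choice(SENSE, size=n))
    # derive b by point mutations so p stays moderate
    b = list(a)
    for _ in range(data.draw(st.integers(0, n))):
        i = int(rng.integers(0, len(b)))
        b[i] = str(rng.choice(list("ACGT")))
    b = "".join(b)
    # skip if a stop codon appeared in b
    if any(TABLE5.forward_table.get(b[i:i+3]) is None for i in range(0, len(b), 3)):
        return
    est = ng_kaks(a, b)
    ks_o, ka_o, S_o, N_o, Sd_o, Nd_o = oracle_kaks(a, b)
    assert est.S == pytest.approx(S_o) and est.N == pytest.approx(N_o)
    assert est.Sd == pytest.approx(Sd_o) and est.Nd == pytest.approx(Nd_o)
    for got, want in ((est.ks, ks_o), (est.ka, ka_o)):
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want)


def test_kaks_symmetric():
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(SENSE, size=40))
    b = "".join(rng.choice(SENSE, size=40))
    e1, e2 = ng_kaks(a, b), ng_kaks(b, a)
    assert e1.Sd == pytest.approx(e2.Sd) and e1.Nd == pytest.approx(e2.Nd)
    assert e1.S == pytest.approx(e2.S)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_zero_variation_zero_se():
    a = "ATGAAATTT" * 20
    res = bootstrap_se(lambda x, y: jc_distance(x, y).d, (a, a), n_reps=50,
                       seed=1, unit="site")
    assert res["se"] == 0.0


def test_bootstrap_deterministic():
    rng = np.random.default_rng(3)
    a = "".join(rng.choice(SENSE, size=60))
    b = list(a)
    for i in rng.choice(len(b), size=30, replace=False):
        b[i] = str(rng.choice(list("ACGT")))
    b = "".join(b)
    f = lambda x, y: jc_distance(x, y).d
    r1 = bootstrap_se(f, (a, b), n_reps=100, seed=7, unit="site")
    r2 = bootstrap_se(f, (a, b), n_reps=100, seed=7, unit="site")
    assert r1["se"] == r2["se"] > 0


def test_bootstrap_matches_binomial_se():
    # p-distance estimator: analytic SE = sqrt(p(1-p)/n) at n sites
    n, k = 500, 50
    a = "A" * n
    b = "G" * k + "A" * (n - k)
    p = k / n
    analytic = math.sqrt(p * (1 - p) / n)
    res = bootstrap_se(lambda x, y: jc_distance(x, y).p, (a, b),
                       n_reps=500, seed=11, unit="site")
    assert res["se"] == pytest.approx(analytic, rel=0.2)


def test_bootstrap_failure_report():
    a, b = _pair_with_p(12, 10)  # p far beyond saturation
    with pytest.raises(RuntimeError):
        bootstrap_se(lambda x, y: jc_distance(x, y).d, (a, b), n_reps=50,
                     seed=2, unit="site")


# ---------------------------------------------------------------------------
# Correlation and utilities
# ---------------------------------------------------------------------------

def test_correlation_antilinear():
    pairs = [(i, 10 - i) for i in range(8)]
    assert rate_gc_correlation(pairs)["r"] == pytest.approx(-1.0)


def test_correlation_preconditions():
    with pytest.raises(ValueError):
        rate_gc_correlation([(1, 2), (2, 3)])
    assert rate_gc_correlation([(1, 2), (1, 3), (1, 4)])["undefined"]


def test_published_r_gives_published_p():
    # consistency of the t-based p-value with the printed pair (n=13)
    assert round(pearson_p_from_r(-0.676, 13), 3) == 0.011


def test_back_translate():
    cds = "ATGAAATTT"
    assert back_translate("MKF", cds) == cds
    assert back_translate("M-KF", cds) == "ATG---AAATTT"
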