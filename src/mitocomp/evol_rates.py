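"""Pairwise substitution-rate analysis for mitochondrial protein genes.

Distances use the Jukes-Cantor one-parameter model,
``d = -(3/4) ln(1 - 4p/3)`` with the gamma-rate-variation generalisation
``d = (3a/4) ((1 - 4p/3)^(-1/a) - 1)`` for shape ``a``; both are undefined
(saturated) at ``p >= 0.75``.

Ka/Ks follows Nei & Gojobori (1986): per-codon synonymous site fractions by
single-base mutation enumeration (changes to stop codons excluded from the
denominator), observed differences resolved by averaging over all minimal
substitution pathways (pathways through stop codons discarded when any
stop-free pathway exists), and the Jukes-Cantor correction applied to
``ps = Sd/S`` and ``pn = Nd/N``.  Standard errors come from seeded
codon-level (Ka/Ks) or site-level (distances) bootstrap resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .codon_usage import INVERTEBRATE_MITO_CODE

__all__ = [
    "PairwiseDistance",
    "KaKsEstimate",
    "GeneRateSummary",
    "jc_distance",
    "jc_gamma_distance",
    "ng_kaks",
    "bootstrap_se",
    "rate_gc_correlation",
    "pearson_p_from_r",
    "strip_terminal_stop",
    "back_translate",
    "gene_rate_summary",
    "SaturationError",
]


class SaturationError(ValueError):
    """p >= 3/4: the Jukes-Cantor correction is undefined."""


_VALID = set("ACGT")


@dataclass
class PairwiseDistance:
    p: float
    d: float | None
    n_sites: int
    saturated: bool = False
    alpha: float | None = None  # None = no rate variation (plain JC)


def _compared_sites(seq_a: str, seq_b: str):
    a, b = seq_a.upper().replace("U", "T"), seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    pairs = [(x, y) for x, y in zip(a, b) if x in _VALID and y in _VALID]
    if not pairs:
        raise ValueError("no comparable sites after pairwise deletion")
    return pairs


def _jc(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _jc_gamma(p: float, alpha: float) -> float:
    return 0.75 * alpha * ((1.0 - 4.0 * p / 3.0) ** (-1.0 / alpha) - 1.0)


def jc_distance(seq_a: str, seq_b: str) -> PairwiseDistance:
    """Jukes-Cantor distance with pairwise deletion of gap/ambiguity columns."""
    pairs = _compared_sites(seq_a, seq_b)
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    if p >= 0.75:
        return PairwiseDistance(p, None, len(pairs), saturated=True)
    return PairwiseDistance(p, _jc(p), len(pairs))


def jc_gamma_distance(seq_a: str, seq_b: str, alpha: float) -> PairwiseDistance:
    """Gamma-corrected Jukes-Cantor distance (shape *alpha* > 0)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    pairs = _compared_sites(seq_a, seq_b)
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    if p >= 0.75:
        return PairwiseDistance(p, None, len(pairs), saturated=True, alpha=alpha)
    return PairwiseDistance(p, _jc_gamma(p, alpha), len(pairs), alpha=alpha)


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks
# ---------------------------------------------------------------------------

def _aa(codon: str, table) -> str | None:
    """Amino acid, or None for a stop codon."""
    return table.forward_table.get(codon)


def _syn_sites(codon: str, table) -> float:
    """Synonymous site count of one codon (0..3).

    At each position the 3 possible changes are classified; mutations to
    stop codons are excluded from the denominator.
    """
    aa0 = _aa(codon, table)
    if aa0 is None:
        raise ValueError(f"stop codon {codon} in coding sequence")
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            aa1 = _aa(alt, table)
            if aa1 is None:
                continue
            valid += 1
            if aa1 == aa0:
                syn += 1
        if valid:
            s += syn / valid
    return s


def _pathway_diffs(c1: str, c2: str, table) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal substitution
    pathways; pathways through stop codons are discarded unless none remain."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    stopfree = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = _aa(cur, table), _aa(nxt, table)
            if aa_nxt is None:
                ok = False
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd))
        if ok:
            stopfree.append((sd, nd))
    use = stopfree or results
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


@dataclass
class KaKsEstimate:
    ks: float | None
    ka: float | None
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    saturated: bool = False
    method: str = "Nei-Gojobori (1986), equal pathway weighting, JC correction"

    @property
    def ratio(self) -> float | None:
        if self.ka is None or self.ks in (None, 0.0):
            return None
        return self.ka / self.ks


def _codon_pairs(cds_a: str, cds_b: str):
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("CDS pair must be codon-aligned to equal length")
    if len(a) % 3:
        raise ValueError("aligned CDS length must be a codon multiple")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca) | set(cb) <= _VALID:
            pairs.append((ca, cb))
    return pairs


def ng_kaks(
    cds_a: str, cds_b: str, code_id: int = INVERTEBRATE_MITO_CODE
) -> KaKsEstimate:
    """Nei-Gojobori Ka/Ks for one codon-aligned CDS pair.

    Codons containing gaps or ambiguity symbols are excluded pairwise;
    internal stop codons raise.  Site counts S and N are averaged between
    the two sequences; S + N = 3 x (compared codons).
    """
    table = _dna_table(code_id)
    pairs = _codon_pairs(cds_a, cds_b)
    if not pairs:
        raise ValueError("no comparable codons")
    S = Sd = Nd = 0.0
    for ca, cb in pairs:
        S += (_syn_sites(ca, table) + _syn_sites(cb, table)) / 2.0
        sd, nd = _pathway_diffs(ca, cb, table)
        Sd += sd
        Nd += nd
    N = 3.0 * len(pairs) - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    ks = None if ps >= 0.75 else _jc(ps)
    ka = None if pn >= 0.75 else _jc(pn)
    return KaKsEstimate(ks, ka, S, N, Sd, Nd, len(pairs), saturated)


def _dna_table(code_id: int):
    from Bio.Data import CodonTable

    return CodonTable.unambiguous_dna_by_id[code_id]


# ---------------------------------------------------------------------------
# Bootstrap and correlations
# ---------------------------------------------------------------------------

def bootstrap_se(
    estimator,
    alignment: tuple[str, str],
    n_reps: int = 500,
    seed: int = 0,
    unit: str = "codon",
) -> dict:
    """Bootstrap standard error of ``estimator(seq_a, seq_b)``.

    Resamples aligned columns with replacement — codon triplets
    (``unit="codon"``, for Ka/Ks) or single sites (``unit="site"``, for
    distances) — and reports the sd of the estimator across replicates.
    Replicates where the estimator is undefined (None or raises ValueError)
    are dropped; more than 50% undefined is a failure.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    a, b = alignment
    if len(a) != len(b):
        raise ValueError("alignment sequences differ in length")
    step = 3 if unit == "codon" else 1
    n_cols = len(a) // step
    cols_a = [a[i * step : (i + 1) * step] for i in range(n_cols)]
    cols_b = [b[i * step : (i + 1) * step] for i in range(n_cols)]
    rng = np.random.default_rng(seed)
    values = []
    failed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        ra = "".join(cols_a[i] for i in idx)
        rb = "".join(cols_b[i] for i in idx)
        try:
            v = estimator(ra, rb)
        except ValueError:
            v = None
        if v is None or (isinstance(v, float) and math.isnan(v)):
            failed += 1
        else:
            values.append(v)
    if failed > n_reps / 2:
        raise RuntimeError(
            f"estimator undefined on {failed}/{n_reps} bootstrap replicates"
        )
    se = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return {"se": se, "n_reps": n_reps, "n_failed": failed, "seed": seed}


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via t = r*sqrt((n-2)/(1-r^2)),
    t-distributed with n-2 df under the null."""
    if n < 3:
        raise ValueError("need n >= 3")
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(stats.t.sf(t, df=n - 2))


def rate_gc_correlation(pairs: list[tuple[float, float]]) -> dict:
    """Pearson correlation of (Ka/Ks, G+C%) across genes; p two-sided from
    the t distribution with n-2 df."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 genes")
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return {"r": None, "p": None, "n": len(pairs), "undefined": True}
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "n": len(pairs), "undefined": False}


def strip_terminal_stop(cds: str, code_id: int = INVERTEBRATE_MITO_CODE) -> str:
    """Trim to complete codons and drop a terminal stop codon if present."""
    s = cds.upper().replace("U", "T")
    s = s[: len(s) - len(s) % 3]
    table = _dna_table(code_id)
    if len(s) >= 3 and s[-3:] in table.stop_codons:
        s = s[:-3]
    return s


def back_translate(protein_alignment: str, cds: str) -> str:
    """Map a gapped protein alignment row back onto its ungapped CDS,
    producing a codon-aligned CDS row with '---' gaps."""
    out = []
    i = 0
    cds = cds.upper().replace("U", "T")
    for aa in protein_alignment:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[i : i + 3])
            i += 3
    if i != len(cds) - (len(cds) % 3 or 0) and i != len(cds):
        # allow a trailing (incomplete or stop) codon to remain unused
        if len(cds) - i not in (0, 1, 2, 3):
            raise ValueError("protein alignment does not match CDS length")
    return "".join(out)


@dataclass
class GeneRateSummary:
    gene: str
    mean_d: float | None
    mean_ks: float | None
    mean_ka: float | None
    gc_percent: float
    n_pairs: int
    alpha: float | None = None

    @property
    def ka_ks(self) -> float | None:
        if self.mean_ka is None or self.mean_ks in (None, 0.0):
            return None
        return self.mean_ka / self.mean_ks


def gene_rate_summary(
    gene: str,
    aligned_cds: list[str],
    code_id: int = INVERTEBRATE_MITO_CODE,
    alpha: float | None = None,
) -> GeneRateSummary:
    """Mean pairwise distance / Ks / Ka over all sequence pairs of one gene,
    plus the gene's G+C content (over ungapped bases)."""
    if len(aligned_cds) < 2:
        raise ValueError("need at least two sequences")
    ds, kss, kas = [], [], []
    for i in range(len(aligned_cds)):
        for j in range(i + 1, len(aligned_cds)):
            a, b = aligned_cds[i], aligned_cds[j]
            dist = (
                jc_gamma_distance(a, b, alpha) if alpha else jc_distance(a, b)
            )
            if dist.d is not None:
                ds.append(dist.d)
            est = ng_kaks(a, b, code_id)
            if est.ks is not None:
                kss.append(est.ks)
            if est.ka is not None:
                kas.append(est.ka)
    joined = "".join(aligned_cds).upper().replace("U", "T")
    bases = [c for c in joined if c in _VALID]
    gc = 100.0 * sum(1 for c in bases if c in "GC") / len(bases)
    n_pairs = len(aligned_cds) * (len(aligned_cds) - 1) // 2
    return GeneRateSummary(
        gene=gene,
        mean_d=float(np.mean(ds)) if ds else None,
        mean_ks=float(np.mean(kss)) if kss else None,
        mean_ka=float(np.mean(kas)) if kas else None,
        gc_percent=gc,
        n_pairs=n_pairs,
        alpha=alpha,
    )
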