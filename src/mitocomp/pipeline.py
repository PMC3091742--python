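"""End-to-end analysis report: every number traceable to one module call.

``run_full_analysis`` executes composition -> codon usage -> gene order ->
tRNA summary -> substitution rates over one or more annotated genomes and
returns a JSON-serialisable report.  Section failures are isolated: a
failing stage contributes an ``error`` entry instead of aborting the run.
"""

from __future__ import annotations

import sys
import time

from . import __version__
from .genome_io import MitoGenomeRecord, audit_start_stop, extract_gene_seq, read_genbank
from . import composition as comp
from . import codon_usage as cu
from . import gene_order as go
from . import trna_struct as ts
from . import evol_rates as er

__all__ = ["run_full_analysis"]


def _load(genome) -> MitoGenomeRecord:
    if isinstance(genome, MitoGenomeRecord):
        return genome
    return read_genbank(genome)


def _log(msg: str, verbose: bool) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def run_full_analysis(
    genomes,
    reference=None,
    config: dict | None = None,
    verbose: bool = False,
) -> dict:
    """Run the full comparative analysis.

    Parameters
    ----------
    genomes:
        One or more GenBank paths or :class:`MitoGenomeRecord` objects; the
        first genome is the focal one.
    reference:
        Optional reference for the gene-order comparison: a GenBank path, a
        record, or a :class:`~mitocomp.gene_order.GeneOrder`.
    config:
        Optional keys: ``alpha`` (gamma shape for distances), ``n_boot``,
        ``seed``, ``min_t_stretch``, ``family_map`` ("paper"/"standard").
    """
    cfg = {"alpha": None, "n_boot": 500, "seed": 0, "min_t_stretch": 4,
           "family_map": "paper"}
    cfg.update(config or {})
    if not isinstance(genomes, (list, tuple)):
        genomes = [genomes]
    if not genomes:
        raise ValueError("need at least one genome")
    records = [_load(g) for g in genomes]
    focal = records[0]
    report: dict = {
        "tool": {"name": "mitocomp", "version": __version__},
        "config": {k: v for k, v in cfg.items()},
        "seed": cfg["seed"],
        "genome_id": focal.id,
    }

    def section(name, fn):
        t0 = time.perf_counter()
        try:
            report[name] = fn()
        except Exception as exc:  # isolated per-section failure
            report[name] = {"error": f"{type(exc).__name__}: {exc}"}
        _log(f"[{name}] {time.perf_counter() - t0:.2f}s", verbose)

    def genome_summary():
        c = comp.base_composition(focal.sequence)
        sk = comp.skews(c)
        by_strand = {"J": 0, "N": 0}
        by_kind: dict[str, int] = {}
        for f in focal.features:
            if f.kind == "other":
                continue
            by_strand[f.strand] += 1
            by_kind[f.kind] = by_kind.get(f.kind, 0) + 1
        return {
            "length": focal.length,
            "circular": focal.circular,
            "composition_percent": {b: c.fraction(b) for b in "ATGC"},
            "at_percent": c.at_percent,
            "at_skew_signed": sk.at_skew_signed,
            "at_skew_magnitude": sk.at_skew_magnitude,
            "gc_skew_signed": sk.gc_skew_signed,
            "genes_by_strand": by_strand,
            "genes_by_kind": by_kind,
        }

    def codon_usage():
        pcgs = [f for f in focal.features if f.kind == "PCG"]
        seqs = [extract_gene_seq(focal, f) for f in pcgs]
        counts = cu.count_codons(seqs)
        fam = (cu.paper_family_map() if cfg["family_map"] == "paper"
               else cu.standard_family_map())
        table = cu.rscu(counts, fam)
        rep = cu.codon_percent_report(counts)
        pos = comp.codon_position_composition(seqs)
        return {
            "n_sense_codons": counts.total,
            "rscu": table.values,
            "percent": rep["percent"],
            "top4_at_rich_share": rep["named_set_share"],
            "unused_codons": list(cu.unused_codons(counts)),
            "codon_position_at_percent": list(pos),
            "start_stop": audit_start_stop(focal),
        }

    def junctions():
        table = go.junction_accounting(focal)
        return {**table.summary(), "inconsistencies": table.inconsistencies}

    def order_comparison():
        if reference is None:
            return {"skipped": "no reference order supplied"}
        if isinstance(reference, go.GeneOrder):
            ref_order = reference
        else:
            ref_order = go.gene_order(_load(reference))
        order = go.gene_order(focal)
        cmpres = go.conserved_boundaries(order, ref_order)
        labels = go.classify_rearrangements(order, ref_order)
        return {
            "conserved_boundary_count": cmpres.conserved_boundary_count,
            "dropped_genes": list(cmpres.dropped_genes),
            "labels": labels,
            "order": go.format_order(order),
            "reference_order": go.format_order(ref_order),
        }

    def trna_summary():
        anns = [f for f in focal.features if f.kind == "tRNA"]
        if not anns:
            return {"skipped": "no annotated tRNAs"}
        lengths = [f.length for f in anns]
        summ = ts.trna_size_summary(
            [ts.TrnaAnnotation(f.name, f.strand, f.begin, f.end,
                               f.anticodon or "", 0, 0, False, False)
             for f in anns]
        )
        return {**summ, "lengths": {f.name: f.length for f in anns},
                "n_lengths": len(lengths)}

    def control_region():
        cr = next((f for f in focal.features if f.kind == "control_region"), None)
        if cr is None:
            return {"skipped": "no control region annotated"}
        stretches = comp.find_t_stretches(focal, cr, min_len=cfg["min_t_stretch"])
        sub = extract_gene_seq(focal, cr)
        loops = comp.find_stem_loops(sub, min_stem=4, max_mismatch=0)
        return {
            "length": cr.length,
            "t_stretches": [
                {"strand": t.strand, "length": t.length, "begin": t.begin,
                 "nearest_feature": t.nearest_feature, "distance": t.distance}
                for t in stretches
            ],
            "stem_loops": [
                {"stem": c.stem_length, "loop": c.loop_length,
                 "arm5_begin": c.arm5_begin, "mismatches": c.mismatches}
                for c in loops
            ],
        }

    def rates():
        if len(records) < 2:
            return {"skipped": "need >= 2 genomes for pairwise rates"}
        genes: dict[str, list[str]] = {}
        for rec in records:
            for f in rec.features:
                if f.kind == "PCG":
                    genes.setdefault(f.name, []).append(extract_gene_seq(rec, f))
        out = {}
        pairs = []
        for gene, seqs in sorted(genes.items()):
            if len(seqs) < 2 or len({len(s) for s in seqs}) != 1:
                out[gene] = {"error": "sequences unaligned or missing"}
                continue
            trimmed = [er.strip_terminal_stop(s) for s in seqs]
            summ = er.gene_rate_summary(gene, trimmed, alpha=cfg["alpha"])
            out[gene] = {
                "mean_d": summ.mean_d, "mean_ks": summ.mean_ks,
                "mean_ka": summ.mean_ka, "ka_ks": summ.ka_ks,
                "gc_percent": summ.gc_percent, "n_pairs": summ.n_pairs,
            }
            if summ.ka_ks is not None:
                pairs.append((summ.ka_ks, summ.gc_percent))
        if len(pairs) >= 3:
            out["kaks_gc_correlation"] = er.rate_gc_correlation(pairs)
        return out

    section("genome_summary", genome_summary)
    section("codon_usage", codon_usage)
    section("junctions", junctions)
    section("gene_order", order_comparison)
    section("trna", trna_summary)
    section("control_region", control_region)
    section("rates", rates)
    return report
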