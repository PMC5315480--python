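"""Nei-Gojobori (1986) Ka/Ks estimation and the core-vs-accessory comparison.

The NG86 estimator counts, for each codon, the fraction of the three possible
point mutations at each position that are synonymous (fractional synonymous
site counts), averages site counts over the two sequences, averages observed
synonymous/nonsynonymous differences over all shortest mutational pathways
between differing codons, and applies the Jukes-Cantor multiple-hit
correction d = -(3/4) ln(1 - (4/3) p). Pathways passing through stop codons
are excluded; mutations to stop codons do not count as possible changes when
tallying sites. The bacterial genetic code (translation table 11) is the
default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Data import CodonTable

__all__ = ["KaKsResult", "ng86_ka_ks", "compare_compartments"]

_BASES = "ACGT"


def _code(table_id: int) -> tuple[dict[str, str], set[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), set(table.stop_codons)


@dataclass(frozen=True)
class KaKsResult:
    gene_id: str
    ka: float | None  # None = undefined (JC correction out of range)
    ks: float | None
    ratio: float | None  # Ka/Ks; None when either rate undefined or Ks == 0
    n_sites_syn: float
    n_sites_nonsyn: float
    n_diffs_syn: float
    n_diffs_nonsyn: float


def _codon_sites(codon: str, forward: dict[str, str], stops: set[str]) -> float:
    """Fractional synonymous sites of one codon (nonsyn = 3 - syn)."""
    aa = forward[codon]
    syn = 0.0
    for pos in range(3):
        alts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in _BASES
            if b != codon[pos]
        ]
        alts = [c for c in alts if c not in stops]
        if not alts:
            continue
        syn += sum(forward[c] == aa for c in alts) / len(alts)
    return syn


def _pathway_diffs(
    a: str, b: str, forward: dict[str, str], stops: set[str]
) -> tuple[float, float]:
    """(syn, nonsyn) differences between codons, averaged over pathways.

    All orderings of the differing positions are enumerated; pathways with a
    stop-codon intermediate or endpoint step are dropped, falling back to all
    pathways if every one is dropped.
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in stops:
                blocked = True
                break
            steps.append((current, nxt))
            current = nxt
        if not blocked:
            pathways.append(steps)
    if not pathways:  # every route passes through a stop; count them anyway
        for order in itertools.permutations(diff_pos):
            current = a
            steps = []
            for pos in order:
                nxt = current[:pos] + b[pos] + current[pos + 1 :]
                steps.append((current, nxt))
                current = nxt
            pathways.append(steps)
    syn = nonsyn = 0.0
    aa = lambda c: forward.get(c, "*")
    for steps in pathways:
        for frm, to in steps:
            if aa(frm) == aa(to):
                syn += 1
            else:
                nonsyn += 1
    k = len(pathways)
    return syn / k, nonsyn / k


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


def ng86_ka_ks(
    codon_seq_a: str, codon_seq_b: str, gene_id: str = "gene", table_id: int = 11
) -> KaKsResult:
    """NG86 Ka and Ks with Jukes-Cantor correction for one aligned pair.

    Sequences must be equal-length gapless in-frame codon alignments with no
    internal stops; violations raise ValueError (callers typically skip the
    gene with the reason).
    """
    a, b = codon_seq_a.upper(), codon_seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3 != 0:
        raise ValueError("length is not a multiple of 3")
    if not (set(a) | set(b)) <= set(_BASES):
        raise ValueError("sequences contain gaps or ambiguity characters")
    forward, stops = _code(table_id)
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    if any(c in stops for c in codons_a + codons_b):
        raise ValueError("internal stop codon")

    s_a = sum(_codon_sites(c, forward, stops) for c in codons_a)
    s_b = sum(_codon_sites(c, forward, stops) for c in codons_b)
    n_codons = len(codons_a)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites

    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        ds, dn = _pathway_diffs(ca, cb, forward, stops)
        sd += ds
        nd += dn

    ps = sd / s_sites if s_sites > 0 else None
    pn = nd / n_sites if n_sites > 0 else None
    ks = _jc(ps) if ps is not None else None
    ka = _jc(pn) if pn is not None else None
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(
        gene_id=gene_id,
        ka=ka,
        ks=ks,
        ratio=ratio,
        n_sites_syn=s_sites,
        n_sites_nonsyn=n_sites,
        n_diffs_syn=sd,
        n_diffs_nonsyn=nd,
    )


def compare_compartments(
    core_results: list[KaKsResult],
    accessory_results: list[KaKsResult],
    pseudocount: float | None = None,
) -> dict:
    """Wilcoxon rank-sum comparison of log10(Ka/Ks) between compartments.

    By default genes with an undefined ratio or with Ka=0 or Ks=0 are
    excluded (log10 would be infinite); passing a pseudocount instead adds it
    to both rates before forming the ratio, keeping such genes.
    """
    import math as _math

    from .association import wilcoxon_rank_sum

    def log_ratios(results: list[KaKsResult]) -> list[float]:
        vals = []
        for r in results:
            if r.ka is None or r.ks is None:
                continue
            if pseudocount is not None:
                ka, ks = r.ka + pseudocount, r.ks + pseudocount
            else:
                ka, ks = r.ka, r.ks
            if ka > 0 and ks > 0:
                vals.append(_math.log10(ka / ks))
        return vals

    core = log_ratios(core_results)
    accessory = log_ratios(accessory_results)
    if len(core) < 2 or len(accessory) < 2:
        raise ValueError(
            f"insufficient finite log10 ratios (core {len(core)}, "
            f"accessory {len(accessory)})"
        )
    w, p = wilcoxon_rank_sum(accessory, core)
    import statistics

    return {
        "W": w,
        "p": p,
        "n_core": len(core),
        "n_accessory": len(accessory),
        "median_log10_core": statistics.median(core),
        "median_log10_accessory": statistics.median(accessory),
    }
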