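"""Nei-Gojobori (1986) pairwise Ka/Ks estimation from codon alignments.

The NG86 counting method, as popularized by DnaSP and MEGA:

* Each codon position contributes a fractional count of synonymous sites,
  ``S_pos = n_syn / 3`` over its three single-nucleotide neighbors;
  nonsynonymous sites are the non-stop remainder.  Mutations creating stop
  codons are excluded from both site classes, so ``S + N <= 3`` per codon,
  with equality when no neighbor is a stop.
* Sites are averaged over the two sequences of a pair.
* Observed differences at a codon with d differing positions are averaged
  over all d! orderings of minimal mutational pathways with equal weights;
  pathways passing through a stop codon are excluded (when every pathway is
  blocked, all pathways are used, with steps touching a stop counted as
  nonsynonymous — the neighboring convention degenerate codon pairs need).
* Proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with
  the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p); p >= 3/4 saturates
  and the corresponding rate is flagged undefined.

Ka/Ks well below 1 indicates purifying selection; about 1, neutrality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from .codons import BASES, GeneticCode, codons_of, get_code
from .genome_model import InputError


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; ``None`` when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def count_sites(codon: str, genetic_code: GeneticCode | None = None) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one sense codon."""
    code = genetic_code or get_code()
    return _count_sites_cached(codon.upper(), code)


@lru_cache(maxsize=None)
def _count_sites_cached(codon: str, code: GeneticCode) -> tuple[float, float]:
    if code.is_stop(codon):
        raise InputError(f"stop codon {codon} has no site decomposition")
    aa = code.translate(codon)
    s = n = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(neighbor):
                continue  # excluded from both classes
            if code.translate(neighbor) == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


@lru_cache(maxsize=None)
def _pathway_differences(
    codon_a: str, codon_b: str, code: GeneticCode
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons, equal weights over all orderings of the differing positions.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def _walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        current = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt) and nxt != codon_b:
                if not allow_stops:
                    return None
                nd += 1.0  # degenerate fallback: steps via stops count as nonsyn
            elif code.is_stop(current) or code.is_stop(nxt):
                nd += 1.0
            elif code.translate(current) == code.translate(nxt):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    orders = list(permutations(diff_pos))
    results = [r for r in (_walk(o, False) for o in orders) if r is not None]
    if not results:
        results = [_walk(o, True) for o in orders]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


@dataclass(frozen=True)
class KaKsResult:
    """NG86 statistics for one aligned CDS pair."""

    s_sites: float  # synonymous sites S (averaged over the pair)
    n_sites: float  # nonsynonymous sites N
    sd: float  # synonymous differences
    nd: float  # nonsynonymous differences
    n_codons: int  # codon columns actually compared

    @property
    def ps(self) -> float:
        return self.sd / self.s_sites if self.s_sites > 0 else 0.0

    @property
    def pn(self) -> float:
        return self.nd / self.n_sites if self.n_sites > 0 else 0.0

    @property
    def ks(self) -> float | None:
        return jukes_cantor(self.ps)

    @property
    def ka(self) -> float | None:
        return jukes_cantor(self.pn)

    @property
    def ratio(self) -> float | None:
        """Ka/Ks; ``None`` when Ks is 0 or saturated (flagged undefined)."""
        ks, ka = self.ks, self.ka
        if ks is None or ka is None or ks == 0.0:
            return None
        return ka / ks


def pairwise_kaks(
    cds_a: str, cds_b: str, genetic_code: GeneticCode | None = None
) -> KaKsResult:
    """NG86 Ka/Ks for one pair of equal-length, in-frame aligned CDSs.

    Codon columns containing gaps, N, or a stop codon in either sequence are
    skipped.  Exactly symmetric in its two arguments.
    """
    code = genetic_code or get_code()
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise InputError(f"aligned CDS lengths differ: {len(cds_a)} vs {len(cds_b)}")
    if len(cds_a) % 3:
        raise InputError(f"alignment length {len(cds_a)} is not a multiple of 3")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    compared = 0
    for ca, cb in zip(codons_of(cds_a), codons_of(cds_b)):
        if set(ca + cb) - set("TCAG"):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        sa, na = _count_sites_cached(ca, code)
        sb, nb = _count_sites_cached(cb, code)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n = _pathway_differences(*sorted((ca, cb)), code)
        sd += d_s
        nd += d_n
        compared += 1
    if compared == 0:
        raise InputError("no comparable codon columns")
    return KaKsResult(
        s_sites=(s_a + s_b) / 2.0,
        n_sites=(n_a + n_b) / 2.0,
        sd=sd,
        nd=nd,
        n_codons=compared,
    )


@dataclass(frozen=True)
class GeneMeanKaKs:
    """Per-gene mean over all C(n,2) pairwise comparisons."""

    gene: str
    n_pairs: int
    mean_ka: float
    mean_ks: float
    ratio_of_means: float | None  # mean(Ka) / mean(Ks)
    mean_ratio: float | None  # mean of defined pairwise ratios
    n_undefined: int  # pairs with saturated/undefined Ks or ratio


def gene_mean_kaks(
    per_gene_cds_sets: dict[str, list[str]],
    genetic_code: GeneticCode | None = None,
) -> list[GeneMeanKaKs]:
    """Mean Ka, Ks and Ka/Ks per gene across all sequence pairs.

    Both ratio aggregations are emitted: the ratio of mean rates and the mean
    of defined pairwise ratios.  Genes with fewer than two usable sequences
    are skipped with a warning.
    """
    import warnings

    out: list[GeneMeanKaKs] = []
    for gene, seqs in per_gene_cds_sets.items():
        if len(seqs) < 2:
            warnings.warn(f"gene {gene!r}: fewer than 2 sequences, skipped", stacklevel=2)
            continue
        kas: list[float] = []
        kss: list[float] = []
        ratios: list[float] = []
        undefined = 0
        n_pairs = 0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                r = pairwise_kaks(seqs[i], seqs[j], genetic_code)
                n_pairs += 1
                ka, ks, ratio = r.ka, r.ks, r.ratio
                if ka is None or ks is None:
                    undefined += 1
                    continue
                kas.append(ka)
                kss.append(ks)
                if ratio is None:
                    undefined += 1
                else:
                    ratios.append(ratio)
        mean_ka = sum(kas) / len(kas) if kas else 0.0
        mean_ks = sum(kss) / len(kss) if kss else 0.0
        out.append(
            GeneMeanKaKs(
                gene=gene,
                n_pairs=n_pairs,
                mean_ka=mean_ka,
                mean_ks=mean_ks,
                ratio_of_means=(mean_ka / mean_ks) if mean_ks > 0 else None,
                mean_ratio=(sum(ratios) / len(ratios)) if ratios else None,
                n_undefined=undefined,
            )
        )
    return out


__all__ = [
    "count_sites",
    "pairwise_kaks",
    "gene_mean_kaks",
    "jukes_cantor",
    "KaKsResult",
    "GeneMeanKaKs",
]
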