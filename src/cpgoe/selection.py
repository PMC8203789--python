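"""Pairwise dN/dS estimation (Nei–Gojobori 1986) and bin comparison.

The ratio omega = dN/dS of nonsynonymous to synonymous substitution rates
measures the strength of selection on protein sequence: omega << 1 under
purifying selection, omega = 1 under neutrality.  This module counts
synonymous and nonsynonymous sites by single-base mutant enumeration,
counts differences by averaging over all mutational pathways between two
codons (excluding pathways through stop codons), corrects the observed
proportions for multiple hits with the Jukes–Cantor formula, and compares
omega between gene bins with a Wilcoxon–Mann–Whitney rank-sum test.

Pairs with dN > 2 or dS > 2 are flagged invalid and excluded from group
comparisons, as are pairs with dS = 0 (omega undefined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

from scipy.stats import mannwhitneyu

from .genome_io import translate_cds

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_AA: dict[str, str] = {}
for _b1 in BASES:
    for _b2 in BASES:
        for _b3 in BASES:
            _c = _b1 + _b2 + _b3
            _CODON_AA[_c] = "*" if _c in STOP_CODONS else translate_cds(_c)[0]

SENSE_CODONS = tuple(c for c in _CODON_AA if c not in STOP_CODONS)


@dataclass(frozen=True)
class CodonAlignment:
    """Gap- and ambiguity-free pairwise codon alignment."""

    gene_pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_pair_id}: unequal aligned lengths")
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.gene_pair_id}: length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class DnDsEstimate:
    gene_pair_id: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float | None
    dn: float | None
    omega: float | None
    valid: bool


@dataclass(frozen=True)
class GroupComparison:
    n_low: int
    n_high: int
    u_statistic: float
    p_value: float
    median_low: float
    median_high: float


# ---------------------------------------------------------------------------
# codon alignment construction

def backtranslate_alignment(
    aa_aln_a: str, aa_aln_b: str, cds_a: str, cds_b: str, gene_pair_id: str = "pair"
) -> CodonAlignment:
    """Thread CDS codons onto a pairwise protein alignment.

    Each non-gap residue consumes the next codon of its CDS.  Columns with a
    gap in either sequence, or with a codon containing a non-ACGT base, are
    removed (cleandata behaviour); removal counts are logged.
    """
    if len(aa_aln_a) != len(aa_aln_b):
        raise ValueError(f"{gene_pair_id}: protein alignment rows differ in length")
    for name, aa, cds in (("a", aa_aln_a, cds_a), ("b", aa_aln_b, cds_b)):
        n_res = sum(1 for ch in aa if ch != "-")
        if len(cds) < 3 * n_res:
            raise ValueError(
                f"{gene_pair_id}: CDS {name} too short for {n_res} aligned residues"
            )
    acgt = set("ACGT")
    cols_a: list[str] = []
    cols_b: list[str] = []
    ia = ib = 0
    n_gap = n_ambig = 0
    for ra, rb in zip(aa_aln_a, aa_aln_b):
        ca = cb = None
        if ra != "-":
            ca = cds_a[3 * ia : 3 * ia + 3].upper()
            ia += 1
        if rb != "-":
            cb = cds_b[3 * ib : 3 * ib + 3].upper()
            ib += 1
        if ca is None or cb is None:
            n_gap += 1
            continue
        if not (set(ca) <= acgt and set(cb) <= acgt):
            n_ambig += 1
            continue
        cols_a.append(ca)
        cols_b.append(cb)
    if n_gap or n_ambig:
        logger.info(
            "%s: removed %d gap and %d ambiguous column(s)",
            gene_pair_id,
            n_gap,
            n_ambig,
        )
    return CodonAlignment(gene_pair_id, "".join(cols_a), "".join(cols_b))


# ---------------------------------------------------------------------------
# NG86 site and difference counting

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one sense codon.

    At each position the three single-base mutants are enumerated; mutants
    producing stop codons are excluded from the denominator at that
    position.  Returns (s, n) with s + n = 3 when no stop-mutant exclusion
    applies.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in _CODON_AA:
        raise ValueError(f"invalid codon '{codon}'")
    aa = _CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = counted = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            counted += 1
            if _CODON_AA[mut] == aa:
                syn += 1
        if counted:
            s += syn / counted
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded and the average renormalised over
    the remainder.  If every pathway is blocked the unrestricted average is
    used (with a warning), classifying each step by its amino-acid effect.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS or c not in _CODON_AA:
            raise ValueError(f"invalid or stop codon '{c}'")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        sd = nd = 0.0
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if _CODON_AA[nxt] == _CODON_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [
        r for order in permutations(diff_pos) if (r := walk(order, False)) is not None
    ]
    if not results:
        logger.warning(
            "all pathways %s->%s pass through stops; using unrestricted average", a, b
        )
        results = [walk(order, True) for order in permutations(diff_pos)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor_correct(p: float) -> float | None:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3); None when p >= 3/4."""
    if p < 0:
        raise ValueError("difference proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(aln: CodonAlignment) -> DnDsEstimate:
    """NG86 dN/dS estimate for one codon alignment.

    Site counts are averaged over the two sequences; differences are
    pathway-averaged per codon.  The estimate is flagged invalid when the
    correction is undefined, dS = 0, or dN or dS exceeds 2.
    """
    if aln.n_codons < 1:
        raise ValueError("empty alignment")
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in aln.codon_pairs():
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        s_sites += 0.5 * (sa + sb)
        n_sites += 0.5 * (na + nb)
        d_s, d_n = ng86_differences(ca, cb)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor_correct(ps)
    dn = jukes_cantor_correct(pn)
    omega: float | None = None
    valid = ds is not None and dn is not None
    if valid and (ds > 2 or dn > 2):
        valid = False
    if valid and ds == 0:
        valid = False
    if valid:
        omega = dn / ds
    return DnDsEstimate(
        gene_pair_id=aln.gene_pair_id,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
        omega=omega,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# group comparison

def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sided Wilcoxon–Mann–Whitney test comparing two omega samples.

    Uses the exact null distribution when both samples have at most 8
    values and no ties are present; otherwise the normal approximation with
    tie and continuity corrections.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = list(x) + list(y)
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    med = lambda v: sorted(v)[len(v) // 2] if len(v) % 2 else 0.5 * (
        sorted(v)[len(v) // 2 - 1] + sorted(v)[len(v) // 2]
    )
    return GroupComparison(
        n_low=len(x),
        n_high=len(y),
        u_statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        median_low=float(med(x)),
        median_high=float(med(y)),
    )
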