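"""Seeded generators for every input the analysis consumes, with planted
ground truth.

Four generators mirror the statistical structure the pipeline assumes:

* :func:`simulate_cds_set` — coding sequences whose CpG content is bimodal.
  A planted fraction of "methylated" genes samples codons with every
  CpG-creating candidate down-weighted by a depletion factor delta, so the
  low CpG_o/e mode emerges from the generative process rather than being
  imposed on the realised statistic.  Genes are wrapped into synthetic
  scaffolds with two-segment GFF3 gene models, half on each strand.
* :func:`evolve_codon_pair` — two descendants of an ancestral CDS diverged
  under a chosen dN/dS ratio omega (synonymous proposals always accepted,
  nonsynonymous accepted with probability omega, stop-creating proposals
  rejected).
* :func:`simulate_orthogroups` — an orthogroup membership table with pure
  planted per-species low/high patterns, species-specific orthogroups and
  unassigned genes with a configurable category skew.
* :func:`simulate_go` — a small ontology DAG plus gene annotations with
  planted enriched terms at a configured relative risk in a study bin.

All outputs are reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .selection import SENSE_CODONS, STOP_CODONS, _CODON_AA

LOW, HIGH = "low", "high"

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions.

    The planted methylated fraction of 0.45 and four-species orthogroup
    pattern counts (2182 all-low, 728 all-high, 666 with the three
    hemimetabolous species low and the holometabolous one high) reproduce
    the concordance structure the pipeline is designed to detect; delta and
    GC content are tuning constants chosen to put the two emergent CpG_o/e
    modes near 0.4 and 1.0.
    """

    seed: int = 0
    n_genes: int = 10_000
    frac_methylated: float = 0.45
    cds_length_codons_mean: float = 300.0
    cds_length_dispersion: float = 0.25  # coefficient of variation
    cpg_depletion_factor: float = 0.3  # delta in (0, 1]
    gc_content: float = 0.42
    n_species: int = 4
    og_pattern_counts: dict[str, int] = field(
        default_factory=lambda: {
            "all_low": 2182,
            "all_high": 728,
            "hemi_low_holo_high": 666,
        }
    )
    n_species_specific_ogs: int = 120
    n_unassigned_per_species: int = 150
    unassigned_high_skew: float = 0.8  # P(high) for species-specific genes
    omega_low: float = 0.1
    omega_high: float = 0.3
    divergence_subst_per_site: float = 0.2
    n_enriched_terms: int = 1
    enrichment_relative_risk: float = 4.0
    enriched_term_universe_count: int = 200  # expected K of a planted term
    min_len_codons: int = 30

    def validate(self) -> None:
        if not 0 <= self.frac_methylated <= 1:
            raise ValueError("frac_methylated outside [0, 1]")
        if not 0 < self.cpg_depletion_factor <= 1:
            raise ValueError("cpg_depletion_factor outside (0, 1]")
        if self.cds_length_codons_mean < self.min_len_codons:
            raise ValueError("mean CDS length below the minimum of 30 codons")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content outside (0, 1)")


@dataclass
class SimulatedCdsSet:
    """In-memory product of simulate_cds_set, writable to FASTA/GFF3."""

    cds: dict[str, str]  # gene_id -> coding sequence (stop included)
    genome: dict[str, str]  # scaffold_id -> sequence
    gff3: str
    methylated: dict[str, bool]  # planted truth


def _codon_probs(gc: float, delta: float) -> np.ndarray:
    """(4, 61) sampling probabilities: row = previous base, col = sense codon.

    Codon weight is the product of its base probabilities under the
    {A,T: (1-gc)/2; C,G: gc/2} composition, times delta per CpG dinucleotide
    the codon would create (internal, or at the junction with the previous
    base), renormalised per row.
    """
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    w = np.zeros((4, len(SENSE_CODONS)))
    for j, codon in enumerate(SENSE_CODONS):
        base_w = base_p[codon[0]] * base_p[codon[1]] * base_p[codon[2]]
        internal_cg = sum(
            1 for i in range(2) if codon[i] == "C" and codon[i + 1] == "G"
        )
        for pi, prev in enumerate(_BASES):
            junction_cg = 1 if prev == "C" and codon[0] == "G" else 0
            w[pi, j] = base_w * delta ** (internal_cg + junction_cg)
    row_sums = w.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise ValueError("infeasible config: no sense codon has positive weight")
    return w / row_sums


def simulate_cds_set(config: SimConfig) -> SimulatedCdsSet:
    """Generate a CDS set with a planted bimodal CpG_o/e structure.

    Returns the coding sequences (ATG start, sampled body, TAA stop), a
    synthetic genome in which each gene is annotated as a two-segment CDS
    (half the genes on the minus strand) and the planted methylation truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    meth = rng.random(n) < config.frac_methylated

    mean = config.cds_length_codons_mean
    cv = config.cds_length_dispersion
    shape = 1.0 / (cv * cv)
    lengths = np.maximum(
        config.min_len_codons, np.round(rng.gamma(shape, mean / shape, n))
    ).astype(int)

    probs_plain = _codon_probs(config.gc_content, 1.0)
    probs_meth = _codon_probs(config.gc_content, config.cpg_depletion_factor)
    codon_arr = np.array(list(SENSE_CODONS))
    last_base_idx = np.array([_BASE_IDX[c[-1]] for c in SENSE_CODONS])

    max_len = int(lengths.max())
    chosen = np.full((n, max_len), -1, dtype=np.int32)
    prev = np.full(n, _BASE_IDX["G"], dtype=np.int32)  # genes start with ATG
    # first codon fixed to ATG, sampled body thereafter
    atg = SENSE_CODONS.index("ATG")
    chosen[:, 0] = atg
    for pos in range(1, max_len):
        active = lengths > pos
        if not active.any():
            break
        for is_meth in (False, True):
            table = probs_meth if is_meth else probs_plain
            sel = active & (meth == is_meth)
            if not sel.any():
                continue
            for pb in range(4):
                grp = sel & (prev == pb)
                m = int(grp.sum())
                if not m:
                    continue
                draws = rng.choice(len(SENSE_CODONS), size=m, p=table[pb])
                chosen[grp, pos] = draws
        prev = np.where(active, last_base_idx[np.clip(chosen[:, pos], 0, None)], prev)

    gene_ids = [f"g{i+1:05d}" for i in range(n)]
    cds: dict[str, str] = {}
    for i, gid in enumerate(gene_ids):
        codons = codon_arr[chosen[i, : lengths[i]]]
        cds[gid] = "".join(codons) + "TAA"

    genome, gff3 = _wrap_genome(cds, config, rng)
    return SimulatedCdsSet(
        cds=cds,
        genome=genome,
        gff3=gff3,
        methylated={gid: bool(meth[i]) for i, gid in enumerate(gene_ids)},
    )


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])


_RC = str.maketrans("ACGT", "TGCA")


def _wrap_genome(
    cds: Mapping[str, str], config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], str]:
    """Place each CDS on a scaffold as a two-segment gene model."""
    genome: dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    genes_per_scaffold = 25
    items = list(cds.items())
    for s_idx in range(0, len(items), genes_per_scaffold):
        scaffold_id = f"scf{s_idx // genes_per_scaffold + 1:04d}"
        parts: list[str] = []
        cursor = 0
        for g_idx, (gid, seq) in enumerate(items[s_idx : s_idx + genes_per_scaffold]):
            spacer = _random_nt(rng, int(rng.integers(100, 301)), config.gc_content)
            parts.append(spacer)
            cursor += len(spacer)
            strand = "+" if (s_idx + g_idx) % 2 == 0 else "-"
            placed = seq if strand == "+" else seq.translate(_RC)[::-1]
            split = int(rng.integers(3, len(placed) - 2))
            intron = _random_nt(rng, int(rng.integers(50, 151)), config.gc_content)
            seg1 = (cursor + 1, cursor + split)
            parts.append(placed[:split])
            cursor += split
            parts.append(intron)
            cursor += len(intron)
            seg2 = (cursor + 1, cursor + len(placed) - split)
            parts.append(placed[split:])
            cursor += len(placed) - split
            if strand == "+":
                phases = (0, (3 - split % 3) % 3)
            else:
                tail = len(placed) - split  # transcription starts at seg2
                phases = ((3 - tail % 3) % 3, 0)
            tx = f"{gid}.t1"
            gff_lines.append(
                f"{scaffold_id}\tsim\tgene\t{seg1[0]}\t{seg2[1]}\t.\t{strand}\t.\tID={gid}"
            )
            gff_lines.append(
                f"{scaffold_id}\tsim\tmRNA\t{seg1[0]}\t{seg2[1]}\t.\t{strand}\t.\tID={tx};Parent={gid}"
            )
            for (start, end), phase in zip((seg1, seg2), phases):
                gff_lines.append(
                    f"{scaffold_id}\tsim\tCDS\t{start}\t{end}\t.\t{strand}\t{phase}\tID={tx}.cds;Parent={tx}"
                )
        tail_spacer = _random_nt(rng, int(rng.integers(100, 301)), config.gc_content)
        parts.append(tail_spacer)
        genome[scaffold_id] = "".join(parts)
    return genome, "\n".join(gff_lines) + "\n"


# ---------------------------------------------------------------------------
# codon-pair evolution

def evolve_codon_pair(
    cds: str, omega: float, divergence: float, seed: int
) -> tuple[str, str]:
    """Evolve two descendants of ``cds`` under dN/dS ratio ``omega``.

    Along each of two independent branches, Poisson(divergence/2 * length)
    single-base changes are proposed at uniform positions with uniform
    alternative bases; proposals creating stop codons are rejected,
    synonymous proposals accepted, nonsynonymous accepted with probability
    omega.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at position {i + 1}")
    rng = np.random.default_rng(seed)

    def one_branch(seq: str) -> str:
        s = list(seq)
        n_prop = rng.poisson(divergence / 2.0 * len(seq))
        for _ in range(n_prop):
            pos = int(rng.integers(len(s)))
            old = s[pos]
            alt = [b for b in _BASES if b != old]
            new = alt[int(rng.integers(3))]
            c0 = pos - pos % 3
            codon_old = "".join(s[c0 : c0 + 3])
            codon_new = codon_old[: pos - c0] + new + codon_old[pos - c0 + 1 :]
            if codon_new in STOP_CODONS:
                continue
            if _CODON_AA[codon_new] != _CODON_AA[codon_old]:
                if rng.random() >= omega:
                    continue
            s[pos] = new
        return "".join(s)

    return one_branch(cds), one_branch(cds)


def random_cds(rng: np.random.Generator, n_codons: int, gc: float = 0.42) -> str:
    """Random sense-codon sequence (no planted CpG structure)."""
    probs = _codon_probs(gc, 1.0)[0]
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=probs)
    return "".join(np.array(list(SENSE_CODONS))[idx])


# ---------------------------------------------------------------------------
# orthogroup tables

@dataclass
class SimulatedOrthogroups:
    table_tsv: str
    calls: dict[str, dict[str, str]]  # species -> gene -> category
    planted_patterns: dict[str, str]  # og_id -> pattern name
    species: list[str]


def _pattern_categories(name: str, species: Sequence[str]) -> list[str]:
    if name == "all_low":
        return [LOW] * len(species)
    if name == "all_high":
        return [HIGH] * len(species)
    if name == "hemi_low_holo_high":
        # convention: the last species plays the holometabolous role
        return [LOW] * (len(species) - 1) + [HIGH]
    raise ValueError(f"unknown orthogroup pattern '{name}'")


def simulate_orthogroups(config: SimConfig) -> SimulatedOrthogroups:
    """Orthogroup table with pure planted patterns plus species-specific OGs
    and unassigned genes skewed toward the high bin."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    species = [f"sp{i+1}" for i in range(config.n_species)]
    calls: dict[str, dict[str, str]] = {sp: {} for sp in species}
    planted: dict[str, str] = {}
    lines = ["Orthogroup\t" + "\t".join(species)]
    counter = 0

    def new_gene(sp: str, category: str) -> str:
        nonlocal counter
        counter += 1
        gid = f"{sp}_g{counter:06d}"
        calls[sp][gid] = category
        return gid

    og_no = 0
    for pattern, count in config.og_pattern_counts.items():
        cats = _pattern_categories(pattern, species)
        for _ in range(count):
            og_no += 1
            og_id = f"OG{og_no:07d}"
            planted[og_id] = pattern
            cells = []
            for sp, cat in zip(species, cats):
                n_members = int(rng.integers(1, 4))
                cells.append(", ".join(new_gene(sp, cat) for _ in range(n_members)))
            lines.append(og_id + "\t" + "\t".join(cells))
    for _ in range(config.n_species_specific_ogs):
        og_no += 1
        og_id = f"OG{og_no:07d}"
        sp = species[int(rng.integers(len(species)))]
        cat = HIGH if rng.random() < config.unassigned_high_skew else LOW
        planted[og_id] = f"specific_{sp}_{cat}"
        cells = []
        for s in species:
            if s == sp:
                n_members = int(rng.integers(2, 4))  # >=2 so it is a real group
                cells.append(", ".join(new_gene(s, cat) for _ in range(n_members)))
            else:
                cells.append("")
        lines.append(og_id + "\t" + "\t".join(cells))
    for sp in species:
        for _ in range(config.n_unassigned_per_species):
            cat = HIGH if rng.random() < config.unassigned_high_skew else LOW
            new_gene(sp, cat)  # appears in calls but in no OG row
    return SimulatedOrthogroups(
        table_tsv="\n".join(lines) + "\n",
        calls=calls,
        planted_patterns=planted,
        species=species,
    )


# ---------------------------------------------------------------------------
# GO annotations

@dataclass
class SimulatedGo:
    obo_text: str
    annotations: dict[str, set[str]]  # gene -> direct terms
    planted_terms: list[str]
    universe: list[str]
    study: list[str]


def simulate_go(
    config: SimConfig,
    universe: Sequence[str] | None = None,
    study: Sequence[str] | None = None,
) -> SimulatedGo:
    """Toy ontology (3 levels) plus annotations with planted enrichment.

    Background leaf terms are annotated uniformly at random; each planted
    term is annotated with probability r*q in the study bin and q outside,
    with q set so the expected universe count matches the configured K.
    """
    if config.enrichment_relative_risk < 1:
        raise ValueError("relative risk must be >= 1")
    rng = np.random.default_rng(config.seed + 2)
    if universe is None:
        universe = [f"g{i+1:05d}" for i in range(10_000)]
    universe = list(universe)
    if study is None:
        study = universe[: int(0.4 * len(universe))]
    study_set = set(study)

    n_mid, leaves_per_mid = 5, 8
    root = "GO:0000001"
    mids = [f"GO:{i + 2:07d}" for i in range(n_mid)]
    leaves = [
        f"GO:{100 + i:07d}" for i in range(n_mid * leaves_per_mid)
    ]
    stanzas = [
        "format-version: 1.2",
        "ontology: toy-go",
        "",
        "[Term]",
        f"id: {root}",
        "name: biological_process root",
        "namespace: biological_process",
    ]
    for m in mids:
        stanzas += [
            "",
            "[Term]",
            f"id: {m}",
            f"name: mid {m}",
            "namespace: biological_process",
            f"is_a: {root} ! root",
        ]
    for i, leaf in enumerate(leaves):
        stanzas += [
            "",
            "[Term]",
            f"id: {leaf}",
            f"name: leaf {leaf}",
            "namespace: biological_process",
            f"is_a: {mids[i // leaves_per_mid]} ! mid",
        ]
    obo_text = "\n".join(stanzas) + "\n"

    planted = leaves[: config.n_enriched_terms]
    background = leaves[config.n_enriched_terms :]
    n_genes = len(universe)
    nb = len(background)
    # uniform background: two distinct random background leaves per gene
    first = rng.integers(0, nb, size=n_genes)
    second = (first + rng.integers(1, nb, size=n_genes)) % nb
    annotations: dict[str, set[str]] = {
        g: {background[first[i]], background[second[i]]}
        for i, g in enumerate(universe)
    }
    # planted enrichment
    n_study = len(study_set)
    n_out = n_genes - n_study
    r = config.enrichment_relative_risk
    in_study = np.array([g in study_set for g in universe])
    for term in planted:
        q = config.enriched_term_universe_count / (r * n_study + n_out)
        p_vec = np.where(in_study, r * q, q)
        hits = rng.random(n_genes) < p_vec
        for i in np.flatnonzero(hits):
            annotations[universe[i]].add(term)
    return SimulatedGo(
        obo_text=obo_text,
        annotations=annotations,
        planted_terms=list(planted),
        universe=universe,
        study=list(study),
    )
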