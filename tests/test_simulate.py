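"""Synthetic-data generators: reproducibility, planted structure, round trips."""

import numpy as np
import pytest

from cpgoe import genome_io
from cpgoe.cpg import compute_cpg_oe
from cpgoe.orthogroups import read_orthogroups_tsv, assign_og_status, upset_exclusive_counts
from cpgoe.selection import CodonAlignment, STOP_CODONS, pairwise_dnds
from cpgoe.simulate import (
    SimConfig,
    evolve_codon_pair,
    random_cds,
    simulate_cds_set,
    simulate_go,
    simulate_orthogroups,
)


@pytest.fixture(scope="module")
def small_sim():
    return simulate_cds_set(SimConfig(seed=7, n_genes=300))


class TestSimulateCdsSet:
    def test_bit_for_bit_reproducible(self, small_sim):
        again = simulate_cds_set(SimConfig(seed=7, n_genes=300))
        assert again.cds == small_sim.cds
        assert again.genome == small_sim.genome
        assert again.gff3 == small_sim.gff3

    def test_cds_are_valid_orfs(self, small_sim):
        for seq in small_sim.cds.values():
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG") and seq.endswith("TAA")
            internal = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
            assert not (set(internal) & STOP_CODONS)

    def test_gff3_round_trip_recovers_cds_both_strands(self, tmp_path, small_sim):
        fasta = tmp_path / "g.fa"
        gff = tmp_path / "a.gff3"
        genome_io.write_fasta(small_sim.genome, fasta)
        gff.write_text(small_sim.gff3)
        genome = genome_io.read_fasta(fasta)
        genes = genome_io.read_gff3(gff)
        recs = genome_io.extract_longest_cds(genes, genome)
        assert set(recs) == set(small_sim.cds)
        strands = set()
        for gid, rec in recs.items():
            assert rec.nt_seq == small_sim.cds[gid]
            strands.add(genes[gid][0].strand)
        assert strands == {"+", "-"}

    def test_no_depletion_means_no_signal(self):
        sim = simulate_cds_set(
            SimConfig(seed=3, n_genes=400, cpg_depletion_factor=1.0)
        )
        values = {g: compute_cpg_oe(s, g).cpg_oe for g, s in sim.cds.items()}
        meth = [values[g] for g, m in sim.methylated.items() if m]
        plain = [values[g] for g, m in sim.methylated.items() if not m]
        diff = abs(np.mean(meth) - np.mean(plain))
        se = np.sqrt(np.var(meth) / len(meth) + np.var(plain) / len(plain))
        assert diff < 2 * se

    @pytest.mark.parametrize("seed", range(5))
    def test_depleted_genes_have_lower_cpgoe(self, seed):
        sim = simulate_cds_set(
            SimConfig(seed=seed, n_genes=200, cpg_depletion_factor=0.5)
        )
        values = {g: compute_cpg_oe(s, g).cpg_oe for g, s in sim.cds.items()}
        meth = [values[g] for g, m in sim.methylated.items() if m]
        plain = [values[g] for g, m in sim.methylated.items() if not m]
        assert np.mean(meth) < np.mean(plain)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(cpg_depletion_factor=0.0).validate()


class TestEvolveCodonPair:
    def test_zero_divergence_identity(self, rng):
        anc = random_cds(rng, 50)
        a, b = evolve_codon_pair(anc, omega=0.3, divergence=0.0, seed=1)
        assert a == anc and b == anc

    def test_omega_zero_preserves_protein(self, rng):
        # with omega = 0 only synonymous proposals are accepted, so both
        # descendant proteins equal the ancestral protein; the pathway-
        # averaged Nd stays near zero (orderings through a nonsynonymous
        # intermediate can contribute fractional counts)
        from cpgoe.genome_io import translate_cds

        anc = random_cds(rng, 100)
        a, b = evolve_codon_pair(anc, omega=0.0, divergence=0.3, seed=2)
        assert translate_cds(a)[0] == translate_cds(anc)[0]
        assert translate_cds(b)[0] == translate_cds(anc)[0]
        est = pairwise_dnds(CodonAlignment("p", a, b))
        assert est.nd <= 0.1 * est.sd

    def test_negative_omega_rejected(self, rng):
        with pytest.raises(ValueError):
            evolve_codon_pair(random_cds(rng, 40), -0.1, 0.1, 1)

    def test_no_stops_introduced(self, rng):
        anc = random_cds(rng, 80)
        a, b = evolve_codon_pair(anc, omega=1.0, divergence=0.5, seed=3)
        for seq in (a, b):
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOP_CODONS)


class TestSimulateOrthogroups:
    config = SimConfig(
        seed=11,
        og_pattern_counts={"all_low": 40, "all_high": 15, "hemi_low_holo_high": 10},
        n_species_specific_ogs=6,
        n_unassigned_per_species=20,
    )

    def test_planted_counts_recovered_exactly(self, tmp_path):
        sim = simulate_orthogroups(self.config)
        path = tmp_path / "Orthogroups.tsv"
        path.write_text(sim.table_tsv)
        table = read_orthogroups_tsv(path)
        status = assign_og_status(table, sim.calls)
        counts = upset_exclusive_counts(status)
        sp = sim.species
        all_low = frozenset((s, "low") for s in sp)
        all_high = frozenset((s, "high") for s in sp)
        hemi = frozenset(
            [(s, "low") for s in sp[:-1]] + [(sp[-1], "high")]
        )
        assert counts[all_low] == 40
        assert counts[all_high] == 15
        assert counts[hemi] == 10

    def test_single_pattern_concentration(self):
        cfg = SimConfig(
            seed=1,
            og_pattern_counts={"all_low": 25},
            n_species_specific_ogs=0,
            n_unassigned_per_species=0,
        )
        sim = simulate_orthogroups(cfg)
        status = {
            og: {sp: sim.calls[sp][genes[0]] for sp, genes in members.items()}
            for og, members in _parse_table(sim.table_tsv).items()
        }
        counts = upset_exclusive_counts(status)
        assert list(counts.values()) == [25]

    @pytest.mark.parametrize("seed", range(5))
    def test_specific_genes_skew_high(self, seed, tmp_path):
        from cpgoe.orthogroups import species_specific_fraction

        cfg = SimConfig(
            seed=seed,
            og_pattern_counts={"all_low": 30, "all_high": 30},
            n_species_specific_ogs=15,
            n_unassigned_per_species=40,
            unassigned_high_skew=0.85,
        )
        sim = simulate_orthogroups(cfg)
        path = tmp_path / "og.tsv"
        path.write_text(sim.table_tsv)
        table = read_orthogroups_tsv(path)
        frac = species_specific_fraction(table, sim.calls, "sp1")
        assert frac["high"] > frac["low"]


def _parse_table(tsv):
    lines = tsv.strip().splitlines()
    species = lines[0].split("\t")[1:]
    out = {}
    for line in lines[1:]:
        cells = line.split("\t")
        out[cells[0]] = {
            sp: [g.strip() for g in cell.split(",") if g.strip()]
            for sp, cell in zip(species, cells[1:])
            if cell.strip()
        }
    return out


class TestSimulateGo:
    def test_planted_term_power(self):
        # relative risk 4, K ~ 200, universe 10k, study 4k: planted term
        # significant at p < 0.001 in nearly all seeds
        from cpgoe.enrichment import fisher_enrichment, propagate, read_obo

        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = SimConfig(seed=seed, enrichment_relative_risk=4.0)
            sim = simulate_go(cfg)
            p = _planted_p(sim, tmp=None)
            if p < 0.001:
                hits += 1
        assert hits >= int(0.95 * n_runs)

    def test_null_relative_risk_one_uniform_p(self):
        from scipy.stats import kstest

        pvals = []
        for seed in range(200):
            cfg = SimConfig(
                seed=seed,
                enrichment_relative_risk=1.0,
            )
            sim = simulate_go(
                cfg,
                universe=[f"g{i}" for i in range(2000)],
                study=[f"g{i}" for i in range(800)],
            )
            pvals.append(_planted_p(sim, tmp=None))
        stat = kstest(pvals, "uniform")
        assert stat.pvalue > 0.01

    def test_empty_planted_set_is_background(self):
        cfg = SimConfig(seed=5, n_enriched_terms=0)
        sim = simulate_go(cfg, universe=[f"g{i}" for i in range(500)])
        assert sim.planted_terms == []
        terms = set().union(*sim.annotations.values())
        assert all(not t.endswith("0000100") for t in sim.planted_terms)
        assert terms  # background still annotated

    def test_obo_text_parses_into_three_levels(self, tmp_path):
        from cpgoe.enrichment import read_obo

        cfg = SimConfig(seed=0)
        sim = simulate_go(cfg, universe=["g1"], study=["g1"])
        path = tmp_path / "toy.obo"
        path.write_text(sim.obo_text)
        graph = read_obo(path)
        leaf = sim.planted_terms[0]
        ancestors = graph.ancestors(leaf)
        assert len(ancestors) == 2  # mid + root


def _planted_p(sim, tmp):
    """Hypergeometric p of the planted term, computed directly on counts."""
    from scipy.stats import hypergeom

    term = sim.planted_terms[0]
    universe = sim.universe
    study = set(sim.study)
    K = sum(1 for g in universe if term in sim.annotations[g])
    k = sum(1 for g in study if term in sim.annotations[g])
    return float(hypergeom.sf(k - 1, len(universe), K, len(study)))
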