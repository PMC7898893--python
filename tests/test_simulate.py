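"""The study simulator: determinism, design invariants, and error models."""

import math

import numpy as np
import pandas as pd
import pytest

from ednamix.simulate import (
    MESOCOSM_DESIGN,
    SimulationConfig,
    emit_fastq,
    gen_edna_reads,
    gen_mesocosms,
    gen_panel,
    gen_population,
    gen_tissue_reads,
    simulate_study,
)


@pytest.fixture(scope="module")
def cfg():
    return SimulationConfig(n_loci=6, tissue_depth=3000, edna_depth=3000, seed=5)


@pytest.fixture(scope="module")
def panel(cfg):
    return gen_panel(cfg, np.random.default_rng(5))


class TestPanel:
    def test_default_panel_has_28_loci_within_richness_bounds(self):
        c = SimulationConfig(seed=2)
        sp = gen_panel(c, np.random.default_rng(2))
        rich = list(sp.richness().values())
        assert len(rich) == 28
        assert all(c.richness_min <= r <= c.richness_max for r in rich)

    def test_mean_richness_matches_configuration(self):
        """Mean alleles per locus over several panels within 3 SE of target."""
        c = SimulationConfig(seed=6)
        rng = np.random.default_rng(6)
        rich = []
        for _ in range(6):
            rich.extend(gen_panel(c, rng).richness().values())
        rich = np.array(rich)
        se = rich.std(ddof=1) / math.sqrt(len(rich))
        assert abs(rich.mean() - c.richness_mean) < 3 * se

    def test_same_seed_reproduces_panel(self, cfg):
        a = gen_panel(cfg, np.random.default_rng(5))
        b = gen_panel(cfg, np.random.default_rng(5))
        assert a.sequences == b.sequences
        assert {l: d.fwd_primer for l, d in a.panel.loci.items()} == {
            l: d.fwd_primer for l, d in b.panel.loci.items()
        }


class TestPopulation:
    def test_frequencies_sum_to_one(self, cfg, panel):
        pop, _ = gen_population(panel, 10, cfg, np.random.default_rng(1))
        for fr in pop.values():
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_heterozygosity_matches_hwe_expectation(self, cfg, panel):
        """Observed het over N=500 within 3 SE of 1 - sum p^2 per locus."""
        rng = np.random.default_rng(2)
        pop, gts = gen_population(panel, 500, cfg, rng)
        by_locus = {}
        for g in gts:
            by_locus.setdefault(g.locus, []).append(g.heterozygous)
        for locus, hets in by_locus.items():
            h_exp = 1.0 - sum(p * p for p in pop[locus].values())
            se = math.sqrt(h_exp * (1 - h_exp) / len(hets))
            assert abs(np.mean(hets) - h_exp) < 3 * se + 1e-9

    def test_same_seed_identical_genotypes(self, cfg, panel):
        _, a = gen_population(panel, 5, cfg, np.random.default_rng(3))
        _, b = gen_population(panel, 5, cfg, np.random.default_rng(3))
        assert a == b


class TestMesocosms:
    def test_default_design_totals_58_disjoint(self):
        inds = [f"i{k}" for k in range(60)]
        units = gen_mesocosms(inds, SimulationConfig())
        sizes = {u: len(m) for u, m in units.items()}
        assert sizes == MESOCOSM_DESIGN
        assert sum(sizes.values()) == 58
        flat = [i for m in units.values() for i in m]
        assert len(flat) == len(set(flat))

    def test_insufficient_individuals_raises(self):
        with pytest.raises(ValueError):
            gen_mesocosms([f"i{k}" for k in range(10)], SimulationConfig())


class TestTissueReads:
    def test_errorfree_homozygote_all_reads_on_one_allele(self, cfg, panel):
        rng = np.random.default_rng(4)
        pop, gts = gen_population(panel, 1, cfg, rng)
        hom = next(g for g in gts if not g.heterozygous)
        reads = gen_tissue_reads([hom], panel, cfg.errorfree(), rng)
        assert reads["allele"].nunique() == 1
        assert reads["allele"].iloc[0] == hom.alleles[0]

    def test_errorfree_heterozygote_calls_recoverable(self, cfg, panel):
        """Binomial tail oracle: at depth ~500 each allele holds >=20% of
        reads with probability ~1, so truth is recoverable."""
        rng = np.random.default_rng(10)
        pop, gts = gen_population(panel, 6, cfg, rng)
        reads = gen_tissue_reads(gts, panel, cfg.errorfree(), rng)
        for (ind, locus), grp in reads.groupby(["sample", "locus"]):
            total = grp["reads"].sum()
            for _, row in grp.iterrows():
                assert row["reads"] >= 0.2 * total

    def test_stutter_rate_recovered_in_expectation(self, cfg, panel):
        rng = np.random.default_rng(12)
        from dataclasses import replace

        c = replace(cfg, stutter_prob=0.05, substitution_prob=0.0)
        pop, gts = gen_population(panel, 10, cfg, rng)
        homs = [g for g in gts if not g.heterozygous]
        reads = gen_tissue_reads(homs, panel, c, rng)
        stutter = parent = 0
        for g in homs:
            grp = reads[(reads["sample"] == g.individual) & (reads["locus"] == g.locus)]
            by = dict(zip(grp["allele"], grp["reads"]))
            tgt = panel.stutter_target[(g.locus, g.alleles[0])]
            parent += by.get(g.alleles[0], 0)
            stutter += by.get(tgt, 0)
        rate = stutter / (stutter + parent)
        assert rate == pytest.approx(0.05, abs=0.01)


class TestEdnaReads:
    def test_single_member_errorfree_matches_dosage(self, cfg, panel):
        rng = np.random.default_rng(20)
        pop, gts = gen_population(panel, 1, cfg, rng)
        reads, w = gen_edna_reads(gts, panel, cfg.errorfree(), rng, depth=100_000,
                                  n_replicates=1)
        assert w == {gts[0].individual: pytest.approx(1.0)}
        truth = {g.locus: g.alleles for g in gts}
        for locus, grp in reads.groupby("locus"):
            fr = grp.set_index("allele")["reads"] / grp["reads"].sum()
            a1, a2 = truth[locus]
            if a1 == a2:
                assert fr[a1] == 1.0
            else:
                assert fr[a1] == pytest.approx(0.5, abs=0.02)

    def test_deep_sequencing_converges_to_pooled_frequencies(self, cfg, panel):
        """Law of large numbers at depth 1e6 with equalised weights."""
        from dataclasses import replace

        rng = np.random.default_rng(21)
        c = replace(cfg.errorfree(), contribution_concentration=1e6)
        pop, gts = gen_population(panel, 5, cfg, rng)
        reads, _ = gen_edna_reads(gts, panel, c, rng, depth=2_000_000,
                                  n_replicates=1)
        dosage: dict = {}
        for g in gts:
            d = dosage.setdefault(g.locus, {})
            for a in g.alleles:
                d[a] = d.get(a, 0) + 1
        for locus, grp in reads.groupby("locus"):
            fr = dict(zip(grp["allele"], grp["reads"] / grp["reads"].sum()))
            for a, copies in dosage[locus].items():
                assert fr.get(a, 0.0) == pytest.approx(copies / 10, abs=0.01)

    def test_same_seed_identical_tables(self, cfg, panel):
        pop, gts = gen_population(panel, 3, cfg, np.random.default_rng(7))
        a, _ = gen_edna_reads(gts, panel, cfg, np.random.default_rng(8))
        b, _ = gen_edna_reads(gts, panel, cfg, np.random.default_rng(8))
        pd.testing.assert_frame_equal(a, b)


class TestFastqEmission:
    def test_record_counts_and_syntax(self, cfg, panel, tmp_path):
        rng = np.random.default_rng(30)
        pop, gts = gen_population(panel, 2, cfg, rng)
        from dataclasses import replace

        c = replace(cfg.errorfree(), tissue_depth=300)
        counts = gen_tissue_reads(gts, panel, c, rng)
        paths = emit_fastq(counts, panel, tmp_path, c)
        total = counts["reads"].sum()
        n_rec = 0
        for r1, r2 in paths.values():
            for p in (r1, r2):
                lines = p.read_text().splitlines()
                assert len(lines) % 4 == 0
                for i in range(0, len(lines), 4):
                    assert lines[i].startswith("@")
                    assert lines[i + 2] == "+"
                    assert len(lines[i + 1]) == len(lines[i + 3])
                n_rec += len(lines) // 4
        assert n_rec == 2 * total


def test_full_study_is_seed_reproducible():
    cfg = SimulationConfig(n_loci=5, tissue_depth=2000, edna_depth=2000,
                           field_depth=800, seed=33)
    a = simulate_study(cfg, np.random.default_rng(33))
    b = simulate_study(cfg, np.random.default_rng(33))
    pd.testing.assert_frame_equal(a.tissue_counts, b.tissue_counts)
    pd.testing.assert_frame_equal(a.edna_counts, b.edna_counts)
    pd.testing.assert_frame_equal(a.field_counts, b.field_counts)
    assert a.mesocosms == b.mesocosms


def test_zero_error_pipeline_reproduces_genotypes():
    """gen -> FASTQ -> read processing -> genotyping recovers every genotype."""
    import tempfile

    from ednamix.genotyping import genotype_matrix
    from ednamix.reads import fastq_to_counts

    cfg = SimulationConfig(n_loci=4, tissue_depth=400, seed=44).errorfree()
    rng = np.random.default_rng(44)
    sp = gen_panel(cfg, rng)
    pop, gts = gen_population(sp, 4, cfg, rng)
    counts = gen_tissue_reads(gts, sp, cfg, rng)
    with tempfile.TemporaryDirectory() as d:
        pairs = emit_fastq(counts, sp, d, cfg)
        table, _ = fastq_to_counts(pairs, sp.panel)
    labels = sp.panel.sequence_labels()
    table = table.assign(
        allele=[labels[(l, s)] for l, s in zip(table["locus"], table["allele"])]
    )
    calls, _ = genotype_matrix(table, sp.loci)
    truth = {(g.individual, g.locus): g.alleles for g in gts}
    assert all(truth[(g.individual, g.locus)] == g.alleles for g in calls)
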