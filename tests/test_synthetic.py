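"""Synthetic trio generator: determinism, composition statistics,
Mendelian consistency, the PL emission model, and file round-trips."""

import math
from collections import Counter

import numpy as np
import pysam
import pytest

from crisprtrio import (EditSpec, SimConfig, emit_outputs, generate_genome,
                        implant_guide_sites, simulate_read_evidence,
                        simulate_trio)
from crisprtrio.synthetic import (ORIGIN_INDUCED, ORIGIN_INHERITED,
                                  ORIGIN_SPONTANEOUS, _phred_pl)


class TestSimConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(genome_length=5_000),
        dict(gc_fraction=0.0),
        dict(gc_fraction=1.0),
        dict(mean_depth=0.5),
        dict(base_error=0.6),
        dict(caller2_discordance=1.5),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenerateGenome:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(genome_length=10_000, seed=1)
        assert generate_genome(cfg) == generate_genome(cfg)

    def test_gc_fraction_within_binomial_ci(self):
        n = 100_000
        cfg = SimConfig(genome_length=n, gc_fraction=0.5, seed=2)
        seq = "".join(generate_genome(cfg).values())
        gc = (seq.count("G") + seq.count("C")) / n
        se = math.sqrt(0.25 / n)
        assert abs(gc - 0.5) < 3 * se

    def test_contig_count_and_length_conservation(self):
        cfg = SimConfig(genome_length=30_000, n_contigs=3, seed=3)
        genome = generate_genome(cfg)
        assert len(genome) == 3
        assert sum(len(s) for s in genome.values()) == 30_000

    def test_scaffold_contigs_are_extra_and_named(self):
        cfg = SimConfig(genome_length=20_000, seed=4, n_scaffold_contigs=2,
                        scaffold_length=1_000)
        genome = generate_genome(cfg)
        scaffolds = [c for c in genome if c.startswith("scaffold")]
        assert len(scaffolds) == 2
        assert all(len(genome[c]) == 1_000 for c in scaffolds)


class TestSimulateTrio:
    def test_zero_rates_give_no_founder_specific_variants(self, small_genome):
        cfg = SimConfig(genome_length=50_000, seed=5, mu_dnm=0.0,
                        n_inherited=20)
        variants, truth = simulate_trio(small_genome, cfg)
        assert all(t.origin == ORIGIN_INHERITED for t in truth)

    def test_spontaneous_count_matches_poisson_mean(self):
        # mean count over replicates ~ 2 * mu * L
        mu, L, reps = 1e-5, 100_000, 300
        genome = generate_genome(SimConfig(genome_length=L, seed=6))
        counts = []
        for s in range(reps):
            cfg = SimConfig(genome_length=L, seed=s, mu_dnm=mu, n_inherited=0)
            _, truth = simulate_trio(genome, cfg)
            counts.append(sum(t.origin == ORIGIN_SPONTANEOUS for t in truth))
        expect = 2 * mu * L
        se = math.sqrt(expect / reps)
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_induced_variants_placed_near_every_site(self, guide, small_genome):
        genome, planted = implant_guide_sites(small_genome, guide,
                                              {(1, 2): 10}, seed=7)
        cfg = SimConfig(genome_length=50_000, seed=8, mu_dnm=0.0,
                        n_inherited=0, offtarget_induced_rate=1.0,
                        induced_distance_sd=15.0)
        _, truth = simulate_trio(genome, cfg, planted)
        induced = [t for t in truth if t.origin == ORIGIN_INDUCED]
        assert len(induced) == 10
        cut_of = {s.site_id: s.cut_site for s in planted}
        for t in induced:
            assert abs(t.pos - cut_of[t.site_id]) <= 6 * 15.0

    def test_mendelian_consistency(self, small_genome):
        cfg = SimConfig(genome_length=50_000, seed=9, mu_dnm=2e-4,
                        n_inherited=40)
        variants, truth = simulate_trio(small_genome, cfg)
        origins = {(v.contig, v.pos): v for v in variants}
        for t in truth:
            v = origins[(t.contig, t.pos)]
            in_parent = v.gt["father"] > 0 or v.gt["mother"] > 0
            if t.origin == ORIGIN_INHERITED:
                assert in_parent
            else:
                assert not in_parent

    def test_truth_rows_equal_founder_nonref_alleles(self, small_genome):
        cfg = SimConfig(genome_length=50_000, seed=10, mu_dnm=1e-4,
                        n_inherited=30)
        variants, truth = simulate_trio(small_genome, cfg)
        assert len(truth) == sum(1 for v in variants if v.gt["founder"] > 0)
        assert len({(t.contig, t.pos, t.alt) for t in truth}) == len(truth)


class TestReadEvidence:
    def test_het_with_balanced_reads_is_ml_het(self):
        pl = _phred_pl(n_alt=5, n_ref=5, base_error=0.01)
        assert pl[1] == 0 and pl[0] > 0 and pl[2] > 0

    def test_pl_matches_direct_likelihood_product(self):
        # hom-ref, 30 reads, 0 alt: PL(AB) from the direct product
        e = 0.01
        pl = _phred_pl(n_alt=0, n_ref=30, base_error=e)
        assert pl[0] == 0
        raw_aa = -10 * 30 * math.log10(1 - e)
        raw_ab = -10 * 30 * math.log10(0.5)
        assert pl[1] == round(raw_ab) - round(raw_aa)
        assert pl[0] < pl[1] < pl[2]

    def test_count_conservation(self):
        rng = np.random.default_rng(11)
        for g in (0, 1, 2):
            for _ in range(50):
                ev = simulate_read_evidence(g, 20, 0.01, rng)
                assert ev.ad[0] + ev.ad[1] == ev.dp
                assert ev.adf[1] + ev.adr[1] == ev.ad[1]
                assert ev.adf[0] + ev.adr[0] == ev.ad[0]
                assert min(ev.pl) == 0 and all(p >= 0 for p in ev.pl)
                assert ev.dp >= 1

    def test_pl_calibration_het_sites(self):
        # >= 99% of simulated het sites at depth 25 have arg-min PL = AB
        rng = np.random.default_rng(12)
        ok = sum(
            int(np.argmin(simulate_read_evidence(1, 25, 0.005, rng).pl) == 1)
            for _ in range(1_000))
        assert ok >= 990


@pytest.fixture(scope="module")
def trio_run(tmp_path_factory, guide):
    cfg = SimConfig(genome_length=60_000, seed=13, mu_dnm=1e-4,
                    n_inherited=30, caller2_discordance=0.0,
                    edit_config=(EditSpec("sg1", "del", 3),),
                    plant_inversion=True, n_scaffold_contigs=1)
    genome = generate_genome(cfg)
    genome, planted = implant_guide_sites(genome, guide,
                                          {(0, 0): 2, (1, 4): 2}, seed=14)
    variants, truth = simulate_trio(genome, cfg, planted)
    outdir = tmp_path_factory.mktemp("simout")
    paths = emit_outputs(genome, variants, truth, planted, cfg, str(outdir))
    return cfg, genome, variants, truth, planted, paths


class TestEmitOutputs:
    def test_identical_site_sets_when_no_discordance(self, trio_run):
        _, _, _, _, _, paths = trio_run
        def keys(path):
            with pysam.VariantFile(path) as vf:
                return [(r.contig, r.pos, r.ref, r.alts) for r in vf]
        assert keys(paths["caller1_vcf"]) == keys(paths["caller2_vcf"])

    def test_full_discordance_empties_caller2(self, tmp_path, small_genome):
        cfg = SimConfig(genome_length=50_000, seed=15, mu_dnm=1e-4,
                        n_inherited=10, caller2_discordance=1.0)
        variants, truth = simulate_trio(small_genome, cfg)
        paths = emit_outputs(small_genome, variants, truth, [], cfg,
                             str(tmp_path / "out"))
        with pysam.VariantFile(paths["caller2_vcf"]) as vf:
            assert sum(1 for _ in vf) == 0

    def test_vcf_round_trip_reproduces_evidence(self, trio_run):
        # bit-exact FORMAT fields after write + read
        cfg, genome, variants, _, _, paths = trio_run
        import crisprtrio.synthetic as syn
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        order = {c: i for i, c in enumerate(genome)}
        recs = sorted(variants, key=lambda v: (order[v.contig], v.pos))
        expected = [{s: syn.simulate_read_evidence(
            v.gt[s], cfg.mean_depth, cfg.base_error, rng)
            for s in syn.SAMPLES} for v in recs]
        with pysam.VariantFile(paths["caller1_vcf"]) as vf:
            got = list(vf)
        assert len(got) == len(recs)
        for rec, exp in zip(got, expected):
            for s in syn.SAMPLES:
                fmt = rec.samples[s]
                ev = exp[s]
                assert fmt["DP"] == ev.dp
                assert tuple(fmt["AD"]) == ev.ad
                assert tuple(fmt["ADF"]) == ev.adf
                assert tuple(fmt["ADR"]) == ev.adr
                assert tuple(fmt["PL"]) == ev.pl

    def test_byte_identical_outputs_across_runs(self, trio_run, tmp_path):
        cfg, genome, variants, truth, planted, paths = trio_run
        paths2 = emit_outputs(genome, variants, truth, planted, cfg,
                              str(tmp_path / "again"))
        for key in paths:
            with open(paths[key], "rb") as a, open(paths2[key], "rb") as b:
                assert a.read() == b.read(), key

    def test_truth_table_covers_origins(self, trio_run):
        _, _, _, truth, _, paths = trio_run
        origins = Counter(t.origin for t in truth)
        assert origins["on_target_edit"] == 1
        with open(paths["truth_tsv"]) as fh:
            n_rows = sum(1 for _ in fh) - 1
        assert n_rows == len(truth)

    def test_sv_callset_contains_inversion_and_decoys(self, trio_run):
        _, _, _, _, planted, paths = trio_run
        rows = [l.split("\t") for l in open(paths["sv_tsv"])][1:]
        types = Counter(r[2] for r in rows)
        assert types["INV"] >= 2  # planted + distant decoy
        assert any(r[3].startswith("scaffold") for r in rows)
        exact = sorted((s for s in planted if s.m_total == 0),
                       key=lambda s: s.cut_site)
        inv = [r for r in rows if r[2] == "INV" and r[1] == "founder1"]
        planted_inv = [r for r in inv
                       if abs(int(r[4]) - exact[0].cut_site) <= 10]
        assert planted_inv
        assert int(planted_inv[0][4]) == exact[0].cut_site - 8
        assert int(planted_inv[0][5]) == exact[1].cut_site + 2
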