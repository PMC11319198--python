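"""Generator correctness: locus geometry, read/splice/expression/panel/sibling sims."""

import numpy as np
import pysam
import pytest
import scipy.stats

import svalocus as sv
from svalocus.synthetic import LocusConfigError, SpliceSimConfig


class TestLocusModel:
    def test_default_geometry_matches_real_locus(self, model):
        # the miniature locus preserves the real element lengths and spacing
        assert model.sva_f1_interval[0] - model.sva_f_interval[1] == 3900
        assert model.sva_f1_interval[1] - model.sva_f1_interval[0] == 3296
        assert model.sva_f_interval[1] - model.sva_f_interval[0] == 1612
        assert model.right_breakpoint == model.sva_f1_interval[1] - 1

    def test_deterministic_for_fixed_config(self):
        assert sv.build_locus_model({}) == sv.build_locus_model({})

    @pytest.mark.parametrize(
        "overrides",
        [
            {"exon3_acceptor": 1500},  # exon 3 before exon 2
            {"polya_site": 4000},  # poly(A) inside the SVA F element
            {"sva_f1_gap": -100},
            {"contig_length": 9000},  # SVA F1 runs off the contig
            {"no_such_key": 1},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(LocusConfigError):
            sv.build_locus_model(overrides)


class TestDnaReadPairs:
    def test_hom_anc_yields_no_breakpoint_reads(self, model):
        reads = sv.simulate_dna_read_pairs(sv.SimTruth("a", 0), model, seed=11)
        rb = model.right_breakpoint
        spanning = [r for r in reads if r.reference_start <= rb - 1 and r.reference_end > rb + 1]
        assert spanning == []

    def test_hom_ins_yields_no_inflated_template_lengths(self, model):
        reads = sv.simulate_dna_read_pairs(sv.SimTruth("a", 2), model, seed=11)
        limit = 450 + model.insertion_length / 2
        assert all(abs(r.template_length) <= limit for r in reads)

    def test_het_long_tlen_pair_count_matches_closed_form(self, model):
        """Mean count of inflated-TLEN pairs across seeds vs the closed form.

        A fragment of length F whose deletion-junction offset is in
        [read_len/2, F - read_len/2) yields a long-TLEN pair under the
        clip-to-larger-side alignment model, so the expectation is
        sum_F P(F) * n_frags(F) * (F - read_len) / (n_start_positions(F)).
        """
        read_len, frag_mean, frag_sd, coverage = 150, 450.0, 100.0, 25.0
        hap_len = model.contig_length - model.insertion_length
        # discrete truncated-normal fragment distribution (rounded draws)
        fs = np.arange(2 * read_len, int(frag_mean + 8 * frag_sd))
        lower = (2 * read_len - frag_mean) / frag_sd
        pdf = scipy.stats.truncnorm.pdf(fs, lower, np.inf, loc=frag_mean, scale=frag_sd)
        pdf /= pdf.sum()
        n_frag_mean = (coverage / 2) * hap_len / (2 * read_len)
        expected = n_frag_mean * np.sum(pdf * (fs - read_len) / (hap_len - fs + 1))

        counts = []
        for seed in range(1, 101):
            reads = sv.simulate_dna_read_pairs(
                sv.SimTruth("s", 1), model,
                coverage=coverage, read_len=read_len,
                frag_mean=frag_mean, frag_sd=frag_sd, seed=seed,
            )
            counts.append(len({r.query_name for r in reads if r.template_length > 2500}))
        counts = np.asarray(counts, float)
        sem = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * sem

    def test_breakpoint_reads_only_from_insertion_haplotypes(self, model):
        reads = sv.simulate_dna_read_pairs(sv.SimTruth("s", 1), model, seed=5)
        rb = model.right_breakpoint
        for r in reads:
            if r.reference_start <= rb - 1 and r.reference_end - 1 >= rb + 1:
                # haplotype index 0 is the single insertion haplotype
                assert r.query_name.split(":")[1] == "0"

    def test_bit_reproducible_and_sam_round_trip(self, model, locus, tmp_path):
        reads1 = sv.simulate_dna_read_pairs(sv.SimTruth("s", 1), model, seed=42)
        reads2 = sv.simulate_dna_read_pairs(sv.SimTruth("s", 1), model, seed=42)
        assert reads1 == reads2

        path = tmp_path / "sample.sam"
        sv.write_sam(reads1, model, path)
        with pysam.AlignmentFile(str(path)) as af:
            rt = list(af)
        rules = sv.RuleSet.ukb()
        before = sv.count_evidence(reads1, locus, rules, "s")
        after = sv.count_evidence(rt, locus, rules, "s")
        assert (before.n_ins, before.n_anc) == (after.n_ins, after.n_anc)
        # record fields used downstream survive serialization
        by_name = {(r.query_name, r.is_read1): r for r in reads1}
        for rec in rt:
            sim = by_name[(rec.query_name, rec.is_read1)]
            assert rec.reference_start == sim.reference_start
            assert rec.template_length == sim.template_length
            assert rec.mapping_quality == sim.mapping_quality
            assert tuple(rec.cigartuples) == sim.cigartuples

    def test_precondition_errors(self, model):
        with pytest.raises(ValueError):
            sv.simulate_dna_read_pairs(sv.SimTruth("s", 0), model, frag_mean=200.0)
        with pytest.raises(ValueError):
            sv.simulate_dna_read_pairs(sv.SimTruth("s", 0), model, coverage=0.0)


class TestSpliceCounts:
    def test_hom_ins_never_aberrant_when_p_ins_zero(self):
        cfg = SpliceSimConfig(p_aberrant_anc=0.3, p_aberrant_ins=0.0, depth=200)
        for seed in range(20):
            _, n_ab = sv.simulate_splice_counts(sv.SimTruth("s", 2), cfg, seed=seed)
            assert n_ab == 0

    def test_law_of_large_numbers(self):
        cfg = SpliceSimConfig(p_aberrant_anc=0.5, depth=200_000)
        n_can, n_ab = sv.simulate_splice_counts(sv.SimTruth("s", 0), cfg, seed=1)
        assert n_ab / (n_ab + n_can) == pytest.approx(0.5, abs=0.01)

    def test_het_expected_fraction_formula(self):
        cfg = SpliceSimConfig(p_aberrant_anc=0.2, p_aberrant_ins=0.0,
                              allelic_expression_ratio=1.0)
        assert cfg.expected_fraction(1) == pytest.approx(0.1)
        # higher expression from the insertion allele dilutes the aberrant share
        diluted = SpliceSimConfig(p_aberrant_anc=0.2, allelic_expression_ratio=3.0)
        assert diluted.expected_fraction(1) == pytest.approx(0.2 / 4.0)

    def test_mean_fraction_matches_expectation_across_seeds(self):
        cfg = SpliceSimConfig(p_aberrant_anc=0.156, depth=50)
        fracs = []
        for seed in range(100):
            n_can, n_ab = sv.simulate_splice_counts(sv.SimTruth("s", 0), cfg, seed=seed)
            if n_can + n_ab:
                fracs.append(n_ab / (n_ab + n_can))
        fracs = np.asarray(fracs)
        sem = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.156) < 3 * sem


class TestExpression:
    def _truths(self, dosages):
        return [sv.SimTruth(f"s{k}", int(d)) for k, d in enumerate(dosages)]

    def test_afc_one_means_no_genotype_effect(self):
        truths = self._truths([0, 1, 2, 1, 0])
        y = sv.simulate_expression(truths, beta0=2.0, afc_true=1.0, noise_sd=0.0)
        assert np.ptp(y) == 0

    def test_effect_size_parameterization(self):
        # beta_g = beta0*(aFC-1)/2: with beta0=2, aFC=3 each allele adds 2
        truths = self._truths([0, 1, 2])
        y = sv.simulate_expression(truths, beta0=2.0, afc_true=3.0, noise_sd=0.0)
        assert np.allclose(np.diff(y), 2.0)

    def test_noiseless_identifiability(self):
        rng = np.random.default_rng(3)
        dosages = sv.simulate_dosages(80, 0.3, rng)
        truths = self._truths(dosages)
        X = rng.normal(size=(80, 2))
        y = sv.simulate_expression(truths, 2.0, 2.2, X, np.array([0.5, -0.2]), 0.0, seed=rng)
        fit = sv.fit_eqtl_linear(y, dosages.astype(float), X)
        assert sv.estimate_afc(fit) == pytest.approx(2.2, abs=1e-9)

    def test_dimension_mismatch_raises(self):
        truths = self._truths([0, 1, 2])
        with pytest.raises(ValueError):
            sv.simulate_expression(truths, 2.0, 2.0,
                                   covariates=np.ones((3, 2)), cov_effects=np.ones(3))


class TestHaplotypePanel:
    def test_perfect_sweep_gives_identical_derived_haplotypes(self):
        panel = sv.simulate_haplotype_panel(100, 41, 0.2, sweep_strength=1.0,
                                            mut_rate=0.0, seed=1)
        curve = sv.ehh_curve(panel, 1)
        assert (curve.ehh_values == 1.0).all()

    def test_focal_count_rounding_contract(self):
        panel = sv.simulate_haplotype_panel(1000, 21, 0.11, 0.9, seed=7)
        count = int(panel.alleles[:, panel.focal_index].sum())
        assert count in (109, 110, 111)

    def test_no_sweep_is_null(self):
        """sweep_strength 0: derived and ancestral EHH indistinguishable (KS)."""
        derived_vals, ancestral_vals = [], []
        for seed in range(100):
            panel = sv.simulate_haplotype_panel(60, 21, 0.4, 0.0, seed=seed)
            j = panel.focal_index + 5
            for allele, sink in ((1, derived_vals), (0, ancestral_vals)):
                curve = sv.ehh_curve(panel, allele)
                sink.append(
                    curve.value_at(j) if j in curve.variant_indices else 0.0
                )
        stat = scipy.stats.ks_2samp(derived_vals, ancestral_vals)
        assert stat.pvalue > 0.01


class TestSiblingGenotypes:
    def test_ibd2_pairs_identical_without_error(self):
        sib = sv.simulate_sibling_genotypes(30, 200, 0.0, 1.0, seed=2)
        assert (sib.geno_a == sib.geno_b).all()
        assert sib.ibd2.all()

    def test_mismatch_probability_matches_enumeration_oracle(self):
        """Per-site IBD2 mismatch rate at err 0.5 vs brute-force enumeration."""
        err = 0.5
        # enumerate error indicators and the 3 possible replacement values on
        # each side; mismatch happens when the observed values differ.  The
        # result is the same for every true genotype g (uniform replacement),
        # so enumerating one g suffices.
        g = 1
        p_mismatch = 0.0
        for ea in (0, 1):
            for eb in (0, 1):
                pe = (err if ea else 1 - err) * (err if eb else 1 - err)
                vals_a = (0, 1, 2) if ea else (g,)
                vals_b = (0, 1, 2) if eb else (g,)
                for va in vals_a:
                    for vb in vals_b:
                        if va != vb:
                            p_mismatch += pe / (len(vals_a) * len(vals_b))
        sib = sv.simulate_sibling_genotypes(300, 500, err, 1.0, seed=9)
        observed = float((sib.geno_a != sib.geno_b).mean())
        n = sib.geno_a.size
        tol = 4 * np.sqrt(p_mismatch * (1 - p_mismatch) / n)
        assert abs(observed - p_mismatch) < tol

    def test_non_ibd2_pairs_differ(self):
        sib = sv.simulate_sibling_genotypes(50, 400, 0.0, 0.0, seed=4)
        assert not sib.ibd2.any()
        mismatches = (sib.geno_a != sib.geno_b).sum(axis=1)
        assert (mismatches > 3).all()


class TestPresets:
    def test_presets_carry_cohort_calibration(self):
        nse = sv.load_preset("nse_skin")
        se = sv.load_preset("se_skin")
        ukb = sv.load_preset("ukb_wgs")
        assert nse["splice"]["p_aberrant_anc"] == pytest.approx(0.156)
        assert se["splice"]["p_aberrant_anc"] == pytest.approx(0.141)
        assert nse["expression"]["afc_true"] == pytest.approx(2.2)
        assert ukb["cohort"]["allele_frequency"] == pytest.approx(0.11)
        with pytest.raises(ValueError):
            sv.load_preset("nope")
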