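"""TPM recovery, linear eQTL fitting, aFC estimation and the BCa bootstrap."""

import numpy as np
import pytest

import svalocus as sv
from svalocus.expression import EqtlFit, RegionQuant

from conftest import make_read


class TestTpm:
    @pytest.mark.parametrize(
        "counts, length, tpm, expected", [(1000, 1000, 1, 1.0), (2000, 1000, 4, 0.5)]
    )
    def test_scaling_factor_examples(self, counts, length, tpm, expected):
        assert sv.tpm_scaling_factor(counts, length, tpm) == pytest.approx(expected)

    def test_scaling_factor_ratio_invariance(self):
        f = sv.tpm_scaling_factor(1234, 2000, 7.5)
        assert sv.tpm_scaling_factor(2 * 1234, 2000, 2 * 7.5) == pytest.approx(f)

    def test_nonpositive_inputs_rejected(self):
        for bad in [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-5, 1, 1)]:
            with pytest.raises(ValueError):
                sv.tpm_scaling_factor(*bad)
        with pytest.raises(ValueError):
            sv.region_tpm(10, 100, 0)

    @pytest.mark.parametrize("count, length, factor, expected",
                             [(500, 250, 0.5, 4.0), (0, 100, 1.0, 0.0)])
    def test_region_tpm_examples(self, count, length, factor, expected):
        assert sv.region_tpm(count, length, factor) == pytest.approx(expected)

    def test_round_trip_recovers_reference_tpm(self):
        # factor derived from a gene, then applied back to the same gene
        counts, length, tpm = 48_231, 3_902, 2_743.8
        factor = sv.tpm_scaling_factor(counts, length, tpm)
        assert sv.region_tpm(counts, length, factor) == pytest.approx(tpm)

    def test_region_tpm_linearity(self):
        base = sv.region_tpm(100, 500, 0.2)
        assert sv.region_tpm(300, 500, 0.2) == pytest.approx(3 * base)
        assert sv.region_tpm(100, 1500, 0.2) == pytest.approx(base / 3)


class TestCountRegionReads:
    REGION = [RegionQuant("r1", 50, 200)]

    def _rna_read(self, pos, cigar="100M", mapq=255, nm=0, **kw):
        return make_read(pos, cigar=cigar, mapq=mapq, tags={"NM": nm}, **kw)

    def test_overlapping_read_counted(self):
        quants, _ = sv.count_region_reads([self._rna_read(10)], self.REGION)
        assert quants[0].read_count == 1

    def test_spliced_read_gap_spanning_region_not_counted(self):
        # aligned blocks [10,60) and [5060,5110): the N gap covers [50,200)
        rec = self._rna_read(10, cigar="50M5000N50M")
        quants, _ = sv.count_region_reads([rec], self.REGION)
        assert quants[0].read_count == 1  # block [10,60) still overlaps [50,200)
        narrow = [RegionQuant("r2", 100, 4000)]
        quants, _ = sv.count_region_reads([rec], narrow)
        assert quants[0].read_count == 0

    def test_mapq_must_be_255(self):
        quants, _ = sv.count_region_reads([self._rna_read(60, mapq=60)], self.REGION)
        assert quants[0].read_count == 0

    def test_edit_distance_filter(self):
        quants, _ = sv.count_region_reads([self._rna_read(60, nm=7)], self.REGION)
        assert quants[0].read_count == 0
        quants, _ = sv.count_region_reads([self._rna_read(60, nm=6)], self.REGION)
        assert quants[0].read_count == 1

    def test_missing_nm_tag_excluded_with_warning(self):
        rec = make_read(60, mapq=255)  # no NM tag at all
        with pytest.warns(UserWarning, match="NM"):
            quants, n_warned = sv.count_region_reads([rec], self.REGION)
        assert n_warned == 1 and quants[0].read_count == 0


class TestEqtlFit:
    def test_noiseless_line(self):
        g = np.array([0.0, 1, 2, 1, 0, 2, 1])
        fit = sv.fit_eqtl_linear(3 + 2 * g, g)
        assert fit.beta0 == pytest.approx(3.0)
        assert fit.beta_g == pytest.approx(2.0)

    def test_null_effect_within_three_se(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, 2000).astype(float)
        y = 5.0 + rng.normal(0, 1, 2000)
        fit = sv.fit_eqtl_linear(y, g)
        assert abs(fit.beta_g) < 3 * fit.se_beta_g

    def test_agreement_with_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, k = 60, int(rng.integers(0, 4))
            g = rng.binomial(2, 0.4, n).astype(float)
            if np.ptp(g) == 0:
                continue
            X = rng.normal(size=(n, k)) if k else None
            y = rng.normal(size=n)
            fit = sv.fit_eqtl_linear(y, g, X)
            cols = [np.ones(n), g] + ([X[:, j] for j in range(k)] if k else [])
            A = np.column_stack(cols)
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert fit.beta0 == pytest.approx(beta[0], abs=1e-8)
            assert fit.beta_g == pytest.approx(beta[1], abs=1e-8)
            if k:
                assert np.allclose(fit.beta_cov, beta[2:], atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        g = np.array([0.0, 1, 2, 1, 0, 2])
        X = np.column_stack([g, g])  # both collinear with genotype
        with pytest.raises(ValueError, match="cov"):
            sv.fit_eqtl_linear(np.ones(6), g, X)

    def test_conditional_analysis_removes_proxy_signal(self):
        """A perfect-LD proxy's effect vanishes once the causal dosage is a covariate."""
        rng = np.random.default_rng(23)
        causal = rng.binomial(2, 0.3, 3000).astype(float)
        proxy = causal.copy()
        y = 1.0 + 0.8 * causal + rng.normal(0, 1, 3000)
        # perturb proxy slightly so the design is full rank
        flip = rng.random(3000) < 0.05
        proxy[flip] = rng.binomial(2, 0.3, int(flip.sum()))
        fit = sv.fit_eqtl_linear(y, proxy, causal[:, None])
        assert abs(fit.beta_g) < 3 * fit.se_beta_g


class TestAfc:
    @pytest.mark.parametrize(
        "beta0, beta_g, expected",
        [(4.0, 2.0, 2.0), (3.0, 0.0, 1.0), (2.0, 1.2, 2.2)],
    )
    def test_formula(self, beta0, beta_g, expected):
        fit = EqtlFit(beta0, beta_g, np.array([]), 1.0, 100, 0.1)
        assert sv.estimate_afc(fit) == pytest.approx(expected)

    def test_positivity_clamp(self):
        # alternate-allele expression 1 + 2*(-0.6) = -0.2 clamps to the floor
        fit = EqtlFit(1.0, -0.6, np.array([]), 1.0, 100, 0.1)
        assert sv.estimate_afc(fit) == pytest.approx(1e-6)

    @pytest.mark.parametrize("afc_true", [0.5, 1.0, 2.2, 3.0, 7.5])
    def test_noiseless_exact_recovery_any_afc(self, afc_true):
        rng = np.random.default_rng(int(afc_true * 10))
        dosages = sv.simulate_dosages(60, 0.35, rng)
        truths = [sv.SimTruth(f"s{k}", int(d)) for k, d in enumerate(dosages)]
        X = rng.normal(size=(60, 3))
        y = sv.simulate_expression(
            truths, 1.7, afc_true, X, np.array([0.3, -0.4, 0.1]), 0.0, seed=rng
        )
        fit = sv.fit_eqtl_linear(y, dosages.astype(float), X)
        assert sv.estimate_afc(fit) == pytest.approx(afc_true, abs=1e-9)


class TestBcaInterval:
    def test_close_to_percentile_for_symmetric_statistic(self):
        rng = np.random.default_rng(4)
        import scipy.stats

        diffs = []
        for _ in range(5):
            x = rng.normal(0, 1, 150)
            low, high = sv.bca_interval(x, np.mean, n_boot=2000, seed=1)
            res = scipy.stats.bootstrap(
                (x,), np.mean, n_resamples=2000, method="percentile",
                rng=np.random.default_rng(1),
            )
            diffs.append(abs(low - res.confidence_interval.low))
            diffs.append(abs(high - res.confidence_interval.high))
        assert max(diffs) < 0.02

    def test_coverage_of_true_mean(self):
        """Nominal 95% BCa interval for the mean of N(0,1), n=100."""
        rng = np.random.default_rng(99)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            x = rng.normal(0, 1, 100)
            low, high = sv.bca_interval(x, np.mean, n_boot=1000, seed=rng.integers(2**31))
            hits += low <= 0.0 <= high
        assert 0.92 <= hits / n_sim <= 0.98

    def test_replicate_stability(self):
        x = np.random.default_rng(2).normal(0, 1, 200)
        a = sv.bca_interval(x, np.mean, n_boot=1000, seed=5)
        b = sv.bca_interval(x, np.mean, n_boot=10_000, seed=5)
        assert abs(a[0] - b[0]) < 0.05 and abs(a[1] - b[1]) < 0.05

    def test_degenerate_distribution_returns_point(self):
        x = np.ones(50)
        with pytest.warns(UserWarning, match="degenerate"):
            low, high = sv.bca_interval(x, np.mean, n_boot=1000, seed=0)
        assert low == high == 1.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sv.bca_interval(np.ones(5), np.mean, n_boot=1000)
        with pytest.raises(ValueError):
            sv.bca_interval(np.ones(50), np.mean, n_boot=10)

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(3).normal(size=60)
        assert sv.bca_interval(x, np.mean, seed=7, n_boot=1000) == sv.bca_interval(
            x, np.mean, seed=7, n_boot=1000
        )


class TestGct:
    def test_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"Description": ["gene A", "gene B"], "S1": [1.5, 2.0], "S2": [0.0, 3.25]},
            index=pd.Index(["GA", "GB"], name="Name"),
        )
        path = tmp_path / "x.gct"
        sv.write_gct(df, path)
        text = path.read_text().splitlines()
        assert text[0] == "#1.2" and text[1] == "2\t2"
        back = sv.read_gct(path)
        assert list(back.columns) == ["Description", "S1", "S2"]
        assert back.loc["GB", "S2"] == 3.25

    def test_rejects_other_versions(self, tmp_path):
        p = tmp_path / "bad.gct"
        p.write_text("#1.3\n1\t1\nName\tDescription\tS1\ng\tg\t1\n")
        with pytest.raises(ValueError):
            sv.read_gct(p)
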