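"""LR statistics, thresholds, and genome scans."""

import numpy as np
import pytest
from scipy.stats import chi2

from hollimap.covariance import SADParams, build_sad1_covariance
from hollimap.dynamics import HollingLVParams
from hollimap.likelihood import FitConfig, GenotypeModel, genotype_mean_curves
from hollimap.scan import (
    ThresholdSpec,
    _order_statistic_threshold,
    bonferroni_chisq_threshold,
    lr_statistic,
    pair_labels,
    permutation_threshold,
    scan_one_genome,
    scan_two_genomes,
    subset_test,
)


class TestLRStatistic:
    def test_equal_likelihoods_zero(self):
        assert lr_statistic(-50.0, -50.0) == 0.0

    def test_arithmetic(self):
        assert lr_statistic(-100.0, -90.0) == pytest.approx(20.0)

    def test_negative_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert lr_statistic(-90.0, -91.0) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lr_statistic(np.nan, 0.0)


class TestThresholds:
    def test_chisq_quantile_oracle(self):
        assert bonferroni_chisq_threshold(1, 0.05, 1) == pytest.approx(3.8415, abs=1e-4)
        assert bonferroni_chisq_threshold(1, 1e-6, 18) == pytest.approx(
            chi2.isf(1e-6, 18)
        )
        assert bonferroni_chisq_threshold(10, 0.05, 6) == pytest.approx(
            chi2.isf(0.005, 6)
        )

    def test_alpha_one_gives_zero(self):
        assert bonferroni_chisq_threshold(1, 1.0, 3) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_chisq_threshold(0, 0.05, 1)
        with pytest.raises(ValueError):
            bonferroni_chisq_threshold(1, 0.05, 0)

    def test_order_statistic_is_max_for_hundred_permutations(self):
        vals = np.arange(100, dtype=float)
        assert _order_statistic_threshold(vals, 0.01) == 99.0
        assert _order_statistic_threshold(vals, 0.05) == 95.0

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            _order_statistic_threshold(np.arange(50, dtype=float), 0.01)
        with pytest.raises(ValueError):
            ThresholdSpec(method="permutation", permutations=10)

    def test_permutation_threshold_reproducible(self, strong_dataset, fast_fit):
        spec = ThresholdSpec(method="permutation", alpha=0.05, permutations=20)
        kw = dict(
            genome="A", culture_mode="coculture", spec=spec, config=fast_fit,
            markers=["M0000", "M0001"],
        )
        c1 = permutation_threshold(strong_dataset, seed=9, **kw)
        c2 = permutation_threshold(strong_dataset, seed=9, **kw)
        assert c1 == c2


class TestScans:
    def test_causal_marker_attains_max_lr(self, strong_dataset, fast_fit):
        """With a strong simulated QTL, the causal marker must dominate the
        one-genome co-culture scan."""
        out = scan_one_genome(
            strong_dataset,
            genome="A",
            culture_mode="coculture",
            threshold=ThresholdSpec(method="bonferroni_chisq", alpha=0.01, df=6),
            config=fast_fit,
        )
        lrs = {r.marker[0]: r.lr for r in out.results}
        assert max(lrs, key=lrs.get) == "M0002"

    def test_monoculture_scan_runs_and_localises(self, strong_dataset, fast_fit):
        out = scan_one_genome(
            strong_dataset,
            genome="A",
            culture_mode="monoculture",
            threshold=ThresholdSpec(method="bonferroni_chisq", alpha=0.01, df=2),
            config=fast_fit,
        )
        lrs = {r.marker[0]: r.lr for r in out.results}
        assert max(lrs, key=lrs.get) == "M0002"

    def test_identical_phenotypes_give_zero_lr(self, strong_dataset, times16, fast_fit):
        ds = strong_dataset
        template = ds.Y_coculture()[0]
        clone = type(ds)(
            genotypes_a=ds.genotypes_a,
            genotypes_b=ds.genotypes_b,
            pairing=ds.pairing,
            times=ds.times,
            co_E=np.tile(template[:16], (ds.n_pairs, 1)),
            co_S=np.tile(template[16:], (ds.n_pairs, 1)),
        )
        # constant data is degenerate (rank-1 scatter); allow deep cycling so
        # the shared-curve fit converges fully before comparison
        deep = FitConfig(step=0.1, n_restarts=1, max_cycles=15, tol=1e-4)
        out = scan_one_genome(
            clone, genome="A",
            threshold=ThresholdSpec(method="bonferroni_chisq", alpha=0.01, df=6),
            config=deep,
        )
        # negligible against any scan threshold (~17 at alpha=0.01, df=6)
        assert all(r.lr < 0.5 for r in out.results)

    def test_monomorphic_marker_skipped(self, strong_dataset, fast_fit):
        ds = strong_dataset
        geno = ds.genotypes_a.copy()
        geno["M0001"] = 1  # force monomorphism
        clone = type(ds)(
            genotypes_a=geno, genotypes_b=ds.genotypes_b, pairing=ds.pairing,
            times=ds.times, co_E=ds.co_E, co_S=ds.co_S,
        )
        out = scan_one_genome(
            clone, genome="A",
            threshold=ThresholdSpec(method="bonferroni_chisq", alpha=0.01, df=6),
            config=fast_fit, markers=["M0001", "M0002"],
        )
        assert [m for m, _ in out.skipped] == ["M0001"]
        assert len(out.results) == 1

    def test_two_genome_scan_ranks_causal_pair_first(self, strong_dataset, fast_fit):
        out = scan_two_genomes(
            strong_dataset,
            threshold=ThresholdSpec(method="bonferroni_chisq", alpha=1e-6, df=18),
            config=fast_fit,
            markers_a=["M0001", "M0002"],
            markers_b=["M0003", "M0004"],
        )
        best = max(out.results, key=lambda r: r.lr)
        assert best.marker == ("M0002", "M0003")


def _synthetic_four_combo_dataset(times, thetas, sad, n_per=12, seed=0):
    """Build a co-culture dataset directly from four combination models."""
    import pandas as pd

    from hollimap.dataset import CommunityDataset

    rng = np.random.default_rng(seed)
    labels = np.repeat(["AB", "Ab", "aB", "ab"], n_per)
    model = GenotypeModel(
        thetas=thetas, sad=sad, inits={c: (0.9, 0.9) for c in thetas}
    )
    mus = genotype_mean_curves(model, times, step=0.02)
    sigma = build_sad1_covariance(sad, len(times))
    Y = np.stack([rng.multivariate_normal(mus[l], sigma) for l in labels])
    n = len(labels)
    ga = pd.DataFrame(
        {"M0": (labels == "AB") | (labels == "Ab")},
        index=[f"A{i:04d}" for i in range(n)], dtype=int,
    )
    gb = pd.DataFrame(
        {"M0": (labels == "AB") | (labels == "aB")},
        index=[f"B{i:04d}" for i in range(n)], dtype=int,
    )
    pairing = pd.DataFrame(
        {"pair_id": [f"P{i:04d}" for i in range(n)],
         "strain_a": ga.index, "strain_b": gb.index}
    )
    T = len(times)
    return (
        CommunityDataset(
            genotypes_a=ga, genotypes_b=gb, pairing=pairing, times=times,
            co_E=Y[:, :T], co_S=Y[:, T:],
        ),
        labels,
    )


class TestSubsetTests:
    sad = SADParams(0.4, 0.4, 0.35, 0.35, 0.2)
    base = dict(r_e=0.30, K_e=24.0, alpha_es=-0.10, r_s=0.26, K_s=21.0, alpha_se=-0.15)

    def _run(self, times, thetas, fast_fit):
        ds, labels = _synthetic_four_combo_dataset(times, thetas, self.sad, seed=5)
        crit = ThresholdSpec(method="bonferroni_chisq", alpha=0.01, df=12)
        indep = subset_test(ds, labels, "independent", threshold=crit, config=fast_fit)
        inter = subset_test(ds, labels, "interaction", threshold=crit, config=fast_fit)
        return indep, inter

    def test_alpha_only_difference_flags_interaction(self, times16, fast_fit):
        thetas = {}
        for i, c in enumerate(("AB", "Ab", "aB", "ab")):
            vals = dict(self.base)
            vals["alpha_es"] = -0.10 - 0.25 * i  # strong alpha spread, K shared
            vals["alpha_se"] = -0.15 - 0.25 * i
            thetas[c] = HollingLVParams(**vals)
        indep, inter = self._run(times16, thetas, fast_fit)
        assert inter.significant
        assert inter.lr > indep.lr

    def test_capacity_only_difference_flags_independent(self, times16, fast_fit):
        thetas = {}
        for i, c in enumerate(("AB", "Ab", "aB", "ab")):
            vals = dict(self.base)
            vals["K_e"] = 24.0 + 3.0 * i
            vals["K_s"] = 21.0 + 3.0 * i
            thetas[c] = HollingLVParams(**vals)
        indep, inter = self._run(times16, thetas, fast_fit)
        assert indep.significant
        assert indep.lr > inter.lr

    def test_identical_combinations_give_small_lr(self, times16, fast_fit):
        th = HollingLVParams(**self.base)
        thetas = {c: th for c in ("AB", "Ab", "aB", "ab")}
        ds, labels = _synthetic_four_combo_dataset(times16, thetas, self.sad, seed=6)
        crit = ThresholdSpec(method="bonferroni_chisq", alpha=0.01, df=12)
        indep = subset_test(ds, labels, "independent", threshold=crit, config=fast_fit)
        assert not indep.significant


def test_pair_labels(strong_dataset):
    labels = pair_labels(strong_dataset, "M0002", "M0003")
    assert set(np.unique(labels)) <= {"AB", "Ab", "aB", "ab"}
    assert len(labels) == strong_dataset.n_pairs
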