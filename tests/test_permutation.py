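import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dtmeta.datatypes import BootstrapConfig, PairedRecord, PermutationConfig
from dtmeta.effect_size import compute_effects, rma_ln_slope
from dtmeta.errors import DegenerateModeratorError
from dtmeta.permutation import (
    paired_temp_diet_test,
    permutation_test_moderator,
    permutation_test_overall,
    sex_permute_dataset,
    standardize_slopes,
)
from dtmeta.phylo_meta import MultilevelModel, build_model, phylo_correlation
from dtmeta.synthetic import SimulationConfig, simulate_corpus
from dtmeta.uncertainty import attach_uncertainty

from conftest import make_dataset


class _ForcedRng:
    """Stub rng whose random() returns a fixed value."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


class TestSexPermuteDataset:
    def test_all_swaps_negate_slope_exactly(self, three_treatment_ds):
        s0, _ = rma_ln_slope(three_treatment_ds)
        swapped = sex_permute_dataset(three_treatment_ds, _ForcedRng(0.0))
        s1, _ = rma_ln_slope(swapped)
        assert s1 == -s0

    def test_no_swaps_identity(self, three_treatment_ds):
        out = sex_permute_dataset(three_treatment_ds, _ForcedRng(0.99))
        assert out.records == three_treatment_ds.records

    def test_swap_moves_ses_with_means(self, three_treatment_ds):
        out = sex_permute_dataset(three_treatment_ds, _ForcedRng(0.0))
        for a, b in zip(out.records, three_treatment_ds.records):
            assert a.male_mean_dt == b.female_mean_dt
            assert a.male_se == b.female_se

    def test_uniform_over_2k_patterns(self, rng):
        # k=3 -> 8 equally likely patterns; chi-square GOF over 8000 draws
        ds = make_dataset(female=[10.0, 20.0, 30.0], male=[11.0, 22.0, 33.0])
        counts = {}
        for _ in range(8000):
            out = sex_permute_dataset(ds, rng)
            key = tuple(r.male_mean_dt for r in out.records)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 8
        chi2 = sum((c - 1000) ** 2 / 1000 for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=7)


def _small_corpus(seed=5, mu=0.0, n_species=8):
    cfg = SimulationConfig(n_species=n_species, seed=seed, mu_true=mu,
                           meas_sd=0.004, sigma2_phylo=0.001,
                           sigma2_study=0.001, sigma2_obs=0.002)
    corpus = simulate_corpus(cfg)
    corr = phylo_correlation(corpus.tree)
    return corpus, corr


class TestOverallPermutationTest:
    def test_symmetric_corpus_p_one(self):
        # male == female everywhere: z_obs ~ 0 and a degenerate null at 0
        datasets = [
            make_dataset(female=[30.0, 20.0, 10.0], male=[30.0, 20.0, 10.0],
                         female_se=[0.3, 0.2, 0.1], male_se=[0.3, 0.2, 0.1],
                         dataset_id=f"d{i}", species=f"sp{i}", study_id=f"s{i}")
            for i in range(5)
        ]
        res = permutation_test_overall(
            datasets, None, PermutationConfig(n_perms=99, seed=1),
            BootstrapConfig(n_reps=150, seed=2), recompute_variances=False)
        assert abs(res.z_obs) < 1e-6
        assert res.p_perm == 1.0

    def test_min_p_with_plus_one_correction(self):
        corpus, corr = _small_corpus(mu=0.4)
        res = permutation_test_overall(
            corpus.datasets, corr, PermutationConfig(n_perms=99, seed=3),
            BootstrapConfig(n_reps=150, seed=4), recompute_variances=False)
        assert res.p_perm >= 1 / 100
        assert 0 < res.p_perm <= 1

    def test_seeded_determinism(self):
        corpus, corr = _small_corpus()
        kwargs = dict(boot_cfg=BootstrapConfig(n_reps=150, seed=4),
                      recompute_variances=False)
        a = permutation_test_overall(
            corpus.datasets, corr, PermutationConfig(n_perms=120, seed=7), **kwargs)
        b = permutation_test_overall(
            corpus.datasets, corr, PermutationConfig(n_perms=120, seed=7), **kwargs)
        assert a.p_perm == b.p_perm
        assert np.array_equal(a.null_z, b.null_z)

    def test_null_distribution_symmetric(self):
        corpus, corr = _small_corpus(mu=0.0)
        res = permutation_test_overall(
            corpus.datasets, corr, PermutationConfig(n_perms=400, seed=11),
            BootstrapConfig(n_reps=150, seed=12), recompute_variances=False)
        # antisymmetry of the slope under full swaps -> mean z ~ 0
        assert abs(np.mean(res.null_z)) < 4 * np.std(res.null_z) / math.sqrt(
            res.null_z.size)

    def test_full_mode_agrees_with_fast_mode(self):
        corpus, corr = _small_corpus(mu=0.1)
        full = permutation_test_overall(
            corpus.datasets, corr, PermutationConfig(n_perms=120, seed=13),
            BootstrapConfig(n_reps=120, seed=14), recompute_variances=True)
        fast = permutation_test_overall(
            corpus.datasets, corr, PermutationConfig(n_perms=120, seed=13),
            BootstrapConfig(n_reps=120, seed=14), recompute_variances=False)
        assert full.z_obs == pytest.approx(fast.z_obs, rel=1e-6)
        # same null law, different draws: p within a few MC sd
        assert abs(full.p_perm - fast.p_perm) < 0.25

    def test_mc_p_converges_to_exact_enumeration(self):
        # 3 near-proportional k=3 datasets -> 8^3 = 512 equally likely joint
        # swap patterns, all valid; exact null by full enumeration
        from dataclasses import replace
        specs = [
            ([30.0, 20.0, 10.0], [29.0, 19.6, 9.9]),
            ([25.0, 16.0, 11.0], [25.8, 16.1, 11.3]),
            ([40.0, 22.0, 14.0], [38.5, 21.8, 13.6]),
        ]
        datasets = [
            make_dataset(female=f, male=m,
                         female_se=[0.2] * 3, male_se=[0.2] * 3,
                         dataset_id=f"d{i}", species=f"sp{i}", study_id=f"s{i}")
            for i, (f, m) in enumerate(specs)
        ]
        effects, _ = compute_effects(datasets)
        boot = BootstrapConfig(n_reps=300, seed=21)
        attach_uncertainty(effects, datasets, boot)
        model = build_model(effects, None)
        from dtmeta.phylo_meta import fit_meta
        fit_obs = fit_meta(effects, None)
        v = model.v

        def z_for(y):
            m = MultilevelModel(np.asarray(y, float), v, model.X, model.A, model.S)
            th, _, _ = m.fit(n_restarts=1, warm_start=fit_obs._theta)
            beta, cov = m.gls(np.exp(th))
            return beta[0] / math.sqrt(cov[0, 0])

        per_ds = []
        for ds in datasets:
            vals = []
            for pattern in itertools.product([False, True], repeat=ds.k):
                recs = tuple(r.swapped() if s else r
                             for r, s in zip(ds.records, pattern))
                s_val, _ = rma_ln_slope(replace(ds, records=recs))
                vals.append(s_val)
            per_ds.append(vals)
        z_obs = z_for(model.y)
        exact_null = np.array([abs(z_for(list(combo)))
                               for combo in itertools.product(*per_ds)])
        p_exact = float(np.mean(exact_null >= abs(z_obs) - 1e-9))
        res = permutation_test_overall(
            datasets, None, PermutationConfig(n_perms=400, seed=22),
            boot_cfg=boot, recompute_variances=False)
        mc_se = math.sqrt(p_exact * (1 - p_exact) / 400)
        assert abs(res.p_perm - p_exact) < 4 * mc_se + 0.02


class TestModeratorPermutationTest:
    def test_constant_moderator_refused(self):
        corpus, corr = _small_corpus()
        effects, _ = compute_effects(corpus.datasets)
        attach_uncertainty(effects, corpus.datasets, BootstrapConfig(n_reps=100, seed=1))
        for e in effects:
            e.sdtd = 0.25
        with pytest.raises(DegenerateModeratorError):
            permutation_test_moderator(effects, corr, PermutationConfig(n_perms=99, seed=2))

    def test_recovery_with_strong_moderator(self):
        corpus, corr = _small_corpus(seed=9)
        effects, _ = compute_effects(corpus.datasets)
        attach_uncertainty(effects, corpus.datasets, BootstrapConfig(n_reps=200, seed=3))
        rng = np.random.default_rng(4)
        for e in effects:
            e.sdtd = rng.normal(0.1, 0.2)
            e.ln_slope = 0.5 * e.sdtd + rng.normal(0, 0.01)
        res = permutation_test_moderator(effects, corr,
                                         PermutationConfig(n_perms=199, seed=5))
        assert res.fit_obs.beta_hat == pytest.approx(0.5, abs=0.1)
        assert res.p_perm < 0.05

    def test_determinism(self):
        corpus, corr = _small_corpus(seed=10)
        effects, _ = compute_effects(corpus.datasets)
        attach_uncertainty(effects, corpus.datasets, BootstrapConfig(n_reps=100, seed=6))
        a = permutation_test_moderator(effects, corr, PermutationConfig(n_perms=120, seed=8))
        b = permutation_test_moderator(effects, corr, PermutationConfig(n_perms=120, seed=8))
        assert a.p_perm == b.p_perm


class TestStandardizeSlopes:
    def _effect(self, species, factor, trait, ln_slope, gradient):
        from dtmeta.datatypes import EffectSize
        return EffectSize(
            dataset_id=f"{species}_{factor}_{trait}", study_id="s1",
            species=species, order_name="Diptera", trait=trait, factor=factor,
            k=3, ln_slope=ln_slope, sdtd=0.0, gradient_length=gradient,
        )

    def test_zero_slope_zero_under_all_rules(self):
        effs = [self._effect("sp1", "temperature", "total", 0.0, 3.0),
                self._effect("sp1", "diet", "total", 0.0, 1.3)]
        for rule in ("none", "gradient_scaled"):
            pairs, _ = standardize_slopes(effs, std_rule=rule)
            assert pairs[0].abs_std_slope_temp == 0.0
            assert pairs[0].abs_std_slope_diet == 0.0

    def test_gradient_scaled_value(self):
        effs = [self._effect("sp1", "temperature", "total", 0.1, math.e**2),
                self._effect("sp1", "diet", "total", -0.3, math.e)]
        pairs, _ = standardize_slopes(effs, std_rule="gradient_scaled")
        assert pairs[0].abs_std_slope_temp == pytest.approx(0.2)
        assert pairs[0].abs_std_slope_diet == pytest.approx(0.3)
        assert pairs[0].std_rule == "gradient_scaled"

    def test_trait_mismatch_skipped(self):
        effs = [self._effect("sp1", "temperature", "total", 0.1, 2.0),
                self._effect("sp1", "diet", "larval", 0.2, 1.3)]
        pairs, skipped = standardize_slopes(effs)
        assert not pairs
        assert skipped == [("sp1", "no factor pair on a common trait")]

    def test_total_preferred_and_averaging(self):
        effs = [self._effect("sp1", "temperature", "total", 0.1, 2.0),
                self._effect("sp1", "diet", "total", 0.2, 1.3),
                self._effect("sp1", "temperature", "larval", 0.9, 2.0),
                self._effect("sp1", "diet", "larval", 0.9, 1.3)]
        effs.append(self._effect("sp1", "temperature", "total", 0.3, 2.0))
        effs[-1].dataset_id = "other"
        pairs, _ = standardize_slopes(effs)
        assert pairs[0].trait == "total"
        assert pairs[0].abs_std_slope_temp == pytest.approx(0.2)


class TestPairedTest:
    def _pairs(self, temps, diets):
        return [PairedRecord(species=f"sp{i}", abs_std_slope_temp=t,
                             abs_std_slope_diet=d, trait="total", std_rule="none")
                for i, (t, d) in enumerate(zip(temps, diets))]

    def test_identical_magnitudes_p_one(self):
        pairs = self._pairs([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        res = paired_temp_diet_test(pairs, PermutationConfig(n_perms=200, seed=1))
        assert res.statistic == 0.0
        assert res.p_perm == 1.0

    def test_exact_enumeration_small_n_oracle(self):
        # brute-force oracle over all sign patterns, written independently
        temps = [0.05, 0.02, 0.10, 0.01]
        diets = [0.30, 0.25, 0.05, 0.40]
        pairs = self._pairs(temps, diets)
        diffs = [d - t for t, d in zip(temps, diets)]
        t_obs = sum(diffs) / len(diffs)
        count = 0
        total = 0
        for signs in itertools.product([-1, 1], repeat=len(diffs)):
            t = sum(s * d for s, d in zip(signs, diffs)) / len(diffs)
            total += 1
            if abs(t) >= abs(t_obs) - 1e-15:
                count += 1
        res = paired_temp_diet_test(pairs, exact=True)
        assert res.p_perm == pytest.approx(count / total, abs=1e-12)

    def test_mc_matches_exact_at_n10(self, rng):
        temps = rng.uniform(0.0, 0.2, 10)
        diets = rng.uniform(0.0, 0.5, 10)
        pairs = self._pairs(temps, diets)
        exact = paired_temp_diet_test(pairs, exact=True)
        mc = paired_temp_diet_test(pairs, PermutationConfig(n_perms=4000, seed=2))
        mc_se = math.sqrt(exact.p_perm * (1 - exact.p_perm) / 4000)
        assert abs(mc.p_perm - exact.p_perm) < 4 * mc_se + 1e-3

    def test_exclusions_and_table(self):
        pairs = self._pairs([0.1, 0.5, 0.2], [0.3, 0.1, 0.6])
        res = paired_temp_diet_test(pairs, PermutationConfig(n_perms=200, seed=3),
                                    exclusions=["sp1"])
        assert res.n_excluded == 1
        assert list(res.table["species"]) == ["sp0", "sp2"]
        assert list(res.table["larger_factor"]) == ["diet", "diet"]

    def test_too_few_pairs(self):
        pairs = self._pairs([0.1], [0.3])
        with pytest.raises(ValueError):
            paired_temp_diet_test(pairs)
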