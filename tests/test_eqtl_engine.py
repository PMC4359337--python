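from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from stromaqtl import (
    DataFormatError,
    ExpressionMatrix,
    GenotypeMatrix,
    ModelFit,
    SemConfig,
    call_associations,
    fit_sem,
    prepare_genotypes,
    sem_step,
    standardize,
)
from stromaqtl.eqtl_engine import (
    _init_state,
    inclusion_log_odds,
    standardize_and_prepare,
)

from oracles import gibbs_inclusion_support


def expr_from(arr, prefix="T"):
    arr = np.asarray(arr, float)
    return ExpressionMatrix(values=pd.DataFrame(
        arr, index=[f"S{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    ))


def geno_from(arr):
    arr = np.asarray(arr, float)
    return GenotypeMatrix(dosages=pd.DataFrame(
        arr, index=[f"S{i}" for i in range(arr.shape[0])],
        columns=[f"snp{k}" for k in range(arr.shape[1])],
    ))


class TestStandardize:
    def test_unit_moments(self):
        expr = expr_from(np.array([[1.0], [2.0], [3.0]]))
        out = standardize(expr)
        col = out.values.iloc[:, 0]
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std(ddof=1) == pytest.approx(1.0)

    def test_constant_transcript_dropped_with_warning(self):
        expr = expr_from(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = standardize(expr)
        assert out.transcript_ids == ["T0"]

    def test_idempotent(self, rng):
        expr = expr_from(rng.normal(size=(10, 4)))
        once = standardize(expr)
        twice = standardize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataFormatError, match="3 samples"):
            standardize(expr_from(np.array([[1.0], [2.0]])))


class TestPrepareGenotypes:
    def test_monomorphic_excluded_with_reason(self):
        gm = geno_from(np.array([[0, 1], [0, 2], [0, 0]]))
        prepared, excluded = prepare_genotypes(gm, gm.sample_ids)
        assert excluded == [("snp0", "monomorphic")]
        assert prepared.snp_ids == ["snp1"]

    def test_missing_imputed_to_mean(self):
        arr = np.array([[0.0], [2.0], [np.nan]])
        gm = geno_from(arr)
        prepared, excluded = prepare_genotypes(gm, gm.sample_ids)
        assert prepared.dosages.iloc[2, 0] == pytest.approx(1.0)
        assert excluded == []

    def test_clean_input_unchanged(self):
        gm = geno_from(np.array([[0, 1], [1, 2], [2, 0]]))
        prepared, excluded = prepare_genotypes(gm, gm.sample_ids)
        assert excluded == []
        np.testing.assert_array_equal(prepared.dosages.to_numpy(),
                                      gm.dosages.to_numpy())

    def test_maf_threshold(self):
        # one copy of the minor allele among 10 samples: maf 0.05
        col = np.zeros((10, 1)); col[0, 0] = 1
        gm = geno_from(col)
        _, excluded = prepare_genotypes(gm, gm.sample_ids, maf_min=0.1)
        assert "below threshold" in excluded[0][1]

    def test_empty_subset_rejected(self):
        gm = geno_from(np.array([[0], [1]]))
        with pytest.raises(DataFormatError, match="empty"):
            prepare_genotypes(gm, [])


class TestSemConfig:
    @pytest.mark.parametrize("kwargs", [
        {"burn_in": 3000, "n_iterations": 3000},
        {"support_threshold": 1.0},
        {"pi_bounds": (0.0, 0.5)},
        {"slab_var_floor": 0.0},
        {"var_estimator": "other"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SemConfig(**kwargs)

    def test_default_pi_bounds_resolve_from_j(self):
        assert SemConfig().resolved_pi_bounds(500) == (1 / 1000, 0.5)


class TestSemStep:
    def test_strong_signal_inclusion_near_certain(self):
        # one transcript, one SNP, noise-free y = z: slab dominates spike
        rng = np.random.default_rng(0)
        z = rng.binomial(2, 0.4, size=30).astype(float)
        zc = z - z.mean()
        s = zc @ zc
        lo = inclusion_log_odds(np.array([1.0]), np.array([1e-4 / s]),
                                slab_var=1.0, pi=0.01)
        p = 1 / (1 + np.exp(-lo))
        assert p[0] > 0.999

    def test_null_inclusion_rate_matches_pi(self, rng):
        # pure noise with a slab close to the effect-estimate noise floor:
        # the Bayes factor is near 1, so the expected fraction of slab draws
        # per sweep equals the prior proportion pi (a wide slab saturates the
        # posterior for lucky transcripts and the rate falls below pi)
        n, J = 30, 80
        z = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        config = SemConfig(seed=0)
        rates = []
        for rep in range(300):
            Y = rng.normal(size=(n, J))
            state = _init_state(J, 1, Y, config, rng)
            state.eta[:] = False
            state.pi[:] = 0.05
            state.slab_var[:] = 0.05
            new = sem_step(state, Y, z, config, rng)
            rates.append(new.eta.mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.01)

    def test_all_zero_eta_mstep_is_intercept_only(self, rng):
        n, J = 20, 5
        Y = rng.normal(size=(n, J)) + 3.0
        z = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        config = SemConfig(seed=0, init_pi=1e-9, pi_bounds=(1e-12, 0.5))
        state = _init_state(J, 1, Y, config, rng)
        state.eta[:] = False
        state.slab_var[:] = 1e-12  # slab collapses onto the spike
        new = sem_step(state, Y, z, config, rng_zero())
        np.testing.assert_allclose(new.beta, Y.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(new.resid_var, Y.var(axis=0), atol=1e-9)

    def test_spike_exactness_invariant(self, small_study, short_sem_config):
        cfg = short_sem_config
        se, sg, _ = standardize_and_prepare(
            small_study.expression, small_study.genotypes,
            small_study.expression.sample_ids, cfg,
        )
        Y = se.values.to_numpy()
        Z = sg.dosages.to_numpy()
        rng = np.random.default_rng(3)
        state = _init_state(Y.shape[1], Z.shape[1], Y, cfg, rng)
        for _ in range(5):
            state = sem_step(state, Y, Z, cfg, rng)
            inactive = ~state.eta
            assert np.all(state.gamma[inactive] == 0.0)
            assert np.all(state.gamma[state.eta] != 0.0)

    def test_dimension_mismatch_rejected(self, rng):
        Y = rng.normal(size=(10, 3))
        z = rng.binomial(2, 0.4, size=(10, 1)).astype(float)
        config = SemConfig()
        state = _init_state(5, 1, rng.normal(size=(10, 5)), config, rng)
        with pytest.raises(DataFormatError, match="dimensions"):
            sem_step(state, Y, z, config, rng)


def rng_zero():
    """RNG stand-in whose uniforms are ~1, so no indicator is ever drawn active."""

    class NeverInclude:
        def random(self, size=None):
            return np.ones(size) * (1 - 1e-12) if size else 1 - 1e-12

    return NeverInclude()


class TestFitSem:
    def test_planted_pairs_supported_and_nulls_not(self, small_study,
                                                   short_sem_config):
        se, sg, ex = standardize_and_prepare(
            small_study.expression, small_study.genotypes,
            small_study.expression.sample_ids, short_sem_config,
        )
        fit = fit_sem(se, sg, short_sem_config, excluded_snps=ex)
        for snp, transcript in small_study.truth_pairs:
            assert fit.support.loc[transcript, snp] > 0.8
        called = {c.pair for c in call_associations(fit)}
        assert len(called - small_study.truth_pairs) <= 1

    def test_deterministic_given_seed(self, small_study, short_sem_config):
        se, sg, _ = standardize_and_prepare(
            small_study.expression, small_study.genotypes,
            small_study.expression.sample_ids, short_sem_config,
        )
        a = fit_sem(se, sg, short_sem_config)
        b = fit_sem(se, sg, short_sem_config)
        pd.testing.assert_frame_equal(a.support, b.support)

    def test_seed_changes_null_support(self, rng, short_sem_config):
        Y = rng.normal(size=(25, 40))
        Z = rng.binomial(2, 0.4, size=(25, 4)).astype(float)
        expr, geno = expr_from(Y), geno_from(Z)
        a = fit_sem(expr, geno, short_sem_config)
        b = fit_sem(expr, geno, replace(short_sem_config, seed=99))
        assert not a.support.equals(b.support)

    def test_sample_mismatch_rejected(self, rng, short_sem_config):
        expr = expr_from(rng.normal(size=(10, 3)))
        geno = geno_from(rng.binomial(2, 0.3, size=(8, 2)))
        with pytest.raises(DataFormatError, match="sample sets differ"):
            fit_sem(expr, geno, short_sem_config)


class TestCallAssociations:
    def _fit(self, supports):
        df = pd.DataFrame(supports, index=[f"T{j}" for j in range(len(supports))],
                          columns=["snp0"])
        return ModelFit(support=df, config=SemConfig(), n_post_burnin=2000)

    def test_strict_threshold(self):
        fit = self._fit([[0.81], [0.80], [0.79]])
        called = call_associations(fit)
        assert [(c.transcript_id, c.support) for c in called] == [("T0", 0.81)]

    def test_empty_support(self):
        fit = ModelFit(support=pd.DataFrame(), config=SemConfig(), n_post_burnin=1)
        assert call_associations(fit) == []

    def test_full_support_calls_everything(self):
        fit = self._fit([[1.0], [1.0]])
        assert len(call_associations(fit)) == 2

    def test_stratum_label_propagates(self):
        fit = self._fit([[0.9]])
        assert call_associations(fit, ">70%")[0].stratum_label == ">70%"


class TestSmallInstanceAgainstGibbs:
    def test_sem_and_gibbs_agree_on_calls(self):
        # 3 transcripts, 1 SNP: one strong effect, two nulls
        rng = np.random.default_rng(5)
        z = rng.binomial(2, 0.4, size=12).astype(float)
        Y = rng.normal(size=(12, 3))
        Y[:, 0] += 2.5 * (z - z.mean()) / z.std()
        expr = standardize(expr_from(Y))
        geno = geno_from(z[:, None])
        config = SemConfig(n_iterations=3000, burn_in=1000, seed=2)
        fit = fit_sem(expr, geno, config)
        sem_calls = {c.transcript_id for c in call_associations(fit)}

        support = gibbs_inclusion_support(
            expr.values.to_numpy(), z, pi=float(fit.diagnostics["mean_pi"].iloc[0]),
            slab_var=float(fit.diagnostics["mean_slab_var"].iloc[0]),
            resid_var=fit.diagnostics["mean_resid_var"].to_numpy(),
            n_iter=20000, seed=3,
        )
        gibbs_calls = {expr.transcript_ids[j] for j in np.nonzero(support > 0.8)[0]}
        assert sem_calls == gibbs_calls == {"T0"}
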