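import math

import numpy as np
import pandas as pd
import pytest
from importlib import resources

from loopscape.alphabet import AA20
from loopscape.design_fit import (
    InputMatrixSet,
    StabilityMatrix,
    convergence_driver,
    effective_weights,
    fit_weights,
    homolog_frequency_matrix,
    model_matrix,
    mutational_tolerance,
    stability_to_frequency,
    zscore_vs_unbiased,
)
from loopscape.repertoire_core import FrequencyMatrix


def random_fm(sites, rng):
    freqs = rng.dirichlet(np.ones(20), size=len(sites))
    df = pd.DataFrame(freqs, index=sites, columns=list(AA20))
    return FrequencyMatrix(freqs=df, weight=pd.Series(1.0, index=sites))


def make_inputs(sites, rng, k=3):
    labels = ["complementarity", "stability", "homolog"][:k]
    return InputMatrixSet(
        matrices={lab: random_fm(sites, rng) for lab in labels}
    )


def forward_objective(inputs, eps, alpha, beta):
    sites = inputs.sites
    out = np.zeros((len(sites), 20))
    e = eps.loc[sites].values[:, None]
    for a, b, lab in zip(alpha, beta, inputs.labels):
        out += (a + b * e) * inputs.matrices[lab].freqs.values
    df = pd.DataFrame(out, index=sites, columns=list(AA20))
    return FrequencyMatrix(
        freqs=df, weight=pd.Series(1.0, index=sites)
    )


SITES = [f"S{i}" for i in range(25)]


class TestHomologFrequencyMatrix:
    def test_sqrt_replicate_weighting_hand_case(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a1\nAS\n" + "".join(f">r{i}\nYS\n" for i in range(9)))
        fm = homolog_frequency_matrix(p, {0: "X1", 1: "X2"})
        # weights: sqrt(9)=3 for YS, 1 for AS -> Y:0.75, A:0.25
        assert fm.freqs.loc["X1", "Y"] == pytest.approx(0.75)
        assert fm.freqs.loc["X1", "A"] == pytest.approx(0.25)
        assert fm.freqs.loc["X2", "S"] == pytest.approx(1.0)

    def test_all_unique_is_plain_counting(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nAA\n>b\nAC\n>c\nAD\n>d\nAE\n")
        fm = homolog_frequency_matrix(p, {1: "X1"})
        assert fm.freqs.loc["X1", "C"] == pytest.approx(0.25)

    def test_gaps_excluded(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nA-\n>b\nAC\n")
        fm = homolog_frequency_matrix(p, {0: "X1", 1: "X2"})
        assert fm.freqs.loc["X2", "C"] == pytest.approx(1.0)

    def test_packaged_fixture_matches_brute_force(self):
        path = resources.files("loopscape.data") / "homolog_fixture.fasta"
        mapping = {i: f"H{i}" for i in range(25)}
        fm = homolog_frequency_matrix(str(path), mapping)
        # brute-force oracle: collapse replicates, sqrt weights, count
        from Bio import SeqIO

        occ = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            occ[str(rec.seq)] = occ.get(str(rec.seq), 0) + 1
        for col in (0, 7, 24):
            weights = {}
            for seq, n in occ.items():
                aa = seq[col]
                if aa == "-":
                    continue
                weights[aa] = weights.get(aa, 0.0) + math.sqrt(n)
            total = sum(weights.values())
            for aa, w in weights.items():
                assert fm.freqs.loc[f"H{col}", aa] == pytest.approx(w / total)


class TestStabilityToFrequency:
    def make_sm(self, rows):
        df = pd.DataFrame(rows, columns=list(AA20))
        df.index = [f"S{i}" for i in range(len(rows))]
        return StabilityMatrix(ddg=df)

    def test_flat_row_uniform(self):
        sm = self.make_sm([[1.0] * 20])
        fm = stability_to_frequency(sm)
        assert np.allclose(fm.freqs.values, 0.05)

    def test_one_stabilized_residue_closed_form(self):
        row = [2.0] * 20
        row[0] = 0.0  # alanine 2 kcal/mol lower
        fm = stability_to_frequency(self.make_sm([row]), rt=0.59)
        x = math.exp(2.0 / 0.59)
        assert fm.freqs.loc["S0", "A"] == pytest.approx(x / (x + 19))

    def test_infinite_temperature_limit(self):
        rng = np.random.default_rng(16)
        sm = self.make_sm([list(rng.normal(0, 1, 20))])
        fm = stability_to_frequency(sm, rt=1e9)
        assert np.allclose(fm.freqs.values, 0.05, atol=1e-6)

    def test_rt_must_be_positive(self):
        with pytest.raises(ValueError):
            stability_to_frequency(self.make_sm([[0.0] * 20]), rt=0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            self.make_sm([[np.inf] + [0.0] * 19])


class TestMutationalTolerance:
    def test_all_zero_counts_twenty(self):
        df = pd.DataFrame([[0.0] * 20], columns=list(AA20), index=["S0"])
        assert mutational_tolerance(StabilityMatrix(ddg=df))["S0"] == 20

    def test_counting(self):
        row = [10.0] * 20
        for i in range(5):
            row[i] = 0.5
        df = pd.DataFrame([row], columns=list(AA20), index=["S0"])
        assert mutational_tolerance(StabilityMatrix(ddg=df))["S0"] == 5


class TestConvergenceDriver:
    def test_constant_oracle_converges_immediately(self):
        mean, n = convergence_driver(
            lambda s, r, rng: 1.25, "S0", "A", seed=0
        )
        assert mean == pytest.approx(1.25)
        assert n == 51  # min_n + 1

    def test_noisy_oracle_recovers_truth(self):
        truth = -0.8
        for seed in range(20):
            mean, n = convergence_driver(
                lambda s, r, rng: truth + rng.normal(0, 0.05),
                "S0", "A", seed=seed,
            )
            assert abs(mean - truth) < 0.1
            assert n > 50

    def test_diverging_oracle_raises(self):
        state = {"i": 0}

        def drift(s, r, rng):
            state["i"] += 1
            return state["i"] * 1.0

        with pytest.raises(RuntimeError, match="no convergence"):
            convergence_driver(drift, "S0", "A", seed=1, max_n=500)

    def test_non_finite_oracle_rejected(self):
        with pytest.raises(ValueError):
            convergence_driver(
                lambda s, r, rng: float("nan"), "S0", "A", seed=2
            )


class TestFitWeights:
    def test_planted_weight_recovery(self):
        rng = np.random.default_rng(17)
        inputs = make_inputs(SITES, rng)
        eps = pd.Series(rng.uniform(0, 1, len(SITES)), index=SITES)
        alpha = np.array([0.62, 0.30, 0.08])
        beta = np.array([0.10, -0.04, -0.06])
        obj = forward_objective(inputs, eps, alpha, beta)
        fit = fit_weights(obj, inputs, eps)
        assert np.allclose(fit.alpha, alpha, atol=1e-6)
        assert np.allclose(fit.beta, beta, atol=1e-6)
        assert fit.residual < 1e-12

    def test_recovery_many_random_instances(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            inputs = make_inputs(SITES, rng)
            eps = pd.Series(rng.uniform(0, 1, len(SITES)), index=SITES)
            # keep effective weights positive so the forward-constructed
            # objective stays a valid frequency matrix
            alpha = rng.dirichlet(np.full(3, 5.0))
            beta = rng.normal(0, 0.03, 3)
            beta -= beta.mean()
            obj = forward_objective(inputs, eps, alpha, beta)
            fit = fit_weights(obj, inputs, eps)
            assert np.allclose(fit.alpha, alpha, atol=1e-6)
            assert np.allclose(fit.beta, beta, atol=1e-6)

    def test_constraints_satisfied_on_noisy_fits(self):
        rng = np.random.default_rng(19)
        inputs = make_inputs(SITES, rng)
        eps = pd.Series(rng.uniform(0, 1, len(SITES)), index=SITES)
        obj = random_fm(SITES, rng)
        fit = fit_weights(obj, inputs, eps)
        assert fit.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert fit.beta.sum() == pytest.approx(0.0, abs=1e-9)

    def test_identical_inputs_rejected(self):
        rng = np.random.default_rng(20)
        fm = random_fm(SITES, rng)
        inputs = InputMatrixSet(matrices={"a": fm, "b": fm})
        eps = pd.Series(0.5, index=SITES)
        with pytest.raises(ValueError, match="non-identifiable"):
            fit_weights(random_fm(SITES, rng), inputs, eps)

    def test_single_input_forced_weights(self):
        rng = np.random.default_rng(21)
        fm = random_fm(SITES, rng)
        inputs = InputMatrixSet(matrices={"only": fm})
        eps = pd.Series(0.5, index=SITES)
        fit = fit_weights(fm, inputs, eps)
        assert fit.alpha[0] == 1.0 and fit.beta[0] == 0.0
        assert fit.residual == pytest.approx(0.0, abs=1e-12)

    def test_exposure_out_of_bounds_rejected(self):
        rng = np.random.default_rng(22)
        inputs = make_inputs(SITES, rng)
        eps = pd.Series(1.5, index=SITES)
        with pytest.raises(ValueError):
            fit_weights(random_fm(SITES, rng), inputs, eps)

    def test_residual_invariant_to_site_permutation(self):
        rng = np.random.default_rng(23)
        inputs = make_inputs(SITES, rng)
        eps = pd.Series(rng.uniform(0, 1, len(SITES)), index=SITES)
        obj = random_fm(SITES, rng)
        fit1 = fit_weights(obj, inputs, eps)
        perm = list(rng.permutation(SITES))

        def permuted(fm):
            return FrequencyMatrix(
                freqs=fm.freqs.loc[perm], weight=fm.weight.loc[perm]
            )

        inputs_p = InputMatrixSet(
            matrices={k: permuted(v) for k, v in inputs.matrices.items()}
        )
        fit2 = fit_weights(permuted(obj), inputs_p, eps.loc[perm])
        assert fit2.residual == pytest.approx(fit1.residual)
        assert np.allclose(fit1.alpha, fit2.alpha)


class TestEffectiveWeights:
    @pytest.fixture
    def fit(self):
        rng = np.random.default_rng(24)
        inputs = make_inputs(SITES, rng)
        eps = pd.Series(rng.uniform(0, 1, len(SITES)), index=SITES)
        obj = forward_objective(
            inputs, eps, np.array([0.5, 0.3, 0.2]),
            np.array([0.2, -0.1, -0.1]),
        )
        return fit_weights(obj, inputs, eps)

    def test_epsilon_zero_gives_alpha(self, fit):
        ew = effective_weights(fit, 0.0)
        assert list(ew.values()) == pytest.approx(list(fit.alpha))

    def test_sum_is_one_at_any_epsilon(self, fit):
        for e in (0.0, 0.3, 0.7, 1.0):
            assert sum(effective_weights(fit, e).values()) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_linear_in_epsilon_with_slope_beta(self, fit):
        ew0 = effective_weights(fit, 0.2)
        ew1 = effective_weights(fit, 0.7)
        for lab, b in zip(fit.labels, fit.beta):
            assert (ew1[lab] - ew0[lab]) / 0.5 == pytest.approx(b)


class TestZScore:
    def test_null_uniform_inputs_near_zero(self):
        rng = np.random.default_rng(25)
        sites = SITES
        df = pd.DataFrame(0.05, index=sites, columns=list(AA20))
        uni = FrequencyMatrix(freqs=df, weight=pd.Series(1.0, index=sites))
        inputs = InputMatrixSet(
            matrices={"a": uni, "b": random_fm(sites, rng)}
        )
        # objective equals uniform: model and control coincide at optimum
        eps = pd.Series(rng.uniform(0, 1, len(sites)), index=sites)
        obj = uni
        fit = fit_weights(obj, inputs, eps)
        z = zscore_vs_unbiased(fit, obj, inputs, eps, seed=0)
        assert abs(z) < 0.5

    def test_planted_objective_large_z(self):
        rng = np.random.default_rng(26)
        for seed in range(5):
            inputs = make_inputs(SITES, rng)
            eps = pd.Series(rng.uniform(0, 1, len(SITES)), index=SITES)
            obj = forward_objective(
                inputs, eps, np.array([0.6, 0.3, 0.1]),
                np.array([0.05, -0.02, -0.03]),
            )
            fit = fit_weights(obj, inputs, eps)
            z = zscore_vs_unbiased(fit, obj, inputs, eps, seed=seed)
            assert z > 5

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(27)
        inputs = make_inputs(SITES, rng)
        eps = pd.Series(rng.uniform(0, 1, len(SITES)), index=SITES)
        obj = random_fm(SITES, rng)
        fit = fit_weights(obj, inputs, eps)
        z1 = zscore_vs_unbiased(fit, obj, inputs, eps, seed=7)
        z2 = zscore_vs_unbiased(fit, obj, inputs, eps, seed=7)
        assert z1 == z2

    def test_too_few_sites_rejected(self):
        rng = np.random.default_rng(28)
        sites = ["S0", "S1", "S2"]
        inputs = make_inputs(sites, rng)
        eps = pd.Series([0.1, 0.5, 0.9], index=sites)
        obj = random_fm(sites, rng)
        fit = fit_weights(obj, inputs, eps)
        with pytest.raises(ValueError):
            zscore_vs_unbiased(fit, obj, inputs, eps, seed=0)
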