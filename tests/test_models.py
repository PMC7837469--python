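"""Family likelihoods, the model hierarchy, and the selection tests."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from gsca.likelihood import compute_U, genotype_pairs
from gsca.models import (
    MODELS_2013,
    MODELS_2014,
    Family,
    FitResult,
    ModelSpec,
    SnpFamilyData,
    change_test,
    family_loglik,
    fit_model,
    fit_year,
    lrt,
    maternal_prior,
    offspring_coefficients,
    offspring_lik_selfed,
    reweight_frequencies,
    run_tests,
    selfing_rate,
)
from gsca.panel import HaplotypePanel
from gsca.simulate import SimulationConfig, simulate_panel, simulate_year

from conftest import random_panel


def brute_force_family_loglik(family, params, tables, panel, snp_index):
    """Independent oracle: exhaustive genotype enumeration with explicit sums.

    Evaluates the family probability directly — Hardy-Weinberg maternal
    prior under the reweighted haplotype frequencies, the mother's U, and
    per-offspring sums over every possible sire haplotype — with no shared
    code with the implementation.
    """
    K = panel.K
    Q, delta, p = panel.Q, panel.delta(snp_index), panel.p_panel(snp_index)
    p_mother = params["p_A"] if family.cohort == "A" else params["p_L"]
    p_M = params.get("p_M", p)
    Qm = [
        Q[k] * p_mother / p if delta[k] else Q[k] * (1 - p_mother) / (1 - p)
        for k in range(K)
    ]
    Qsire = [
        Q[k] * p_M / p if delta[k] else Q[k] * (1 - p_M) / (1 - p) for k in range(K)
    ]
    total = 0.0
    for i in range(K):
        for j in range(i, K):
            prior = Qm[i] ** 2 if i == j else 2 * Qm[i] * Qm[j]
            mt = tables.get(family.maternal_plant)
            Um = math.exp(mt.effective_loglik()[i, j]) if mt is not None else 1.0
            term = prior * Um
            for pid, cross in family.offspring:
                ot = tables.get(pid)
                Uo = (
                    np.exp(ot.effective_loglik())
                    if ot is not None
                    else np.ones((K, K))
                )
                if cross == "S":
                    v = 0.25 * Uo[i, i] + 0.5 * Uo[i, j] + 0.25 * Uo[j, j]
                else:
                    v = sum(
                        Qsire[k] * 0.5 * (Uo[i, k] + Uo[j, k]) for k in range(K)
                    )
                term *= v
            total += term
    return math.log(total)


def random_family_instance(rng, K=3, m=4, n_off=2, cohort="A"):
    panel = random_panel(rng, K=K, m=m)
    fam_off = []
    tables = {}

    def make_table(pid, n_reads):
        from gsca.likelihood import ReadPairObservation

        reads = []
        for r in range(n_reads):
            s = int(rng.integers(1, m + 1))
            idx = rng.choice(m, size=s, replace=False)
            reads.append(
                ReadPairObservation(pid, panel.set_id, f"{pid}_r{r}", idx, rng.integers(0, 2, s))
            )
        tables[pid] = compute_U(reads, panel, 0.005, plant_id=pid)

    make_table("mom", int(rng.integers(0, 4)))
    if cohort == "A":
        for z in range(n_off):
            cross = "S" if rng.random() < 0.3 else "O"
            fam_off.append((f"off{z}", cross))
            make_table(f"off{z}", int(rng.integers(0, 4)))
    fam = Family("f1", 2013, "mom", cohort, fam_off)
    return fam, tables, panel


class TestReweighting:
    def test_direct_example(self):
        Q = np.array([0.5, 0.3, 0.2])
        delta = np.array([1, 1, 0])
        Qs = reweight_frequencies(Q, delta, 0.8, 0.6)
        np.testing.assert_allclose(Qs, [0.375, 0.225, 0.4])
        assert math.isclose(Qs.sum(), 1.0)

    def test_identity_when_pstar_equals_p(self):
        Q = np.array([0.5, 0.3, 0.2])
        delta = np.array([1, 1, 0])
        np.testing.assert_allclose(reweight_frequencies(Q, delta, 0.8, 0.8), Q)

    def test_boundary_all_mass_on_ref_class(self):
        Q = np.array([0.5, 0.3, 0.2])
        delta = np.array([1, 1, 0])
        Qs = reweight_frequencies(Q, delta, 0.8, 1.0)
        assert math.isclose(Qs[:2].sum(), 1.0)
        assert Qs[2] == 0.0

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError):
            reweight_frequencies(np.array([0.5, 0.5]), np.array([1, 1]), 1.0, 0.5)

    def test_normalization_preserved(self, rng):
        for _ in range(20):
            K = int(rng.integers(2, 8))
            q = rng.random(K) + 0.1
            q /= q.sum()
            delta = np.zeros(K, dtype=int)
            delta[rng.choice(K, size=int(rng.integers(1, K)), replace=False)] = 1
            p = float(delta @ q)
            ps = float(rng.random())
            np.testing.assert_allclose(
                reweight_frequencies(q, delta, p, ps).sum(), 1.0, atol=1e-12
            )


class TestMaternalPrior:
    def test_het_and_hom_values(self):
        Qs = np.array([0.6, 0.4])
        assert math.isclose(maternal_prior(0, 1, Qs), 0.48)
        assert math.isclose(maternal_prior(0, 0, Qs), 0.36)

    def test_sums_to_one(self):
        Qs = np.array([0.6, 0.4])
        total = sum(maternal_prior(i, j, Qs) for i in range(2) for j in range(i, 2))
        assert math.isclose(total, 1.0)


class TestOffspringTerms:
    def test_selfed_values(self):
        U = np.zeros((2, 2))
        U[0, 0] = 1.0
        assert math.isclose(offspring_lik_selfed(U, 0, 1), 0.25)
        U2 = np.full((2, 2), 0.7)
        assert math.isclose(offspring_lik_selfed(U2, 0, 1), 0.7)
        U3 = np.array([[0.3, 0.9], [0.9, 0.1]])
        assert math.isclose(offspring_lik_selfed(U3, 1, 1), 0.1)

    def test_coefficient_endpoints_and_flat(self, rng):
        panel = random_panel(rng, K=3, m=4)
        Q, delta, p = panel.Q, panel.delta(0), panel.p_panel(0)
        U = np.full((3, 3), 0.42)
        t1, t2 = offspring_coefficients(U, 0, 1, Q, delta, p)
        assert math.isclose(t1, 0.42) and math.isclose(t2, 0.42)

    def test_factorization_matches_direct_sum(self, rng):
        """V = p_M T1 + (1-p_M) T2 equals the explicit sire-haplotype sum."""
        for _ in range(30):
            panel = random_panel(rng, K=int(rng.integers(2, 5)), m=4)
            K = panel.K
            Q, delta, p = panel.Q, panel.delta(0), panel.p_panel(0)
            U = rng.random((K, K))
            U = (U + U.T) / 2
            i, j = sorted(rng.integers(0, K, 2))
            t1, t2 = offspring_coefficients(U, i, j, Q, delta, p)
            for p_M in np.linspace(0.0, 1.0, 11):
                Qs = reweight_frequencies(Q, delta, p, p_M)
                direct = sum(Qs[k] * 0.5 * (U[i, k] + U[j, k]) for k in range(K))
                assert math.isclose(p_M * t1 + (1 - p_M) * t2, direct, abs_tol=1e-12)


class TestFamilyLoglik:
    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(15):
            fam, tables, panel = random_family_instance(
                rng, K=int(rng.integers(2, 4)), n_off=int(rng.integers(0, 3))
            )
            params = {
                "p_A": float(rng.uniform(0.1, 0.9)),
                "p_M": float(rng.uniform(0.1, 0.9)),
                "p_L": float(rng.uniform(0.1, 0.9)),
            }
            got = family_loglik(fam, params, tables, panel, 0)
            want = brute_force_family_loglik(fam, params, tables, panel, 0)
            assert math.isclose(got, want, abs_tol=1e-9)

    def test_smallest_case_exhaustive(self, rng):
        """K=2 panel, mother with one read, one outcrossed offspring with one read."""
        panel = HaplotypePanel(
            "gs", np.array([[0, 1], [1, 0]], dtype=np.int8), np.array([0.5, 0.5])
        )
        from gsca.likelihood import ReadPairObservation

        tables = {
            "mom": compute_U(
                [ReadPairObservation("mom", "gs", "r1", np.array([0]), np.array([0]))],
                panel, 0.005,
            ),
            "kid": compute_U(
                [ReadPairObservation("kid", "gs", "r1", np.array([1]), np.array([0]))],
                panel, 0.005,
            ),
        }
        fam = Family("f", 2013, "mom", "A", [("kid", "O")])
        params = {"p_A": 0.3, "p_M": 0.7}
        got = family_loglik(fam, params, tables, panel, 0)
        want = brute_force_family_loglik(fam, params, tables, panel, 0)
        assert math.isclose(got, want, abs_tol=1e-12)

    def test_flat_family_independent_of_params(self, rng):
        panel = random_panel(rng, K=3, m=4)
        fam = Family("f", 2013, "mom", "A", [("kid", "O")])
        a = family_loglik(fam, {"p_A": 0.2, "p_M": 0.9}, {}, panel, 0)
        b = family_loglik(fam, {"p_A": 0.7, "p_M": 0.1}, {}, panel, 0)
        assert math.isclose(a, b, abs_tol=1e-12)
        assert math.isclose(a, 0.0, abs_tol=1e-12)  # priors sum to 1

    def test_doubling_family_doubles_contribution(self, rng):
        fam, tables, panel = random_family_instance(rng)
        params = {"p_A": 0.4, "p_M": 0.6}
        single = family_loglik(fam, params, tables, panel, 0)
        data1 = SnpFamilyData([fam], tables, panel, 0)
        data2 = SnpFamilyData([fam, fam], tables, panel, 0)
        assert math.isclose(data1.loglik(0.4, 0.6), single, abs_tol=1e-9)
        assert math.isclose(data2.loglik(0.4, 0.6), 2 * single, abs_tol=1e-9)

    def test_haplotype_relabeling_invariance(self, rng):
        seed = int(rng.integers(2**31))
        cfg = SimulationConfig(seed=seed, n_families=20, K=4, n_snps_per_gene=5)
        r = np.random.default_rng(seed)
        panel = simulate_panel(cfg, r)
        y = simulate_year(cfg, panel, r, 2013)
        d = y.snp_data()
        base = d.loglik(0.35, 0.55)

        perm = np.array([2, 0, 3, 1])
        panel2 = HaplotypePanel(panel.set_id, panel.alleles[perm], panel.Q[perm])
        y2 = y
        logU = y.stacked_loglik(0.005)
        d2 = SnpFamilyData.from_stacked(
            logU[:, perm][:, :, perm],
            y2.mother_idx, y2.is_A, y2.off_plant, y2.off_selfed,
            panel2.Q, panel2.delta(y.focal_snp),
        )
        assert math.isclose(d2.loglik(0.35, 0.55), base, abs_tol=1e-8)


class TestFitAndTests:
    def test_h0_mle_matches_allele_count(self):
        """Unambiguous genotypes: p-hat is the empirical allele frequency."""
        panel = HaplotypePanel(
            "gs", np.array([[0, 1], [1, 0]], dtype=np.int8), np.array([0.5, 0.5])
        )
        from gsca.likelihood import ReadPairObservation

        def hard_table(pid, hap_i, hap_j):
            reads = []
            for r in range(15):
                hap = hap_i if r % 2 == 0 else hap_j
                reads.append(
                    ReadPairObservation(
                        pid, "gs", f"{pid}_r{r}", np.array([0, 1]), panel.alleles[hap]
                    )
                )
            return compute_U(reads, panel, 0.005, plant_id=pid)

        # 4 mothers: genotypes (0,0), (0,0), (1,1), (0,0); one outcrossed kid each
        # with known sire haplotype (mother homozygous -> transmission determined)
        tables = {}
        fams = []
        mother_haps = [(0, 0), (0, 0), (1, 1), (0, 0)]
        sire_haps = [0, 1, 1, 0]
        for n, ((hi, hj), s) in enumerate(zip(mother_haps, sire_haps)):
            tables[f"m{n}"] = hard_table(f"m{n}", hi, hj)
            tables[f"k{n}"] = hard_table(f"k{n}", hi, s)
            fams.append(Family(f"f{n}", 2013, f"m{n}", "A", [(f"k{n}", "O")]))
        data = SnpFamilyData(fams, tables, panel, 0)
        fit = fit_model(data, MODELS_2013["H0"])
        # ref-base (haplotype 0) draws: 6 of 8 maternal alleles + 2 of 4 sire alleles
        assert abs(fit.estimates["p"] - 8 / 12) < 1e-3

    def test_fixed_spec_returns_lnL_only(self, rng):
        fam, tables, panel = random_family_instance(rng)
        data = SnpFamilyData([fam], tables, panel, 0)
        spec = ModelSpec("fixed", (), {"A": 0.4, "M": 0.6, "L": 0.4})
        res = fit_model(data, spec)
        assert res.n_free == 0
        assert math.isclose(res.lnL, data.loglik(0.4, 0.6, 0.4), abs_tol=1e-12)

    def test_nesting_on_simulated_2014_data(self):
        for seed in (3, 17):
            cfg = SimulationConfig(seed=seed, n_families=40)
            r = np.random.default_rng(seed)
            panel = simulate_panel(cfg, r)
            y = simulate_year(cfg, panel, r, 2014, include_failed=True)
            fits = fit_year(y.snp_data(), 2014)
            assert fits["H3"].lnL >= fits["H1"].lnL - 1e-6
            assert fits["H3"].lnL >= fits["H2"].lnL - 1e-6
            assert fits["H1"].lnL >= fits["H0"].lnL - 1e-6
            assert fits["H2"].lnL >= fits["H0"].lnL - 1e-6

    def test_lrt_arithmetic(self):
        spec0 = MODELS_2013["H0"]
        spec1 = MODELS_2013["H1"]
        f0 = FitResult(spec0, {"p": 0.5}, -100.0, 1, True)
        same = FitResult(spec1, {"p_A": 0.5, "p_M": 0.5}, -100.0, 2, True)
        t = lrt(same, f0)
        assert t.statistic == 0.0 and t.p_value == 1.0 and t.df == 1
        crit = FitResult(spec1, {"p_A": 0.5, "p_M": 0.6}, -100.0 + 3.841 / 2, 2, True)
        assert math.isclose(lrt(crit, f0).p_value, 0.05, rel_tol=1e-3)
        assert math.isclose(chi2.sf(3.841, 1), 0.05, rel_tol=1e-3)

    def test_run_tests_layout(self):
        cfg = SimulationConfig(seed=5, n_families=30)
        r = np.random.default_rng(5)
        panel = simulate_panel(cfg, r)
        y13 = simulate_year(cfg, panel, r, 2013)
        y14 = simulate_year(cfg, panel, r, 2014, include_failed=True)
        t13 = run_tests(fit_year(y13.snp_data(), 2013), 2013)
        t14 = run_tests(fit_year(y14.snp_data(), 2014), 2014)
        assert set(t13) == {"male"} and set(t14) == {"male", "viability"}
        for t in list(t13.values()) + list(t14.values()):
            assert t.df == 1 and 0.0 <= t.p_value <= 1.0 and t.statistic >= 0.0


class TestChangeTest:
    def test_duplicated_year_gives_small_statistic(self):
        stats = []
        for seed in (1, 2, 3, 5, 8):
            cfg = SimulationConfig(seed=seed, n_families=100)
            r = np.random.default_rng(seed)
            panel = simulate_panel(cfg, r)
            y = simulate_year(cfg, panel, r, 2013)
            d = y.snp_data()
            res = change_test(d, d)
            assert res.lrt.df == 1
            stats.append(res.lrt.statistic)
        assert np.median(stats) < 0.5

    def test_power_under_frequency_shift(self):
        """p shifting 0.5 -> 0.6 between years is strongly detected.

        At 200 families per year the median p-value sits near 1e-3, so the
        stable assertions are that the median is well below 0.01 and that a
        sizeable fraction of replicates reach p < 1e-3.
        """
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(15):
            seed = int(rng.integers(2**31))
            r = np.random.default_rng(seed)
            cfg1 = SimulationConfig(seed=seed, n_families=200,
                                    cohort_freqs={"p_A": 0.5, "p_M": 0.5})
            panel = simulate_panel(cfg1, r)
            y1 = simulate_year(cfg1, panel, r, 2013)
            cfg2 = SimulationConfig(seed=seed, n_families=200,
                                    cohort_freqs={"p_A": 0.6, "p_M": 0.6, "p_L": 0.6})
            y2 = simulate_year(cfg2, panel, r, 2014, include_failed=True)
            res = change_test(y1.snp_data(), y2.snp_data())
            pvals.append(res.lrt.p_value)
            assert res.observed_dp > 0  # direction recovered
        pvals = np.array(pvals)
        assert np.median(pvals) < 0.01
        assert (pvals < 1e-3).mean() >= 1 / 3

    def test_null_calibration(self):
        """Independent neutral years: type-I error near nominal 0.05."""
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(120):
            seed = int(rng.integers(2**31))
            r = np.random.default_rng(seed)
            cfg = SimulationConfig(seed=seed, n_families=100)
            panel = simulate_panel(cfg, r)
            y1 = simulate_year(cfg, panel, r, 2013)
            y2 = simulate_year(cfg, panel, r, 2014, include_failed=True)
            pvals.append(change_test(y1.snp_data(), y2.snp_data()).lrt.p_value)
        rate = np.mean(np.array(pvals) < 0.05)
        # binomial 99% bounds around 0.05 at n=120
        assert 0.0 <= rate < 0.11


def test_selfing_rate_helper():
    assert math.isclose(selfing_rate(54, 537), 0.100558659, rel_tol=1e-6)
    assert math.isclose(selfing_rate(48, 508), 0.094488189, rel_tol=1e-6)
    with pytest.raises(ValueError):
        selfing_rate(1, 0)
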