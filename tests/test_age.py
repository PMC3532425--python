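"""Haplotype-decay age estimation: closed-form checks, outcome-probability
normalization, breakpoint detection and the year conversion."""

import numpy as np
import pytest

from sweepscan import (
    AgeEstimate,
    GeneticMap,
    HaplotypePanel,
    PopulationStructure,
    Variant,
    build_carrier_set,
    detect_breakpoints,
    estiage_loglik,
    haldane_fraction,
    mle_age,
    modal_carrier_haplotype,
    side_outcome_probs,
)
from sweepscan.age import SideData, sides_from_concordance


class TestHaldane:
    def test_limits(self):
        assert haldane_fraction(0.0) == 0.0
        assert haldane_fraction(1e9) == pytest.approx(0.5)
        # small distances: c ~ d in Morgans
        assert haldane_fraction(0.1) == pytest.approx(0.001, rel=1e-3)

    def test_monotone(self):
        d = np.linspace(0, 500, 100)
        assert np.all(np.diff(haldane_fraction(d)) >= 0)


class TestSideOutcomeProbs:
    def test_single_marker_closed_form(self):
        """One marker at c=0.01, no IBS matching: P(break) = 1-(0.99)^n."""
        for n in (1, 10, 69, 200):
            probs = side_outcome_probs(np.array([0.01]), np.array([0.0]), n, mu=0.0)
            assert probs[0] == pytest.approx(1 - 0.99**n, abs=1e-12)
            assert probs[1] == pytest.approx(0.99**n, abs=1e-12)
        # n = 69 puts the break probability at one half
        probs = side_outcome_probs(np.array([0.01]), np.array([0.0]), 69, mu=0.0)
        assert probs[0] == pytest.approx(0.5, abs=1e-3)

    @pytest.mark.parametrize("mu", [0.0, 1e-6, 1e-3])
    @pytest.mark.parametrize("n", [1, 45, 700])
    def test_outcomes_sum_to_one(self, mu, n):
        rng = np.random.default_rng(3)
        c = np.sort(rng.uniform(0, 0.3, size=5))
        f = rng.uniform(0, 1, size=5)
        probs = side_outcome_probs(c, f, n, mu)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_enumeration_three_markers(self):
        """Hand enumeration over (recombination interval, state matches)."""
        c = np.array([0.02, 0.05, 0.1])
        f = np.array([0.3, 0.6, 0.4])
        n = 25
        A = np.concatenate([[1.0], (1 - c) ** n])
        expected = np.zeros(4)
        for j in (1, 2, 3):  # recombination in interval j
            w = A[j - 1] - A[j]
            # drawn markers j..3 match with prob f; first mismatch = outcome
            for k in range(j, 4):
                prod = np.prod(f[j - 1 : k - 1])
                expected[k - 1] += w * prod * (1 - f[k - 1])
            expected[3] += w * np.prod(f[j - 1 :])
        expected[3] += A[3]
        probs = side_outcome_probs(c, f, n, mu=0.0)
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_n1_all_concordant_probability_near_one(self):
        c = np.full(4, 1e-6)
        probs = side_outcome_probs(c, np.zeros(4), 1, mu=0.0)
        assert probs[-1] == pytest.approx(1.0, abs=1e-5)


class TestLoglikAndMle:
    def make_sides(self, n_true, n_hap=17, seed=0, n_markers=40):
        rng = np.random.default_rng(seed)
        cm = np.sort(rng.uniform(0.05, 3.0, size=n_markers))
        f = rng.uniform(0.2, 0.8, size=n_markers)
        c = haldane_fraction(cm)
        sides = []
        for _ in range(2):
            breaks = np.zeros(n_hap, dtype=int)
            for i in range(n_hap):
                x = rng.exponential(100.0 / n_true)
                drawn = cm > x
                miss = drawn & (rng.uniform(size=n_markers) >= f)
                idx = np.nonzero(miss)[0]
                breaks[i] = idx[0] + 1 if idx.size else 0
            sides.append(SideData(c, f, breaks))
        return sides

    def test_monotone_decay(self):
        """Broader sharing (all breaks farther) gives a smaller age."""
        c = haldane_fraction(np.linspace(0.1, 3, 30))
        f = np.zeros(30)
        near = [SideData(c, f, np.full(10, 3))]
        far = [SideData(c, f, np.full(10, 25))]
        assert mle_age(far, n_max=2000).generations < mle_age(near, n_max=2000).generations

    def test_loglik_validates_n(self):
        sides = self.make_sides(100)
        with pytest.raises(ValueError):
            estiage_loglik(sides, 0)

    def test_point_estimate_recovers_truth(self):
        ests = [
            mle_age(self.make_sides(181, seed=s), n_max=1500).generations
            for s in range(8)
        ]
        assert abs(np.median(ests) - 181) <= 0.25 * 181

    def test_ci_contains_estimate_and_orders(self):
        est = mle_age(self.make_sides(181, seed=1), n_max=1500)
        lo, hi = est.ci_generations
        assert lo <= est.generations <= hi

    def test_year_conversion(self):
        est = AgeEstimate(181, (128, 256), generation_time=25.0)
        assert est.years == 4525
        assert est.ci_years == (3200, 6400)

    def test_boundary_warning(self):
        sides = [SideData(haldane_fraction(np.array([3.0])), np.zeros(1), np.array([1]))]
        with pytest.warns(UserWarning, match="boundary"):
            est = mle_age(sides, n_max=5)
        assert est.at_boundary

    def test_halving_recombination_roughly_doubles_age(self):
        sides = self.make_sides(200, seed=4)
        n1 = mle_age(sides, n_max=3000).generations
        halved = [SideData(s.rec_fraction / 2, s.match_freq, s.breaks) for s in sides]
        n2 = mle_age(halved, n_max=3000).generations
        assert n2 == pytest.approx(2 * n1, rel=0.15)


class TestPanelPipeline:
    def build_panel(self):
        """12 carriers share a long haplotype around the focal SNP."""
        rng = np.random.default_rng(7)
        m = 41
        focal = 20
        haps = rng.integers(0, 2, size=(40, m)).astype(np.uint8)
        haps[:, focal] = 0
        ancestral = rng.integers(0, 2, size=m).astype(np.uint8)
        for i in range(12):
            haps[i] = ancestral
            haps[i, focal] = 1
            # recombine away from the core at a random marker
            b = rng.integers(5, 15)
            haps[i, focal + b :] = rng.integers(0, 2, size=m - focal - b)
        variants = [Variant(f"m{i}", "c", 1000 + i * 5000, ("A", "G"), "A") for i in range(m)]
        samples = [f"s{i}" for i in range(20) for _ in range(2)]
        panel = HaplotypePanel(haps, samples, variants)
        s2p = {f"s{i}": f"pop{i % 4}" for i in range(20)}
        structure = PopulationStructure(s2p, {f"pop{i}": "regA" for i in range(4)})
        gmap = GeneticMap.uniform(1000 + m * 5000, 1.0)
        return panel, structure, gmap, focal

    def test_single_carrier_returned_verbatim(self):
        panel, structure, gmap, focal = self.build_panel()
        # restrict to a population with exactly one carrier haplotype
        carriers = np.nonzero(panel.haplotypes[:, focal] == 1)[0]
        one = panel.sample_of_haplotype[carriers[0]]
        pop = structure.sample_to_population[one]
        rows = panel.haplotype_rows_of_samples(structure.samples_of_population(pop))
        pop_carriers = rows[panel.haplotypes[rows, focal] == 1]
        if pop_carriers.size == 1:
            modal = modal_carrier_haplotype(panel, structure, pop, focal, window_bp=1e9)
            np.testing.assert_array_equal(modal, panel.haplotypes[pop_carriers[0]])

    def test_majority_rule(self):
        panel, structure, gmap, focal = self.build_panel()
        modal = modal_carrier_haplotype(panel, structure, "pop0", focal, window_bp=1e9)
        rows = panel.haplotype_rows_of_samples(structure.samples_of_population("pop0"))
        carriers = rows[panel.haplotypes[rows, focal] == 1]
        sub = panel.haplotypes[carriers]
        clear = (2 * sub.sum(axis=0) != carriers.size)
        expected = (2 * sub.sum(axis=0) > carriers.size).astype(np.uint8)
        np.testing.assert_array_equal(modal[clear], expected[clear])

    def test_breakpoints_on_construction(self):
        """A haplotype differing only at the 3rd right marker breaks there."""
        m = 9
        focal = 4
        base = np.zeros((6, m), dtype=np.uint8)
        base[:, focal] = 1
        # sample s2 (rows 4, 5) discordant only at the 3rd marker right of
        # the core, so its population's modal haplotype carries the break
        base[4:6, focal + 3] = 1
        variants = [Variant(f"m{i}", "c", 100 + i * 1000, ("A", "G"), "A") for i in range(m)]
        panel = HaplotypePanel(base, [f"s{i}" for i in range(3) for _ in range(2)], variants)
        structure = PopulationStructure(
            {f"s{i}": f"p{i}" for i in range(3)}, {f"p{i}": "r" for i in range(3)}
        )
        gmap = GeneticMap.uniform(100 + m * 1000, 1.0)
        cset = build_carrier_set(panel, gmap, structure, [f"p{i}" for i in range(3)], focal,
                                 window_bp=1e9)
        # p2's modal haplotype is the discordant row (single carrier pair)
        left, right = detect_breakpoints(cset)
        assert np.all(left.breaks == 0)
        assert sorted(right.breaks) == [0, 0, 3]

    def test_all_identical_no_breaks(self):
        m = 7
        focal = 3
        haps = np.tile(np.array([1, 0, 1, 1, 0, 0, 1], dtype=np.uint8), (4, 1))
        variants = [Variant(f"m{i}", "c", 100 + i * 1000, ("A", "G"), "A") for i in range(m)]
        panel = HaplotypePanel(haps, ["a", "a", "b", "b"], variants)
        structure = PopulationStructure({"a": "p1", "b": "p2"}, {"p1": "r", "p2": "r"})
        gmap = GeneticMap.uniform(100 + m * 1000, 1.0)
        cset = build_carrier_set(panel, gmap, structure, ["p1", "p2"], focal, window_bp=1e9)
        left, right = detect_breakpoints(cset)
        assert np.all(left.breaks == 0) and np.all(right.breaks == 0)


class TestSimulationRecovery:
    def test_recovery_against_mechanistic_simulator(self):
        """Crossovers as a Poisson process, IBS matching beyond: CI behaves."""
        from sweepscan import simulate_carrier_haplotypes

        rng = np.random.default_rng(0)
        cm = np.sort(rng.uniform(0.02, 3.0, size=60))
        f = rng.uniform(0.2, 0.8, size=60)
        hits = 0
        ests = []
        for s in range(12):
            left, right = simulate_carrier_haplotypes(181, 17, cm, f, mu=1e-6, seed=s)
            sides = sides_from_concordance(left, right, cm, f)
            est = mle_age(sides, n_max=1500)
            ests.append(est.generations)
            lo, hi = est.ci_generations
            hits += lo <= 181 <= hi
        assert hits >= 10  # ~95% nominal coverage
        assert abs(np.median(ests) - 181) <= 0.25 * 181
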