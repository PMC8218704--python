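import math

import numpy as np
import pytest

from ddctdna.errors import ValidationError
from ddctdna.lod import compute_lod
from ddctdna.simulate import (
    FluidSpec,
    SimulationDesign,
    default_cohort_spec,
    simulate_cohort,
    simulate_dilution_series,
    simulate_well,
)


class TestSimulateWell:
    def test_null_allele_never_produces_mutant_templates(self):
        for seed in range(5):
            well = simulate_well(SimulationDesign(true_vaf=0.0, seed=seed))
            assert well.mut_occupancy.sum() == 0
            assert not np.any(well.labels == "mut")

    def test_template_copy_accounting(self):
        # 5 ng at 0.003 ng/genome -> 1667 copies; VAF partitions them
        d = SimulationDesign(dna_input_ng=5.0, true_vaf=0.05)
        mut, wt = d.template_copies()
        assert mut + wt == round(5.0 / 0.003)
        assert mut == round((5.0 / 0.003) * 0.05)

    def test_wildtype_positive_droplets_match_poisson_expectation(self):
        # 4.5 ng of pure wild type -> 1500 copies -> lambda = 0.1 per droplet
        d = SimulationDesign(dna_input_ng=4.5, true_vaf=0.0, seed=11)
        well = simulate_well(d)
        n, lam = d.n_droplets, 0.1
        p = 1 - math.exp(-lam)
        expected = n * p
        assert expected == pytest.approx(1427.4, abs=0.1)
        sd = math.sqrt(n * p * (1 - p))
        assert abs(well.true_counts().n_wt - expected) < 3 * sd

    def test_dilute_mutant_expectation(self):
        # ~17 mutant copies among 15,000 droplets: nearly every copy sits alone
        d = SimulationDesign(dna_input_ng=5.0, true_vaf=0.01, seed=3)
        mut_copies, _ = d.template_copies()
        well = simulate_well(d)
        assert abs(well.true_counts().n_mut - mut_copies) <= 3 * math.sqrt(mut_copies)

    def test_reproducible_from_seed(self):
        d = SimulationDesign(true_vaf=0.02, seed=42)
        a, b = simulate_well(d), simulate_well(d)
        np.testing.assert_array_equal(a.table.ch1, b.table.ch1)
        np.testing.assert_array_equal(a.table.ch2, b.table.ch2)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_multinomial_partitioning_conserves_totals_exactly(self):
        d = SimulationDesign(true_vaf=0.3, partitioning="multinomial", seed=5)
        mut, wt = d.template_copies()
        well = simulate_well(d)
        assert well.mut_occupancy.sum() == mut == well.n_mut_templates
        assert well.wt_occupancy.sum() == wt == well.n_wt_templates

    def test_labels_consistent_with_occupancy(self):
        well = simulate_well(SimulationDesign(true_vaf=0.2, seed=9))
        m, w = well.mut_occupancy >= 1, well.wt_occupancy >= 1
        assert np.array_equal(well.labels == "double", m & w)
        assert np.array_equal(well.labels == "mut", m & ~w)
        assert np.array_equal(well.labels == "empty", ~m & ~w)

    def test_false_positive_rate_lifts_empty_amplitudes(self):
        base = SimulationDesign(true_vaf=0.0, dna_input_ng=0.0, seed=13)
        noisy = SimulationDesign(true_vaf=0.0, dna_input_ng=0.0,
                                 false_positive_rate=0.05, seed=13)
        clean_high = (simulate_well(base).table.ch1 > 4500).sum()
        noisy_high = (simulate_well(noisy).table.ch1 > 4500).sum()
        assert clean_high == 0
        assert noisy_high == pytest.approx(750, abs=3 * math.sqrt(750))

    def test_design_validation(self):
        with pytest.raises(ValidationError):
            SimulationDesign(true_vaf=1.5)
        with pytest.raises(ValidationError):
            SimulationDesign(n_droplets=0)
        with pytest.raises(ValidationError):
            SimulationDesign(partitioning="exact")


class TestDilutionSeries:
    NEAT = SimulationDesign(true_vaf=0.793, dna_input_ng=5.0, seed=21)

    def test_factor_one_reproduces_neat_copy_numbers(self):
        (neat_point,) = simulate_dilution_series(self.NEAT, factors=(), replicates=2,
                                                 include_neat=True)
        mut, wt = self.NEAT.template_copies()
        assert neat_point.dilution_factor == 1.0
        # occupancy counts sit near the (dilute-corrected) copy numbers
        lam = mut / self.NEAT.n_droplets
        expected = self.NEAT.n_droplets * (1 - math.exp(-lam))
        for c in neat_point.mutant_counts:
            assert abs(c - expected) < 4 * math.sqrt(expected)

    def test_mutant_scales_and_wildtype_held_constant(self):
        pts = simulate_dilution_series(self.NEAT, factors=(10, 100), replicates=3)
        mut, wt = self.NEAT.template_copies()
        for pt, factor in zip(pts, (10, 100)):
            exp_mut = round(mut / factor)
            assert np.mean(pt.mutant_counts) == pytest.approx(
                exp_mut, abs=3 * math.sqrt(max(exp_mut, 1)))
            exp_wt = self.NEAT.n_droplets * (1 - math.exp(-wt / self.NEAT.n_droplets))
            assert np.mean(pt.wt_counts) == pytest.approx(exp_wt, rel=0.05)

    def test_deepest_dilution_usually_empty(self):
        # ~0.13 expected mutant copies at 1:10,000
        zeros = 0
        for seed in range(10):
            d = SimulationDesign(true_vaf=0.793, seed=seed)
            (pt,) = simulate_dilution_series(d, factors=(10000,), replicates=2)
            zeros += sum(pt.mutant_counts) == 0
        assert zeros >= 7

    def test_end_to_end_lod_arithmetic(self):
        """Whenever the simulated series detects 1:100 but not 1:1000, the
        computed LoD is exactly neat/100."""
        seen = 0
        for seed in range(12):
            d = SimulationDesign(true_vaf=0.793, seed=seed)
            pts = simulate_dilution_series(d)
            by_factor = {p.dilution_factor: sum(p.mutant_counts) for p in pts}
            if by_factor[100] >= 2 and by_factor[1000] < 2 and by_factor[10000] < 2:
                res = compute_lod(0.793, pts)
                assert 100 * res.lod == pytest.approx(0.793)
                seen += 1
        assert seen >= 1

    def test_unsorted_factors_rejected(self):
        with pytest.raises(ValidationError):
            simulate_dilution_series(self.NEAT, factors=(100, 10))


class TestSimulateCohort:
    def test_zero_positivity_yields_no_positive_samples(self):
        specs = {"plasma": FluidSpec(10, 0.0), "csf": FluidSpec(5, 0.0)}
        _, counts, truth = simulate_cohort(specs, seed=1)
        assert all(wc.n_mut < 2 for wc in counts.values())
        assert not truth["carries_ctdna"].any()

    def test_fixed_seed_reproduces_cohort_exactly(self):
        a = simulate_cohort(seed=7)
        b = simulate_cohort(seed=7)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2].equals(b[2])

    def test_positivity_parameters_recovered_across_seeds(self):
        """Mean detected fraction per fluid approaches its design parameter."""
        specs = {
            "plasma": FluidSpec(27, 7 / 27, median_vaf=0.008),
            "csf": FluidSpec(9, 6 / 9, median_vaf=0.15, vaf_log_sd=1.5),
        }
        n_seeds = 30
        detected = {"plasma": 0, "csf": 0}
        for seed in range(n_seeds):
            _, counts, truth = simulate_cohort(specs, seed=seed)
            for fluid in detected:
                ids = truth.loc[truth.sample_type == fluid, "sample_id"]
                detected[fluid] += sum(counts[i].n_mut >= 2 for i in ids)
        for fluid, spec in specs.items():
            p = spec.positivity
            se = math.sqrt(p * (1 - p) / (spec.n_samples * n_seeds))
            assert detected[fluid] / (spec.n_samples * n_seeds) == pytest.approx(p, abs=3 * se)

    def test_default_spec_mirrors_feasibility_cohort_composition(self):
        specs = default_cohort_spec()
        assert {f: s.n_samples for f, s in specs.items()} == {
            "plasma": 27, "serum": 6, "csf": 9, "cyst": 1
        }
        samples, counts, truth = simulate_cohort(specs, seed=0)
        assert len(samples) == 43 == len(counts) == len(truth)
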