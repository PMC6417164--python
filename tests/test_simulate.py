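"""Structured-cohort simulator: default scenario, determinism, self-tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import kstest

from haplopop import fto
from haplopop.amova import amova_from_arrays
from haplopop.diffstat import permutation_pvalue
from haplopop.hapfreq import count_haplotypes
from haplopop.panel import extract_haplotypes, load_sample_panel
from haplopop.simulate import (
    GroupSpec,
    PopulationSpec,
    SimulationSpec,
    default_fto_spec,
    recount_truth,
    simulate_cohort,
)

from conftest import binary_panel


class TestDefaultSpec:
    def test_pool_carries_published_major_frequencies(self):
        spec = default_fto_spec()
        bases = {g.name: g.base_frequencies for g in spec.groups}
        assert bases["AFR"]["AATTAAGTAGAGGCG"] == 0.240
        assert "AATTAAGTAGAGGCG" not in bases["EUR"]
        assert "AATTAAGTAGAGGCG" not in bases["EAS"]
        assert bases["EUR"]["AACAAGGTAGAGGTA"] == 0.295

    def test_pool_strings_span_the_panel(self):
        spec = default_fto_spec()
        assert all(len(h) == 15 for h in spec.pool)
        for g in spec.groups:
            assert sum(g.base_frequencies.values()) == pytest.approx(1.0, abs=1e-12)

    def test_study_cohort_layout(self):
        spec = default_fto_spec()
        n_pops = sum(len(g.populations) for g in spec.groups)
        n_ind = sum(p.n_individuals for g in spec.groups for p in g.populations)
        assert n_pops == 18
        assert n_ind == 2000

    def test_rare_tail_stays_below_reporting_threshold(self):
        """No filler haplotype accumulates a total (cross-group) base
        frequency above the 0.1 reporting threshold."""
        spec = default_fto_spec()
        totals: dict[str, float] = {}
        for g in spec.groups:
            for h, f in g.base_frequencies.items():
                totals[h] = totals.get(h, 0.0) + f
        majors = set(fto.FULL_HAPLOTYPE_FREQS)
        for h, tot in totals.items():
            if h not in majors:
                assert tot < 0.1


class TestSimulateCohort:
    def test_concentration_limit_pins_populations_to_base(self, tmp_path):
        """With a huge Dirichlet concentration every drawn population
        frequency vector coincides with the group base."""
        spec = default_fto_spec(size_factor=0.01, concentration=1e9, seed=3)
        sim = simulate_cohort(spec, tmp_path)
        for g in spec.groups:
            for p in g.populations:
                drawn = sim.manifest.population_frequencies[p.name]
                for h, base in g.base_frequencies.items():
                    assert abs(drawn.get(h, 0.0) - base) < 1e-3

    def test_single_haplotype_pool(self, tmp_path):
        panel = binary_panel(3)
        spec = SimulationSpec(
            panel=panel,
            groups=[
                GroupSpec("G1", [PopulationSpec("P1", 5), PopulationSpec("P2", 5)],
                          {"AAA": 1.0}),
                GroupSpec("G2", [PopulationSpec("P3", 5), PopulationSpec("P4", 5)],
                          {"AAA": 1.0}),
            ],
            seed=1,
        )
        sim = simulate_cohort(spec, tmp_path)
        for pop, mono in sim.manifest.monomorphic_positions.items():
            assert mono == [1, 2, 3]
        cohort = extract_haplotypes(sim.vcf_path, panel,
                                    load_sample_panel(sim.sample_panel_path))
        assert (cohort.matrix == 1).all()

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        spec = default_fto_spec(size_factor=0.02, seed=9)
        a = simulate_cohort(spec, tmp_path / "a")
        b = simulate_cohort(spec, tmp_path / "b")
        assert a.vcf_path.read_bytes() == b.vcf_path.read_bytes()
        assert a.manifest_path.read_bytes() == b.manifest_path.read_bytes()
        assert a.sample_panel_path.read_bytes() == b.sample_panel_path.read_bytes()

    def test_gzip_output_readable(self, tmp_path):
        spec = default_fto_spec(size_factor=0.02, seed=9)
        sim = simulate_cohort(spec, tmp_path, gzip_vcf=True)
        assert sim.vcf_path.suffix == ".gz"
        cohort = extract_haplotypes(sim.vcf_path, spec.panel,
                                    load_sample_panel(sim.sample_panel_path))
        assert cohort.n_individuals == sum(
            p.n_individuals for g in spec.groups for p in g.populations
        )

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PopulationSpec("P", 0)


class TestRecountTruth:
    def test_roundtrip_is_exact(self, small_sim):
        table = recount_truth(
            small_sim["sim"].vcf_path, small_sim["sim"].sample_panel_path,
            small_sim["spec"].panel, small_sim["sim"].manifest,
        )
        assert sorted(table.units) == sorted(small_sim["sim"].manifest.realized_counts)

    def test_tampered_vcf_detected(self, tmp_path, small_sim):
        text = small_sim["sim"].vcf_path.read_text().splitlines()
        body = [i for i, l in enumerate(text) if not l.startswith("#")]
        row = text[body[0]].split("\t")
        row[9] = "1|1" if row[9] != "1|1" else "0|0"
        text[body[0]] = "\t".join(row)
        bad = tmp_path / "tampered.vcf"
        bad.write_text("\n".join(text) + "\n")
        with pytest.raises(ValueError, match="mismatch"):
            recount_truth(bad, small_sim["sim"].sample_panel_path,
                          small_sim["spec"].panel, small_sim["sim"].manifest)


class TestStatisticalProperties:
    def test_extraction_recovers_drawn_frequencies(self, small_sim):
        """End to end, extraction + counting recovers each population's drawn
        haplotype frequencies within 3 binomial standard errors."""
        table = count_haplotypes(small_sim["cohort"], "population")
        manifest = small_sim["sim"].manifest
        for pop, drawn in manifest.population_frequencies.items():
            two_n = int(small_sim["samples"].table["pop"].eq(pop).sum()) * 2
            for h, p in drawn.items():
                got = table.freq.loc[h, pop] if h in table.freq.index else 0.0
                # binomial 3-sigma bound on counts, with small-count slack
                # where the normal approximation is invalid
                slack = 3 * np.sqrt(two_n * p * (1 - p)) + 3
                assert abs(got - p) * two_n <= slack

    def test_divergence_decreases_with_concentration(self, tmp_path):
        """Larger Dirichlet concentration means less among-population
        variance within a group (checked as a monotone trend of the mean
        among-population AMOVA percent over c in {1, 10, 1000})."""
        panel = binary_panel(4)
        means = []
        for c in (1.0, 10.0, 1000.0):
            vals = []
            for rep in range(15):
                spec = SimulationSpec(
                    panel=panel,
                    groups=[
                        GroupSpec("G1",
                                  [PopulationSpec("P1", 40), PopulationSpec("P2", 40)],
                                  {"AAAA": 0.5, "GGGG": 0.3, "AAGG": 0.2}),
                        GroupSpec("G2",
                                  [PopulationSpec("P3", 40), PopulationSpec("P4", 40)],
                                  {"AAAA": 0.5, "GGGG": 0.3, "AAGG": 0.2}),
                    ],
                    concentration=c,
                    seed=1000 + rep,
                )
                sim = simulate_cohort(spec, tmp_path / f"c{c}_{rep}")
                cohort = extract_haplotypes(sim.vcf_path, panel,
                                            load_sample_panel(sim.sample_panel_path))
                res = amova_from_arrays(
                    cohort.matrix, cohort.populations, cohort.supergroups
                )
                vals.append(res.percent["among_populations_within_groups"])
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_null_permutation_pvalues_are_uniform(self, tmp_path):
        """With identical group bases and a large concentration, permutation
        p-values between groups follow Uniform(0, 1] (KS test at alpha=0.01)."""
        spec = default_fto_spec()
        eur = next(g for g in spec.groups if g.name == "EUR")
        pool = list(eur.base_frequencies)
        probs = np.array([eur.base_frequencies[h] for h in pool])
        codes = np.array([spec.panel.encode(h) for h in pool])
        rng = np.random.default_rng(55)
        pvals = []
        for _ in range(400):
            draws = rng.choice(len(pool), size=100, p=probs)
            X, Y = codes[draws[:50]], codes[draws[50:]]
            r = permutation_pvalue(X, Y, n_perm=99,
                                   seed=int(rng.integers(2**31)))
            pvals.append(r.p_value)
        stat = kstest(pvals, "uniform").statistic
        assert stat < 1.63 / np.sqrt(len(pvals))  # alpha = 0.01 critical value
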