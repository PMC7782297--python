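"""Stepwise-mutation simulator: invariance, determinism, and calibration
against closed-form expectations.

The per-locus identity check uses the closed form for a single allele copy:
P(unchanged repeat count after g meioses) is at least (1-mu)^g (no mutation
at all) and at most (1-mu)^g plus the probability of two or more mutations
(which can return the count to its start); with mu*g << 1 the two-step
return term is bounded by C(g,2) mu^2 / 2 + O(mu^3).
"""

import math

import numpy as np
import pytest

from ystr import (
    MULTI_COPY_LOCI,
    PANEL,
    MutationModel,
    StudyDesign,
    empirical_allele_frequencies,
    haplotype_frequency,
    identity_classes,
    locus_match,
    percent_similarity,
    similarity_matrix,
    simulate_lineage,
    simulate_surname_study,
    simulate_unrelated,
    write_population,
)


@pytest.fixture(scope="module")
def founder(obrien):
    return obrien["OB1"]


class TestLineage:
    def test_zero_mutation_rate_is_invariant(self, founder):
        pop = simulate_lineage(founder, generations=25,
                               model=MutationModel.uniform(0.0),
                               n_descendants=20, seed=7)
        for h in pop:
            assert percent_similarity(founder, h).percent == 100.00
        assert np.all(similarity_matrix(pop).values == 100.00)

    def test_zero_generations_is_invariant_at_any_rate(self, founder):
        pop = simulate_lineage(founder, generations=0,
                               model=MutationModel.uniform(1.0),
                               n_descendants=5, seed=7)
        for h in pop:
            assert h.same_haplotype(founder)

    def test_forced_mutation_changes_every_single_copy_locus(self, founder):
        pop = simulate_lineage(founder, generations=1,
                               model=MutationModel.uniform(1.0),
                               n_descendants=10, seed=7)
        single_copy = [loc for loc in PANEL if loc not in MULTI_COPY_LOCI]
        for h in pop:
            for loc in single_copy:
                assert not locus_match(h[loc], founder[loc])
            assert percent_similarity(founder, h, panel=single_copy).percent == 0.00

    def test_seed_determinism_byte_identical(self, founder):
        a = simulate_lineage(founder, 10, MutationModel.uniform(0.01), 50, seed=42)
        b = simulate_lineage(founder, 10, MutationModel.uniform(0.01), 50, seed=42)
        assert write_population(a) == write_population(b)
        c = simulate_lineage(founder, 10, MutationModel.uniform(0.01), 50, seed=43)
        assert write_population(a) != write_population(c)

    def test_per_locus_rates_respected(self, founder):
        model = MutationModel(per_locus_rate={"DYS19": 1.0}, default_rate=0.0)
        pop = simulate_lineage(founder, 1, model, 10, seed=3)
        for h in pop:
            assert not locus_match(h["DYS19"], founder["DYS19"])
            assert percent_similarity(founder, h, mask={"DYS19"}).percent == 100.00

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            MutationModel.uniform(1.5)
        with pytest.raises(ValueError):
            MutationModel(per_locus_rate={"DYS19": -0.1})

    def test_identity_fraction_matches_closed_form(self, founder):
        # per-copy identity after g generations vs (1-mu)^g bound
        mu, g, n = 0.002, 10, 2000
        pop = simulate_lineage(founder, g, MutationModel.uniform(mu), n, seed=11)
        single_copy = [loc for loc in PANEL if loc not in MULTI_COPY_LOCI]
        identical = np.array([
            [locus_match(h[loc], founder[loc]) for loc in single_copy]
            for h in pop
        ])
        p_hat = identical.mean()
        lower = (1 - mu) ** g
        # allele can return after an even number of mutations; bound loosely
        upper = lower + (math.comb(g, 2) * mu**2)
        se = math.sqrt(lower * (1 - lower) / (n * len(single_copy)))
        assert lower - 3 * se <= p_hat <= upper + 3 * se

    def test_mean_similarity_non_increasing_in_depth(self, founder):
        # averaged over replicates; star genealogy, within-lineage pairs
        mu = 0.02
        rng = np.random.default_rng(5)
        means = []
        for depth in (0, 5, 20):
            vals = []
            for _ in range(100):
                pop = simulate_lineage(founder, depth,
                                       MutationModel.uniform(mu), 6,
                                       seed=rng)
                m = similarity_matrix(pop).values
                vals.append(m[np.triu_indices_from(m, k=1)].mean())
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]
        assert means[0] == 100.00  # depth 0 is exact identity


class TestUnrelated:
    def test_degenerate_table_gives_identical_samples(self, obrien):
        freqs = {loc: {obrien["OB1"][loc].alleles[0]: 1.0} for loc in PANEL}
        pop = simulate_unrelated(freqs, 8, seed=1)
        assert identity_classes(pop).n_distinct == 1

    def test_empty_population(self, obrien):
        freqs = empirical_allele_frequencies(obrien)
        assert simulate_unrelated(freqs, 0, seed=1).N == 0

    def test_frequencies_must_normalise(self):
        freqs = {loc: {12: 0.5} for loc in PANEL}
        with pytest.raises(ValueError, match="sum"):
            simulate_unrelated(freqs, 1, seed=1)

    def test_missing_locus_table_rejected(self, obrien):
        freqs = empirical_allele_frequencies(obrien)
        del freqs["DYS392"]
        with pytest.raises(ValueError, match="DYS392"):
            simulate_unrelated(freqs, 1, seed=1)

    def test_realised_frequency_matches_source(self, obrien):
        # binomial check: DYS19=14 appears at 0.9 in the source table
        n = 5000
        pop = simulate_unrelated(empirical_allele_frequencies(obrien), n, seed=9)
        from ystr import AlleleSet
        hits = sum(h["DYS19"] == AlleleSet([14]) for h in pop) / n
        se = math.sqrt(0.9 * 0.1 / n)
        assert abs(hits - 0.9) <= 3 * se

    def test_dys385_draws_two_copies(self, obrien):
        pop = simulate_unrelated(empirical_allele_frequencies(obrien), 20, seed=2)
        assert all(len(h["DYS385"]) == 2 for h in pop)
        assert all(len(h["DYS19"]) == 1 for h in pop)


class TestSurnameStudy:
    def test_single_cluster_mu_zero_is_one_identity_class(self, obrien):
        design = StudyDesign(
            founders=((obrien["OB1"], 12, 8),),
            model=MutationModel.uniform(0.0),
            seed=4,
        )
        study = simulate_surname_study(design)
        assert len(study.clusters) == 1
        assert identity_classes(study.clusters[0]).n_distinct == 1
        # connects simulator to the counting method
        assert haplotype_frequency(obrien["OB1"], study.clusters[0]).frequency == 1.0

    def test_depth_zero_ignores_mutation_rate(self, obrien):
        design = StudyDesign(
            founders=((obrien["OB2"], 5, 0),),
            model=MutationModel.uniform(1.0),
            seed=4,
        )
        study = simulate_surname_study(design)
        for h in study.clusters[0]:
            assert h.same_haplotype(obrien["OB2"])

    def test_within_exceeds_between_cluster_similarity(self, obrien):
        # OB2 and OB9 differ at 14 of 16 loci (hand count)
        assert percent_similarity(obrien["OB2"], obrien["OB9"]).matched_loci <= 8
        design = StudyDesign(
            founders=((obrien["OB2"], 8, 5), (obrien["OB9"], 8, 5)),
            model=MutationModel.uniform(0.01),
            seed=12,
        )
        study = simulate_surname_study(design)
        a, b = study.clusters
        within = []
        for pop in (a, b):
            m = similarity_matrix(pop).values
            within.append(m[np.triu_indices_from(m, k=1)].mean())
        between = np.mean([
            percent_similarity(h1, h2).percent for h1 in a for h2 in b
        ])
        assert min(within) > between

    def test_reproducible_from_seed(self, obrien):
        design = StudyDesign(
            founders=((obrien["OB1"], 6, 4),),
            n_unrelated=6,
            allele_freqs=obrien,
            seed=99,
        )
        s1 = simulate_surname_study(design)
        s2 = simulate_surname_study(design)
        assert write_population(s1.clusters[0]) == write_population(s2.clusters[0])
        assert write_population(s1.unrelated) == write_population(s2.unrelated)

    def test_invalid_design_rejected(self, obrien):
        with pytest.raises(ValueError):
            StudyDesign(founders=((obrien["OB1"], 0, 3),))
        with pytest.raises(ValueError):
            StudyDesign(founders=(), n_unrelated=5)
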