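"""Simulator: abundance laws, read sampling statistics, reproducibility."""

import numpy as np
import pytest

import ark16s as a
from ark16s.errors import InvalidConfigError


class TestMakeReference:
    def test_single_taxon(self):
        records, taxonomy = a.make_reference(1, length=100, seed=0)
        assert len(records) == 1
        assert taxonomy.taxon_of(records[0][0]) == "taxon_0001"

    def test_deterministic_per_seed(self):
        r1, _ = a.make_reference(5, length=300, seed=9)
        r2, _ = a.make_reference(5, length=300, seed=9)
        assert r1 == r2
        r3, _ = a.make_reference(5, length=300, seed=10)
        assert r1 != r3

    def test_profiles_well_separated(self):
        """Random references keep pairwise 6-mer distances away from zero."""
        for seed in range(3):
            records, _ = a.make_reference(50, length=1500, seed=seed)
            profiles = np.vstack([a.profile(s, 6).values for _, s in records])
            d = np.linalg.norm(profiles[:, None] - profiles[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 1e-3

    def test_families_share_backbone(self):
        records, taxonomy = a.make_reference(
            4, length=1000, seed=1, family_size=2, backbone_share=0.8
        )
        seqs = [np.frombuffer(s.encode(), dtype=np.uint8) for _, s in records]
        same_family = (seqs[0] == seqs[1]).mean()
        cross_family = (seqs[0] == seqs[2]).mean()
        # each member keeps 80% of the backbone independently, so pairwise
        # identity is 0.8^2 + (1 - 0.8^2) * 0.25 ~ 0.73; unrelated ~ 0.25
        assert same_family == pytest.approx(0.73, abs=0.05)
        assert cross_family == pytest.approx(0.25, abs=0.05)
        # family grouping is visible at the genus rank of the lineage
        g = [taxonomy.rank_label(taxonomy.taxon_of(rid)) for rid, _ in records]
        assert g[0] == g[1] and g[2] == g[3] and g[0] != g[2]


class TestDrawAbundances:
    def test_uniform(self):
        np.testing.assert_allclose(a.draw_abundances(4, "uniform"), [0.25] * 4)

    def test_linear_before_permutation(self):
        p = a.draw_abundances(3, "linear", seed=0)
        np.testing.assert_allclose(sorted(p), [1 / 6, 2 / 6, 3 / 6])

    def test_power_law_alpha_one(self):
        p = a.draw_abundances(2, "power_law", seed=0, alpha=1.0)
        np.testing.assert_allclose(sorted(p), [1 / 3, 2 / 3])

    @pytest.mark.parametrize("law", ["power_law", "uniform", "linear"])
    def test_simplex(self, law):
        p = a.draw_abundances(30, law, seed=2)
        assert (p >= 0).all() and p.sum() == pytest.approx(1.0)


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        cfg = a.SimulationConfig(M_taxa=1, ref_length=600, depth=50,
                                 read_length_model=a.FixedLength(100), seed=3)
        sample = a.simulate_sample(cfg)
        ref_seq = sample.reference[0][1]
        assert all(seq in ref_seq for _, seq in sample.reads)

    def test_depth_and_truth_invariants(self):
        cfg = a.SimulationConfig(M_taxa=6, depth=500, abundance_law="power_law",
                                 seed=4)
        sample = a.simulate_sample(cfg)
        assert len(sample.reads) == 500
        assert sample.truth.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_origin_frequencies_within_binomial_bounds(self):
        """Uniform truth over 4 taxa at depth 10^4: empirical origin
        frequencies fall within 3 sigma of 0.25."""
        cfg = a.SimulationConfig(M_taxa=4, depth=10_000, abundance_law="uniform",
                                 seed=5)
        sample = a.simulate_sample(cfg)
        sigma = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.abs(sample.truth.p - 0.25).max() < 3 * sigma

    def test_chimera_count_within_binomial_bounds(self):
        cfg = a.SimulationConfig(M_taxa=10, depth=10_000, chimera_rate=0.35, seed=6)
        sample = a.simulate_sample(cfg)
        sigma = np.sqrt(0.35 * 0.65 * 10_000)
        assert abs(sample.n_chimeras - 3_500) < 3 * sigma

    def test_substitution_rate_close_to_nominal(self):
        """With a single reference and no chimeras, the per-base mismatch
        rate of reads against their source window matches error_rate."""
        cfg = a.SimulationConfig(M_taxa=1, ref_length=500, depth=300,
                                 read_length_model=a.FixedLength(200),
                                 error_rate=0.02, seed=7)
        sample = a.simulate_sample(cfg)
        ref = np.frombuffer(sample.reference[0][1].encode(), dtype=np.uint8)
        mismatches = total = 0
        for _, seq in sample.reads:
            read = np.frombuffer(seq.encode(), dtype=np.uint8)
            # locate the source window as the best alignment over all offsets
            best = min(
                ((ref[s : s + 200] != read).sum(), s)
                for s in range(len(ref) - 200 + 1)
            )
            mismatches += best[0]
            total += 200
        rate = mismatches / total
        assert rate == pytest.approx(0.02, rel=0.25)

    def test_normal_lengths_truncated_and_centered(self):
        cfg = a.SimulationConfig(
            M_taxa=2, ref_length=1500, depth=2000,
            read_length_model=a.NormalLength(), seed=8)
        sample = a.simulate_sample(cfg)
        lengths = np.array([len(s) for _, s in sample.reads])
        assert lengths.mean() == pytest.approx(450, abs=1.0)
        assert lengths.std() == pytest.approx(np.sqrt(50), rel=0.15)
        assert lengths.max() <= 1500

    def test_reproducible_per_seed(self):
        cfg = a.SimulationConfig(M_taxa=3, depth=40, error_rate=0.01,
                                 chimera_rate=0.1, seed=13)
        s1, s2 = a.simulate_sample(cfg), a.simulate_sample(cfg)
        assert s1.reads == s2.reads
        np.testing.assert_array_equal(s1.truth.p, s2.truth.p)

    def test_read_longer_than_reference_rejected(self):
        with pytest.raises(InvalidConfigError):
            a.simulate_sample(a.SimulationConfig(
                M_taxa=1, ref_length=100,
                read_length_model=a.FixedLength(250), depth=5))

    @pytest.mark.parametrize("bad", [dict(error_rate=1.0), dict(chimera_rate=-0.1),
                                     dict(depth=0)])
    def test_config_validation(self, bad):
        with pytest.raises(InvalidConfigError):
            a.SimulationConfig(**bad)


class TestEndToEndRecovery:
    def test_clean_reads_recovered_by_ark(self):
        """Error-free, chimera-free reads from well-separated references:
        ARK at Q=16 lands within VD 0.05 of the truth."""
        cfg = a.SimulationConfig(M_taxa=10, depth=3000, abundance_law="power_law",
                                 seed=17)
        sample = a.simulate_sample(cfg)
        feats = a.featurize(sample.reads, 6)
        ref = a.build_reference(sample.reference, sample.taxonomy, 6)
        result = a.ark_estimate(feats, ref, a.ArkConfig(strategy="random", Q=16,
                                                        seed=17))
        truth = np.array([sample.truth.as_dict()[t] for t in result.estimate.taxa])
        assert a.variational_distance(result.estimate.p, truth) < 0.05
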