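import numpy as np
import pytest

from thx import (
    CDSRecord,
    GenomeProfile,
    aa_frequency,
    compare_gc_windows,
    gc_positional_profile,
    gc_windows,
    protein_length_stats,
    rscu,
    sample_random_sets,
    start_stop_usage,
)
from thx.seqfeatures import RSCU_CODONS, _FAMILY_COLS


def _rec(gene_id, cds, upstream50="A" * 50, pseudo=False):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CDSRecord.from_sequence(gene_id, "+", cds, upstream50, pseudo)


@pytest.fixture(scope="module")
def toy_profile():
    recs = [
        _rec("g1", "ATG" + "AAA" * 4 + "TAA"),            # MKKKK
        _rec("g2", "ATG" + "GCC" * 6 + "TGA", "G" * 50),   # MAAAAAA
        _rec("g3", "GTG" + "GAA" * 5 + "TAG"),            # VEEEEE
        _rec("g4", "ATG" + "AAA" * 2 + "GCC" * 2 + "TGA"),
        _rec("p1", "ATG" + "CCC" * 3 + "TAA", pseudo=True),
    ]
    return GenomeProfile.from_records(recs)


class TestRandomSets:
    def test_pseudogenes_excluded_and_full_set(self, toy_profile):
        sets = sample_random_sets(toy_profile, set_size=4, n_sets=5, seed=1)
        for s in sets:
            assert sorted(s) == ["g1", "g2", "g3", "g4"]

    def test_deterministic_under_seed(self, toy_profile):
        a = sample_random_sets(toy_profile, 2, n_sets=10, seed=3)
        b = sample_random_sets(toy_profile, 2, n_sets=10, seed=3)
        assert a == b

    def test_oversized_request_rejected(self, toy_profile):
        with pytest.raises(ValueError, match="eligible"):
            sample_random_sets(toy_profile, 5, n_sets=1, seed=0)

    def test_inclusion_frequency_uniform(self, small_sim):
        profile = GenomeProfile.from_records(small_sim.genome.to_cds_records())
        size, n_sets = 20, 400
        sets = sample_random_sets(profile, size, n_sets=n_sets, seed=5)
        counts = {}
        for s in sets:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        p = size / profile.n_eligible
        freqs = np.array([counts.get(g, 0) / n_sets for g in profile.gene_ids])
        # binomial 5-sigma band on per-gene inclusion frequency
        tol = 5 * np.sqrt(p * (1 - p) / n_sets)
        assert np.abs(freqs[np.array(profile.eligible)] - p).max() <= tol


class TestAAFrequency:
    def test_single_protein(self, toy_profile):
        freq = aa_frequency(["g1"], toy_profile)
        assert freq["M"] == pytest.approx(20.0)
        assert freq["K"] == pytest.approx(80.0)
        assert freq.drop(["M", "K"]).sum() == 0

    def test_sums_to_100(self, toy_profile):
        for subset in (["g1"], ["g1", "g2"], ["g1", "g2", "g3", "g4"]):
            assert aa_frequency(subset, toy_profile).sum() == pytest.approx(100.0)


class TestGCWindows:
    def test_extreme_sequences(self):
        recs = [_rec("hi", "GTG" + "GGC" * 5 + "TGA", "G" * 50),
                _rec("lo", "ATG" + "AAT" * 5 + "TAA", "A" * 50)]
        prof = GenomeProfile.from_records(recs)
        w = gc_windows(["hi", "lo"], prof)
        assert w.loc["hi", "upstream50_gc"] == 100.0
        assert w.loc["hi", "full_cds_gc"] == pytest.approx(100 * 18 / 21)
        assert w.loc["lo", "upstream50_gc"] == 0.0
        assert w.loc["lo", "downstream50_gc"] == pytest.approx(100 * 1 / 21)

    def test_values_bounded(self, small_sim):
        profile = GenomeProfile.from_records(small_sim.genome.to_cds_records())
        w = gc_windows(profile.gene_ids, profile)
        vals = w.to_numpy()
        ok = vals[~np.isnan(vals)]
        assert ok.min() >= 0 and ok.max() <= 100

    def test_truncated_upstream_dropped_with_warning(self):
        recs = [_rec("full", "ATG" + "GCA" * 5 + "TAA"),
                _rec("edge", "ATG" + "GCA" * 5 + "TAA", upstream50="ACG"),
                _rec("bg1", "ATG" + "GGC" * 5 + "TAA"),
                _rec("bg2", "ATG" + "ATA" * 5 + "TAA")]
        prof = GenomeProfile.from_records(recs)
        with pytest.warns(UserWarning, match="truncated"):
            out = compare_gc_windows(["full", "edge"], prof, n_sets=10, seed=0)
        assert np.isfinite(out.loc["upstream50_gc", "observed"])


class TestPositionalProfile:
    def test_all_g_sequences(self):
        recs = [_rec("g", "G" * 90, "G" * 50)]
        prof = GenomeProfile.from_records(recs)
        series = gc_positional_profile(["g"], prof, half_window=5, start=-30, end=60)
        assert np.nanmax(series.to_numpy()) == pytest.approx(100.0)
        assert np.nanmin(series.to_numpy()) == pytest.approx(100.0)

    def test_planted_gc_block_peaks_near_63(self, small_sim):
        profile = GenomeProfile.from_records(small_sim.genome.to_cds_records())
        truth = small_sim.truth
        te = truth.loc[truth.in_te_set, "gene_id"].tolist()
        series = gc_positional_profile(te, profile)
        covered = series.dropna()
        peak = int(covered.idxmax())
        assert 50 <= peak <= 76

    def test_random_set_profile_tracks_background(self, small_sim):
        profile = GenomeProfile.from_records(small_sim.genome.to_cds_records())
        rand = sample_random_sets(profile, 40, n_sets=1, seed=2)[0]
        series = gc_positional_profile(rand, profile).dropna()
        coding = series[series.index > 0]
        assert abs(coding.mean() - 72.0) < 3.0


class TestRSCU:
    def test_single_codon_family_usage(self, toy_profile):
        # g2's internal codons are all GCC (alanine, 4 synonymous codons)
        vec = rscu(["g2"], toy_profile)
        assert vec["GCC"] == pytest.approx(4.0)
        assert vec["GCA"] == 0.0

    def test_uniform_usage_gives_one(self):
        cds = "ATG" + "GCA" + "GCC" + "GCG" + "GCT" + "TAA"
        prof = GenomeProfile.from_records([_rec("u", cds)])
        vec = rscu(["u"], prof)
        for c in ("GCA", "GCC", "GCG", "GCT"):
            assert vec[c] == pytest.approx(1.0)

    def test_family_means_exactly_one(self, small_sim):
        profile = GenomeProfile.from_records(small_sim.genome.to_cds_records())
        rand = sample_random_sets(profile, 30, n_sets=1, seed=4)[0]
        vec = rscu(rand, profile)
        for aa, cols in _FAMILY_COLS.items():
            fam = vec.iloc[cols]
            if not fam.isna().any():
                assert fam.mean() == pytest.approx(1.0)

    def test_single_codon_families_excluded(self):
        assert "ATG" not in RSCU_CODONS
        assert "TGG" not in RSCU_CODONS
        assert len(RSCU_CODONS) == 59


class TestStartStopUsage:
    def test_start_percentages(self, toy_profile):
        starts, _ = start_stop_usage(["g1", "g2", "g3"], toy_profile)
        assert starts["ATG"] == pytest.approx(100 * 2 / 3)
        assert starts["GTG"] == pytest.approx(100 / 3)
        assert starts.sum() == pytest.approx(100.0)

    def test_stop_percentages(self, toy_profile):
        _, stops = start_stop_usage(["g1", "g2", "g3", "g4"], toy_profile)
        assert stops["TAA"] == pytest.approx(25.0)
        assert stops["TGA"] == pytest.approx(50.0)
        assert stops["TAG"] == pytest.approx(25.0)
        assert stops.sum() == pytest.approx(100.0)


class TestProteinLength:
    def test_median_gene_wilcoxon_near_half(self, small_sim):
        profile = GenomeProfile.from_records(small_sim.genome.to_cds_records())
        lengths = profile.protein_len[profile.eligible]
        median_gene = profile.gene_ids[
            int(np.flatnonzero(profile.eligible)[np.argsort(lengths)[len(lengths) // 2]])
        ]
        stats = protein_length_stats([median_gene], profile, n_sets=50, seed=1)
        assert 0.2 <= stats.wilcoxon_p <= 0.8

    def test_empty_set_rejected(self, small_sim):
        profile = GenomeProfile.from_records(small_sim.genome.to_cds_records())
        with pytest.raises(ValueError, match="empty"):
            protein_length_stats([], profile)

    def test_null_seed_stability(self, small_sim):
        """Rerunning the null with a different seed moves z only slightly."""
        profile = GenomeProfile.from_records(small_sim.genome.to_cds_records())
        te = small_sim.truth.loc[small_sim.truth.in_te_set, "gene_id"].tolist()
        z1 = protein_length_stats(te, profile, n_sets=1000, seed=1).comparison.z
        z2 = protein_length_stats(te, profile, n_sets=1000, seed=2).comparison.z
        assert abs(z1 - z2) < 0.3 * max(1.0, abs(z1))
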