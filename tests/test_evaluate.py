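import itertools

import numpy as np
import pandas as pd
import pytest

from nucpattern import evaluate as ev
from nucpattern import patterns as pt
from nucpattern import synthetic as syn


def mann_whitney_auc(pos, neg):
    """Brute-force pair enumeration: P(pos>neg) + 0.5 P(pos=neg)."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert ev.roc_auc([3, 4, 5], [0, 1, 2]).auc == 1.0

    def test_all_tied_is_half(self):
        assert ev.roc_auc([1.0] * 5, [1.0] * 7).auc == 0.5

    def test_equals_mann_whitney_on_random_scores(self, rng):
        pos = np.round(rng.normal(0.5, 1, 120), 1)  # rounding forces ties
        neg = np.round(rng.normal(0.0, 1, 80), 1)
        r = ev.roc_auc(pos, neg)
        assert r.auc == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        pos, neg = rng.normal(1, 1, 60), rng.normal(0, 1, 60)
        a1 = ev.roc_auc(pos, neg).auc
        a2 = ev.roc_auc(np.exp(pos), np.exp(neg)).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_swap_complements(self, rng):
        pos, neg = rng.normal(1, 1, 50), np.round(rng.normal(0, 1, 50), 1)
        assert ev.roc_auc(neg, pos).auc == pytest.approx(
            1 - ev.roc_auc(pos, neg).auc, abs=1e-12)

    def test_curve_endpoints_monotone(self, rng):
        r = ev.roc_auc(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_tpr_at_fpr_perfect(self):
        assert ev.roc_auc([2, 3], [0, 1]).tpr_at_fpr(0.10) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            ev.roc_auc([], [1.0])
        with pytest.raises(ValueError):
            ev.roc_auc([np.nan], [1.0])


class TestPatternSignificance:
    def test_constant_psfm_gives_p_one(self):
        genome = {"c1": "A" * 5000}
        dyads = pd.DataFrame({"chrom": "c1", "pos": [1000, 2000, 3000],
                              "confidence": 1.0})
        null = ev.pattern_significance(dyads, genome, n_sets=20, seed=0)
        assert all(p == 1.0 for p in null.p_values.values())

    def test_reproducible_under_seed(self, small_genome):
        _, genome, truth = small_genome
        d = truth.head(100)
        a = ev.pattern_significance(d, genome, n_sets=30, seed=5)
        b = ev.pattern_significance(d, genome, n_sets=30, seed=5)
        assert a.p_values == b.p_values
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_planted_oscillation_attains_floor(self, small_genome):
        _, genome, truth = small_genome
        null = ev.pattern_significance(truth, genome, n_sets=99, seed=2)
        assert all(p == pytest.approx(1 / 100) for p in null.p_values.values())

    def test_p_granularity(self, small_genome):
        _, genome, truth = small_genome
        null = ev.pattern_significance(truth.head(50), genome, n_sets=9, seed=0)
        grid = {(k + 1) / 10 for k in range(10)}
        assert all(round(p, 10) in {round(g, 10) for g in grid}
                   for p in null.p_values.values())

    def test_n_sets_validation(self, small_genome):
        _, genome, truth = small_genome
        with pytest.raises(ValueError):
            ev.pattern_significance(truth.head(5), genome, n_sets=0)

    def test_tail_extrapolation_is_small_for_extreme_observed(self, rng):
        samples = rng.exponential(0.01, 500)
        p = ev.extrapolate_tail_p(samples, observed=0.3)
        assert 0 < p < 1e-6


class TestInterdyadHistogram:
    def test_exact_lattice_is_point_mass(self):
        dyads = pd.DataFrame({"chrom": "c1", "pos": np.arange(0, 165 * 50, 165),
                              "confidence": 1.0})
        hist = ev.interdyad_histogram(dyads, max_dist=300)
        assert hist.loc[hist["distance"] == 165, "count"].iloc[0] == 49
        assert hist["count"].sum() == 49

    def test_no_cross_chromosome_distances(self):
        dyads = pd.DataFrame({"chrom": ["c1", "c1", "c2", "c2"],
                              "pos": [0, 100, 5, 105], "confidence": 1.0})
        hist = ev.interdyad_histogram(dyads, max_dist=200)
        assert hist["count"].sum() == 2
        assert hist.loc[hist["distance"] == 100, "count"].iloc[0] == 2

    def test_bernoulli_placement_matches_geometric(self, rng):
        hits = np.nonzero(rng.random(800_000) < 1 / 165)[0]
        dyads = pd.DataFrame({"chrom": "c1", "pos": hits, "confidence": 1.0})
        hist = ev.interdyad_histogram(dyads, max_dist=600, mean_spacing=165)
        # chi-square on bins with decent expected counts, plus the tail
        from scipy import stats
        n = len(hits) - 1
        obs = hist["count"].to_numpy().astype(float)
        exp = hist["geometric_expected"].to_numpy()
        tail_obs = n - obs.sum()
        tail_exp = n * stats.geom.sf(600, 1 / 165)
        obs, exp = np.append(obs, tail_obs), np.append(exp, tail_exp)
        keep = exp >= 5
        res = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert res.pvalue > 0.01

    def test_needs_two_positions(self):
        dyads = pd.DataFrame({"chrom": ["c1", "c2"], "pos": [5, 7],
                              "confidence": 1.0})
        with pytest.raises(ValueError):
            ev.interdyad_histogram(dyads)


class TestAnchoredProfile:
    @staticmethod
    def _trace_fn(base):
        def fn(chrom, start, end):
            return base[start:end] if 0 <= start and end <= len(base) else None
        return fn

    def test_single_anchor_equals_trace(self):
        base = np.sin(np.arange(1000) / 7.0)
        anchors = pd.DataFrame({"chrom": ["c1"], "pos": [500], "strand": ["+"]})
        prof = ev.anchored_profile(self._trace_fn(base), anchors, half_width=20)
        np.testing.assert_allclose(prof["mean_score"], base[480:521])

    def test_constant_scores_flat_profile(self):
        base = np.full(500, 1.25)
        anchors = pd.DataFrame({"chrom": "c1", "pos": [100, 200, 300],
                                "strand": "+"})
        prof = ev.anchored_profile(self._trace_fn(base), anchors, half_width=30)
        np.testing.assert_allclose(prof["mean_score"], 1.25)
        assert (prof["n"] == 3).all()

    def test_minus_strand_flipped(self):
        base = np.arange(400.0)
        plus = pd.DataFrame({"chrom": ["c1"], "pos": [200], "strand": ["+"]})
        minus = pd.DataFrame({"chrom": ["c1"], "pos": [200], "strand": ["-"]})
        p1 = ev.anchored_profile(self._trace_fn(base), plus, 10)["mean_score"]
        p2 = ev.anchored_profile(self._trace_fn(base), minus, 10)["mean_score"]
        np.testing.assert_allclose(p2, p1[::-1])

    def test_peak_at_planted_offset(self, small_genome):
        # anchors a fixed 30 bp from planted dyads: the mean dyad-score
        # profile must peak at that offset (within 1 bp)
        from nucpattern import model as md
        spec, genome, truth = small_genome
        model = md.fit_dyad_model(genome, truth.head(250), width=301, k_max=1)
        anchors = truth.iloc[250:330].copy()
        anchors["pos"] = anchors["pos"] + 30
        anchors["strand"] = "+"

        def fn(chrom, start, end):
            if start < 0 or end > len(genome[chrom]):
                return None
            return md.scan_region(genome, chrom, start, end, model).scores

        prof = ev.anchored_profile(fn, anchors, half_width=60)
        peak = prof.loc[prof["mean_score"].idxmax(), "offset"]
        assert abs(peak - (-30)) <= 1

    def test_no_valid_anchors(self):
        anchors = pd.DataFrame({"chrom": ["c1"], "pos": [5], "strand": ["+"]})
        with pytest.raises(ValueError):
            ev.anchored_profile(lambda c, s, e: None, anchors, 10)


@pytest.fixture(scope="module")
def variants():
    spec = syn.GeneratorSpec(seed=21, genome_length=50_000)
    windows = syn.sample_dyad_windows(spec, 4000, width=147)
    mono = {n: pt.learn_pattern(windows, n) for n in "ACGT"}
    return spec, mono, pt.permuted_variants(mono)


class TestAssignVariant:

    def test_generator_windows_assigned_to_identity_variant(self, variants):
        spec, _, vs = variants
        rng = np.random.default_rng(3)
        windows = syn.sample_dyad_windows(spec, 60, width=147, rng=rng)
        labels = [ev.assign_variant(w, vs, threshold=0.2) for w in windows]
        frac = labels.count("AGCT") / len(labels)
        assert frac > 0.5  # well above the 25% chance level

    def test_reversed_profile_assigned_to_tcga(self, variants):
        spec, _, vs = variants
        flipped = syn.GeneratorSpec(seed=22, genome_length=50_000,
                                    profile=spec.profile[::-1].copy())
        rng = np.random.default_rng(4)
        windows = syn.sample_dyad_windows(flipped, 60, width=147, rng=rng)
        labels = [ev.assign_variant(w, vs, threshold=0.2) for w in windows]
        assert labels.count("TCGA") / len(labels) > 0.5

    def test_uniform_windows_mostly_no_match(self, variants, random_windows):
        _, _, vs = variants
        labels = [ev.assign_variant(w, vs, threshold=0.2)
                  for w in random_windows(60, 147)]
        assert labels.count("no-match") / len(labels) > 0.5


class TestRepeatPartitioning:
    def test_no_repeats_all_low(self):
        dyads = pd.DataFrame({"chrom": "c1", "pos": [500, 900], "confidence": 1.0})
        reps = pd.DataFrame(columns=["chrom", "start", "end"])
        parts = ev.partition_by_repeat(dyads, reps)
        assert len(parts["low"]) == 2 and len(parts["high"]) == 0

    def test_fully_covered_all_high(self):
        dyads = pd.DataFrame({"chrom": "c1", "pos": [500], "confidence": 1.0})
        reps = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [2000]})
        parts = ev.partition_by_repeat(dyads, reps)
        assert len(parts["high"]) == 1

    def test_fraction_matches_per_base_oracle(self, rng):
        dyads = pd.DataFrame({"chrom": "c1",
                              "pos": rng.integers(200, 4800, 20),
                              "confidence": 1.0})
        reps = pd.DataFrame({
            "chrom": "c1",
            "start": (s := np.sort(rng.integers(0, 4900, 30))),
            "end": s + rng.integers(1, 120, 30),
        })
        got = ev.repeat_fraction(dyads, reps, window=200)
        covered = np.zeros(6000, dtype=bool)
        for a, b in zip(reps["start"], reps["end"]):
            covered[a:b] = True
        want = np.array([covered[p - 100: p + 100].mean() for p in dyads["pos"]])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_malformed_interval_rejected(self):
        dyads = pd.DataFrame({"chrom": "c1", "pos": [500], "confidence": 1.0})
        reps = pd.DataFrame({"chrom": ["c1"], "start": [10], "end": [10]})
        with pytest.raises(ValueError):
            ev.partition_by_repeat(dyads, reps)

    def test_at_fraction_partitioning_shares_implementation(self):
        genome = {"c1": "A" * 1000 + "G" * 1000}
        dyads = pd.DataFrame({"chrom": "c1", "pos": [500, 1500],
                              "confidence": 1.0})
        fr = ev.at_fraction(dyads, genome)
        parts = ev.partition_by_scalar(dyads, fr, lo=0.25, hi=0.75)
        assert parts["high"]["pos"].tolist() == [500]
        assert parts["low"]["pos"].tolist() == [1500]
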