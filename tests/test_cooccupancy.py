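import itertools

import numpy as np
import pytest

from clipcoreg.core import HostFeature, ValidationError
from clipcoreg.cooccupancy import (
    density_profile,
    overlap_sites,
    overlap_zscore,
    randomize_within_host,
    utr_cooccupancy,
)

from conftest import make_site, random_sites


def brute_force_pairs(a, b):
    pairs = []
    for sa, sb in itertools.product(a, b):
        if (
            sa.feature_id == sb.feature_id
            and sa.start < sb.end
            and sb.start < sa.end
        ):
            pairs.append((sa.site_id, sb.site_id))
    return pairs


class TestOverlapSites:
    def test_one_nt_intersection(self, simple_features):
        a = [make_site("a1", "f0", 10, 30)]
        b = [make_site("b1", "f0", 29, 40)]
        pairs, ca, cb = overlap_sites(a, b)
        assert len(pairs) == 1 and ca == 1 and cb == 1

    def test_half_open_abutment(self, simple_features):
        a = [make_site("a1", "f0", 10, 30)]
        b = [make_site("b1", "f0", 30, 40)]
        pairs, ca, cb = overlap_sites(a, b)
        assert pairs == [] and ca == 0 and cb == 0

    def test_different_features_never_overlap(self):
        a = [make_site("a1", "f0", 10, 30)]
        b = [make_site("b1", "f1", 10, 30)]
        assert overlap_sites(a, b)[0] == []

    def test_matches_brute_force_on_random_fixtures(self, simple_features):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = random_sites(rng, simple_features, 20, "A")
            b = random_sites(rng, simple_features, 20, "B")
            pairs, ca, cb = overlap_sites(a, b)
            expected = brute_force_pairs(a, b)
            assert sorted((x.site_id, y.site_id) for x, y in pairs) == sorted(
                expected
            )
            assert ca == len({x for x, _ in expected})
            assert cb == len({y for _, y in expected})

    def test_symmetric_in_pair_production(self, simple_features):
        rng = np.random.default_rng(4)
        a = random_sites(rng, simple_features, 15, "A")
        b = random_sites(rng, simple_features, 15, "B")
        p_ab, ca, cb = overlap_sites(a, b)
        p_ba, cb2, ca2 = overlap_sites(b, a)
        assert sorted((x.site_id, y.site_id) for x, y in p_ab) == sorted(
            (y.site_id, x.site_id) for x, y in p_ba
        )
        assert (ca, cb) == (ca2, cb2)
        assert ca <= len(a) and cb <= len(b)


class TestUtrCooccupancy:
    def test_single_protein_venn(self, simple_features):
        classes = utr_cooccupancy(
            {"A": [make_site("a1", "f0", 0, 10)]}, simple_features
        )
        assert classes.count("A") == 1
        assert classes.count() == 9  # unbound remainder

    def test_disjoint_proteins_no_intersection(self, simple_features):
        site_sets = {
            "A": [make_site("a1", "f0", 0, 10)],
            "B": [make_site("b1", "f1", 0, 10)],
            "C": [make_site("c1", "f2", 0, 10)],
        }
        classes = utr_cooccupancy(site_sets, simple_features)
        assert classes.count("A", "B") == 0
        assert classes.count("A", "B", "C") == 0
        assert classes.count("A") == 1

    def test_matches_set_algebra_oracle(self, simple_features):
        rng = np.random.default_rng(5)
        site_sets = {
            p: random_sites(rng, simple_features, 8, p) for p in "ABC"
        }
        classes = utr_cooccupancy(site_sets, simple_features)
        bound = {
            p: {s.feature_id for s in sites}
            for p, sites in site_sets.items()
        }
        for combo_size in range(4):
            for combo in itertools.combinations("ABC", combo_size):
                inside = set.intersection(
                    set(simple_features), *(bound[p] for p in combo)
                ) if combo else set(simple_features)
                outside = set.union(
                    *(bound[p] for p in set("ABC") - set(combo)), set()
                )
                assert classes.count(*combo) == len(inside - outside)

    def test_venn_counts_sum_to_universe(self, simple_features):
        rng = np.random.default_rng(6)
        site_sets = {
            p: random_sites(rng, simple_features, 6, p) for p in "AB"
        }
        classes = utr_cooccupancy(site_sets, simple_features)
        assert sum(classes.venn.values()) == len(simple_features)

    def test_site_outside_universe_raises(self, simple_features):
        with pytest.raises(ValidationError):
            utr_cooccupancy(
                {"A": [make_site("a1", "nope", 0, 5)]}, simple_features
            )


class TestRandomizeWithinHost:
    def test_full_width_site_position_forced(self, simple_features):
        site = make_site("a1", "f0", 0, 100)
        (out,) = randomize_within_host([site], simple_features, 1)
        assert (out.start, out.end) == (0, 100)

    def test_uniform_over_valid_starts(self):
        feats = {"f": HostFeature(feature_id="f", transcript_id="f", length=10)}
        site = make_site("s", "f", 0, 3)
        rng = np.random.default_rng(11)
        starts = [
            randomize_within_host([site], feats, rng)[0].start
            for _ in range(10_000)
        ]
        counts = np.bincount(starts, minlength=8)
        assert counts.sum() == 10_000 and len(counts) == 8
        from scipy import stats

        chi2, p = stats.chisquare(counts)
        assert p > 1e-4  # consistent with uniformity over the 8 starts

    def test_deterministic_given_seed(self, simple_features):
        rng = np.random.default_rng(8)
        sites = random_sites(rng, simple_features, 10, "A")
        out1 = randomize_within_host(sites, simple_features, 123)
        out2 = randomize_within_host(sites, simple_features, 123)
        assert out1 == out2

    def test_width_and_counts_preserved(self, simple_features):
        site = make_site("a1", "f0", 10, 25, counts={"x": 4})
        (out,) = randomize_within_host([site], simple_features, 2)
        assert out.width == 15 and out.counts == {"x": 4}

    def test_too_wide_site_raises(self):
        feats = {"f": HostFeature(feature_id="f", transcript_id="f", length=5)}
        feats_short = {
            "f": HostFeature(feature_id="f", transcript_id="f", length=4)
        }
        with pytest.raises(ValidationError, match="a1"):
            randomize_within_host(
                [make_site("a1", "f", 0, 5)], feats_short, 0
            )


class TestOverlapZscore:
    def host(self, length=10):
        return {
            "f": HostFeature(feature_id="f", transcript_id="f", length=length)
        }

    def test_saturated_null_flags_undefined_z(self):
        feats = self.host()
        a = [make_site("a1", "f", 2, 5)]
        b = [make_site("b1", "f", 0, 10)]  # covers the whole host
        res = overlap_zscore(a, b, feats, n=50, rng_seed=0)
        assert res.null_sd == 0 and res.z is None
        assert res.observed == 1

    def test_null_mean_matches_exhaustive_enumeration(self):
        # width-3 site on a length-10 host: 8 equiprobable starts, of which
        # starts 3..7 intersect [5, 8) -> P(overlap) = 5/8
        feats = self.host()
        a = [make_site("a1", "f", 0, 3)]
        b = [make_site("b1", "f", 5, 8)]
        res = overlap_zscore(a, b, feats, n=10_000, rng_seed=1)
        exact = 5 / 8
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert res.null_mean == pytest.approx(exact, abs=4 * se)

    def test_exhaustive_enumeration_general_hosts(self):
        # compare the Monte-Carlo null mean against full enumeration of all
        # joint placements on hosts short enough to enumerate
        feats = {
            "f": HostFeature(feature_id="f", transcript_id="f", length=12),
            "g": HostFeature(feature_id="g", transcript_id="g", length=9),
        }
        a = [make_site("a1", "f", 0, 4), make_site("a2", "g", 2, 5)]
        b = [make_site("b1", "f", 6, 9), make_site("b2", "g", 0, 2)]
        # exact expected number of a-sites overlapping b under
        # randomization of a
        exact = 0.0
        for sa in a:
            L = feats[sa.feature_id].length
            w = sa.width
            n_starts = L - w + 1
            hits = 0
            for s in range(n_starts):
                if any(
                    sb.feature_id == sa.feature_id
                    and s < sb.end
                    and sb.start < s + w
                    for sb in b
                ):
                    hits += 1
            exact += hits / n_starts
        res = overlap_zscore(a, b, feats, n=20_000, rng_seed=2)
        assert res.null_mean == pytest.approx(exact, abs=0.02)

    def test_z_near_zero_when_observed_typical(self):
        feats = self.host(50)
        rng = np.random.default_rng(9)
        b = [make_site(f"b{i}", "f", i * 10, i * 10 + 5) for i in range(5)]
        zs = []
        for rep in range(200):
            a = randomize_within_host(
                [make_site("a1", "f", 0, 4)], feats, rng
            )
            res = overlap_zscore(a, b, feats, n=100, rng_seed=rep)
            if res.z is not None:
                zs.append(res.z)
        assert abs(np.mean(zs)) < 0.2

    def test_empty_set_raises(self):
        with pytest.raises(ValidationError):
            overlap_zscore([], [make_site("b1", "f", 0, 5)], self.host())


class TestDensityProfile:
    def setup_feats(self, n=5, length=1000):
        return {
            f"f{i}": HostFeature(
                feature_id=f"f{i}", transcript_id=f"f{i}", length=length
            )
            for i in range(n)
        }

    def test_no_queries_all_zero(self):
        feats = self.setup_feats()
        refs = [make_site("r0", "f0", 490, 510)]
        prof = density_profile(refs, [], feats, window=100, bin=10, n=5)
        assert np.all(prof.observed == 0)

    def test_centered_query_in_zero_bin(self):
        feats = self.setup_feats()
        refs = [make_site("r0", "f0", 490, 510)]  # center 499
        qry = [make_site("q0", "f0", 495, 504)]  # width 9, center 499
        prof = density_profile(refs, qry, feats, window=100, bin=10, n=5)
        zero_bin = np.searchsorted(prof.bin_edges, 0, side="right") - 1
        assert prof.observed[zero_bin] == 1.0
        assert prof.observed.sum() == 1.0

    def test_planted_offset_peak_exceeds_null(self):
        feats = self.setup_feats(n=50)
        refs, qry = [], []
        for i in range(50):
            refs.append(make_site(f"r{i}", f"f{i}", 480, 500))  # center 489
            # query center 20 nt 3' of the reference center
            qry.append(make_site(f"q{i}", f"f{i}", 500, 519))  # center 509
        prof = density_profile(
            refs, qry, feats, window=100, bin=10, n=100, rng_seed=0
        )
        peak = int(np.argmax(prof.observed))
        assert prof.bin_edges[peak] <= 20 < prof.bin_edges[peak + 1]
        assert (
            prof.observed[peak]
            > prof.null_mean[peak] + 3 * prof.null_sd[peak]
        )

    def test_window_must_be_bin_multiple(self):
        feats = self.setup_feats()
        refs = [make_site("r0", "f0", 0, 10)]
        with pytest.raises(ValueError):
            density_profile(refs, [], feats, window=105, bin=10)

    def test_no_reference_sites_raises(self):
        with pytest.raises(ValidationError):
            density_profile([], [], self.setup_feats())
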