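import numpy as np
import pytest

from clipcoreg.core import HostFeature, ValidationError
from clipcoreg.diffbind import (
    SiteLFC,
    compute_lfc,
    ks_class_compare,
    normalize_lfc,
    seed_repertoire_correlation,
    site_lfc_table,
    site_signal,
    stratify_sites_by_overlap,
    utr_extremes,
)
from clipcoreg.motifs import SeedMatch

from conftest import make_site, random_sites


def lfc_of(site_id, feature_id, value):
    return SiteLFC(
        site_id=site_id, feature_id=feature_id, raw_lfc=value,
        mrna_lfc=0.0, normalized_lfc=value,
        conditions=("control", "perturbed"),
    )


class TestSiteSignal:
    def test_cpm_scaling(self, two_condition_design):
        site = make_site(
            "s", "f0", 0, 10,
            counts={s: 10 for s in two_condition_design.samples},
        )
        assert site_signal(site, two_condition_design, "control") == 10.0

    def test_replicate_mean(self, two_condition_design):
        counts = {"control_1": 10, "control_2": 30, "control_3": 20}
        counts.update({f"perturbed_{r}": 0 for r in (1, 2, 3)})
        site = make_site("s", "f0", 0, 10, counts=counts)
        assert site_signal(site, two_condition_design, "control") == 20.0
        assert site_signal(site, two_condition_design, "perturbed") == 0.0

    def test_missing_sample_raises(self, two_condition_design):
        site = make_site("s", "f0", 0, 10, counts={"control_1": 5})
        with pytest.raises(ValidationError):
            site_signal(site, two_condition_design, "control")


class TestComputeLfc:
    def test_equal_signals_zero(self, two_condition_design):
        site = make_site(
            "s", "f0", 0, 10,
            counts={s: 50 for s in two_condition_design.samples},
        )
        assert compute_lfc(
            site, two_condition_design, "control", "perturbed"
        ) == 0.0

    def test_doubling_near_one(self, two_condition_design):
        counts = {f"control_{r}": 1000 for r in (1, 2, 3)}
        counts.update({f"perturbed_{r}": 2000 for r in (1, 2, 3)})
        site = make_site("s", "f0", 0, 10, counts=counts)
        lfc = compute_lfc(site, two_condition_design, "control", "perturbed")
        assert lfc == pytest.approx(1.0, abs=0.01)  # pseudocount bias only

    def test_zero_counts_floor_at_zero(self, two_condition_design):
        site = make_site(
            "s", "f0", 0, 10,
            counts={s: 0 for s in two_condition_design.samples},
        )
        assert compute_lfc(
            site, two_condition_design, "control", "perturbed"
        ) == 0.0

    def test_negative_pseudocount_rejected(self, two_condition_design):
        site = make_site(
            "s", "f0", 0, 10,
            counts={s: 1 for s in two_condition_design.samples},
        )
        with pytest.raises(ValueError):
            compute_lfc(
                site, two_condition_design, "control", "perturbed",
                pseudocount=-1,
            )


class TestNormalizeLfc:
    def feature(self, mrna):
        return HostFeature(
            feature_id="f0", transcript_id="f0", length=100,
            mrna_lfc={"PUM_KD": mrna},
        )

    @pytest.mark.parametrize(
        "raw,mrna,expected",
        [(0.5, 0.0, 0.5), (0.5, 0.5, 0.0), (-1.2, -0.4, -0.8)],
    )
    def test_subtraction(self, raw, mrna, expected):
        site = make_site("s", "f0", 0, 10)
        res = normalize_lfc(raw, site, self.feature(mrna), "PUM_KD")
        assert res.normalized_lfc == pytest.approx(expected)
        assert res.raw_lfc == raw and res.mrna_lfc == mrna

    def test_identity_property_at_zero_mrna(self):
        rng = np.random.default_rng(0)
        site = make_site("s", "f0", 0, 10)
        feat = self.feature(0.0)
        for raw in rng.normal(0, 2, size=50):
            assert normalize_lfc(
                float(raw), site, feat, "PUM_KD"
            ).normalized_lfc == pytest.approx(raw)

    def test_missing_mrna_condition_raises(self):
        site = make_site("s", "f0", 0, 10)
        with pytest.raises(KeyError):
            normalize_lfc(0.5, site, self.feature(0.1), "other_cond")

    def test_batch_excludes_and_reports_missing(
        self, two_condition_design
    ):
        feats = {
            "f0": self.feature(0.2),
            "f1": HostFeature(feature_id="f1", transcript_id="f1", length=100),
        }
        counts = {s: 10 for s in two_condition_design.samples}
        sites = [
            make_site("s0", "f0", 0, 10, counts=dict(counts)),
            make_site("s1", "f1", 0, 10, counts=dict(counts)),
        ]
        lfcs, excluded = site_lfc_table(
            sites, feats, two_condition_design, "control", "perturbed",
            mrna_condition="PUM_KD",
        )
        assert [s.site_id for s in lfcs] == ["s0"]
        assert excluded == ["s1"]


class TestUtrExtremes:
    def test_single_site(self):
        (ext,) = utr_extremes([lfc_of("s1", "f0", 0.7)])
        assert ext.min_lfc == ext.max_lfc == 0.7
        assert ext.n_sites == 1

    def test_min_max(self):
        ext = utr_extremes(
            [lfc_of("s1", "f0", -1.0), lfc_of("s2", "f0", 0.0),
             lfc_of("s3", "f0", 2.0)]
        )
        assert (ext[0].min_lfc, ext[0].max_lfc) == (-1.0, 2.0)

    def test_ties(self):
        (ext,) = utr_extremes(
            [lfc_of("s1", "f0", 1.0), lfc_of("s2", "f0", 1.0)]
        )
        assert (ext.min_lfc, ext.max_lfc) == (1.0, 1.0)

    def test_monotone_envelope(self):
        rng = np.random.default_rng(1)
        values = list(rng.normal(0, 1, size=30))
        lfcs = []
        prev_min, prev_max = np.inf, -np.inf
        for i, v in enumerate(values):
            lfcs.append(lfc_of(f"s{i}", "f0", float(v)))
            (ext,) = utr_extremes(lfcs)
            assert ext.min_lfc <= prev_min or np.isinf(prev_min)
            assert ext.max_lfc >= prev_max or np.isinf(prev_max)
            prev_min, prev_max = ext.min_lfc, ext.max_lfc


class TestKsCompare:
    def test_identical_samples_d_zero(self):
        vals = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        res = ks_class_compare(vals, "a", "b")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_d_one(self):
        vals = {"a": [0, 1, 2], "b": [10, 11, 12]}
        assert ks_class_compare(vals, "a", "b").statistic == 1.0

    def test_hand_computed_ecdf_sup_difference(self):
        # ECDFs of {1,2,3,4} and {2,3,4,5} differ maximally by 1/4 on
        # [1,2) and [4,5)
        vals = {"a": [1, 2, 3, 4], "b": [2, 3, 4, 5]}
        res = ks_class_compare(vals, "a", "b")
        assert res.statistic == pytest.approx(0.25)
        assert res.n == (4, 4)

    def test_undersized_class_raises(self):
        with pytest.raises(ValidationError):
            ks_class_compare({"a": [1.0], "b": [1, 2, 3]}, "a", "b")

    def test_ecdf_support_is_sorted_sample(self):
        vals = {"a": [3.0, 1.0, 2.0], "b": [5.0, 4.0, 6.0]}
        res = ks_class_compare(vals, "a", "b")
        assert list(res.ecdf_support["a"]) == [1.0, 2.0, 3.0]


class TestStratify:
    def test_no_partner_sites(self, simple_features):
        a = [make_site("a1", "f0", 0, 10)]
        labels = stratify_sites_by_overlap(a, [])
        assert labels == {"a1": False}

    def test_partner_covers_everything(self, simple_features):
        a = [make_site(f"a{i}", f"f{i}", 10, 20) for i in range(3)]
        b = [make_site(f"b{i}", f"f{i}", 0, 100) for i in range(3)]
        labels = stratify_sites_by_overlap(a, b)
        assert all(labels.values()) and len(labels) == 3

    def test_partition_matches_brute_force(self, simple_features):
        rng = np.random.default_rng(10)
        a = random_sites(rng, simple_features, 25, "A")
        b = random_sites(rng, simple_features, 25, "B")
        labels = stratify_sites_by_overlap(a, b)
        assert set(labels) == {s.site_id for s in a}  # exhaustive partition
        for sa in a:
            expected = any(
                sa.feature_id == sb.feature_id
                and sa.start < sb.end
                and sb.start < sa.end
                for sb in b
            )
            assert labels[sa.site_id] is expected


class TestRepertoireCorrelation:
    def matches_for(self, tallies, feature_id="f0"):
        """One synthetic SeedMatch per occurrence, all inside [0, 50)."""
        out = []
        for fam, k in tallies.items():
            for i in range(k):
                out.append(SeedMatch(feature_id, i, fam, "8mer"))
        return out

    def test_identical_groups_rho_one(self):
        g = [make_site("s1", "f0", 0, 50)]
        matches = self.matches_for({"fam1": 1, "fam2": 2, "fam3": 3})
        assert seed_repertoire_correlation(g, g, matches) == pytest.approx(
            1.0
        )

    def test_reversed_ranks_rho_minus_one(self):
        g1 = [make_site("s1", "f0", 0, 50)]
        g2 = [make_site("s2", "f1", 0, 50)]
        matches = self.matches_for(
            {"fam1": 1, "fam2": 2, "fam3": 3}, "f0"
        ) + self.matches_for({"fam1": 3, "fam2": 2, "fam3": 1}, "f1")
        assert seed_repertoire_correlation(
            g1, g2, matches
        ) == pytest.approx(-1.0)

    def test_hand_rank_formula(self):
        # tallies (1,2,3,4) vs (1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8
        g1 = [make_site("s1", "f0", 0, 50)]
        g2 = [make_site("s2", "f1", 0, 50)]
        matches = self.matches_for(
            {"f1m": 1, "f2m": 2, "f3m": 3, "f4m": 4}, "f0"
        ) + self.matches_for({"f1m": 1, "f2m": 3, "f3m": 2, "f4m": 4}, "f1")
        assert seed_repertoire_correlation(
            g1, g2, matches
        ) == pytest.approx(0.8)

    def test_constant_tallies_undefined(self):
        g1 = [make_site("s1", "f0", 0, 50)]
        g2 = [make_site("s2", "f1", 0, 50)]
        matches = self.matches_for(
            {"fam1": 2, "fam2": 2, "fam3": 2}, "f0"
        ) + self.matches_for({"fam1": 1, "fam2": 2, "fam3": 3}, "f1")
        assert seed_repertoire_correlation(g1, g2, matches) is None

    def test_too_few_families_raises(self):
        g = [make_site("s1", "f0", 0, 50)]
        with pytest.raises(ValidationError):
            seed_repertoire_correlation(
                g, g, self.matches_for({"fam1": 1, "fam2": 2})
            )
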