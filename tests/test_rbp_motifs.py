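import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from splicespan.io_formats import Config, Motif
from splicespan.rbp_motifs import (
    ScanRegion,
    count_matches,
    group_enrichment,
    motif_psi_correlation,
    percentile_bicluster,
    percentile_matrix,
    rate_matrix,
    scan,
)


def _region(event_id, seq, etype="SE"):
    return ScanRegion(event_id=event_id, event_type=etype, sequence=seq)


class TestScan:
    def test_direct_count_and_rate(self):
        motifs = {"FUS": [Motif(name="FUS", consensus="TGGTG")]}
        df = scan([_region("e1", "TGGTGAATGGTG")], motifs)
        row = df.iloc[0]
        assert row["raw_count"] == 2
        assert row["rate"] == pytest.approx(2 / 12)

    def test_absent_motif_zero(self):
        motifs = {"QKI": [Motif(name="QKI", consensus="ACTAAC")]}
        df = scan([_region("e1", "GGGGGGGGGG")], motifs)
        assert df.iloc[0]["raw_count"] == 0

    def test_overlapping_matches_counted(self):
        motifs = {"X": [Motif(name="X", consensus="AAAA")]}
        df = scan([_region("e1", "AAAAAA")], motifs)
        assert df.iloc[0]["raw_count"] == 3

    def test_motif_longer_than_sequence(self):
        m = Motif(name="X", consensus="ACGTACGT")
        assert count_matches("ACG", m) == 0

    def test_n_never_matches(self):
        m = Motif(name="X", consensus="ANGT")  # N in motif matches any base
        assert count_matches("AAGT", m) == 1
        assert count_matches("ANGT", m) == 0  # N in sequence matches nothing

    def test_iupac_degeneracy(self):
        m = Motif(name="X", consensus="TGYTG")  # Y = C or T
        assert count_matches("TGCTGTGTTG", m) == 2
        assert count_matches("TGATG", m) == 0

    def test_pwm_threshold_scanning(self):
        # PWM strongly favoring ACGT; at threshold 1.0 only the exact word
        pwm = np.array(
            [
                [0.97, 0.01, 0.01, 0.01],
                [0.01, 0.97, 0.01, 0.01],
                [0.01, 0.01, 0.97, 0.01],
                [0.01, 0.01, 0.01, 0.97],
            ]
        )
        strict = Motif(name="P", pwm=pwm, threshold=1.0)
        assert count_matches("AACGTA", strict) == 1
        assert count_matches("AACTTA", strict) == 0

    def test_split_invariance_away_from_boundaries(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        m = {"X": [Motif(name="X", consensus="TGGTG")]}
        whole = scan([_region("e", seq)], m).iloc[0]["raw_count"]
        left = scan([_region("l", seq[:150])], m).iloc[0]["raw_count"]
        right = scan([_region("r", seq[150:])], m).iloc[0]["raw_count"]
        assert abs(whole - (left + right)) <= 4  # only cut-straddling matches


def _null_profiles(n_events=120, seed=0, rate=0.02, length=300):
    """Profiles with a single motif occurring at a uniform rate."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_events):
        etype = "SE" if k % 2 == 0 else "RI"
        count = rng.poisson(rate * length)
        rows.append(
            {
                "event_id": f"e{k:03d}",
                "event_type": etype,
                "rbp": "X",
                "raw_count": count,
                "length": length,
                "rate": count / length,
            }
        )
    return pd.DataFrame(rows)


class TestGroupEnrichment:
    def test_null_target_ratio_near_one(self):
        profiles = _null_profiles(seed=1)
        rng = np.random.default_rng(2)
        target = set(rng.choice(profiles["event_id"].unique(), 30, replace=False))
        res = group_enrichment(target, profiles, n_draws=500, seed=3)
        ratio = res.loc["X", "ratio"]
        se = res.loc["X", "null_sd"] / res.loc["X", "null_mean"] / math.sqrt(500)
        # target is itself one random group: compare against the draw SD
        sd_rel = res.loc["X", "null_sd"] / res.loc["X", "null_mean"]
        assert abs(ratio - 1.0) < 3 * sd_rel
        assert 0.9 < ratio < 1.1

    def test_planted_threefold_rate_recovered(self):
        """Targets carrying motifs at 3x the universe rate recover a ratio
        near 3.  The target is kept to a small fraction of the universe so
        that its own contribution to the random-group mean (which dilutes
        the ratio by 1 + 2k/n) stays within the 10% tolerance."""
        profiles = _null_profiles(n_events=600, seed=4, rate=0.05, length=500)
        rng = np.random.default_rng(5)
        target = sorted(rng.choice(profiles["event_id"].unique(), 15, replace=False))
        boost = profiles["event_id"].isin(target)
        profiles.loc[boost, "raw_count"] = rng.poisson(
            3 * 0.05 * 500, size=int(boost.sum())
        )
        profiles["rate"] = profiles["raw_count"] / profiles["length"]
        res = group_enrichment(set(target), profiles, n_draws=500, seed=6)
        assert res.loc["X", "ratio"] == pytest.approx(3.0, rel=0.10)

    def test_target_equals_universe_ratio_exactly_one(self):
        profiles = _null_profiles(seed=7)
        target = set(profiles["event_id"].unique())
        res = group_enrichment(target, profiles, n_draws=50, seed=8)
        assert res.loc["X", "ratio"] == pytest.approx(1.0, abs=1e-12)

    def test_matched_draws_preserve_type_composition(self):
        profiles = _null_profiles(seed=9)
        types = profiles.set_index("event_id")["event_type"]
        se_events = [e for e in types.index if types[e] == "SE"]
        target = set(se_events[:20])  # SE-only target
        # a universe with too few SE events must be rejected
        small = profiles[profiles["event_type"] == "RI"]
        with pytest.raises(ValueError, match="not profiled"):
            group_enrichment(target, small, n_draws=10, seed=0)

    def test_null_ratio_unbiased_across_seeds(self):
        """Meta-test: the null enrichment ratio is centred on 1."""
        profiles = _null_profiles(n_events=150, seed=10, rate=0.03)
        rng = np.random.default_rng(11)
        ratios = []
        for s in range(20):
            target = set(rng.choice(profiles["event_id"].unique(), 30, replace=False))
            res = group_enrichment(target, profiles, n_draws=100, seed=s)
            ratios.append(res.loc["X", "ratio"])
        mean = float(np.mean(ratios))
        se = float(np.std(ratios, ddof=1) / math.sqrt(len(ratios)))
        assert abs(mean - 1.0) <= 3 * se + 1e-3


class TestPercentiles:
    def test_monotone_transform_of_rates(self):
        profiles = _null_profiles(seed=12)
        rates = rate_matrix(profiles)
        pct = percentile_matrix(profiles)
        r = rates["X"].to_numpy()
        p = pct["X"].to_numpy()
        order = np.argsort(r)
        assert (np.diff(p[order]) >= -1e-12).all()
        assert p.max() <= 100 and p.min() >= 0

    def test_planted_blocks_recovered(self):
        """Two event x RBP blocks of elevated percentiles are separated by
        average-linkage clustering with near-perfect agreement."""
        rng = np.random.default_rng(13)
        n_a, n_b = 30, 30
        events = [f"e{k:03d}" for k in range(n_a + n_b)]
        rbps = [f"R{j}" for j in range(8)]
        rows = []
        for i, ev in enumerate(events):
            for j, rbp in enumerate(rbps):
                hot = (i < n_a) == (j < 4)
                rate = rng.normal(0.06 if hot else 0.02, 0.005)
                rows.append(
                    {
                        "event_id": ev,
                        "event_type": "SE",
                        "rbp": rbp,
                        "raw_count": max(rate, 0) * 300,
                        "length": 300,
                        "rate": max(rate, 0),
                    }
                )
        pct = percentile_matrix(pd.DataFrame(rows))
        out = percentile_bicluster(pct, n_clusters=2)
        truth = [0] * n_a + [1] * n_b
        assert adjusted_rand_score(truth, out["event_clusters"]) >= 0.9

    def test_identical_rows_merge_at_zero_height(self):
        mat = pd.DataFrame(
            [[50.0, 50.0], [50.0, 50.0], [10.0, 90.0]],
            index=["a", "b", "c"],
            columns=["R1", "R2"],
        )
        out = percentile_bicluster(mat)
        assert out["event_linkage"][0, 2] == pytest.approx(0.0)

    def test_too_small_matrix_rejected(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["R1", "R2"])
        with pytest.raises(ValueError):
            percentile_bicluster(mat)


class TestMotifPsiCorrelation:
    def _tables(self, n_species, rho_perfect=True, n_pairs=1):
        species = [f"sp{i}" for i in range(n_species)]
        rates = pd.DataFrame(
            [np.linspace(0.01, 0.05, n_species)],
            index=pd.MultiIndex.from_tuples([("e1", "RBFOX1")]),
            columns=species,
        )
        psi = pd.DataFrame(
            [np.linspace(10, 90, n_species)], index=["e1"], columns=species
        )
        return rates, psi

    def test_monotone_relation_significant(self):
        rates, psi = self._tables(12)
        df = motif_psi_correlation(rates, psi, Config())
        assert df.loc[("e1", "RBFOX1"), "rho"] == pytest.approx(1.0)
        assert bool(df.loc[("e1", "RBFOX1"), "significant"])

    def test_exactly_ten_points_excluded(self):
        rates, psi = self._tables(10)
        df = motif_psi_correlation(rates, psi, Config())
        assert len(df) == 0
        rates11, psi11 = self._tables(11)
        assert len(motif_psi_correlation(rates11, psi11, Config())) == 1

    def test_planted_relation_recovered_across_replicates(self):
        """A linear rate-PSI relation with noise across 26 species is called
        significant in most replicates."""
        rng = np.random.default_rng(14)
        species = [f"sp{i}" for i in range(26)]
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            psi_vals = rng.uniform(10, 90, 26)
            rates_vals = 0.0005 * psi_vals + rng.normal(0, 0.004, 26)
            rates = pd.DataFrame(
                [rates_vals],
                index=pd.MultiIndex.from_tuples([("e1", "X")]),
                columns=species,
            )
            psi = pd.DataFrame([psi_vals], index=["e1"], columns=species)
            df = motif_psi_correlation(rates, psi, Config())
            hits += bool(df["significant"].iloc[0])
        assert hits / n_rep >= 0.8

    def test_constant_rate_dropped(self):
        species = [f"sp{i}" for i in range(12)]
        rates = pd.DataFrame(
            [[0.02] * 12],
            index=pd.MultiIndex.from_tuples([("e1", "X")]),
            columns=species,
        )
        psi = pd.DataFrame(
            [np.linspace(10, 90, 12)], index=["e1"], columns=species
        )
        assert len(motif_psi_correlation(rates, psi, Config())) == 0


def test_paired_group_comparison_detects_systematic_difference():
    """Group A ratios uniformly above group B over shared RBPs give a
    significant positive paired t statistic."""
    import pandas as pd
    from splicespan.rbp_motifs import paired_group_comparison

    rbps = [f"R{j}" for j in range(25)]
    rng = np.random.default_rng(0)
    base = rng.uniform(0.8, 1.2, len(rbps))
    a = pd.DataFrame({"ratio": base + 0.5}, index=rbps)
    b = pd.DataFrame({"ratio": base}, index=rbps)
    t, p = paired_group_comparison(a, b, top_n=20)
    assert t > 0
    assert p < 1e-6
    t2, p2 = paired_group_comparison(a, a, top_n=None)
    assert np.isnan(t2) or abs(t2) < 1e-9 or p2 > 0.9
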