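import math
import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

from splicespan.io_formats import Config
from splicespan.mls_assoc import (
    SpeciesTraits,
    bm_decompose,
    pic,
    pic_correlation,
    pic_robustness,
    spearman_trait_assoc,
    tissue_specificity,
)
from splicespan.synthetic_data import SimConfig, simulate_tree_traits


def _tree(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )


def _traits(mls, bm=None):
    species = list(mls)
    bm = bm or {s: 10.0 for s in species}
    return SpeciesTraits(mls=pd.Series(mls), bm=pd.Series(bm))


class TestSpearman:
    def _psi(self, rows, species):
        return pd.DataFrame(rows, columns=species)

    def test_monotone_psi_gives_rho_one(self):
        species = [f"s{i}" for i in range(12)]
        mls = {s: float(i + 1) for i, s in enumerate(species)}
        psi = pd.DataFrame(
            [np.linspace(10, 90, 12)], index=["e1"], columns=species
        )
        df = spearman_trait_assoc(psi, _traits(mls), "MLS", config=Config())
        assert df.loc["e1", "rho"] == pytest.approx(1.0)
        assert df.loc["e1", "direction"] == "pos"

    def test_hand_ranked_example(self):
        """PSI (10..50) against MLS (5,3,4,2,1): rank differences give
        rho = 1 - 6*38/120 = -0.9."""
        species = list("abcde")
        psi = pd.DataFrame(
            [[10.0, 20.0, 30.0, 40.0, 50.0]], index=["e"], columns=species
        )
        mls = dict(zip(species, [5.0, 3.0, 4.0, 2.0, 1.0]))
        cfg = Config(min_species=5)
        df = spearman_trait_assoc(psi, _traits(mls), "MLS", config=cfg)
        assert df.loc["e", "rho"] == pytest.approx(-0.9)

    def test_constant_psi_dropped(self):
        species = [f"s{i}" for i in range(12)]
        mls = {s: float(i + 1) for i, s in enumerate(species)}
        psi = pd.DataFrame([[50.0] * 12], index=["e"], columns=species)
        df = spearman_trait_assoc(psi, _traits(mls), "MLS", config=Config())
        assert len(df) == 0

    def test_too_few_species_skipped(self):
        species = [f"s{i}" for i in range(8)]
        mls = {s: float(i + 1) for i, s in enumerate(species)}
        psi = pd.DataFrame(
            [np.linspace(0, 100, 8)], index=["e"], columns=species
        )
        df = spearman_trait_assoc(psi, _traits(mls), "MLS", config=Config())
        assert len(df) == 0

    def test_pos_plus_neg_equals_total_significant(self, mls_associations):
        for assoc in mls_associations.values():
            sig = assoc[assoc["significant"]]
            pos = (sig["direction"] == "pos").sum()
            neg = (sig["direction"] == "neg").sum()
            assert pos + neg == len(sig)


class TestPic:
    def test_two_tip_closed_form(self):
        tree = _tree("(A:2,B:3);")
        (c,) = pic(tree, {"A": 5.0, "B": 1.0})
        assert c == pytest.approx((5 - 1) / math.sqrt(5), abs=1e-9)

    def test_three_tip_felsenstein_recursion(self):
        """First contrast (3-1)/sqrt(2); ancestral value 2 with branch
        lengthened to 1.5, so the second contrast is (2-2)/sqrt(3.5) = 0."""
        tree = _tree("((A:1,B:1):1,C:2);")
        contrasts = pic(tree, {"A": 3.0, "B": 1.0, "C": 2.0})
        assert sorted(np.abs(contrasts)) == pytest.approx(
            [0.0, math.sqrt(2)], abs=1e-9
        )

    def test_identical_tip_values_zero_contrasts(self):
        tree = _tree("((A:1,B:1):1,(C:2,D:1):2);")
        assert np.allclose(pic(tree, {t: 7.0 for t in "ABCD"}), 0.0)

    def test_missing_tip_value_rejected(self):
        with pytest.raises(KeyError):
            pic(_tree("(A:1,B:1);"), {"A": 1.0})

    def test_matches_ape_on_simulated_tree(self):
        """Independent oracle: ape::pic on a 8-tip simulated tree."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        sim = SimConfig(seed=5, n_species=8)
        tree, traits = simulate_tree_traits(sim)
        newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
        values = traits.mls
        vec = ",".join(f"{s}={values[s]}" for s in sorted(values.index))
        script = (
            "suppressMessages(library(ape));"
            f"t <- read.tree(text='{newick}');"
            f"v <- c({vec});"
            "cat(sort(abs(pic(v, t))), sep=',')"
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert res.returncode == 0, res.stderr
        expected = np.array([float(x) for x in res.stdout.strip().split(",")])
        ours = np.sort(np.abs(pic(tree, values.to_dict())))
        assert np.allclose(ours, expected, atol=1e-6)

    def test_star_phylogeny_equals_tip_correlation(self):
        rng = np.random.default_rng(10)
        tips = [f"T{i}" for i in range(15)]
        star = _tree("(" + ",".join(f"{t}:1" for t in tips) + ");")
        x = {t: float(rng.normal()) for t in tips}
        y = {t: float(rng.normal()) for t in tips}
        r_pic = pic_correlation(star, x, y)
        xa = np.array([x[t] for t in tips])
        ya = np.array([y[t] for t in tips])
        r_tip = np.corrcoef(xa, ya)[0, 1]
        assert r_pic == pytest.approx(r_tip, abs=1e-6)


class TestPicRobustness:
    def _assoc_row(self, event_id, rho):
        return pd.DataFrame(
            {
                "tissue": ["t"],
                "trait": ["MLS"],
                "rho": [rho],
                "n_used": [12],
                "p": [1e-4],
                "fdr": [1e-3],
                "significant": [True],
                "direction": ["pos" if rho > 0 else "neg"],
            },
            index=pd.Index([event_id], name="event_id"),
        )

    def test_star_tree_retention_matches_raw_significance(self):
        rng = np.random.default_rng(11)
        tips = [f"T{i}" for i in range(20)]
        star = _tree("(" + ",".join(f"{t}:1" for t in tips) + ");")
        mls = pd.Series({t: float(i + 1) for i, t in enumerate(tips)})
        traits = SpeciesTraits(mls=mls, bm=pd.Series(1.0, index=tips))
        psi_vals = 5.0 * mls + rng.normal(0, 3, size=len(tips))
        psi = pd.DataFrame([psi_vals.to_numpy()], index=["e"], columns=tips)
        rho = 0.9
        frac, table = pic_robustness(
            self._assoc_row("e", rho), star, psi, traits, contrast_cutoff=0.2
        )
        # independent tips: the contrast correlation approximates the tip
        # correlation, so a strong raw association survives correction
        assert frac == 1.0

    def test_clade_driven_signal_discounted(self):
        """An association carried by one deep split is a single contrast; a
        modest between-clade PSI shift drowning in within-clade noise gives
        a near-perfect tip rank correlation but a contrast correlation below
        the 0.2 retention cutoff."""
        tips_a = [f"A{i}" for i in range(8)]
        tips_b = [f"B{i}" for i in range(8)]
        newick = (
            "("
            + "(" + ",".join(f"{t}:0.1" for t in tips_a) + "):5,"
            + "(" + ",".join(f"{t}:0.1" for t in tips_b) + "):5"
            + ");"
        )
        tree = _tree(newick)
        rng = np.random.default_rng(12)
        mls = pd.Series(
            {**{t: 5.0 + rng.normal(0, 0.05) for t in tips_a},
             **{t: 30.0 + rng.normal(0, 0.05) for t in tips_b}}
        )
        traits = SpeciesTraits(mls=mls, bm=pd.Series(1.0, index=mls.index))
        psi_vals = {
            **{t: 46.0 + rng.normal(0, 1.5) for t in tips_a},
            **{t: 54.0 + rng.normal(0, 1.5) for t in tips_b},
        }
        psi = pd.DataFrame(
            [[psi_vals[t] for t in mls.index]], index=["e"], columns=mls.index
        )
        # the raw rank correlation is driven to ~1 by the clade separation
        from scipy import stats

        raw = stats.spearmanr(
            psi.loc["e"], mls.loc[psi.columns]
        ).statistic
        assert abs(raw) > 0.7
        frac, table = pic_robustness(
            self._assoc_row("e", raw), tree, psi, traits, contrast_cutoff=0.2
        )
        assert frac == 0.0

    def test_zero_cutoff_retains_sign_consistent_events(self, species_dataset, mls_associations):
        assoc = mls_associations["heart"]
        frac, table = pic_robustness(
            assoc,
            species_dataset["tree"],
            species_dataset["matrices"]["heart"],
            species_dataset["traits"],
            contrast_cutoff=0.0,
        )
        # all retained events must be sign-consistent by definition
        assert frac > 0.9


class TestBmDecompose:
    def _traits_from(self, mls, bm, species):
        return SpeciesTraits(
            mls=pd.Series(mls, index=species), bm=pd.Series(bm, index=species)
        )

    def test_psi_only(self):
        rng = np.random.default_rng(13)
        n = 20
        species = [f"s{i}" for i in range(n)]
        psi = pd.Series(rng.uniform(20, 80, n), index=species)
        mls = 2.0 * psi.to_numpy() + rng.normal(0, 0.01, n)
        bm = rng.uniform(1, 100, n)
        d = bm_decompose("e", psi, self._traits_from(mls, bm, species))
        assert d.category == "PSI_only"

    def test_bm_only(self):
        rng = np.random.default_rng(14)
        n = 20
        species = [f"s{i}" for i in range(n)]
        bm = rng.uniform(1, 100, n)
        mls = bm + rng.normal(0, 0.01, n)
        psi = pd.Series(rng.uniform(20, 80, n), index=species)
        d = bm_decompose("e", psi, self._traits_from(mls, bm, species))
        assert d.category == "BM_only"

    def test_joint_category_recovered(self):
        rng = np.random.default_rng(15)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 50
            species = [f"s{i}" for i in range(n)]
            bm = rng.uniform(1, 50, n)
            psi = pd.Series(rng.uniform(20, 80, n), index=species)
            mls = 0.5 * bm + 0.5 * psi.to_numpy() + rng.normal(0, 2, n)
            d = bm_decompose("e", psi, self._traits_from(mls, bm, species))
            hits += d.category == "joint"
        assert hits / n_rep > 0.95

    def test_collinear_rejected(self):
        species = [f"s{i}" for i in range(12)]
        psi = pd.Series(np.linspace(10, 90, 12), index=species)
        traits = self._traits_from(
            np.linspace(2, 30, 12), psi.to_numpy(), species
        )
        with pytest.raises(ValueError, match="collinear"):
            bm_decompose("e", psi, traits)


class TestTissueSpecificity:
    def _assoc(self, rho, significant):
        return pd.DataFrame(
            {
                "rho": [rho],
                "significant": [significant],
            },
            index=pd.Index(["e"], name="event_id"),
        )

    def test_brain_divergent_flagged(self):
        tables = {"brain": self._assoc(0.8, True)}
        for t in ("heart", "kidney", "liver", "lung", "skin"):
            tables[t] = self._assoc(-0.3, False)
        spec = tissue_specificity(tables, focal_tissue="brain")
        assert bool(spec.loc["e", "divergent"])

    def test_same_sign_everywhere_not_divergent(self):
        tables = {t: self._assoc(0.8, True) for t in ("brain", "heart", "lung")}
        spec = tissue_specificity(tables, focal_tissue="brain")
        assert not bool(spec.loc["e", "divergent"])
        assert bool(spec.loc["e", "multi_tissue"])

    def test_single_tissue_without_opposing_evidence(self):
        tables = {
            "heart": self._assoc(0.8, True),
            "brain": pd.DataFrame(
                {"rho": [], "significant": []},
                index=pd.Index([], name="event_id"),
            ),
        }
        spec = tissue_specificity(tables, focal_tissue="brain")
        assert not bool(spec.loc["e", "divergent"])
        assert spec.loc["e", "tissues"] == "heart"


def test_upset_counts_groups_by_exact_tissue_combination():
    from splicespan.mls_assoc import upset_counts

    spec = pd.DataFrame(
        {"tissues": ["brain", "brain,heart", "brain,heart", "lung"]},
        index=["e1", "e2", "e3", "e4"],
    )
    counts = upset_counts(spec)
    assert counts["brain,heart"] == 2
    assert counts["brain"] == 1
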