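"""Partition summaries, drop-one ANOVA vs brute force, BH step-up, and the
model-derived sign-epistasis zone."""

import numpy as np
import numpy.linalg as la
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermlimit.epistasis import (
    RankDeficiencyError,
    benjamini_hochberg,
    classify_interaction,
    drop_one_anova,
    partition_by_genotype,
    sign_epistasis_zone,
)
from spermlimit.model import EggLayingParams, egg_rate


def bh_enumerated(p, q=0.05):
    """Literal step-up rule: largest k with p_(k) <= k q / m, reject the k
    smallest p-values (independent of any library implementation)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            kmax = k
    reject[order[:kmax]] = True
    return reject


class TestPartition:
    def test_single_class_grand_mean(self, hand_panel):
        y = pd.DataFrame(
            {"t1": np.arange(12.0)}, index=hand_panel.strains
        )
        geno = hand_panel.genotypes.copy()
        geno["cII_m02"] = 0  # monomorphic: everyone in one class
        from spermlimit.panel import RILPanel

        panel = RILPanel(genotypes=geno, gmap=hand_panel.gmap)
        out = partition_by_genotype(panel, y, ["cII_m02"])
        row = out[(out["g_cII_m02"] == 0)].iloc[0]
        assert row["mean"] == pytest.approx(np.arange(12.0).mean())
        empty = out[(out["g_cII_m02"] == 1)].iloc[0]
        assert empty["n"] == 0 and np.isnan(empty["mean"])

    def test_means_and_sems_match_hand_arithmetic(self, hand_panel):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=12)
        y = pd.DataFrame({"t1": vals}, index=hand_panel.strains)
        out = partition_by_genotype(hand_panel, y, ["cI_m00", "cII_m00"])
        g1 = hand_panel.genotypes["cI_m00"].to_numpy()
        g2 = hand_panel.genotypes["cII_m00"].to_numpy()
        for a in (0, 1):
            for b in (0, 1):
                sel = vals[(g1 == a) & (g2 == b)]
                row = out[
                    (out["g_cI_m00"] == a) & (out["g_cII_m00"] == b)
                ].iloc[0]
                assert row["n"] == sel.size
                assert row["mean"] == pytest.approx(sel.mean())
                if sel.size >= 2:
                    assert row["sem"] == pytest.approx(
                        sel.std(ddof=1) / np.sqrt(sel.size)
                    )

    def test_class_of_one_reports_mean_withholds_sem(self, tiny_map):
        from spermlimit.panel import RILPanel

        geno = pd.DataFrame(
            np.array([[1, 0, 0, 0, 0, 0]] + [[0] * 6] * 4, dtype=np.int8),
            index=[f"RIL{i:03d}" for i in range(5)],
            columns=tiny_map.markers,
        )
        panel = RILPanel(genotypes=geno, gmap=tiny_map)
        y = pd.DataFrame({"t1": [5.0, 1.0, 2.0, 3.0, 4.0]}, index=panel.strains)
        out = partition_by_genotype(panel, y, ["cI_m00"])
        lone = out[out["g_cI_m00"] == 1].iloc[0]
        assert lone["n"] == 1 and lone["mean"] == 5.0 and np.isnan(lone["sem"])


class TestDropOneAnova:
    @staticmethod
    def _brute_force_drop_one(panel, y, markers, focal):
        """Nested-regression F by explicit lstsq on the full/reduced models."""
        geno = panel.genotypes
        one = np.ones(len(y))
        gf = geno[focal].to_numpy(float)
        mains = {m: geno[m].to_numpy(float) for m in markers}
        ints = {m: mains[m] * gf for m in markers if m != focal}
        cols = [one] + [mains[m] for m in markers] + list(ints.values())
        X = np.column_stack(cols)

        def rss(Xm):
            beta, _, _, _ = la.lstsq(Xm, y, rcond=None)
            return float(np.sum((y - Xm @ beta) ** 2))

        rss_full = rss(X)
        dof = len(y) - X.shape[1]
        out = {}
        for m in markers:
            if m == focal:
                keep = [one] + [mains[k] for k in markers if k != focal]
                df1 = 1 + len(ints)
            else:
                keep = (
                    [one]
                    + [mains[k] for k in markers if k != m]
                    + [v for k, v in ints.items() if k != m]
                )
                df1 = 2
            rss_d = rss(np.column_stack(keep))
            out[m] = ((rss_d - rss_full) / df1) / (rss_full / dof)
        return out

    def test_f_matches_brute_force_nested_regression(self, hand_panel):
        rng = np.random.default_rng(1)
        y = rng.normal(size=12)
        markers = ["cI_m00", "cII_m00", "cII_m02"]
        tab = drop_one_anova(
            hand_panel,
            pd.DataFrame({"t1": y}, index=hand_panel.strains),
            markers,
            focal_marker="cI_m00",
        )
        oracle = self._brute_force_drop_one(hand_panel, y, markers, "cI_m00")
        for m, f_expect in oracle.items():
            got = tab[(tab["qtl"] == m)]["f_drop"].iloc[0]
            assert got == pytest.approx(f_expect, rel=1e-10)

    def test_null_qtl_rarely_significant(self):
        """A marker with no planted effect should survive FDR control."""
        from spermlimit.panel import generate_ril_genotypes

        n_sig = 0
        n_rep = 60
        for s in range(n_rep):
            panel = generate_ril_genotypes(40, seed=300 + s)
            rng = np.random.default_rng(400 + s)
            y = pd.DataFrame(
                {"t1": rng.normal(size=40)}, index=panel.strains
            )
            tab = drop_one_anova(
                panel, y, ["cII_m16", "cX_m16"], focal_marker="cII_m16"
            )
            n_sig += int((tab[~tab["is_focal"]]["q_drop"] < 0.05).any())
        assert n_sig <= 0.15 * n_rep

    def test_variance_explained_bounds(self, hand_panel):
        rng = np.random.default_rng(2)
        y = pd.DataFrame(
            {"t1": rng.normal(size=12), "t2": rng.normal(size=12)},
            index=hand_panel.strains,
        )
        tab = drop_one_anova(
            hand_panel, y, ["cI_m00", "cII_m00"], focal_marker="cI_m00"
        )
        assert ((tab["variance_explained"] >= 0) & (tab["variance_explained"] <= 1)).all()
        assert ((tab["p_drop"] >= 0) & (tab["p_drop"] <= 1)).all()

    def test_collinear_terms_rejected(self, hand_panel):
        y = pd.DataFrame({"t1": np.arange(12.0)}, index=hand_panel.strains)
        # cI_m02 duplicated via a map alias: same column twice is rank deficient
        geno = hand_panel.genotypes.copy()
        geno["cII_m01"] = geno["cI_m02"]
        from spermlimit.panel import RILPanel

        panel = RILPanel(genotypes=geno, gmap=hand_panel.gmap)
        with pytest.raises(RankDeficiencyError):
            drop_one_anova(
                panel, y, ["cI_m02", "cII_m01", "cI_m00"], focal_marker="cI_m00"
            )


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        reject, q = benjamini_hochberg([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert reject.tolist() == [True, True, True, False]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_enumerated_step_up_rule(self, pvals):
        reject, _ = benjamini_hochberg(pvals, alpha=0.05)
        assert reject.tolist() == bh_enumerated(pvals, 0.05).tolist()


class TestClassification:
    @pytest.mark.parametrize(
        "a,b,int_sig,eff_sig,label",
        [
            (2.0, 1.0, True, True, "positive epistasis"),
            (2.0, -1.0, True, True, "negative epistasis"),
            (2.0, 2.0, False, True, "additive"),
            (2.0, 2.0, False, False, "not significant"),
            (-0.5, -2.0, True, True, "positive epistasis"),
        ],
    )
    def test_direction_rules(self, a, b, int_sig, eff_sig, label):
        call = classify_interaction(
            a, b, interaction_significant=int_sig, effect_significant=eff_sig
        )
        assert call.label == label

    def test_zero_effect_boundary_flagged(self):
        call = classify_interaction(0.0, 1.0, interaction_significant=True)
        assert call.boundary and call.label == "positive epistasis"

    def test_non_finite_effect_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction(np.nan, 1.0, interaction_significant=True)


class TestSignEpistasisZone:
    def test_zone_nonempty_for_study_effect_sizes(self):
        z = sign_epistasis_zone(6.0, 5.2, -1.0, 263.0, 2.6e-4)
        assert not z.empty and z.t_open < z.t_close

    def test_contrasts_opposite_inside_same_outside(self):
        z = sign_epistasis_zone(6.0, 5.2, -1.0, 263.0, 2.6e-4)
        pm = z.class_params

        def contrasts(t):
            d0 = egg_rate(pm["mod"], t) - egg_rate(pm["base"], t)
            d1 = egg_rate(pm["focal+mod"], t) - egg_rate(pm["focal"], t)
            return d0, d1

        inside = contrasts(z.midpoint())
        assert np.sign(inside[0]) != np.sign(inside[1])
        # double difference (non-linearity) is nonzero inside the zone
        assert abs(inside[1] - inside[0]) > 0
        before = contrasts(0.5 * z.t_open)
        after = contrasts(z.t_close + 0.3 * (z.t_close - z.t_open))
        assert np.sign(before[0]) == np.sign(before[1])
        assert np.sign(after[0]) == np.sign(after[1])

    def test_zero_modifier_empty(self):
        assert sign_epistasis_zone(6.0, 5.2, 0.0, 263.0).empty

    def test_zero_focal_effect_crossings_coincide(self):
        z = sign_epistasis_zone(6.0, 0.0, -1.0, 263.0)
        assert z.empty

    def test_endpoints_continuous_in_modifier_effect(self):
        """Endpoints converge as the modifier effect shrinks (the zone tends
        to the window between the two backgrounds' sensitivity sign changes,
        not to a point, because the focal effect keeps the backgrounds apart)."""
        zones = [
            sign_epistasis_zone(6.0, 5.2, m, 263.0) for m in (-1.0, -0.5, -0.25)
        ]
        opens = [z.t_open for z in zones]
        closes = [z.t_close for z in zones]
        assert np.all(np.abs(np.diff(opens)) < 3.0)
        assert np.all(np.abs(np.diff(closes)) < 3.0)

    def test_nonpositive_class_rejected(self):
        with pytest.raises(ValueError):
            sign_epistasis_zone(2.0, -5.2, -1.0, 263.0)

    def test_classification_from_model_contrasts(self):
        """Inside the zone the model contrasts classify as negative epistasis,
        outside as positive."""
        z = sign_epistasis_zone(6.0, 5.2, -1.0, 263.0)
        pm = z.class_params

        def call_at(t):
            d0 = egg_rate(pm["mod"], t) - egg_rate(pm["base"], t)
            d1 = egg_rate(pm["focal+mod"], t) - egg_rate(pm["focal"], t)
            return classify_interaction(
                d0, d1, interaction_significant=True
            ).label

        assert call_at(z.midpoint()) == "negative epistasis"
        assert call_at(0.5 * z.t_open) == "positive epistasis"
        assert call_at(z.t_close + 10.0) == "positive epistasis"
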