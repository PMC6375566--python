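"""Nonparametric tests against brute-force oracles; zone, corpse and
diakinesis analyses."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from germscreen.cytostats import (corpse_analysis, diakinesis_tally,
                                  fisher_exact_two_sided,
                                  lethality_fractions,
                                  mann_whitney_two_tailed,
                                  significance_stars, zone_assign,
                                  zone_profile_compare)
from germscreen.presets import get_exposure, get_strain, vehicle_exposure
from germscreen.simkit import simulate_germline


# ---------------------------------------------------------------------------
# independent brute-force oracles

def mw_oracle_p(x, y):
    """Enumerate every relabeling of the pooled sample; two-tailed p of
    the U deviation from its null mean, mid-ranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    mean_u = n1 * n2 / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    d_obs = abs(u_of(range(n1)) - mean_u)
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - mean_u) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def fisher_oracle_p(a, b, c, d):
    """Sum exact multivariate-hypergeometric table probabilities over
    all tables with the observed margins, computed from factorials."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def table_p(k):
        # P(table) with margins fixed, via the hypergeometric formula
        return (math.comb(r1, k) * math.comb(n - r1, c1 - k)
                / math.comb(n, c1))

    p_obs = table_p(a)
    return sum(table_p(k)
               for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
               if table_p(k) <= p_obs * (1 + 1e-7))


# ---------------------------------------------------------------------------
# lethality

@pytest.mark.parametrize("counts, expected", [
    ((100, 100, 100), (0.0, 0.0)),
    ((200, 150, 120), (0.25, 0.2)),
])
def test_lethality_fractions(counts, expected):
    assert lethality_fractions(*counts) == pytest.approx(expected)


def test_lethality_undefined_denominators_are_nan():
    emb, larv = lethality_fractions(100, 0, 0)
    assert emb == 1.0 and math.isnan(larv)
    emb, larv = lethality_fractions(0, 0, 0)
    assert math.isnan(emb) and math.isnan(larv)


def test_lethality_rejects_unnested_counts():
    with pytest.raises(ValueError, match="nested"):
        lethality_fractions(10, 20, 5)


# ---------------------------------------------------------------------------
# Mann-Whitney

class TestMannWhitney:
    def test_complete_overlap_gives_p_one(self):
        res = mann_whitney_two_tailed([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0
        assert res.method == "exact"

    def test_small_separated_samples_exact_third(self):
        # all C(4,2)=6 labelings; 2 are as extreme as U=0
        res = mann_whitney_two_tailed([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.statistic == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # small integer samples force ties
        x = rng.integers(0, 6, size=rng.integers(3, 9))
        y = rng.integers(0, 6, size=rng.integers(3, 9))
        res = mann_whitney_two_tailed(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(mw_oracle_p(x, y), abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.poisson(3, 200)
        y = rng.poisson(3.5, 200)
        res = mann_whitney_two_tailed(x, y)
        assert res.method == "normal_approx"
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)

    @given(st.lists(st.integers(0, 8), min_size=3, max_size=7),
           st.lists(st.integers(0, 8), min_size=3, max_size=7),
           st.sampled_from(["exp", "cube", "affine"]))
    @settings(deadline=None, max_examples=30)
    def test_invariant_under_strictly_monotone_transforms(self, x, y, kind):
        f = {"exp": np.exp,
             "cube": lambda v: np.asarray(v, dtype=float) ** 3,
             "affine": lambda v: 2.5 * np.asarray(v, dtype=float) + 7}[kind]
        p0 = mann_whitney_two_tailed(x, y).p_value
        p1 = mann_whitney_two_tailed(f(np.array(x)), f(np.array(y))).p_value
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_two_tailed([], [1.0])


# ---------------------------------------------------------------------------
# Fisher exact

class TestFisherExact:
    def test_symmetric_table_gives_p_one(self):
        assert fisher_exact_two_sided(5, 5, 5, 5).p_value == \
            pytest.approx(1.0)

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_exact_two_sided(0, 10, 0, 12).p_value == \
            pytest.approx(1.0)

    def test_gonad_gap_table_significant(self):
        # gaps in pachytene: 16/53 exposed vs 6/55 vehicle gonads
        res = fisher_exact_two_sided(16, 37, 6, 49)
        assert res.p_value < 0.05
        assert res.p_value == pytest.approx(fisher_oracle_p(16, 37, 6, 49),
                                            rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_enumeration_oracle_and_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b, c, d = rng.integers(0, 15, size=4)
        res = fisher_exact_two_sided(a, b, c, d)
        assert res.p_value == pytest.approx(fisher_oracle_p(a, b, c, d),
                                            rel=1e-9)
        ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-6)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20))
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_transposition(self, a, b, c, d):
        p1 = fisher_exact_two_sided(a, b, c, d).p_value
        p2 = fisher_exact_two_sided(a, c, b, d).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_non_integer_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(1.5, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# zones

class TestZones:
    @pytest.mark.parametrize("pos, zone", [
        (0.0, 1), (0.999, 7), (1 / 7 - 1e-9, 1), (1 / 7, 2), (6 / 7, 7),
    ])
    def test_zone_assign(self, pos, zone):
        assert zone_assign(pos) == zone

    def test_zone_assign_rejects_out_of_range(self):
        for bad in (-0.01, 1.0, 1.5):
            with pytest.raises(ValueError):
                zone_assign(bad)

    def test_uniform_positions_fill_zones_evenly(self, rng):
        zones = [zone_assign(p) for p in rng.uniform(0, 1, 7000)]
        counts = np.bincount(zones, minlength=8)[1:]
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert stats.chi2.sf(chi2, df=6) > 1e-4

    def test_identical_inputs_give_all_p_one(self, screen_strain, vehicle):
        profiles = simulate_germline(screen_strain, vehicle, 5, rng=2)
        out = zone_profile_compare(profiles, profiles)
        assert np.allclose(out.p_value, 1.0)

    def test_exposure_elevates_only_meiotic_zones(self, screen_strain, dbp,
                                                  vehicle):
        exposed = simulate_germline(screen_strain, dbp, 8, rng=3)
        veh = simulate_germline(screen_strain, vehicle, 8, rng=4)
        out = zone_profile_compare(exposed, veh)
        meiotic = out[out.zone >= 4]
        mitotic = out[out.zone <= 2]
        assert (meiotic.p_value < 0.01).all()
        assert (meiotic.mean_exposed > meiotic.mean_vehicle).all()
        assert (mitotic.p_value > 0.05).all()

    def test_empty_zone_vector_rejected(self, screen_strain, vehicle):
        profiles = simulate_germline(screen_strain, vehicle, 3, rng=5)
        profiles[1].zone_foci[4] = np.array([])
        with pytest.raises(ValueError, match="empty"):
            zone_profile_compare(profiles, profiles)


# ---------------------------------------------------------------------------
# corpses

def corpse_frame(rng, n=35):
    rows = []
    for genotype in ("screen", "cep-1"):
        strain = get_strain(genotype)
        for cond in ("DMSO", "DBP"):
            exposure = get_exposure(cond)
            for i, p in enumerate(simulate_germline(strain, exposure, n,
                                                    rng)):
                rows.append((cond, genotype, i, p.corpse_count))
    return pd.DataFrame(rows, columns=["condition", "genotype", "gonad",
                                       "count"])


class TestCorpseAnalysis:
    def test_vehicle_fold_one_not_significant(self, rng):
        df = corpse_frame(rng)
        table, _ = corpse_analysis(df)
        veh = table[table.condition == "DMSO"]
        assert np.allclose(veh.fold_vs_vehicle, 1.0)
        assert (veh.p_value == 1.0).all()

    def test_dbp_doubles_corpses_and_is_cep1_dependent(self, rng):
        df = corpse_frame(rng)
        table, labels = corpse_analysis(df)
        row = table[(table.condition == "DBP")
                    & (table.genotype == "screen")].iloc[0]
        assert row.fold_vs_vehicle >= 2.0
        assert row.p_value < 0.01
        assert labels["DBP"] == "cep-1-dependent"

    def test_missing_genotype_arm_rejected(self, rng):
        df = corpse_frame(rng)
        df = df[~((df.condition == "DBP") & (df.genotype == "cep-1"))]
        with pytest.raises(ValueError, match="genotype arm"):
            corpse_analysis(df)

    def test_missing_vehicle_arm_rejected(self, rng):
        df = corpse_frame(rng)
        with pytest.raises(ValueError, match="vehicle"):
            corpse_analysis(df[df.condition != "DMSO"])


# ---------------------------------------------------------------------------
# diakinesis

class TestDiakinesisTally:
    def test_all_normal(self):
        tally = diakinesis_tally([(6, "normal")] * 10)
        assert tally["percent"]["normal"] == 100.0
        assert tally["modal_dapi_bodies"] == 6

    def test_toy_mixture_percentages(self):
        recs = [(8, "fragments")] * 2 + [(6, "bridges")] + \
            [(6, "normal")] * 7
        tally = diakinesis_tally(recs)
        assert tally["percent"] == pytest.approx(
            {"normal": 70.0, "fragments": 20.0, "bridges": 10.0,
             "frayed": 0.0})
        assert tally["n"] == 10

    def test_spo11_depleted_all_twelve_bodies(self, rng):
        profiles = simulate_germline(get_strain("spo-11-depleted"),
                                     get_exposure("TCMTB"), 30, rng)
        recs = [r for p in profiles for r in p.diakinesis]
        tally = diakinesis_tally(recs)
        assert tally["dapi_body_histogram"] == {12: len(recs)}

    def test_empty_and_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            diakinesis_tally([])
        with pytest.raises(ValueError, match="unknown defect class"):
            diakinesis_tally([(6, "weird")])


def test_significance_stars():
    assert [significance_stars(p) for p in (0.2, 0.04, 0.009, 0.0005)] == \
        ["ns", "*", "**", "***"]
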