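"""Group statistics: gated omnibus, pairwise post-hocs, compact letters, report."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epiderm.params import AGE_GROUPS, LAYER_COUNT_TABLE
from epiderm.stats import (
    NO_LETTER,
    ZeroVarianceError,
    build_report,
    compact_letters,
    compare_groups,
    dunn_pairwise,
    nemenyi_pairwise,
    omnibus,
    pairwise_letters,
)


def draw_groups(rng, means, sd=1.0, n=20, dist="normal"):
    out = {}
    for i, m in enumerate(means):
        if dist == "normal":
            out[f"g{i}"] = rng.normal(m, sd, n)
        else:
            out[f"g{i}"] = np.exp(rng.normal(np.log(max(m, 0.1)), 0.8, n))
    return out


class TestOmnibus:
    def test_separated_groups_reject_strongly(self):
        rng = np.random.default_rng(1)
        g = draw_groups(rng, [0, 10, 20], sd=1.0)
        assert omnibus(g).pvalue < 1e-6

    def test_normal_data_selects_anova_in_majority(self):
        rng = np.random.default_rng(2)
        picks = [omnibus(draw_groups(rng, [0] * 5)).test for _ in range(100)]
        assert picks.count("ANOVA") > 80

    def test_heavy_tailed_data_selects_kruskal_wallis_in_majority(self):
        rng = np.random.default_rng(3)
        picks = [omnibus(draw_groups(rng, [1] * 5, dist="lognormal")).test for _ in range(100)]
        assert picks.count("Kruskal-Wallis") > 80

    def test_constant_data_raises(self):
        with pytest.raises(ZeroVarianceError):
            omnibus({"a": [3.0, 3.0, 3.0], "b": [3.0, 3.0, 3.0]})

    def test_minimum_group_sizes_enforced(self):
        with pytest.raises(ValueError):
            omnibus({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestPosthocOracles:
    """Dunn and Nemenyi reduce to the asymptotic Mann-Whitney test for two
    groups (same pooled midranks and tie-corrected variance): scipy provides
    that reference independently."""

    @pytest.mark.parametrize("round_to", [None, 1])  # rounding forces ties
    def test_two_group_dunn_equals_mann_whitney(self, round_to):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.9, 1, 15)
        if round_to is not None:
            a, b = a.round(round_to), b.round(round_to)
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert dunn_pairwise({"a": a, "b": b}, adjust=None).loc["a", "b"] == pytest.approx(
            ref, rel=1e-12
        )
        assert nemenyi_pairwise({"a": a, "b": b}).loc["a", "b"] == pytest.approx(
            ref, rel=1e-9
        )

    def test_holm_adjustment_is_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        g = draw_groups(rng, [0, 0.5, 1.5, 3.0], n=15)
        raw = dunn_pairwise(g, adjust=None)
        adj = dunn_pairwise(g, adjust="holm")
        for a, b in itertools.combinations(g, 2):
            assert adj.loc[a, b] >= raw.loc[a, b] - 1e-15
            assert adj.loc[a, b] <= 1.0


class TestLetters:
    def test_two_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(4)
        g = {"young": rng.normal(0, 1, 20), "old": rng.normal(8, 1, 20)}
        res = pairwise_letters(g, "ANOVA", omnibus_p=1e-9)
        assert {res.letters["young"], res.letters["old"]} == {"a", "b"}
        assert res.letters["young"] == "a"  # smallest mean anchored to 'a'

    def test_identical_groups_forced_through_all_share_a(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 20)
        g = {f"g{i}": base + rng.normal(0, 1e-3, 20) for i in range(5)}
        res = pairwise_letters(g, "ANOVA", force=True)
        assert all(v == "a" for v in res.letters.values())

    def test_gate_returns_dashes_when_omnibus_not_significant(self):
        rng = np.random.default_rng(6)
        g = draw_groups(rng, [0] * 5)
        res = pairwise_letters(g, "ANOVA", omnibus_p=0.4)
        assert all(v == NO_LETTER for v in res.letters.values())
        assert res.pvalues is None

    @pytest.mark.parametrize("seed", range(25))
    def test_consistency_on_random_p_matrices(self, seed):
        """Sharing a letter must be equivalent to a non-significant pair,
        for arbitrary (even non-transitive) significance patterns."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        names = [f"g{i}" for i in range(k)]
        m = pd.DataFrame(np.eye(k) * 0 + 1.0, index=names, columns=names)
        for a, b in itertools.combinations(range(k), 2):
            p = float(rng.uniform(0, 1))
            m.iloc[a, b] = m.iloc[b, a] = p
        means = {n: float(rng.normal()) for n in names}
        letters = compact_letters(m, means, alpha=0.3)  # internal assert runs
        for a, b in itertools.combinations(names, 2):
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (m.loc[a, b] >= 0.3)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        g = draw_groups(rng, [0, 1, 4, 4.2], n=18)
        res = pairwise_letters(g, "ANOVA", omnibus_p=1e-6)
        perm = {"g0": "b0", "g1": "b1", "g2": "b2", "g3": "b3"}
        g2 = {perm[k]: v for k, v in g.items()}
        res2 = pairwise_letters(g2, "ANOVA", omnibus_p=1e-6)
        for a, b in itertools.combinations(g, 2):
            share1 = bool(set(res.letters[a]) & set(res.letters[b]))
            share2 = bool(set(res2.letters[perm[a]]) & set(res2.letters[perm[b]]))
            assert share1 == share2


class TestEndpointDiscrimination:
    def test_mandible_layer_cohorts_separate_youngest_and_oldest(self):
        """Replicate cohorts drawn from the mandible layer-number parameters
        (n = 20/group): in the majority of replicates the youngest and oldest
        groups share no letter, reproducing the endpoint discrimination of
        the reference table's letter pattern."""
        rows = LAYER_COUNT_TABLE["mandible"]["layers"]
        rng = np.random.default_rng(99)
        separated = 0
        n_rep = 200
        for _ in range(n_rep):
            g = {
                grp: rng.normal(m, sd, 20) for grp, (m, sd) in zip(AGE_GROUPS, rows)
            }
            comp = compare_groups(g)
            young, old = AGE_GROUPS[0], AGE_GROUPS[-1]
            if comp.letters[young] != NO_LETTER and not (
                set(comp.letters[young]) & set(comp.letters[old])
            ):
                separated += 1
        assert separated > n_rep / 2


class TestReport:
    def _table(self):
        rng = np.random.default_rng(11)
        rows = []
        for site in ("temple", "mandible"):
            for metric, mus in (("sc_thickness", [13, 13.4, 13.5, 13.7, 14.2]),
                                ("csd_M5", [2900, 2800, 2750, 2700, 2600])):
                for grp, mu in zip(AGE_GROUPS, mus):
                    for i in range(8):
                        rows.append(
                            {
                                "subject": f"{site}-{grp}-{i}",
                                "site": site,
                                "age_group": grp,
                                "metric": metric,
                                "value": rng.normal(mu, abs(mu) * 0.02),
                            }
                        )
        return pd.DataFrame(rows)

    def test_row_inventory_and_determinism(self):
        table = self._table()
        rep1 = build_report(table, group_order=AGE_GROUPS)
        rep2 = build_report(table, group_order=AGE_GROUPS)
        assert len(rep1.frame) == 2 * 2 * 5  # site x metric x group
        assert rep1.to_text() == rep2.to_text()
        assert set(rep1.frame["metric"]) == {"sc_thickness", "csd_M5"}

    def test_missing_group_reported_na_and_excluded(self):
        table = self._table()
        table = table[~((table.site == "temple") & (table.age_group == "[41,50]"))]
        rep = build_report(table, group_order=AGE_GROUPS)
        row = rep.frame[
            (rep.frame.site == "temple")
            & (rep.frame.metric == "sc_thickness")
            & (rep.frame.age_group == "[41,50]")
        ].iloc[0]
        assert row["n"] == 0 and np.isnan(row["mean"])
        assert row["letters"] == NO_LETTER

    def test_duplicate_rows_rejected(self):
        table = self._table()
        with pytest.raises(ValueError, match="exactly once"):
            build_report(pd.concat([table, table.iloc[:1]]))

    def test_letters_consistent_with_pairwise_matrix(self):
        table = self._table()
        rep = build_report(table, group_order=AGE_GROUPS)
        for comp in rep.comparisons.values():
            if comp.pairwise_p is None:
                continue
            for a, b in itertools.combinations(comp.pairwise_p.index, 2):
                share = bool(set(comp.letters[a]) & set(comp.letters[b]))
                assert share == (comp.pairwise_p.loc[a, b] >= comp.alpha)
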