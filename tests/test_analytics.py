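"""Single-mark deconvolution, interplay scores, and replicate statistics."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from middledown.analytics import (
    MarkKey,
    compare_single_mark_tables,
    cv_by_mark,
    cv_grouped,
    heavy_fraction,
    hybrid_marks,
    interplay,
    interplay_table,
    replicate_correlation,
    single_mark_table,
    single_ptm_abundance,
)
from middledown.model import NotationError


def table(*items, channel="light", sample="s1"):
    df = pd.DataFrame(
        [
            {"tail": "H3_1_50", "proteoform": pf, "channel": channel,
             "sample": sample, "intensity": ab * 1000, "relative_abundance": ab}
            for pf, ab in items
        ]
    )
    assert abs(df["relative_abundance"].sum() - 1.0) < 1e-9
    return df


class TestMarkKey:
    @pytest.mark.parametrize(
        "s, heavy",
        [("K27me2", 0), ("K27me2:1", 1), ("K27me2:*", None)],
    )
    def test_parse_heavy_forms(self, s, heavy):
        k = MarkKey.parse(s)
        assert (k.site, k.kind, k.heavy) == (27, "me2", heavy)
        assert str(k) == s

    @pytest.mark.parametrize("s", ["K27me4", "K27me2:3", "notamark", "K27"])
    def test_parse_rejects(self, s):
        with pytest.raises((NotationError, ValueError)):
            MarkKey.parse(s)


class TestSingleMark:
    def test_summed_over_combinatorial_forms(self):
        t = table(("K9me2K27me1", 0.5), ("K27me1", 0.3), ("", 0.2))
        assert single_ptm_abundance(t, "K27me1") == pytest.approx(0.8)
        assert single_ptm_abundance(t, "K9me2") == pytest.approx(0.5)

    def test_unmodified_table_gives_zero(self):
        t = table(("", 1.0))
        assert single_ptm_abundance(t, "K27me1") == 0.0

    def test_remainder_is_unmodified_share(self):
        t = table(("K27me1", 0.7), ("", 0.3))
        modified = single_ptm_abundance(t, "K27me1")
        assert 1 - modified == pytest.approx(0.3)

    def test_wildcard_aggregates_heavy_variants(self):
        t = table(("K27me2", 0.4), ("K27me2:1", 0.25), ("K27me2:2", 0.1), ("", 0.25))
        assert single_ptm_abundance(t, "K27me2") == pytest.approx(0.4)
        assert single_ptm_abundance(t, "K27me2:1") == pytest.approx(0.25)
        assert single_ptm_abundance(t, "K27me2:*") == pytest.approx(0.75)

    def test_single_mark_table_long_format(self):
        t = table(("K27me2", 0.6), ("", 0.4))
        out = single_mark_table(t)
        assert out.loc[out["mark"] == "K27me2", "abundance"].item() == pytest.approx(0.6)


class TestHeavyFraction:
    def test_counts_any_heavy_methyl(self):
        t = table(("K27me2:1", 0.3), ("K27me2", 0.7))
        assert heavy_fraction(t) == pytest.approx(0.3)

    def test_zero_when_all_light_and_one_when_all_heavy(self):
        assert heavy_fraction(table(("K27me2", 1.0))) == 0.0
        assert heavy_fraction(table(("K27me2:2", 0.6), ("K9me1:1", 0.4))) == pytest.approx(1.0)


class TestHybridMarks:
    def test_fully_light_or_fully_heavy_excluded(self):
        t = table(("K27me3:3", 0.5), ("K9me1:1", 0.3), ("K27me3", 0.2))
        assert hybrid_marks(t) == []

    def test_sorted_by_abundance(self):
        t = table(("K27me3:1", 0.4), ("K36me2:1", 0.1), ("", 0.5))
        out = hybrid_marks(t)
        assert [(str(k), pytest.approx(v)) for k, v in out] == [
            ("K27me3:1", 0.4),
            ("K36me2:1", 0.1),
        ]


class TestInterplay:
    def test_perfect_cooccurrence_scores_one(self):
        t = table(("K9me2K27me1", 0.5), ("", 0.5))
        r = interplay(t, "K9me2", "K27me1")
        assert (r.f_a, r.f_b, r.f_ab) == (0.5, 0.5, 0.5)
        assert r.score == pytest.approx(1.0)
        assert r.defined

    def test_exclusive_pair_flagged_not_inf(self):
        t = table(("K9me2", 0.5), ("K27me1", 0.5))
        r = interplay(t, "K9me2", "K27me1")
        assert not r.defined and math.isnan(r.score)

    def test_same_site_pair_rejected(self):
        t = table(("K27me1", 1.0))
        with pytest.raises(ValueError, match="site"):
            interplay(t, "K27me1", "K27me2")

    def test_independent_product_table_scores_zero(self):
        # exact product marginals: P(a)=0.4, P(b)=0.3, independent
        t = table(
            ("K9me2K27me1", 0.12),
            ("K9me2", 0.28),
            ("K27me1", 0.18),
            ("", 0.42),
        )
        r = interplay(t, "K9me2", "K27me1")
        assert r.score == pytest.approx(0.0, abs=1e-12)

    def test_fab_bounded_by_marginals(self):
        t = table(
            ("K9me2K27me1", 0.2),
            ("K9me2", 0.3),
            ("K27me1", 0.1),
            ("", 0.4),
        )
        out = interplay_table(t)
        assert (out["f_ab"] <= out[["f_a", "f_b"]].min(axis=1) + 1e-12).all()


class TestReplicateStats:
    def test_identical_and_antiproportional_vectors(self):
        r, p = replicate_correlation([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)
        r, _ = replicate_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = replicate_correlation([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.98198, abs=1e-5)
        # p from t = r*sqrt((n-2)/(1-r^2)), 1 df, two-tailed
        assert 0 < p < 0.2

    def test_zero_variance_flagged(self):
        r, p = replicate_correlation([1, 1, 1], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)

    def test_cv_hand_example(self):
        t1 = table(("K27me2", 0.2), ("", 0.8))
        t2 = table(("K27me2", 0.3), ("", 0.7))
        out = cv_by_mark([t1, t2], keys=["K27me2"])
        assert out.loc[0, "cv"] == pytest.approx(0.2828, abs=1e-4)

    def test_identical_replicates_zero_cv(self):
        t = table(("K27me2", 0.5), ("", 0.5))
        out = cv_by_mark([t, t.copy()])
        assert (out["cv"].dropna() == 0).all()

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            cv_by_mark([table(("K27me2", 1.0))])

    def test_cv_grouping_by_site_and_kind(self):
        t1 = table(("K27me2", 0.2), ("K9me2", 0.3), ("", 0.5))
        t2 = table(("K27me2", 0.3), ("K9me2", 0.3), ("", 0.4))
        out = cv_by_mark([t1, t2])
        by_site = cv_grouped(out, "site")
        assert by_site.loc[9] == pytest.approx(0.0)
        assert by_site.loc[27] > 0
        assert set(cv_grouped(out, "kind").index) == {"me2"}


class TestCompareTables:
    def test_identity_and_scaling(self):
        t1 = pd.Series({"K9me2": 0.2, "K27me2": 0.5, "K36me1": 0.3})
        slope, r, _ = compare_single_mark_tables(t1, t1)
        assert slope == pytest.approx(1.0) and r == pytest.approx(1.0)
        slope, r, _ = compare_single_mark_tables(t1, 2 * t1)
        assert slope == pytest.approx(2.0) and r == pytest.approx(1.0)

    def test_independent_tables_low_correlation(self):
        rng = np.random.default_rng(5)
        marks = [f"K{i}me1" for i in (4, 9, 14, 18, 23, 27, 36)]
        x = pd.Series(rng.uniform(size=50), index=[f"m{i}" for i in range(50)])
        y = pd.Series(rng.uniform(size=50), index=x.index)
        _, r, _ = compare_single_mark_tables(x, y)
        from scipy.stats import pearsonr

        ref_r, _ = pearsonr(x, y)
        assert r == pytest.approx(ref_r, abs=1e-12)
        assert abs(r) < 0.4

    def test_too_few_shared_keys_rejected(self):
        a = pd.Series({"K9me2": 0.1, "K27me2": 0.2})
        with pytest.raises(ValueError):
            compare_single_mark_tables(a, a)
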