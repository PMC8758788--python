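"""miRNA qPCR normalization, testing and selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ladscape.qpcr import CtMatrix, normalize_ct, select_mirnas
from ladscape.qpcr import test_and_rank as rank_assays


def mk_ct(values, assays=None, groups=None, hk=("hk_0",)):
    values = np.asarray(values, dtype=float)
    assays = assays or [f"a{i}" for i in range(values.shape[0] - len(hk))] + list(hk)
    plates = [f"p{i}" for i in range(values.shape[1])]
    half = len(plates) // 2
    groups = groups or {p: ("control" if i < half else "knockout")
                        for i, p in enumerate(plates)}
    return CtMatrix(pd.DataFrame(values, index=assays, columns=plates),
                    groups=groups, housekeeping_ids=list(hk))


class TestNormalizeCt:
    def test_delta_ct_against_housekeeping(self):
        # housekeeping Cts {20, 20}: target 25 -> delta-Ct 5 on every plate
        ct = mk_ct(
            [[25.0] * 4, [20.0] * 4, [20.0] * 4],
            assays=["t", "hk_0", "hk_1"],
            hk=("hk_0", "hk_1"),
        )
        out = normalize_ct(ct)
        assert np.allclose(out.values.loc["t"], 5.0)

    def test_identical_multisets_unchanged_by_quantile_step(self):
        # both plates hold the same value multiset (after delta-Ct), so
        # quantile normalization is a within-plate rank relabelling
        ct = mk_ct([[22.0, 25.0], [25.0, 22.0], [28.0, 28.0], [20.0, 20.0]],
                   assays=["a", "b", "c", "hk_0"])
        out = normalize_ct(ct)
        for col in out.values.columns:
            assert np.allclose(sorted(out.values.loc[["a", "b", "c"], col]), [2.0, 5.0, 8.0])

    def test_three_plate_hand_oracle(self):
        # hand-computed quantile normalization of a 3x4 (assay x plate)
        # delta-Ct matrix: housekeeping row is exactly 20 on every plate
        # so delta-Ct just subtracts 20; sorted columns are then
        # p0: (1,2,6), p1: (0,3,4), p2: (2,4,9); order-statistic means
        # (1, 3, 19/3); each value maps to the mean of its rank.
        vals = np.array([
            [22.0, 23.0, 24.0],
            [21.0, 20.0, 22.0],
            [26.0, 24.0, 29.0],
            [20.0, 20.0, 20.0],
        ])
        out = normalize_ct(mk_ct(vals, assays=["a", "b", "c", "hk_0"])).values
        want = np.array([
            [3.0, 3.0, 3.0],
            [1.0, 1.0, 1.0],
            [19 / 3, 19 / 3, 19 / 3],
        ])
        assert np.allclose(out.loc[["a", "b", "c"]].to_numpy(), want)

    def test_all_missing_housekeeping_names_plate(self):
        vals = np.array([[25.0, 25.0], [20.0, np.nan]])
        ct = mk_ct(vals, assays=["t", "hk_0"])
        with pytest.raises(ValueError, match="p1"):
            normalize_ct(ct)

    def test_plate_order_invariance(self):
        vals = np.array([[22.0, 24.0, 23.0, 26.0], [21.0, 25.0, 24.0, 22.0],
                         [20.0, 20.0, 20.0, 20.0]])
        ct = mk_ct(vals, assays=["a", "b", "hk_0"])
        out1 = normalize_ct(ct).values
        perm = ["p2", "p0", "p3", "p1"]
        ct2 = CtMatrix(ct.values[perm], groups=ct.groups, housekeeping_ids=["hk_0"])
        out2 = normalize_ct(ct2).values
        assert np.allclose(out1[perm].to_numpy(), out2.to_numpy())


def normalized(vals, assays):
    """A CtMatrix of already-normalized delta-Ct values (hk row inert)."""
    ct = mk_ct(vals, assays=assays)
    return CtMatrix(ct.values, ct.groups, ct.housekeeping_ids, normalized=True)


class TestTestAndRank:
    def test_matches_closed_form_t(self):
        # toy 2x3 delta-Ct data checked against the closed-form t
        ctrl, ko = np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0])
        vals = np.vstack([np.concatenate([ctrl, ko]), np.full(6, 20.0)])
        res = rank_assays(normalized(vals, ["t", "hk_0"]))[0]
        t_ref, p_ref = stats.ttest_ind(ko, ctrl)
        assert res.t_stat == pytest.approx(float(t_ref))
        assert res.t_stat == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert res.p_value == pytest.approx(float(p_ref))
        assert res.ddct == pytest.approx(-3.0)
        assert res.fold_change == pytest.approx(8.0)  # 2^3, up in knockout

    def test_identical_groups_p_one(self):
        vals = np.vstack([np.full(6, 25.0), np.full(6, 20.0)])
        res = rank_assays(normalize_ct(mk_ct(vals, assays=["t", "hk_0"])))[0]
        assert res.p_value == 1.0 and res.fold_change == pytest.approx(1.0)

    def test_zero_variance_distinct_means_flagged(self):
        vals = np.vstack([[5.0, 5.0, 5.0, 4.0, 4.0, 4.0], np.full(6, 20.0)])
        res = rank_assays(normalized(vals, ["t", "hk_0"]))[0]
        assert res.zero_variance and res.p_value == 0.0

    def test_needs_two_plates_per_group(self):
        vals = np.vstack([[25.0, 24.0], np.full(2, 20.0)])
        with pytest.raises(ValueError, match="2 plates"):
            rank_assays(mk_ct(vals, assays=["t", "hk_0"]))


class TestSelectMirnas:
    def mk_results(self, n, fcs=()):
        rng = np.random.default_rng(0)
        vals = np.vstack([
            np.concatenate([25 + rng.normal(0, 0.05, 3),
                            25 + rng.normal(0, 0.05, 3) - np.log2(fc) if i < len(fcs) else
                            25 + rng.normal(0, 0.05, 3)])
            for i, fc in enumerate(list(fcs) + [1.0] * (n - len(fcs)))
        ] + [np.full(6, 20.0)])
        assays = [f"a{i:02d}" for i in range(n)] + ["hk_0"]
        return rank_assays(normalize_ct(mk_ct(vals, assays=assays)))

    def test_rank_cutoff_ceiling(self):
        res = self.mk_results(20)
        sel = select_mirnas(res, top_frac=0.15)
        assert sel["rank_cutoff"] == 3

    def test_fold_change_boundary_inclusive(self):
        res = self.mk_results(6, fcs=(2.0,))
        # the planted assay has fold ~2.0; force exact boundary
        target = next(r for r in res if r.assay_id == "a00")
        target.fold_change = 2.0
        sel = select_mirnas(res, top_frac=0.0)
        assert target.selected and target.reason == "fold_change"

    def test_selection_monotone_in_fold(self):
        res = self.mk_results(10, fcs=(4.0, 2.5))
        select_mirnas(res, top_frac=0.0)
        selected_fc = {r.fold_change for r in res if r.selected}
        unselected_fc = {r.fold_change for r in res if not r.selected}
        if selected_fc and unselected_fc:
            assert min(abs(np.log2(f)) for f in selected_fc) >= max(
                abs(np.log2(f)) for f in unselected_fc
            )

    def test_reason_union_semantics(self):
        res = self.mk_results(10, fcs=(8.0,))
        sel = select_mirnas(res, top_frac=0.15)
        top = next(r for r in res if r.rank == 1)
        assert top.reason in ("both", "top_rank")
        assert sel["n_selected"] == len(sel["up"]) + len(sel["down"])
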