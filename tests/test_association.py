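"""Occurrence thresholding, permutation chi-square, FDR, selection, shifts."""

import numpy as np
import pandas as pd
import pytest

from nursepart.core_data import AbundanceTable
from nursepart.association import (
    associate,
    chi_square,
    fdr_adjust,
    occurrence_counts,
    permutation_test,
    select_plant_associated,
    taxon_shift_test,
    OccurrenceTable,
)
from nursepart.errors import ValidationError

HABS = ("xGb", "xGc", "xCb", "xCc", "lCb", "lCc")


def _rel_table(values, ids):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        pd.DataFrame(values, index=ids, columns=[f"m{j}" for j in range(values.shape[1])]),
        mode="relative",
    )


def _uniform_habitats(n_per, habs=HABS):
    out = {}
    for h in habs:
        for k in range(n_per):
            out[f"{h}_{k}"] = h
    return out


class TestOccurrence:
    def test_strict_threshold_boundary(self):
        ids = ["xGb_0", "xGc_0"]
        table = _rel_table([[0.001, 0.999], [0.0011, 0.9989]], ids)
        occ = occurrence_counts(table, {s: s.rsplit("_", 1)[0] for s in ids})
        # exactly 0.1% is NOT an occurrence; 0.11% is
        assert occ.counts.loc["m0", "xGb"] == 0
        assert occ.counts.loc["m0", "xGc"] == 1

    def test_absent_motu_all_zero(self):
        habs = _uniform_habitats(2)
        ids = list(habs)
        vals = np.column_stack([np.zeros(len(ids)), np.ones(len(ids))])
        occ = occurrence_counts(_rel_table(vals, ids), habs)
        assert (occ.counts.loc["m0"] == 0).all()

    def test_known_pattern(self):
        habs = _uniform_habitats(3)
        ids = list(habs)
        vals = np.column_stack(
            [[0.5 if habs[s] == "xGc" else 0.0 for s in ids],
             [0.5 if habs[s] == "xGc" else 1.0 for s in ids]]
        )
        occ = occurrence_counts(_rel_table(vals, ids), habs)
        assert occ.counts.loc["m0", "xGc"] == 3
        assert occ.counts.loc["m0"].drop("xGc").sum() == 0

    def test_occurrence_cannot_exceed_size(self):
        counts = pd.DataFrame({"h1": [3], "h2": [0]}, index=["m0"])
        sizes = pd.Series({"h1": 2, "h2": 2})
        with pytest.raises(ValidationError, match="exceeds"):
            OccurrenceTable(counts, sizes, 0.001)


class TestChiSquare:
    def test_textbook_two_habitat(self):
        # sizes (10,10), present (10,0): classic 2x2 gives chi2 = 20
        occ = OccurrenceTable(
            pd.DataFrame({"h1": [10], "h2": [0]}, index=["m0"]),
            pd.Series({"h1": 10, "h2": 10}),
            0.001,
        )
        out = chi_square(occ)
        assert out.loc["m0", "chi2"] == pytest.approx(20.0, abs=1e-12)

    def test_equal_proportions_zero(self):
        occ = OccurrenceTable(
            pd.DataFrame({"h1": [4], "h2": [2]}, index=["m0"]),
            pd.Series({"h1": 8, "h2": 4}),
            0.001,
        )
        out = chi_square(occ)
        assert out.loc["m0", "chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["m0", "residual_h1"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_margins_flagged(self):
        occ = OccurrenceTable(
            pd.DataFrame({"h1": [5, 0], "h2": [5, 0]}, index=["all", "none"]),
            pd.Series({"h1": 5, "h2": 5}),
            0.001,
        )
        out = chi_square(occ)
        assert (out["chi2"] == 0).all()
        assert out["degenerate"].all()

    def test_matches_brute_force_on_random_tables(self):
        # independent textbook computation: explicit 2xh expected counts
        rng = np.random.default_rng(21)
        for _ in range(200):
            h = rng.integers(2, 7)
            sizes = rng.integers(2, 12, h)
            present = np.array([rng.integers(0, s + 1) for s in sizes])
            if present.sum() in (0, sizes.sum()):
                continue
            occ = OccurrenceTable(
                pd.DataFrame([present], index=["m0"], columns=[f"h{j}" for j in range(h)]),
                pd.Series(sizes, index=[f"h{j}" for j in range(h)]),
                0.001,
            )
            out = chi_square(occ)
            table = np.vstack([present, sizes - present]).astype(float)
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            chi2 = ((table - expected) ** 2 / expected).sum()
            assert out.loc["m0", "chi2"] == pytest.approx(chi2, abs=1e-9)
            resid = (table[0] - expected[0]) / np.sqrt(expected[0])
            for j in range(h):
                assert out.loc["m0", f"residual_h{j}"] == pytest.approx(resid[j], abs=1e-9)


class TestPermutationTest:
    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(22)
        habs = _uniform_habitats(4)
        ids = list(habs)
        vals = rng.uniform(0, 1, (len(ids), 5))
        vals /= vals.sum(axis=1, keepdims=True)
        table = _rel_table(vals, ids)
        a = permutation_test(table, habs, B=99, seed=7)
        b = permutation_test(table, habs, B=99, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_motu_p_one(self):
        habs = _uniform_habitats(3)
        ids = list(habs)
        vals = np.column_stack([np.full(len(ids), 0.4), np.full(len(ids), 0.6)])
        out = permutation_test(_rel_table(vals, ids), habs, B=49, seed=1)
        assert (out["p_perm"] == 1.0).all()

    def test_extreme_statistic_minimal_p(self):
        # one habitat fully occupied, others empty, many samples: observed
        # chi2 should beat every permutation
        habs = _uniform_habitats(8, habs=("xGc", "xGb", "xCb"))
        ids = list(habs)
        vals = np.column_stack(
            [[0.5 if habs[s] == "xGc" else 1e-9 for s in ids],
             [1 - (0.5 if habs[s] == "xGc" else 1e-9) for s in ids]]
        )
        B = 199
        out = permutation_test(_rel_table(vals, ids), habs, B=B, seed=3)
        assert out.loc["m0", "p_perm"] == pytest.approx(1 / (B + 1))

    def test_site_level_unit_is_conservative_under_site_correlation(self, small_dataset):
        # with strong within-site correlation, permuting whole sites should
        # not flag more MOTUs than permuting individual samples
        from nursepart.core_data import assign_habitats, filter_table, to_relative

        table = to_relative(filter_table(small_dataset["abundance"]))
        habitats = assign_habitats(small_dataset["metadata"])
        sites = small_dataset["metadata"].data["site"].to_dict()
        by_sample = permutation_test(table, habitats, B=199, seed=8)
        by_site = permutation_test(table, habitats, B=199, seed=8, unit="sites", sites=sites)
        assert (by_site["p_perm"] < 0.05).sum() <= (by_sample["p_perm"] < 0.05).sum()
        with pytest.raises(ValidationError, match="site"):
            permutation_test(table, habitats, B=9, unit="sites")

    def test_null_calibration(self):
        # exchangeable labels: raw p < 0.05 for ~5% of null MOTUs
        rng = np.random.default_rng(23)
        habs = _uniform_habitats(15)
        ids = list(habs)
        n_motus = 500
        prev = rng.uniform(0.2, 0.8, n_motus)
        occ = rng.uniform(size=(len(ids), n_motus)) < prev
        vals = np.where(occ, 0.0015, 0.0)
        vals = np.column_stack([vals, 1 - vals.sum(axis=1)])
        table = _rel_table(vals, ids)
        out = permutation_test(table, habs, B=999, seed=5)
        frac = (out["p_perm"].iloc[:n_motus] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        p_adj = fdr_adjust(out["p_perm"].iloc[:n_motus].to_numpy())
        assert (p_adj < 0.05).mean() <= 0.07


class TestFDR:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(24)
        p = rng.uniform(0, 1, 50)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(25)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 20))
            m = len(p)
            order = np.argsort(p)
            ranked = p[order] * m / (np.arange(m) + 1)
            stepped = np.minimum.accumulate(ranked[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-9)


class TestSelection:
    def _frame(self, p_adj, residuals):
        row = {"p_adj": p_adj}
        row.update({f"residual_{h}": r for h, r in zip(HABS, residuals)})
        return pd.DataFrame([row], index=["m0"])

    def test_selected_with_driver(self):
        out = select_plant_associated(self._frame(0.001, [-1, 3.1, 0, 0, 0, 0]))
        assert bool(out.loc["m0", "selected"])
        assert out.loc["m0", "driving_habitats"] == "xGc"

    def test_bare_residual_blocks(self):
        out = select_plant_associated(self._frame(0.001, [2.5, 3.0, 0, 0, 0, 0]))
        assert not bool(out.loc["m0", "selected"])

    def test_nonsignificant_blocks(self):
        out = select_plant_associated(self._frame(0.06, [0, 5.0, 0, 0, 0, 0]))
        assert not bool(out.loc["m0", "selected"])

    def test_monotone_in_residual_cut(self):
        # raising the cut never adds a MOTU while the bare-habitat exclusion
        # is not in play (bare residuals below every cut considered)
        rng = np.random.default_rng(26)
        rows = []
        for _ in range(40):
            resid = rng.normal(0, 2, 6)
            resid[[0, 2, 4]] = rng.uniform(-2, 0.5, 3)  # bare habitats stay low
            rows.append(self._frame(rng.uniform(0, 0.1), resid))
        frames = pd.concat(rows)
        frames.index = [f"m{k}" for k in range(40)]
        selected = None
        for cut in (1.0, 2.0, 3.0):
            out = select_plant_associated(frames, residual_cut=cut)
            current = set(out.index[out["selected"]])
            if selected is not None:
                assert current <= selected
            selected = current

    def test_borderline_bare_residual_reappears_at_higher_cut(self):
        # the joint rule is deliberately two-sided: a bare residual of 2.5
        # blocks selection at cut 2 but no longer blocks at cut 3
        frame = self._frame(0.001, [2.5, 4.0, 0, 0, 0, 0])
        assert not select_plant_associated(frame, residual_cut=2.0)["selected"].iloc[0]
        assert select_plant_associated(frame, residual_cut=3.0)["selected"].iloc[0]


class TestTaxonShift:
    def _design(self, n_sites=10, n_per=10, seed=0):
        rng = np.random.default_rng(seed)
        site = np.repeat([f"s{k}" for k in range(n_sites)], n_per)
        loc = np.tile(
            ["cushion"] * (n_per // 2) + ["bare"] * (n_per - n_per // 2), n_sites
        )
        return rng, site, loc

    def test_no_shift_near_null(self):
        rng, site, loc = self._design(seed=30)
        site_eff = {s: rng.normal(0, 1) for s in np.unique(site)}
        y = np.array([site_eff[s] for s in site]) + rng.normal(0, 0.5, len(site))
        res = taxon_shift_test(y, loc, site)
        assert res["p"] > 0.2

    def test_identical_values_degenerate_falls_back(self):
        _, site, loc = self._design(n_sites=3, n_per=4)
        y = np.ones(len(site))
        res = taxon_shift_test(y, loc, site)
        assert res["p"] > 0.9

    def test_large_shift_detected(self):
        rng, site, loc = self._design(seed=31)
        site_eff = {s: rng.normal(0, 1) for s in np.unique(site)}
        within_sd = 0.4
        y = (
            np.array([site_eff[s] for s in site])
            + 5 * within_sd * (np.asarray(loc) == "cushion")
            + rng.normal(0, within_sd, len(site))
        )
        res = taxon_shift_test(y, loc, site)
        assert res["method"] == "lrt"
        assert res["p"] < 0.001

    def test_within_site_permutation_destroys_signal(self):
        rng, site, loc = self._design(seed=32)
        site_eff = {s: rng.normal(0, 1) for s in np.unique(site)}
        y = (
            np.array([site_eff[s] for s in site])
            + 2.0 * (np.asarray(loc) == "cushion")
            + rng.normal(0, 0.4, len(site))
        )
        p_values = []
        for _ in range(50):
            loc_perm = np.asarray(loc).copy()
            for s in np.unique(site):
                idx = np.flatnonzero(site == s)
                loc_perm[idx] = loc_perm[rng.permutation(idx)]
            p_values.append(taxon_shift_test(y, loc_perm, site)["p"])
        assert np.median(p_values) > 0.1


class TestPipeline:
    def test_end_to_end_recovery_on_small_design(self, small_dataset):
        from nursepart.core_data import assign_habitats, filter_table, to_relative

        table = to_relative(filter_table(small_dataset["abundance"]))
        habitats = assign_habitats(small_dataset["metadata"])
        results = associate(table, habitats, B=199, seed=11)
        selected = set(results.index[results["selected"]])
        truth_cushion = set(small_dataset["truth"]["cushion_signatures"])
        truth_bare = set(small_dataset["truth"]["bare_signatures"])
        present = truth_cushion & set(table.motu_ids)
        assert len(selected & present) >= 0.8 * len(present)
        assert not selected & truth_bare
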