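"""Tests for the dynamic-SILAC differential-loss pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psilac import silac as S
from psilac.simulate import SilacSimConfig, simulate_silac

from conftest import make_estimates, make_peptides


class TestAggregate:
    def test_median_of_three(self):
        est = S.aggregate_peptides(make_peptides([("P1", "E1", 0, [-1.0, -0.5, -0.3])]))
        assert est.loc[0, "log2_ratio"] == pytest.approx(-0.5)
        assert est.loc[0, "n_peptides"] == 3

    def test_single_peptide_identity(self):
        est = S.aggregate_peptides(make_peptides([("P1", "E1", 2, [-0.2])]))
        assert est.loc[0, "log2_ratio"] == pytest.approx(-0.2)
        assert est.loc[0, "n_peptides"] == 1

    def test_median_matches_sort_and_middle_oracle(self):
        rng = np.random.default_rng(42)
        vals = -1.0 + rng.normal(0, 0.1, 7)
        est = S.aggregate_peptides(make_peptides([("P1", "E1", 4, vals)]))
        oracle = np.sort(vals)[3]
        assert est.loc[0, "log2_ratio"] == pytest.approx(oracle, abs=1e-12)
        assert abs(est.loc[0, "log2_ratio"] + 1.0) < 0.12

    def test_nonpositive_ratio_rejected(self):
        bad = make_peptides([("P1", "E1", 0, [0.0])])
        bad["ratio_hm"] = 0.0
        with pytest.raises(ValueError):
            S.aggregate_peptides(bad)


class TestNormalize:
    def test_constant_reference_offset(self):
        est = make_estimates([("REF", "E1", 0, 1.0, 5), ("P1", "E1", 0, 0.3, 5)])
        out = S.normalize_to_reference(est, {"REF"})
        assert out.loc[out.protein_id == "P1", "log2_ratio"].iloc[0] == pytest.approx(-0.7)
        assert out.loc[out.protein_id == "REF", "log2_ratio"].iloc[0] == pytest.approx(0.0)

    def test_zero_median_reference_is_identity(self):
        est = make_estimates([("R1", "E1", 0, 0.1, 5), ("R2", "E1", 0, -0.1, 5),
                              ("P1", "E1", 0, 0.4, 5)])
        out = S.normalize_to_reference(est, {"R1", "R2"})
        pd.testing.assert_frame_equal(out, est)

    def test_offsets_cancel_exactly(self):
        """Per experiment x timepoint offsets leave the normalized table unchanged."""
        protein_vals = {"R1": 0.0, "R2": 0.02, "R3": -0.05, "P1": -0.6, "P2": 0.1}
        base = make_estimates([(p, e, t, v, 5) for p, v in protein_vals.items()
                               for e in ("E1", "E2") for t in (0.0, 8.0)])
        rng = np.random.default_rng(3)
        offsets = {(e, t): rng.normal(0, 0.5) for e in ("E1", "E2") for t in (0.0, 8.0)}
        shifted = base.copy()
        shifted["log2_ratio"] += [offsets[(e, t)] for e, t in
                                  zip(shifted.experiment_id, shifted.timepoint_h)]
        refs = {"R1", "R2", "R3"}
        a = S.normalize_to_reference(base, refs)["log2_ratio"].to_numpy()
        b = S.normalize_to_reference(shifted, refs)["log2_ratio"].to_numpy()
        assert np.max(np.abs(a - b)) < 1e-12

    def test_missing_cell_raises_naming_it(self):
        est = make_estimates([("R1", "E1", 0, 0.0, 5), ("P1", "E1", 0, 0.1, 5),
                              ("P1", "E2", 0, 0.1, 5)])
        with pytest.raises(ValueError, match="E2"):
            S.normalize_to_reference(est, {"R1"})

    def test_partial_reference_overlap_warns(self):
        est = make_estimates([("R1", "E1", 0, 0.0, 5), ("P1", "E1", 0, 0.1, 5)])
        with pytest.warns(UserWarning, match="reference proteins absent"):
            S.normalize_to_reference(est, {"R1", "R_missing"})


class TestFilter:
    def test_fixture_two_survivors(self, filter_fixture_peptides):
        est = S.aggregate_peptides(filter_fixture_peptides)
        kept = S.filter_stringent(est)
        assert set(kept["protein_id"]) == {"A", "D"}

    def test_empty_input(self):
        est = make_estimates([]).reindex(columns=S.ESTIMATE_COLUMNS)
        assert S.filter_stringent(est).empty

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        cfg = SilacSimConfig(n_proteins=60, peptides_mean=6.0, n_experiments=5, seed=9)
        est = S.aggregate_peptides(simulate_silac(cfg).peptides)
        # simulate dropout so some groups fall below the thresholds
        est = est.sample(frac=0.4, random_state=7).reset_index(drop=True)
        kept = S.filter_stringent(est, 5, 3)
        surviving = set(map(tuple, kept[["protein_id", "timepoint_h"]].drop_duplicates()
                            .itertuples(index=False)))
        oracle = set()
        for (p, t), grp in est.groupby(["protein_id", "timepoint_h"]):
            if grp["n_peptides"].sum() >= 5 and grp["experiment_id"].nunique() >= 3:
                oracle.add((p, t))
        assert surviving == oracle


class TestVolcano:
    def _two_group_estimates(self, t0_vals, t8_vals, protein="P1", extra=()):
        entries = []
        for i, v in enumerate(t0_vals):
            entries.append((protein, f"E{i + 1}", 0.0, v, 3))
        for i, v in enumerate(t8_vals):
            entries.append((protein, f"E{i + 1}", 8.0, v, 3))
        entries.extend(extra)
        return make_estimates(entries)

    def test_clear_loss_significant_with_permutation_oracle(self):
        t0 = [0.00, 0.05, -0.05, 0.02, -0.02]
        t8 = [-1.0, -0.9, -1.1, -1.05, -0.95]
        # anchor proteins so the t=0 population SD is well defined
        extra = [(f"Q{i}", e, 0.0, v, 3) for i, v in enumerate((0.1, -0.1, 0.05))
                 for e in ("E1", "E2")]
        res = S.volcano(self._two_group_estimates(t0, t8, extra=extra), timepoints=(8.0,))
        rec = res.records[res.records.protein_id == "P1"].iloc[0]
        assert rec["p_value"] < 1e-5
        assert rec["passes_significance"]
        # permutation oracle: observed |mean difference| is the most extreme
        # of all C(10,5)=252 relabelings
        pool = np.array(t0 + t8)
        obs = abs(np.mean(t8) - np.mean(t0))
        diffs = [abs(pool[list(idx)].mean() - np.delete(pool, list(idx)).mean())
                 for idx in itertools.combinations(range(10), 5)]
        assert sum(d >= obs - 1e-12 for d in diffs) == 2  # the split and its mirror

    def test_no_change_fails_magnitude(self):
        vals = [0.3, 0.1, -0.2, 0.0, 0.05]
        res = S.volcano(self._two_group_estimates(vals, vals), timepoints=(8.0,))
        rec = res.records.iloc[0]
        assert rec["log2_fc"] == 0.0
        assert not rec["passes_magnitude"]
        assert rec["klass"] == "not_significant"

    def test_threshold_is_twice_t0_sd(self):
        # t=0 per-protein means scaled to a sample SD of exactly 0.26
        raw = np.array([0.1, -0.3, 0.25, -0.05, 0.0, 0.18, -0.22, 0.07])
        vals = raw / raw.std(ddof=1) * 0.26
        entries = [(f"P{i}", e, 0.0, v, 3) for i, v in enumerate(vals) for e in ("E1", "E2")]
        entries += [(f"P{i}", e, 8.0, v, 3) for i, v in enumerate(vals) for e in ("E1", "E2")]
        res = S.volcano(make_estimates(entries), timepoints=(8.0,))
        assert res.magnitude_threshold == pytest.approx(0.52, abs=1e-9)
        # a fold change at the threshold is a ~30% reduction
        assert 2 ** (-res.magnitude_threshold) == pytest.approx(0.70, abs=0.005)

    def test_single_repeat_gives_undefined_p(self):
        entries = [("P1", "E1", 0.0, 0.0, 3), ("P1", "E1", 8.0, -1.0, 3),
                   ("P2", "E1", 0.0, 0.1, 3), ("P2", "E2", 0.0, -0.1, 3),
                   ("P2", "E1", 8.0, 0.1, 3), ("P2", "E2", 8.0, -0.1, 3)]
        res = S.volcano(make_estimates(entries), timepoints=(8.0,))
        rec = res.records.set_index("protein_id").loc["P1"]
        assert np.isnan(rec["p_value"])
        assert not rec["passes_significance"]

    def test_t0_vs_t0_fold_change_exactly_zero(self):
        entries = [(f"P{i}", e, 0.0, v, 3)
                   for i, v in enumerate((0.2, -0.4, 0.1, 0.0)) for e in ("E1", "E2", "E3")]
        res = S.volcano(make_estimates(entries), timepoints=(0.0,))
        assert (res.records["log2_fc"] == 0.0).all()

    def test_hit_4and8_promotion(self):
        entries = []
        for e in ("E1", "E2", "E3"):
            for i in range(6):
                entries.append((f"P{i}", e, 0.0, 0.01 * (i - 3), 3))
            for tp in (2.0, 4.0, 8.0):
                entries.append(("P0", e, tp, -1.0 + {"E1": 0.02, "E2": -0.02, "E3": 0.0}[e], 3))
                for i in range(1, 6):
                    entries.append((f"P{i}", e, tp, 0.01 * (i - 3), 3))
        res = S.volcano(make_estimates(entries))
        p0 = res.records[res.records.protein_id == "P0"]
        assert p0["is_hit_4and8"].all()
        assert (p0["klass"] == "hit_4and8").all()
        others = res.records[res.records.protein_id != "P0"]
        assert not others["is_hit_4and8"].any()


class TestCompareToModel:
    def test_noise_free_self_consistency(self):
        cfg = SilacSimConfig(n_proteins=120, noise_sigma_log2=0.0,
                             experiment_offset_sigma=0.0, seed=2)
        res = simulate_silac(cfg)
        est = S.aggregate_peptides(res.peptides)
        half = res.truth.set_index("protein_id")["t_half_days"]
        comp = S.compare_to_model(est, half, k=cfg.k_true)
        rs = comp.correlations.dropna(subset=["pearson_r"])
        assert not rs.empty
        assert (rs["pearson_r"] > 1 - 1e-9).all()

    def test_small_stratum_reported_absent(self):
        est = make_estimates([("P1", "E1", 8.0, -0.5, 5), ("P2", "E1", 8.0, -0.2, 5)])
        comp = S.compare_to_model(est, {"P1": 1.0, "P2": 5.0}, k=0.0)
        sub = comp.correlations.query("timepoint_h == 8.0 and stratum_max_days == 2.0")
        assert np.isnan(sub["pearson_r"]).all()

    def test_missing_halflives_counted(self):
        est = make_estimates([("P1", "E1", 8.0, -0.5, 5), ("PX", "E1", 8.0, -0.2, 5)])
        comp = S.compare_to_model(est, {"P1": 1.0}, k=0.0)
        assert comp.n_missing_halflife == 1


class TestRanks:
    def test_basic_and_tied_ranks(self):
        est = make_estimates([(p, "E1", 2.0, v, 5)
                              for p, v in (("A", -2.0), ("B", -1.0), ("C", 0.0))])
        ranks = S.rank_proteins(est, timepoints=(2.0,))
        assert dict(zip(ranks.protein_id, ranks.mean_rank)) == {"A": 1, "B": 2, "C": 3}
        est2 = make_estimates([(p, "E1", 2.0, v, 5)
                               for p, v in (("A", -1.0), ("B", -1.0), ("C", 0.0))])
        ranks2 = S.rank_proteins(est2, timepoints=(2.0,))
        assert dict(zip(ranks2.protein_id, ranks2.mean_rank)) == {"A": 1.5, "B": 1.5, "C": 3}

    def test_mean_rank_matches_brute_force(self):
        rng = np.random.default_rng(0)
        proteins = [f"P{i}" for i in range(9)]
        entries, per_tp = [], {}
        for tp in (2.0, 4.0, 8.0):
            vals = rng.permutation(np.linspace(-2, 1, len(proteins)))
            per_tp[tp] = dict(zip(proteins, vals))
            entries += [(p, "E1", tp, v, 5) for p, v in per_tp[tp].items()]
        ranks = S.rank_proteins(make_estimates(entries))
        for _, row in ranks.iterrows():
            oracle = np.mean([sorted(per_tp[tp].values()).index(per_tp[tp][row.protein_id]) + 1
                              for tp in (2.0, 4.0, 8.0)])
            assert row.mean_rank == pytest.approx(oracle)
            assert row.log10_rank == pytest.approx(np.log10(oracle))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-300, 300), min_size=4, max_size=12, unique=True))
    def test_invariant_under_monotone_transform(self, steps):
        vals = [v / 100.0 for v in steps]
        est = make_estimates([(f"P{i}", "E1", 2.0, v, 5) for i, v in enumerate(vals)])
        est_t = est.copy()
        est_t["log2_ratio"] = np.exp(est_t["log2_ratio"]) * 3 + 1  # strictly monotone
        r1 = S.rank_proteins(est, timepoints=(2.0,)).set_index("protein_id")["mean_rank"]
        r2 = S.rank_proteins(est_t, timepoints=(2.0,)).set_index("protein_id")["mean_rank"]
        pd.testing.assert_series_equal(r1, r2)

    def test_missing_timepoint_averaging_and_strict_mode(self):
        entries = [("A", "E1", 2.0, -1.0, 5), ("B", "E1", 2.0, 0.0, 5),
                   ("A", "E1", 4.0, -1.0, 5)]
        ranks = S.rank_proteins(make_estimates(entries), timepoints=(2.0, 4.0))
        assert set(ranks.protein_id) == {"A", "B"}
        strict = S.rank_proteins(make_estimates(entries), timepoints=(2.0, 4.0),
                                 require_all=True)
        assert set(strict.protein_id) == {"A"}


class TestGroupRanks:
    def test_whole_set_mean(self):
        n = 8
        est = make_estimates([(f"P{i}", "E1", 2.0, -float(i), 5) for i in range(n)])
        ranks = S.rank_proteins(est, timepoints=(2.0,))
        out = S.group_rank_summary(ranks, {"all": {f"P{i}" for i in range(n)}})
        expected = np.mean(np.log10(np.arange(1, n + 1)))
        assert out.summary.loc[0, "mean_log10_rank"] == pytest.approx(expected)
        assert out.summary.loc[0, "n_members"] == n

    def test_disjoint_group(self):
        est = make_estimates([("P1", "E1", 2.0, -1.0, 5)])
        ranks = S.rank_proteins(est, timepoints=(2.0,))
        out = S.group_rank_summary(ranks, {"none": {"X", "Y"}})
        assert out.summary.loc[0, "n_members"] == 0
        assert np.isnan(out.summary.loc[0, "mean_log10_rank"])

    def test_planted_fast_decay_group_ranks_high(self):
        """Accelerated-degradation proteins sit above (below-rank) the bulk."""
        wins = 0
        for seed in range(20):
            cfg = SilacSimConfig(n_proteins=300, accelerated_fraction=0.1, gamma=5.0,
                                 seed=100 + seed)
            res = simulate_silac(cfg)
            est = S.filter_stringent(S.aggregate_peptides(res.peptides))
            ranks = S.rank_proteins(est)
            accel = set(res.truth.loc[res.truth.is_accelerated, "protein_id"])
            out = S.group_rank_summary(ranks, {"accel": accel})
            if out.summary.loc[0, "mean_log10_rank"] < ranks["log10_rank"].mean():
                wins += 1
        assert wins >= 18


class TestEnrichmentFilter:
    def _terms(self, rows):
        return pd.DataFrame(rows, columns=["term_id", "term_name", "fold_enrichment_0",
                                           "fold_enrichment_2", "fold_enrichment_4",
                                           "fold_enrichment_8"])

    def test_t0_enriched_dropped(self):
        terms = self._terms([("t1", "a", 2.0, 5.0, 5.0, 5.0),
                             ("t2", "b", np.nan, 5.0, 5.0, 5.0),
                             ("t3", "c", np.nan, 4.0, 4.0, np.nan),
                             ("t4", "d", np.nan, 3.0, 3.0, 3.0),
                             ("t5", "e", np.nan, 2.0, 2.0, 2.0)])
        kept = S.filter_enrichment_terms(terms, top_fraction=0.5)
        assert "t1" not in set(kept.term_id)

    def test_single_timepoint_dropped(self):
        terms = self._terms([("t1", "a", np.nan, np.nan, np.nan, 9.0),
                             ("t2", "b", np.nan, 4.0, 4.0, 4.0)])
        kept = S.filter_enrichment_terms(terms, top_fraction=1.0)
        assert set(kept.term_id) == {"t2"}

    def test_top_quarter_by_summed_enrichment(self):
        sums = [20, 15, 13, 12, 9, 8, 5, 3]
        terms = self._terms([(f"t{i}", f"n{i}", np.nan, s / 2, s / 2, np.nan)
                             for i, s in enumerate(sums)])
        kept = S.filter_enrichment_terms(terms, top_fraction=0.25)
        assert list(kept.sum_fold_enrichment) == [20, 15]

    def test_ties_at_cut_kept(self):
        sums = [20, 15, 15, 12, 9, 8, 5, 3]
        terms = self._terms([(f"t{i}", f"n{i}", np.nan, s / 2, s / 2, np.nan)
                             for i, s in enumerate(sums)])
        kept = S.filter_enrichment_terms(terms, top_fraction=0.25)
        assert list(kept.sum_fold_enrichment) == [20, 15, 15]
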