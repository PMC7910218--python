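"""The proteomics filter chain: q cutoff, detection, outliers, contaminants,
differential statistics and the cross-shRNA concordance rule."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen import proteomics, synthetic
from phenoscreen.proteomics import (
    DifferentialResult,
    ProteomicsError,
    concordance_filter,
    detection_filter,
    q_threshold,
    remove_contaminants,
    remove_outlier_replicates,
    run_filter_chain,
    set_overlaps,
    shrna_differential,
)


def _meta(groups, median_q=None):
    rows = []
    for g, r in groups.items():
        for i in range(r):
            rows.append({
                "sample": f"{g}_r{i + 1}", "group": g, "replicate": i + 1,
                "median_q": 0.01 if median_q is None else median_q[g][i],
            })
    return pd.DataFrame(rows)


class TestQThreshold:
    def test_mean_of_medians(self):
        meta = _meta({"a": 1, "b": 1, "c": 1},
                     {"a": [0.01], "b": [0.02], "c": [0.03]})
        assert q_threshold(meta) == pytest.approx(0.02)

    def test_single_sample_returns_its_median(self):
        meta = _meta({"a": 1}, {"a": [0.007]})
        assert q_threshold(meta) == pytest.approx(0.007)

    def test_empty_metadata_rejected(self):
        with pytest.raises(ProteomicsError):
            q_threshold(pd.DataFrame(columns=["sample", "median_q"]))


class TestDetectionFilter:
    def _quant(self, detected):
        """detected: dict protein -> dict sample -> bool."""
        meta = _meta({"A": 3, "B": 3})
        data = {
            s: [100.0 if detected[p].get(s, False) else np.nan
                for p in detected]
            for s in meta["sample"]
        }
        return pd.DataFrame(data, index=list(detected)), meta

    def test_two_of_three_within_one_elsewhere_retained(self):
        quant, meta = self._quant({
            "p": {"A_r1": True, "A_r2": True, "B_r1": True},
        })
        assert list(detection_filter(quant, meta).index) == ["p"]

    def test_one_of_three_everywhere_dropped(self):
        quant, meta = self._quant({
            "p": {"A_r1": True, "B_r1": True},
        })
        assert detection_filter(quant, meta).empty

    def test_private_to_one_group_dropped(self):
        quant, meta = self._quant({
            "p": {"A_r1": True, "A_r2": True, "A_r3": True},
        })
        assert detection_filter(quant, meta).empty

    def test_group_with_single_replicate_rejected(self):
        quant = pd.DataFrame({"A_r1": [1.0], "B_r1": [1.0], "B_r2": [1.0]},
                             index=["p"])
        meta = pd.DataFrame({
            "sample": ["A_r1", "B_r1", "B_r2"],
            "group": ["A", "B", "B"],
            "replicate": [1, 1, 2],
            "median_q": [0.01] * 3,
        })
        with pytest.raises(ProteomicsError):
            detection_filter(quant, meta)


class TestOutlierReplicates:
    def test_tenfold_deviating_replicate_removed(self):
        meta = _meta({"A": 3}, {"A": [0.01, 0.01, 0.15]})
        out, removed = remove_outlier_replicates(meta)
        assert removed == ["A_r3"]
        assert len(out) == 2

    def test_low_cv_group_untouched(self):
        meta = _meta({"A": 3}, {"A": [0.01, 0.011, 0.012]})
        out, removed = remove_outlier_replicates(meta)
        assert removed == [] and len(out) == 3

    def test_high_cv_without_tenfold_deviation_untouched(self):
        meta = _meta({"A": 3}, {"A": [0.01, 0.1, 0.1]})
        out, removed = remove_outlier_replicates(meta)
        assert removed == [] and len(out) == 3

    def test_mutual_large_outliers_shield_each_other(self):
        # two high-q replicates raise each other's comparison median, so the
        # tenfold rule removes neither and the group keeps >= 2 replicates
        meta = _meta({"A": 3}, {"A": [0.001, 0.5, 0.6]})
        out, removed = remove_outlier_replicates(meta)
        assert removed == [] and len(out) == 3


class TestContaminants:
    def _quant(self):
        return pd.DataFrame(
            {"description": [
                "Keratin, type I cytoskeletal 10",
                "Syntaxin-7",
                "Immunoglobulin heavy chain",
                "Trypsin precursor",
            ], "s1": [1.0] * 4},
            index=["KRT10", "STX7", "IGH1", "TRY1"],
        )

    def test_default_patterns_remove_known_contaminants(self):
        out = remove_contaminants(self._quant())
        assert list(out.index) == ["STX7"]

    def test_empty_pattern_list_is_identity(self):
        out = remove_contaminants(self._quant(), patterns=())
        assert len(out) == 4


class TestDifferential:
    def _tables(self, kd, ctrl):
        meta = _meta({"sh1": len(kd), "scrambled": len(ctrl)})
        quant = pd.DataFrame(
            [list(kd) + list(ctrl)],
            index=["p"],
            columns=[f"sh1_r{i + 1}" for i in range(len(kd))]
            + [f"scrambled_r{i + 1}" for i in range(len(ctrl))],
        )
        return quant, meta

    def test_identical_sides_give_zero_fc_unit_p(self):
        quant, meta = self._tables([100, 200, 300], [100, 200, 300])
        res = shrna_differential(quant, meta, "sh1").table
        assert res.loc["p", "log2_fc"] == pytest.approx(0.0)
        assert res.loc["p", "p_value"] == pytest.approx(1.0)

    def test_exact_doubling_with_zero_variance(self):
        quant, meta = self._tables([200, 200, 200], [100, 100, 100])
        res = shrna_differential(quant, meta, "sh1").table
        assert res.loc["p", "log2_fc"] == pytest.approx(1.0)
        assert res.loc["p", "p_value"] < 1e-6  # variance floor stabilized

    def test_missing_side_flagged_not_testable(self):
        quant, meta = self._tables([100, np.nan, np.nan], [100, 100, 100])
        res = shrna_differential(quant, meta, "sh1").table
        assert np.isnan(res.loc["p", "p_value"])

    def test_single_replicate_side_rejected(self):
        quant, meta = self._tables([100], [100, 100])
        with pytest.raises(ProteomicsError):
            shrna_differential(quant, meta, "sh1")

    def test_power_on_planted_log2_effect(self, rng):
        """A +1 log2 effect with noise SD 0.1 at n=3 is recovered with a
        significant, accurate fold change in nearly all simulations."""
        hits = 0
        fcs = []
        n_sim = 200
        for _ in range(n_sim):
            ctrl = 2 ** (10 + rng.normal(0, 0.1, 3))
            kd = 2 ** (11 + rng.normal(0, 0.1, 3))
            quant, meta = self._tables(kd, ctrl)
            res = shrna_differential(quant, meta, "sh1").table
            fcs.append(res.loc["p", "log2_fc"])
            if res.loc["p", "p_value"] < 0.05:
                hits += 1
        assert hits / n_sim >= 0.95
        assert np.all(np.abs(np.array(fcs) - 1.0) < 0.5)


def _diff(shrna, fc_p):
    table = pd.DataFrame(
        {"log2_fc": [v[0] for v in fc_p.values()],
         "p_value": [v[1] for v in fc_p.values()],
         "n_kd": 3, "n_ctrl": 3},
        index=list(fc_p),
    )
    return DifferentialResult(shrna=shrna, table=table)


class TestConcordance:
    @pytest.mark.parametrize("fcs,regulated", [
        ([(0.5, 0.01), (0.2, 0.3), (0.1, 0.6)], True),    # one sig, concordant
        ([(0.5, 0.01), (-0.1, 0.8), (0.2, 0.2)], False),  # discordant sign
        ([(0.5, 0.06), (0.2, 0.3), (0.1, 0.6)], False),   # nothing significant
        ([(0.5, 0.01), (0.0, 0.9), (0.2, 0.2)], False),   # zero fc = discordant
    ])
    def test_rule_on_three_shrnas(self, fcs, regulated):
        diffs = [
            _diff(f"sh{i + 1}", {"p": fc}) for i, fc in enumerate(fcs)
        ]
        out = concordance_filter(diffs)
        assert ("p" in out.index) is regulated

    def test_protein_testable_in_fewer_than_two_shrnas_excluded(self):
        diffs = [
            _diff("sh1", {"p": (0.5, 0.01)}),
            _diff("sh2", {"p": (np.nan, np.nan)}),
        ]
        assert concordance_filter(diffs).empty

    def test_members_reverify_both_criteria(self, proteomics_tables):
        cfg, tables = proteomics_tables
        rep = run_filter_chain(
            tables.quant, tables.metadata, tables.q_values,
            "Tcf4", list(cfg.genes["Tcf4"]),
        )
        fc_cols = [c for c in rep.regulated.columns if c.startswith("log2_fc_")]
        for pid, row in rep.regulated.iterrows():
            signs = np.sign(row[fc_cols].dropna().astype(float))
            assert len(set(signs)) == 1 and 0 not in set(signs)
            assert row["significant_shrnas"] != ""

    def test_noise_free_construction_recovers_exactly_planted(self):
        cfg = synthetic.SyntheticProteomicsConfig(
            n_proteins=60,
            genes={"G": ["G_sh1", "G_sh2", "G_sh3"]},
            planted_regulated={"G": {"REG_A": 1.0, "REG_B": -0.7}},
            noise_sd=0.0, contaminant_fraction=0.0, q_tail_fraction=0.0,
            seed=0,
        )
        tables = synthetic.generate_proteomics(cfg)
        rep = run_filter_chain(
            tables.quant, tables.metadata, tables.q_values, "G",
            ["G_sh1", "G_sh2", "G_sh3"],
        )
        assert set(rep.regulated.index) == {"REG_A", "REG_B"}


class TestSetOverlaps:
    def test_common_element_in_all_three(self):
        out = set_overlaps({"a": {"A", "B"}, "b": {"B", "C"}, "c": {"B", "D"}})
        assert out.loc[out["sets"] == "a&b&c", "size"].iloc[0] == 1

    def test_disjoint_sets_overlap_zero(self):
        out = set_overlaps({"a": {"A"}, "b": {"B"}, "c": {"C"}})
        assert (out["size"] == 0).all()

    def test_identical_sets_full_overlap(self):
        out = set_overlaps({"a": {"A", "B"}, "b": {"A", "B"}})
        assert (out["size"] == 2).all()


class TestChainIdempotence:
    def test_rerunning_filters_changes_nothing(self, proteomics_tables):
        cfg, tables = proteomics_tables
        cutoff = q_threshold(tables.metadata)
        once = proteomics.apply_q_threshold(tables.quant, tables.q_values, cutoff)
        once = detection_filter(once, tables.metadata)
        once = remove_contaminants(once)
        twice = proteomics.apply_q_threshold(once, tables.q_values, cutoff)
        twice = detection_filter(twice, tables.metadata)
        twice = remove_contaminants(twice)
        pd.testing.assert_frame_equal(once, twice)
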