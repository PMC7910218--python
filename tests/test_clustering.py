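"""Profile building, the no-effect gate, clustering and gene selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phenoscreen import clustering, qc, synthetic
from phenoscreen.clustering import (
    ProfileSet,
    build_profiles,
    cluster_shrnas,
    coclustering_test,
    gate_no_effect,
    select_genes,
)
from phenoscreen.params import REPRESENTATIVE_PARAMETERS


def _profile_set(profiles: pd.DataFrame, genes=None) -> ProfileSet:
    genes = genes if genes is not None else pd.Series(
        [f"gene{i}" for i in range(len(profiles))], index=profiles.index
    )
    per_div = pd.DataFrame(
        np.repeat(profiles.to_numpy(), 3, axis=1),
        index=profiles.index,
        columns=[f"{p}@DIV{d}" for p in profiles.columns for d in (7, 14, 21)],
    )
    return ProfileSet(profiles, genes, "averaged", per_div)


class TestBuildProfiles:
    def test_profile_entry_is_mean_of_replicates(self, small_normalized):
        profiles = build_profiles(small_normalized, "averaged")
        shrna = profiles.profiles.index[0]
        wells = small_normalized[small_normalized["shrna_id"] == shrna]
        expected = wells["neuron_count"].mean()
        assert profiles.profiles.loc[shrna, "neuron_count"] == pytest.approx(expected)

    def test_scrambled_pseudo_shrna_profiles_near_zero(self, small_normalized):
        """Relabelling scrambled wells as an experimental pseudo-construct
        shows the normalization identity: their profile is ~0."""
        t = small_normalized.copy()
        scr = t["treatment_class"] == "scrambled"
        t.loc[scr, "treatment_class"] = "experimental"
        t.loc[scr, "gene"] = "pseudo"
        t.loc[scr, "shrna_id"] = "pseudo_sh1"
        profiles = build_profiles(t, "averaged")
        assert np.abs(profiles.profiles.loc["pseudo_sh1"]).max() < 0.1

    def test_concatenated_mode_gives_twelve_features(self, small_normalized):
        profiles = build_profiles(small_normalized, "concatenated")
        assert profiles.profiles.shape[1] == 12

    def test_unknown_div_mode_rejected(self, small_normalized):
        with pytest.raises(ValueError):
            build_profiles(small_normalized, "weekly")


class TestGate:
    def _sds(self, sd=0.1):
        return pd.DataFrame(
            sd, index=[7, 14, 21], columns=list(REPRESENTATIVE_PARAMETERS)
        )

    def test_all_effects_within_twice_sd_are_gated(self):
        profiles = _profile_set(pd.DataFrame(
            [[0.2, -0.2, 0.1, 0.15]], index=["sh1"],
            columns=REPRESENTATIVE_PARAMETERS,
        ))
        gated, retained = gate_no_effect(profiles, self._sds())
        assert gated == ["sh1"] and retained == []

    def test_single_exceedance_retains(self):
        profiles = _profile_set(pd.DataFrame(
            [[0.25, 0.0, 0.0, 0.0]], index=["sh1"],
            columns=REPRESENTATIVE_PARAMETERS,
        ))
        gated, retained = gate_no_effect(profiles, self._sds())
        assert retained == ["sh1"]

    def test_gate_scale_consistency(self):
        """Doubling both effects and scrambled SDs leaves gating unchanged."""
        base = pd.DataFrame(
            [[0.15, 0.1, -0.25, 0.05], [0.05, 0.02, 0.01, -0.03]],
            index=["a", "b"], columns=REPRESENTATIVE_PARAMETERS,
        )
        g1, r1 = gate_no_effect(_profile_set(base), self._sds(0.1))
        g2, r2 = gate_no_effect(_profile_set(base * 2), self._sds(0.2))
        assert (g1, r1) == (g2, r2)

    def test_missing_sd_rejected(self):
        profiles = _profile_set(pd.DataFrame(
            [[0.1, 0.1, 0.1, 0.1]], index=["sh1"],
            columns=REPRESENTATIVE_PARAMETERS,
        ))
        bad = self._sds().drop(index=14)
        with pytest.raises(ValueError):
            gate_no_effect(profiles, bad)

    def test_scrambled_controls_themselves_mostly_gated(self, small_normalized):
        """Pseudo-profiles built from scrambled wells fall under the gate at
        close to the rate expected for null 12-condition profiles."""
        t = small_normalized.copy()
        scr = t["treatment_class"] == "scrambled"
        # split scrambled wells into pseudo-constructs by plate
        t.loc[scr, "treatment_class"] = "experimental"
        t.loc[scr, "gene"] = "pseudo"
        t.loc[scr, "shrna_id"] = "pseudo_" + t.loc[scr, "plate"]
        profiles = build_profiles(t[t["gene"] == "pseudo"], "averaged")
        sds = qc.scrambled_sd(small_normalized)[list(REPRESENTATIVE_PARAMETERS)]
        gated, retained = gate_no_effect(profiles, sds)
        assert len(gated) >= 0.6 * (len(gated) + len(retained))


class TestClusterShrnas:
    def test_two_planted_archetypes_fully_recovered(self, rng):
        a = np.array([1.0, 0.1, 0.1, 1.0])
        b = np.array([0.1, 1.0, -1.0, 0.1])
        profiles = pd.DataFrame(
            np.vstack([
                a + rng.normal(0, 0.02, (10, 4)),
                b + rng.normal(0, 0.02, (10, 4)),
            ]),
            index=[f"sh{i:02d}" for i in range(20)],
            columns=REPRESENTATIVE_PARAMETERS,
        )
        ps = _profile_set(profiles)
        out = cluster_shrnas(ps, list(profiles.index), k=2)
        truth = [0] * 10 + [1] * 10
        labels = out.set_index("shrna_id").loc[profiles.index, "cluster"]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicated_profiles_share_a_cluster(self):
        base = np.array([[1.0, 0.2, -0.5, 0.3]])
        profiles = pd.DataFrame(
            np.vstack([base, base, [[-1.0, 0.5, 0.5, -0.2]],
                       [[0.0, 1.0, 0.0, -1.0]]]),
            index=["dup1", "dup2", "other1", "other2"],
            columns=REPRESENTATIVE_PARAMETERS,
        )
        out = cluster_shrnas(_profile_set(profiles), list(profiles.index), k=3)
        lab = out.set_index("shrna_id")["cluster"]
        assert lab["dup1"] == lab["dup2"]

    def test_k_exceeding_retained_rejected(self):
        profiles = pd.DataFrame(
            [[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]],
            index=["a", "b"], columns=REPRESENTATIVE_PARAMETERS,
        )
        with pytest.raises(ValueError):
            cluster_shrnas(_profile_set(profiles), ["a", "b"], k=3)

    def test_labels_ordered_by_severity(self):
        strong = np.tile([-1.0, -0.5, -0.4, -0.6], (3, 1))
        weak = np.tile([0.35, 0.1, 0.1, 0.05], (3, 1))
        profiles = pd.DataFrame(
            np.vstack([strong, weak]) + np.arange(6)[:, None] * 1e-3,
            index=[f"s{i}" for i in range(6)],
            columns=REPRESENTATIVE_PARAMETERS,
        )
        out = cluster_shrnas(_profile_set(profiles), list(profiles.index), k=2)
        lab = out.set_index("shrna_id")["cluster"]
        assert set(lab[["s0", "s1", "s2"]]) == {"I"}   # most severe first
        assert set(lab[["s3", "s4", "s5"]]) == {"II"}


class TestSelectGenes:
    def _assign(self, mapping):
        rows = [
            {"shrna_id": f"{g}_sh{i}", "gene": g, "cluster": c}
            for g, labels in mapping.items() for i, c in enumerate(labels)
        ]
        return pd.DataFrame(rows)

    def test_three_coclustered_shrnas_select_gene(self):
        sel = select_genes(self._assign({"g": ["II", "II", "II", "0", "I"]}))
        assert sel == {"g": "II"}

    def test_two_plus_two_not_selected(self):
        sel = select_genes(self._assign({"g": ["II", "II", "I", "I"]}))
        assert sel == {}

    def test_cluster_zero_never_counts(self):
        sel = select_genes(self._assign({"g": ["0", "0", "0", "0"]}))
        assert sel == {}


class TestCoclusteringTest:
    def _assignments(self, rng, n_genes=12, coclustered=True):
        rows = []
        clusters = ["I", "II", "III", "0"]
        for g in range(n_genes):
            gene = f"g{g}"
            if coclustered:
                lab = clusters[g % 3]
                labels = [lab] * 4
            else:
                labels = rng.choice(clusters, size=4)
            rows += [
                {"shrna_id": f"{gene}_sh{i}", "gene": gene, "cluster": c}
                for i, c in enumerate(labels)
            ]
        return pd.DataFrame(rows)

    def test_maximal_coclustering_hits_permutation_floor(self):
        rng = np.random.default_rng(0)
        a = self._assignments(rng, coclustered=True)
        p, observed = coclustering_test(a, n_permutations=200, seed=1)
        assert observed == 12
        assert p == pytest.approx(1 / 201)

    def test_no_selected_genes_gives_one(self):
        df = pd.DataFrame([
            {"shrna_id": "a_sh1", "gene": "a", "cluster": "I"},
            {"shrna_id": "a_sh2", "gene": "a", "cluster": "II"},
            {"shrna_id": "b_sh1", "gene": "b", "cluster": "I"},
            {"shrna_id": "b_sh2", "gene": "b", "cluster": "II"},
        ])
        p, observed = coclustering_test(df, n_permutations=50, seed=0)
        assert observed == 0
        assert p == 1.0

    def test_null_calibration_is_valid_and_nondegenerate(self):
        """With labels assigned at random the permutation p is valid
        (super-uniform: P(p <= a) <= a up to MC error). The selected-gene
        count is coarsely discrete, so the null p is conservative rather
        than exactly uniform."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(60):
            a = self._assignments(rng, coclustered=False)
            p, _ = coclustering_test(a, n_permutations=60, seed=int(rng.integers(1 << 30)))
            ps.append(p)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1, 0.25):
            mc = 3 * np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + mc
        assert len(np.unique(ps)) > 5  # not degenerate at 1.0

    def test_chi2_variant_orders_like_permutation(self):
        rng = np.random.default_rng(3)
        strong = self._assignments(rng, coclustered=True)
        weak = self._assignments(rng, coclustered=False)
        p_strong, _ = coclustering_test(strong, method="chi2")
        p_weak, _ = coclustering_test(weak, method="chi2")
        assert p_strong < p_weak
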