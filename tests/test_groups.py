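import warnings

import numpy as np
import pandas as pd
import pytest

import imprintarray as ia
from imprintarray.errors import ValidationError
from imprintarray.types import (
    BetaMatrix,
    ImprintedSiteSet,
    ProbeAnnotation,
    StateMatrix,
)


def _annotation(rows):
    frame = pd.DataFrame(
        rows, columns=["probe_id", "gene_symbol", "is_imprinted_gene", "imprint_direction"]
    ).set_index("probe_id")
    return ProbeAnnotation(frame)


def _states(rows, lines, index=None):
    frame = pd.DataFrame(rows, index=index or [f"cg{i}" for i in range(len(rows))], columns=lines)
    return StateMatrix(states=frame, t_low=0.3, t_high=0.7)


def _sites(states, genes=("G1",)):
    return ImprintedSiteSet(
        discordance=0,
        probe_ids=list(states.probe_ids),
        states=states.states,
        genes=list(genes),
    )


class TestMaternalConsistency:
    def test_maternal_methylated_consistent(self):
        states = _states([["methylated"]], ["ph1"], index=["cg0"])
        ann = _annotation([("cg0", "G1", True, "maternally_methylated")])
        rep = ia.maternal_consistency(_sites(states), states, ann, ["ph1"])
        assert rep.n_definitive_sites == 1 and rep.n_consistent == 1
        assert rep.consistency_fraction == 1.0

    def test_paternal_methylated_inconsistent(self):
        states = _states([["methylated"]], ["ph1"], index=["cg0"])
        ann = _annotation([("cg0", "G1", True, "paternally_methylated")])
        rep = ia.maternal_consistency(_sites(states), states, ann, ["ph1"])
        assert rep.n_definitive_sites == 1 and rep.n_consistent == 0

    def test_paternal_unmethylated_consistent(self):
        states = _states([["unmethylated"]], ["ph1"], index=["cg0"])
        ann = _annotation([("cg0", "G1", True, "paternally_methylated")])
        rep = ia.maternal_consistency(_sites(states), states, ann, ["ph1"])
        assert rep.consistency_fraction == 1.0

    def test_partial_not_definitive(self):
        states = _states([["partial"]], ["ph1"], index=["cg0"])
        ann = _annotation([("cg0", "G1", True, "maternally_methylated")])
        rep = ia.maternal_consistency(_sites(states), states, ann, ["ph1"])
        assert rep.n_definitive_sites == 0

    def test_disagreeing_lines_degrade_to_partial(self):
        states = _states([["methylated", "unmethylated"]], ["ph1", "ph2"], index=["cg0"])
        ann = _annotation([("cg0", "G1", True, "maternally_methylated")])
        rep = ia.maternal_consistency(_sites(states), states, ann, ["ph1", "ph2"])
        assert rep.n_definitive_sites == 0
        assert rep.detail.at["cg0", "observed_state"] == "partial"

    def test_partition_property(self, noisy_pipeline, noisy_dataset):
        *_, states = noisy_pipeline
        sites = ia.tissue_partial_filter(
            states, noisy_dataset.annotation, noisy_dataset.samples, 1
        )
        rep = ia.maternal_consistency(
            sites, states, noisy_dataset.annotation,
            noisy_dataset.samples.lines_of_class("parthenote_esc"),
        )
        known = rep.detail[
            rep.detail["definitive"] & (rep.detail["imprint_direction"] != "unknown")
        ]
        assert rep.n_consistent + int((~known["consistent"]).sum()) == rep.n_definitive_sites

    def test_noisefree_fraction_is_one(self, noisefree_pipeline, noisefree_dataset):
        *_, states = noisefree_pipeline
        sites = ia.tissue_partial_filter(
            states, noisefree_dataset.annotation, noisefree_dataset.samples, 0
        )
        rep = ia.maternal_consistency(
            sites, states, noisefree_dataset.annotation,
            noisefree_dataset.samples.lines_of_class("parthenote_esc"),
        )
        assert rep.consistency_fraction == 1.0
        assert rep.n_definitive_sites == sites.n_sites

    def test_all_unknown_direction_error(self):
        states = _states([["methylated"]], ["ph1"], index=["cg0"])
        ann = _annotation([("cg0", "G1", True, "unknown")])
        with pytest.raises(ValidationError, match="direction"):
            ia.maternal_consistency(_sites(states), states, ann, ["ph1"])

    def test_empty_group_error(self):
        states = _states([["methylated"]], ["ph1"], index=["cg0"])
        ann = _annotation([("cg0", "G1", True, "maternally_methylated")])
        with pytest.raises(ValidationError):
            ia.maternal_consistency(_sites(states), states, ann, [])


class TestDifferentialImprinted:
    def _line_beta(self, data, lines):
        return pd.DataFrame(data, index=[f"cg{i}" for i in range(len(data))], columns=lines)

    def test_identical_groups_zero_differential(self):
        beta = self._line_beta([[0.5, 0.5, 0.5, 0.5], [0.2, 0.2, 0.2, 0.2]], list("abcd"))
        ann = _annotation(
            [("cg0", "G1", True, "unknown"), ("cg1", "G2", True, "unknown")]
        )
        table = ia.differential_imprinted(beta, ann, ["a", "b"], ["c", "d"], delta=0.01)
        assert table.n_differential == 0

    def test_planted_shift_any_probe(self, noisefree_dataset, noisefree_pipeline):
        _, _, _, line_beta, _ = noisefree_pipeline
        samples = noisefree_dataset.samples
        table = ia.differential_imprinted(
            line_beta,
            noisefree_dataset.annotation,
            samples.lines_of_class("parthenote_esc"),
            samples.lines_of_class("conventional_esc"),
            delta=0.2,
            aggregation="any_probe",
        )
        dmr = noisefree_dataset.truth.frame["is_true_dmr"].astype(bool)
        genes_with_dmr = set(
            noisefree_dataset.annotation.frame.loc[dmr.to_numpy(), "gene_symbol"]
        )
        flagged = set(table.frame.index[table.frame["is_differential"]])
        assert genes_with_dmr <= flagged

    def test_extreme_delta_flags_nothing(self, noisefree_dataset, noisefree_pipeline):
        _, _, _, line_beta, _ = noisefree_pipeline
        samples = noisefree_dataset.samples
        table = ia.differential_imprinted(
            line_beta,
            noisefree_dataset.annotation,
            samples.lines_of_class("parthenote_esc"),
            samples.lines_of_class("conventional_esc"),
            delta=0.999,
        )
        # gene_mean aggregation averages DMR and non-DMR probes, so no gene
        # reaches a difference of ~1
        assert table.n_differential == 0

    def test_symmetry_under_group_swap(self, noisy_dataset, noisy_pipeline):
        _, _, _, line_beta, _ = noisy_pipeline
        samples = noisy_dataset.samples
        a = samples.lines_of_class("parthenote_esc")
        b = samples.lines_of_class("conventional_esc")
        ab = ia.differential_imprinted(line_beta, noisy_dataset.annotation, a, b, delta=0.2)
        ba = ia.differential_imprinted(line_beta, noisy_dataset.annotation, b, a, delta=0.2)
        np.testing.assert_allclose(
            ab.frame["difference"].to_numpy(), -ba.frame["difference"].to_numpy()
        )
        assert (ab.frame["is_differential"] == ba.frame["is_differential"]).all()

    def test_invalid_delta(self, noisefree_pipeline, noisefree_dataset):
        _, _, _, line_beta, _ = noisefree_pipeline
        with pytest.raises(ValidationError):
            ia.differential_imprinted(
                line_beta, noisefree_dataset.annotation, ["a"], ["b"], delta=1.0
            )

    def test_gene_without_probes_excluded_with_warning(self):
        beta = self._line_beta([[0.9, 0.1]], ["a", "b"])
        ann = _annotation(
            [("cg0", "G1", True, "unknown"), ("cgX", "G2", True, "unknown")]
        )
        beta = beta.drop(index=[])  # cgX absent from beta
        with pytest.warns(UserWarning, match="excluded"):
            table = ia.differential_imprinted(beta, ann, ["a"], ["b"], delta=0.2)
        assert table.n_excluded_genes == 1
        assert list(table.frame.index) == ["G1"]


class TestSampleCorrelation:
    def test_duplicated_sample_correlation_one(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        beta = BetaMatrix(values=pd.DataFrame({"s1": x, "s2": x}))
        corr = ia.sample_correlation_matrix(beta)
        assert corr.at["s1", "s2"] == pytest.approx(1.0)

    def test_complement_correlation_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.random(30)
        beta = BetaMatrix(values=pd.DataFrame({"s1": x, "s2": 1 - x}))
        corr = ia.sample_correlation_matrix(beta)
        assert corr.at["s1", "s2"] == pytest.approx(-1.0)

    def test_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.random((40, 5)), columns=list("abcde"))
        corr = ia.sample_correlation_matrix(BetaMatrix(values=values))
        for i in "abcde":
            for j in "abcde":
                xi, xj = values[i].to_numpy(), values[j].to_numpy()
                mi, mj = xi.mean(), xj.mean()
                expected = float(
                    ((xi - mi) * (xj - mj)).sum()
                    / np.sqrt(((xi - mi) ** 2).sum() * ((xj - mj) ** 2).sum())
                )
                if i == j:
                    expected = 1.0
                assert corr.at[i, j] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_warns(self):
        values = pd.DataFrame(
            {"s1": [0.1, np.nan, np.nan], "s2": [np.nan, 0.5, 0.6], "s3": [0.1, 0.2, 0.3]}
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            corr = ia.sample_correlation_matrix(BetaMatrix(values=values))
        assert np.isnan(corr.at["s1", "s2"])

    def test_single_sample_error(self):
        with pytest.raises(ValidationError):
            ia.sample_correlation_matrix(BetaMatrix(values=pd.DataFrame({"s1": [0.1, 0.2]})))


class TestHierarchicalCluster:
    def test_identical_pair_merges_first(self):
        rng = np.random.default_rng(3)
        x = rng.random(25)
        values = pd.DataFrame({"a": x, "b": x, "c": 1 - x})
        dendro = ia.hierarchical_cluster(ia.sample_correlation_matrix(BetaMatrix(values=values)))
        assert dendro.cluster_members()[0] == frozenset({"a", "b"})

    def test_missing_cells_rejected(self):
        corr = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValidationError, match="missing"):
            ia.hierarchical_cluster(corr)

    def test_permutation_invariance(self, noisy_pipeline, noisy_dataset):
        _, _, normalized, _, _ = noisy_pipeline
        bio = [
            s for s in normalized.sample_ids
            if noisy_dataset.samples.frame.at[s, "sample_class"]
            in ("tissue", "primary_cell", "conventional_esc", "parthenote_esc")
        ]
        values = normalized.values[bio]
        corr = ia.sample_correlation_matrix(BetaMatrix(values=values, normalized=True))
        shuffled_cols = list(reversed(bio))
        corr2 = ia.sample_correlation_matrix(
            BetaMatrix(values=values[shuffled_cols], normalized=True)
        )
        d1 = ia.hierarchical_cluster(corr)
        d2 = ia.hierarchical_cluster(corr2)
        assert d1.labels == d2.labels
        assert set(map(frozenset, d1.cluster_members())) == set(
            map(frozenset, d2.cluster_members())
        )

    def test_heights_nonnegative_and_monotone(self, noisy_pipeline, noisy_dataset):
        _, _, normalized, _, _ = noisy_pipeline
        bio = [
            s for s in normalized.sample_ids
            if noisy_dataset.samples.frame.at[s, "sample_class"]
            in ("tissue", "primary_cell", "conventional_esc", "parthenote_esc")
        ]
        corr = ia.sample_correlation_matrix(
            BetaMatrix(values=normalized.values[bio], normalized=True)
        )
        dendro = ia.hierarchical_cluster(corr)
        heights = dendro.merge_heights()
        assert (heights >= 0).all()
        assert (np.diff(heights) >= -1e-12).all()

    def test_es_cells_form_subtree_excluding_tissue(self, noisy_pipeline, noisy_dataset):
        _, _, normalized, _, _ = noisy_pipeline
        bio = [
            s for s in normalized.sample_ids
            if noisy_dataset.samples.frame.at[s, "sample_class"]
            in ("tissue", "primary_cell", "conventional_esc", "parthenote_esc")
        ]
        corr = ia.sample_correlation_matrix(
            BetaMatrix(values=normalized.values[bio], normalized=True)
        )
        dendro = ia.hierarchical_cluster(corr)
        esc = [
            s for s in bio
            if noisy_dataset.samples.frame.at[s, "sample_class"]
            in ("conventional_esc", "parthenote_esc")
        ]
        tissue = [
            s for s in bio
            if noisy_dataset.samples.frame.at[s, "sample_class"] == "tissue"
        ]
        assert dendro.has_exclusive_cluster(esc, tissue)

    def test_newick_contains_all_labels(self, noisy_pipeline, noisy_dataset):
        _, _, normalized, _, _ = noisy_pipeline
        bio = [
            s for s in normalized.sample_ids
            if noisy_dataset.samples.frame.at[s, "sample_class"] == "parthenote_esc"
        ]
        corr = ia.sample_correlation_matrix(
            BetaMatrix(values=normalized.values[bio], normalized=True)
        )
        newick = ia.hierarchical_cluster(corr).to_newick()
        assert newick.endswith(";")
        for s in bio:
            assert s in newick


class TestDiscordanceCorrelationCurve:
    def test_vacuous_k_selects_all_nonfailed(self, noisy_pipeline, noisy_dataset):
        _, _, _, line_beta, states = noisy_pipeline
        ph = noisy_dataset.samples.lines_of_class("parthenote_esc")
        curve = ia.discordance_correlation_curve(
            line_beta, states, noisy_dataset.annotation, noisy_dataset.samples,
            ph, k_max=len(ph), site_mode="all_sites",
        )
        n_at_kmax = curve.loc[curve["k"] == len(ph), "n_sites"].iloc[0]
        nonfailed = (states.states[ph] != "failed").any(axis=1).sum()
        assert n_at_kmax == nonfailed

    def test_reference_member_monotone_on_noisefree(self, noisefree_pipeline, noisefree_dataset):
        _, _, _, line_beta, states = noisefree_pipeline
        ph = noisefree_dataset.samples.lines_of_class("parthenote_esc")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = ia.discordance_correlation_curve(
                line_beta, states, noisefree_dataset.annotation, noisefree_dataset.samples,
                ph, k_max=len(ph) - 1, site_mode="all_sites",
            )
        member = curve[curve["line_id"] == ph[0]].sort_values("k")
        r = member["correlation"].to_numpy()
        assert (np.diff(r) <= 1e-12).all()  # non-decreasing as k decreases

    def test_imprinted_sites_separate_groups_more(self, noisy_pipeline, noisy_dataset):
        _, _, _, line_beta, states = noisy_pipeline
        samples = noisy_dataset.samples
        ph = samples.lines_of_class("parthenote_esc")
        he = samples.lines_of_class("conventional_esc")

        def gap(mode):
            curve = ia.discordance_correlation_curve(
                line_beta, states, noisy_dataset.annotation, samples, ph,
                k_max=len(ph) - 2, site_mode=mode,
            )
            by_line = curve.groupby("line_id")["correlation"].mean()
            return float(by_line[ph].mean() - by_line[he].mean())

        assert gap("imprinted_sites") > gap("all_sites")

    def test_small_reference_group_rejected(self, noisy_pipeline, noisy_dataset):
        _, _, _, line_beta, states = noisy_pipeline
        with pytest.raises(ValidationError):
            ia.discordance_correlation_curve(
                line_beta, states, noisy_dataset.annotation, noisy_dataset.samples,
                ["phESC_1"], k_max=0,
            )
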