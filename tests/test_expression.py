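"""Count QC, normalization, DE stand-in, BH, DEG filter and signature algebra."""

import numpy as np
import pandas as pd
import pytest

import mitoresponse as mr
from tests.conftest import make_de_table


def make_experiment(counts, meta=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"P{i}" for i in range(len(counts))]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    if meta is None:
        meta = pd.DataFrame(
            {"compound": "x", "concentration": 1.0, "condition": "x@1"},
            index=counts.columns,
        )
    return mr.CountExperiment(counts=counts, samples=meta)


class TestLibraryFilter:
    def test_strictly_below_threshold_removed(self):
        exp = make_experiment(np.array([[99_999, 100_000, 150_000]]))
        out = mr.library_size_filter(exp)
        assert list(out.counts.columns) == ["s1", "s2"]

    def test_no_removals_is_identity(self):
        exp = make_experiment(np.array([[200_000, 300_000]]))
        out = mr.library_size_filter(exp)
        assert out.counts.equals(exp.counts)

    def test_all_removed_is_hard_error(self):
        exp = make_experiment(np.array([[10, 20]]))
        with pytest.raises(ValueError, match="all samples"):
            mr.library_size_filter(exp)


class TestMedianOfRatios:
    def test_identical_samples_unit_factors(self):
        exp = make_experiment(np.array([[10, 10], [20, 20], [5, 5]]))
        out = mr.median_of_ratios(exp)
        assert out.size_factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_two_probes(self):
        """B = 2A over 2 probes -> factors (1/sqrt2, sqrt2)."""
        exp = make_experiment(np.array([[10, 20], [30, 60]]))
        out = mr.median_of_ratios(exp)
        assert out.size_factors.to_numpy() == pytest.approx(
            [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_scale_equivariance(self):
        """Scaling one sample by k multiplies its size factor relative to the
        others by k and leaves relative expression (sample-to-sample ratios of
        normalized values) unchanged; geometric means absorb a k**(1/n)
        common factor."""
        rng = np.random.default_rng(0)
        base = rng.integers(1, 1000, size=(20, 4))
        exp = mr.median_of_ratios(make_experiment(base))
        scaled = base.copy()
        scaled[:, 2] *= 3
        exp2 = mr.median_of_ratios(make_experiment(scaled))
        ratio = exp2.size_factors / exp.size_factors
        assert ratio.iloc[2] / ratio.iloc[0] == pytest.approx(3.0)
        rel = exp.normalized.iloc[:, 1] / exp.normalized.iloc[:, 0]
        rel2 = exp2.normalized.iloc[:, 1] / exp2.normalized.iloc[:, 0]
        assert rel2.to_numpy() == pytest.approx(rel.to_numpy())
        assert exp2.normalized.iloc[:, 2].to_numpy() / exp2.normalized.iloc[:, 0].to_numpy() == \
            pytest.approx(exp.normalized.iloc[:, 2].to_numpy() / exp.normalized.iloc[:, 0].to_numpy())

    def test_global_rescaling_leaves_size_factors_unchanged(self):
        rng = np.random.default_rng(5)
        base = rng.integers(1, 1000, size=(15, 3))
        exp = mr.median_of_ratios(make_experiment(base))
        exp2 = mr.median_of_ratios(make_experiment(base * 4))
        assert exp2.size_factors.to_numpy() == pytest.approx(exp.size_factors.to_numpy())
        assert exp2.normalized.to_numpy() == pytest.approx(4 * exp.normalized.to_numpy())

    def test_no_universally_expressed_probe_errors(self):
        exp = make_experiment(np.array([[0, 5], [5, 0]]))
        with pytest.raises(ValueError, match="pseudo"):
            mr.median_of_ratios(exp)
        out = mr.median_of_ratios(exp, pseudo_count=0.5)
        assert (out.size_factors > 0).all()


class TestDETest:
    def _exp(self, control, treated):
        counts = np.column_stack([control, treated]).astype(int)
        n_c, n_t = control.shape[1], treated.shape[1]
        meta = pd.DataFrame(
            {
                "compound": ["vehicle"] * n_c + ["x"] * n_t,
                "concentration": [0.0] * n_c + [1.0] * n_t,
                "condition": ["vehicle"] * n_c + ["x@1"] * n_t,
            },
            index=[f"s{i}" for i in range(n_c + n_t)],
        )
        return mr.median_of_ratios(make_experiment(counts, meta))

    def test_identical_groups_null(self):
        vals = np.tile([[100], [200], [300]], (1, 3))
        det = mr.de_test(self._exp(vals, vals), "x@1")
        assert det["log2fc"].to_numpy() == pytest.approx(0.0, abs=1e-12)
        assert det["p_value"].to_numpy() == pytest.approx(1.0)

    def test_planted_fourfold_change(self):
        rng = np.random.default_rng(1)
        control = rng.poisson(1000, size=(30, 4))
        treated = rng.poisson(1000, size=(30, 4))
        treated[0] = rng.poisson(4000, size=4)
        # other probes dominate the size factors, so the planted shift survives
        det = mr.de_test(self._exp(control, treated), "x@1")
        assert det["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.2)

    def test_unreplicated_side_refused_unless_allowed(self):
        control = np.array([[100, 110], [50, 60]])
        treated = np.array([[400], [50]])
        exp = self._exp(control, treated)
        with pytest.raises(ValueError, match="unreplicated"):
            mr.de_test(exp, "x@1")
        det = mr.de_test(exp, "x@1", allow_unreplicated=True)
        assert np.isnan(det["p_value"]).all()
        assert np.isfinite(det["log2fc"]).all()

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(2)
        control = rng.poisson(500, size=(2000, 4))
        treated = rng.poisson(500, size=(2000, 4))
        det = mr.de_test(self._exp(control, treated), "x@1")
        from scipy.stats import kstest

        assert kstest(det["p_value"], "uniform").pvalue > 0.01


def brute_force_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        adj[i] = prev
    return adj


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.2], [0.2]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert mr.bh_adjust(p) == pytest.approx(expected)

    def test_matches_step_up_definition_on_grid(self):
        grid = np.array([0.0, 0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0])
        rng = np.random.default_rng(3)
        for n in range(1, 9):
            for _ in range(30):
                p = rng.choice(grid, size=n)
                assert mr.bh_adjust(p) == pytest.approx(brute_force_bh(p))

    def test_nan_propagates_without_shifting_ranks(self):
        p = [0.01, np.nan, 0.02, 0.03]
        out = mr.bh_adjust(p)
        assert np.isnan(out[1])
        assert out[[0, 2, 3]] == pytest.approx(mr.bh_adjust([0.01, 0.02, 0.03]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mr.bh_adjust([0.5, 1.5])


class TestDEGFilter:
    @pytest.mark.parametrize(
        "padj,lfc,trend,passes",
        [
            (0.04, 0.60, 0.01, True),
            (0.05, 0.60, 0.01, False),  # strict <
            (0.04, 0.58, 0.01, False),  # strict >
            (0.04, -0.60, 0.01, True),
            (0.04, 0.60, 0.05, False),
            (0.04, 0.60, np.nan, False),
        ],
    )
    def test_threshold_boundaries(self, padj, lfc, trend, passes):
        det = make_de_table([("g", "c", lfc, padj, trend)])
        assert (mr.deg_filter(det) == {"g"}) is passes


def brute_force_signature(deg_sets, labels):
    probes = set().union(*deg_sets.values()) if deg_sets else set()
    by_probe = {}
    for p in probes:
        in_conds = {c for c, s in deg_sets.items() if p in s}
        by_probe[p] = in_conds
    act = {c for c in deg_sets if labels.loc[c, "activity"] == "active"}
    inact = {c for c in deg_sets if labels.loc[c, "activity"] == "inactive"}
    ctrl = {c for c in deg_sets if labels.loc[c, "class_label"] == "positive_control"}
    ci = {c for c in deg_sets if labels.loc[c, "class_label"] == "CI"}
    ciii = {c for c in deg_sets if labels.loc[c, "class_label"] == "CIII"}
    any_active = {p for p, s in by_probe.items() if s & act}
    unique_ci = {p for p, s in by_probe.items() if s & ci and not s & ciii}
    unique_ciii = {p for p, s in by_probe.items() if s & ciii and not s & ci}
    anc = {p for p in any_active if not by_probe[p] & (inact | ctrl)}
    core = {p for p in anc if act <= by_probe[p]}
    return any_active, unique_ci, unique_ciii, anc, core


class TestSignatureSets:
    def _labels(self, spec):
        return pd.DataFrame(
            [
                {"condition": c, "activity": a, "class_label": k, "compound": c}
                for c, (a, k) in spec.items()
            ]
        ).set_index("condition")

    def test_spec_toy_example(self):
        deg = {"A": {"g1", "g2"}, "B": {"g1"}, "I": {"g3"}, "P": {"g2"}}
        labels = self._labels(
            {"A": ("active", "CI"), "B": ("active", "CIII"),
             "I": ("inactive", "CII"), "P": ("control", "positive_control")}
        )
        sig = mr.signature_sets(deg, labels)
        assert sig.any_active == {"g1", "g2"}
        assert sig.active_not_control == {"g1"}
        assert sig.core == {"g1"}

    def test_empty_active_sets_all_empty(self):
        deg = {"I": {"g1"}}
        labels = self._labels({"I": ("inactive", "CII")})
        sig = mr.signature_sets(deg, labels)
        assert sig.any_active == set() and sig.core == set()

    def test_probe_in_all_actives_and_control_excluded(self):
        deg = {"A": {"g"}, "B": {"g"}, "P": {"g"}}
        labels = self._labels(
            {"A": ("active", "CI"), "B": ("active", "CIII"),
             "P": ("control", "positive_control")}
        )
        sig = mr.signature_sets(deg, labels)
        assert "g" not in sig.core and "g" not in sig.active_not_control

    def test_unlabeled_condition_rejected(self):
        empty = pd.DataFrame(columns=["activity", "class_label", "compound"])
        with pytest.raises(ValueError, match="label"):
            mr.signature_sets({"A": {"g"}}, empty)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        activities = ["active", "inactive", "control"]
        classes = {"active": ["CI", "CIII"], "inactive": ["CII"],
                   "control": ["positive_control"]}
        for _ in range(200):
            n_cond = rng.integers(2, 7)
            n_probes = rng.integers(3, 21)
            probes = [f"g{i}" for i in range(n_probes)]
            spec, deg = {}, {}
            has_active = False
            for j in range(n_cond):
                act = activities[rng.integers(0, 3)]
                has_active |= act == "active"
                cls = classes[act][rng.integers(0, len(classes[act]))]
                spec[f"c{j}"] = (act, cls)
                deg[f"c{j}"] = set(
                    p for p in probes if rng.random() < 0.4
                )
            if not has_active:
                spec["cA"] = ("active", "CI")
                deg["cA"] = set(p for p in probes if rng.random() < 0.4)
            sig = mr.signature_sets(deg, self._labels(spec))
            aa, uci, uciii, anc, core = brute_force_signature(deg, self._labels(spec))
            assert sig.any_active == aa
            assert sig.unique_ci == uci
            assert sig.unique_ciii == uciii
            assert sig.active_not_control == anc
            assert sig.core == core
            # structural invariants
            assert sig.core <= sig.active_not_control
            assert not (sig.unique_ci & sig.unique_ciii)


class TestRefineSignature:
    def test_effect_size_or_annotation(self):
        det = make_de_table(
            [
                ("g_strong", "A", 2.5, 0.01, 0.01),
                ("g_flagged", "A", 1.0, 0.01, 0.01),
                ("g_weak", "A", 1.0, 0.01, 0.01),
            ]
        )
        core = {"g_strong", "g_flagged", "g_weak"}
        refined = mr.refine_signature(core, det, {"g_flagged": True, "g_weak": False})
        assert refined == {"g_strong", "g_flagged"}

    def test_missing_annotation_treated_unflagged(self):
        det = make_de_table([("g", "A", 1.0, 0.01, 0.01)])
        assert mr.refine_signature({"g"}, det, {}) == set()


class TestConcordance:
    def _det(self, lfcs):
        return make_de_table(
            [(f"g{i}", "A", lfc, 0.01, 0.01) for i, lfc in enumerate(lfcs)]
        )

    def test_self_comparison_fully_concordant(self):
        det = self._det([1.0, -1.0, 2.0])
        same, diff, total, _ = mr.concordance(det, det)
        assert (same, diff, total) == (3, 0, 3)

    def test_negated_table_fully_discordant(self):
        det = self._det([1.0, -1.0, 2.0])
        neg = det.copy()
        neg["log2fc"] = -neg["log2fc"]
        same, diff, total, _ = mr.concordance(det, neg)
        assert (same, diff, total) == (0, 3, 3)

    def test_single_planted_flip(self):
        a = self._det([1.0, 1.0, -1.0, 2.0, -2.0])
        b = a.copy()
        b.loc[b["probe"] == "g2", "log2fc"] = 1.0  # flip one sign
        same, diff, total, _ = mr.concordance(a, b)
        assert (same, diff, total) == (4, 1, 5)

    def test_no_shared_passing_probes_warns(self):
        a = self._det([1.0])
        b = self._det([0.1])  # fails |log2fc| filter
        with pytest.warns(UserWarning, match="no shared"):
            same, diff, total, _ = mr.concordance(a, b)
        assert total == 0


class TestGenesetAbsLog2FC:
    def test_all_zero(self):
        det = make_de_table([(f"g{i}", "A", 0.0, 1.0, 1.0) for i in range(5)])
        out = mr.geneset_abs_log2fc(det, {"g0", "g1"})
        assert out["set_mean"].iloc[0] == 0.0
        assert out["overall_mean"].iloc[0] == 0.0

    def test_constructed_means(self):
        det = make_de_table(
            [("g0", "A", 1.0, 0.1, 0.1), ("g1", "A", -1.0, 0.1, 0.1),
             ("g2", "A", 0.0, 0.1, 0.1), ("g3", "A", 0.0, 0.1, 0.1)]
        )
        out = mr.geneset_abs_log2fc(det, {"g0", "g1"})
        assert out["set_mean"].iloc[0] == pytest.approx(1.0)
        assert out["overall_mean"].iloc[0] == pytest.approx(0.5)

    def test_full_set_equals_overall(self):
        det = make_de_table([(f"g{i}", "A", i * 0.3, 0.1, 0.1) for i in range(4)])
        out = mr.geneset_abs_log2fc(det, {f"g{i}" for i in range(4)})
        assert out["set_mean"].iloc[0] == pytest.approx(out["overall_mean"].iloc[0])

    def test_empty_intersection_names_missing(self):
        det = make_de_table([("g0", "A", 1.0, 0.1, 0.1)])
        with pytest.raises(ValueError, match="gX"):
            mr.geneset_abs_log2fc(det, {"gX"})
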