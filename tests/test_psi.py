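import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from splicedyn.events import SpliceEvent
from splicedyn.psi import (
    AnalysisConfig,
    classify_over_normal,
    compare_adjacent,
    compare_tissue_pairs,
    compute_psi,
    compute_psi_table,
    delta_psi,
    over_event_gene_counts,
    paired_wilcoxon,
)
from splicedyn.simulate import SimulationConfig, simulate_dataset
from splicedyn.events import enumerate_events

from oracles import exact_wilcoxon_p


def _event(f1=("a",), f2=("b",)):
    return SpliceEvent(
        event_id="g;RI;0,1,2,3", gene_id="g", event_type="RI",
        scaffold="s1", strand="+", form1_signature=(0, 1, 2, 3),
        form2_signature=(0, 1, 2, 3), F1=set(f1), F2=set(f2),
    )


class TestComputePsi:
    def test_direct_arithmetic(self):
        assert compute_psi(_event(), {"a": 3.0, "b": 1.0}) == pytest.approx(0.75)

    def test_equal_totals_give_half(self):
        assert compute_psi(_event(), {"a": 2.0, "b": 2.0}) == pytest.approx(0.5)

    def test_only_form_one_expressed_gives_one(self):
        assert compute_psi(_event(), {"a": 2.0, "b": 0.0}) == pytest.approx(1.0)

    def test_total_at_or_below_floor_is_undefined(self):
        assert np.isnan(compute_psi(_event(), {"a": 0.5, "b": 0.4}))
        # the floor is strict: exactly 1 TPM total is still undefined
        assert np.isnan(compute_psi(_event(), {"a": 0.6, "b": 0.4}))

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(_event(), {"a": -1.0, "b": 2.0})

    def test_form_swap_antisymmetry(self):
        tpm = {"a": 3.2, "b": 1.7}
        forward = compute_psi(_event(), tpm)
        swapped = compute_psi(_event(f1=("b",), f2=("a",)), tpm)
        assert forward + swapped == pytest.approx(1.0)

    @given(st.floats(0.01, 100.0), st.floats(0.0, 100.0),
           st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_above_floor(self, f1, f2, scale):
        base = compute_psi(_event(), {"a": f1, "b": f2}, floor=0.0)
        scaled = compute_psi(_event(), {"a": f1 * scale, "b": f2 * scale}, floor=0.0)
        assert scaled == pytest.approx(base, abs=1e-9)


class TestDeltaPsi:
    def test_difference(self):
        assert delta_psi(0.2, 0.4) == pytest.approx(0.2)

    def test_undefined_propagates(self):
        assert np.isnan(delta_psi(0.5, float("nan")))
        assert np.isnan(delta_psi(float("nan"), 0.5))

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds(self, a, b):
        assert -1.0 <= delta_psi(a, b) <= 1.0


class TestPairedWilcoxon:
    def test_identical_vectors_carry_no_signal(self):
        stat, p = paired_wilcoxon(np.ones(5), np.ones(5))
        assert p == 1.0

    def test_small_n_matches_exact_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0.4, 1.0, n)
            if np.any(x == y) or len(set(np.abs(x - y))) < n:
                continue
            _, p = paired_wilcoxon(x, y)
            assert p == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)

    def test_large_n_matches_normal_approximation(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0.1, 1.0, n)
        _, p = paired_wilcoxon(x, y)
        # hand-computed large-sample reference (no ties, no zeros)
        d = x - y
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        mean = n * (n + 1) / 4
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        z = (w_plus - mean) / sd
        p_ref = 2 * stats.norm.sf(abs(z))
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_rejects_mismatched_or_empty(self):
        with pytest.raises(ValueError):
            paired_wilcoxon(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            paired_wilcoxon(np.array([]), np.array([]))


def _table_from(psi_frame, types=None):
    from splicedyn.psi import PsiTable

    types = types or {i: "RI" for i in psi_frame.index}
    return PsiTable(
        psi=psi_frame,
        total_tpm=psi_frame * 0 + 10,
        event_types=pd.Series(types),
        event_genes=pd.Series({i: f"g_{i}" for i in psi_frame.index}),
    )


class TestCompareAdjacent:
    def test_identical_distributions_give_p_one(self):
        psi = pd.DataFrame(
            {"T2": np.linspace(0.1, 0.9, 12), "T4": np.linspace(0.1, 0.9, 12)},
            index=[f"e{i}" for i in range(12)],
        )
        out = compare_adjacent(_table_from(psi), AnalysisConfig(adjacency=["T2", "T4"]))
        assert out["p_value"].iloc[0] == 1.0

    def test_undefined_cells_drop_pairs(self):
        psi = pd.DataFrame(
            {"T2": [0.1, np.nan, 0.3], "T4": [0.2, 0.5, np.nan]},
            index=["e0", "e1", "e2"],
        )
        out = compare_adjacent(_table_from(psi), AnalysisConfig(adjacency=["T2", "T4"]))
        assert out["n_pairs"].iloc[0] == 1
        assert bool(out["underpowered"].iloc[0])

    def test_planted_step_yields_minimum_p_at_transition(self):
        cfg = SimulationConfig(
            seed=31, event_mix={"RI": 200}, n_over_ri=60, noise_sd=0.05,
            n_scaffolds=2, scaffold_length=1_000_000, n_background_genes=0,
            n_fragmented=0, n_precursor=0, include_tissues=False,
        )
        ds = simulate_dataset(cfg)
        events = [e for g in ds.genes for e in enumerate_events(g)]
        table = compute_psi_table(events, ds.tpm)
        out = compare_adjacent(table, AnalysisConfig(adjacency=list(cfg.samples)))
        ri = out[out["event_type"] == "RI"].reset_index(drop=True)
        best = ri.loc[ri["p_value"].idxmin()]
        assert (best["sample_a"], best["sample_b"]) == (
            cfg.samples[cfg.activation_index - 1],
            cfg.samples[cfg.activation_index],
        )


class TestCompareTissues:
    def test_pair_count_is_all_unordered_pairs(self):
        rng = np.random.default_rng(5)
        tissues = [f"tis{i}" for i in range(9)]
        cols = {t: [f"{t}_d1", f"{t}_d2"] for t in tissues}
        psi = pd.DataFrame(
            rng.uniform(0, 1, (20, 18)),
            index=[f"e{i}" for i in range(20)],
            columns=[c for cs in cols.values() for c in cs],
        )
        out = compare_tissue_pairs(
            _table_from(psi), AnalysisConfig(tissue_samples=cols)
        )
        assert len(out) == 36  # C(9,2) pairs, one event type

    def test_identical_tissues_give_p_one(self):
        psi = pd.DataFrame(
            {"a_1": np.linspace(0, 1, 10), "b_1": np.linspace(0, 1, 10)},
            index=[f"e{i}" for i in range(10)],
        )
        out = compare_tissue_pairs(
            _table_from(psi),
            AnalysisConfig(tissue_samples={"a": ["a_1"], "b": ["b_1"]}),
        )
        assert out["p_value"].iloc[0] == 1.0

    def test_planted_tissue_shift_dominates_smallest_p(self):
        cfg = SimulationConfig(
            seed=33, event_mix={"RI": 120}, n_over_ri=120, noise_sd=0.05,
            n_scaffolds=2, scaffold_length=1_000_000, n_background_genes=0,
            n_fragmented=0, n_precursor=0,
            tissue_ri_shift=("M", 0.3),
        )
        ds = simulate_dataset(cfg)
        events = [e for g in ds.genes for e in enumerate_events(g)]
        table = compute_psi_table(events, ds.tpm)
        grouping: dict[str, list[str]] = {}
        for c in table.psi.columns:
            if "_" in c:
                grouping.setdefault(c.split("_")[0], []).append(c)
        out = compare_tissue_pairs(
            table, AnalysisConfig(tissue_samples=grouping)
        )
        ri = out[out["event_type"] == "RI"].sort_values("p_value")
        top = ri.head(8)
        assert ((top["sample_a"] == "M") | (top["sample_b"] == "M")).all()


class TestEventTypeComposition:
    def test_one_event_per_type_gives_equal_ratios(self):
        from splicedyn.psi import event_type_composition

        types = dict(zip([f"e{i}" for i in range(7)],
                         ["A3", "A5", "AF", "AL", "MX", "RI", "SE"]))
        psi = pd.DataFrame({"T2": [0.5] * 7, "T4": [0.5] * 7},
                           index=list(types))
        out = event_type_composition(_table_from(psi, types=types),
                                     {"early": ["T2", "T4"]})
        assert len(out) == 7
        assert np.allclose(out["ratio"], 1 / 7)

    def test_event_undefined_throughout_stage_excluded(self):
        from splicedyn.psi import event_type_composition

        types = {"e0": "RI", "e1": "SE"}
        psi = pd.DataFrame({"T2": [np.nan, 0.5], "T4": [np.nan, 0.6],
                            "T5": [0.4, 0.5]}, index=list(types))
        out = event_type_composition(_table_from(psi, types=types),
                                     {"early": ["T2", "T4"], "late": ["T5"]})
        early = out[out["stage"] == "early"]
        assert early["event_type"].tolist() == ["SE"]
        assert early["ratio"].tolist() == [1.0]

    def test_ratios_sum_to_one_per_stage(self):
        from splicedyn.psi import event_type_composition

        rng = np.random.default_rng(2)
        types = {f"e{i}": t for i, t in enumerate(
            rng.choice(["RI", "SE", "A3"], 30))}
        values = rng.uniform(0, 1, (30, 4))
        values[rng.random((30, 4)) < 0.3] = np.nan
        psi = pd.DataFrame(values, index=list(types),
                           columns=["T2", "T4", "T5", "T6"])
        out = event_type_composition(
            _table_from(psi, types=types),
            {"a": ["T2", "T4"], "b": ["T5", "T6"]},
        )
        sums = out.groupby("stage")["ratio"].sum()
        assert np.allclose(sums, 1.0)


class TestClassifyOverNormal:
    def _table(self, deltas):
        psi = pd.DataFrame(
            {"T6": [0.4] * len(deltas), "T7": [0.4 + d for d in deltas]},
            index=[f"e{i}" for i in range(len(deltas))],
        )
        return _table_from(psi)

    def test_threshold_is_strict(self):
        out = classify_over_normal(self._table([0.10, 0.07, -0.30]), "T6", "T7")
        assert out["label"].tolist() == ["over", "normal", "normal"]

    def test_undefined_delta_excluded_with_reason(self):
        psi = pd.DataFrame({"T6": [np.nan], "T7": [0.5]}, index=["e0"])
        out = classify_over_normal(_table_from(psi), "T6", "T7")
        assert out["label"].isna().all()
        assert out["excluded_reason"].iloc[0] != ""

    def test_restricted_to_ri_by_default(self):
        psi = pd.DataFrame({"T6": [0.1, 0.1], "T7": [0.5, 0.5]},
                           index=["e0", "e1"])
        table = _table_from(psi, types={"e0": "RI", "e1": "SE"})
        out = classify_over_normal(table, "T6", "T7")
        assert list(out.index) == ["e0"]
        widened = classify_over_normal(table, "T6", "T7", event_types=("RI", "SE"))
        assert len(widened) == 2

    def test_gene_counts_of_over_events(self):
        out = classify_over_normal(self._table([0.2, 0.3, 0.0]), "T6", "T7")
        out.loc[:, "gene_id"] = ["gA", "gA", "gB"]
        counts = over_event_gene_counts(out)
        assert counts.to_dict() == {"gA": 2}
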