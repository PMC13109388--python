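import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from rule_oracles import (
    brute_force_coverage,
    brute_force_ri_filter,
    brute_force_rmats_filter,
)
from splicequant.significance import (
    coverage_filter,
    delta_inclusion,
    deltas_by_event,
    filter_rmats,
    ir_table_to_inclusion,
    read_rmats,
    ri_exon_length_filter,
    test_ir as ir_ttest,
    write_rmats_like,
)


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=["event_id", "as_type", "condition", "replicate", "inclusion_level", "read_count"],
    )


def event_rows(event_id, values_by_condition, counts_by_condition=None, as_type="SE"):
    rows = []
    for cond, values in values_by_condition.items():
        counts = (counts_by_condition or {}).get(cond, [100] * len(values))
        for k, (v, c) in enumerate(zip(values, counts)):
            rows.append([event_id, as_type, cond, f"rep{k + 1}", v, c])
    return rows


# ---------------------------------------------------------------------------
# coverage filter


def test_coverage_filter_scope_semantics():
    table = make_table(
        event_rows("e1", {"WT": [0.5] * 3, "KO": [0.5] * 3},
                   {"WT": [60, 60, 60], "KO": [10, 10, 10]})
    )
    assert set(coverage_filter(table, 50, "any_condition")["event_id"]) == {"e1"}
    assert coverage_filter(table, 50, "all_conditions").empty


def test_coverage_filter_zero_cutoff_is_identity():
    table = make_table(
        event_rows("e1", {"WT": [0.1, 0.2], "KO": [0.3, 0.4]}, {"WT": [0, 0], "KO": [5, 1]})
    )
    for scope in ("any_condition", "all_conditions"):
        assert coverage_filter(table, 0, scope).equals(table)


def test_coverage_filter_matches_brute_force(rng):
    rows = []
    for i in range(500):
        lam = rng.uniform(10, 120)
        for cond in ("WT", "KO", "KD"):
            for rep in range(3):
                rows.append([f"e{i}", "SE", cond, f"rep{rep}", 0.5, int(rng.poisson(lam))])
    table = make_table(rows)
    triples = list(zip(table["event_id"], table["condition"], table["read_count"]))
    for scope in ("any_condition", "all_conditions"):
        got = set(coverage_filter(table, 50, scope)["event_id"])
        assert got == brute_force_coverage(triples, 50, scope)


def test_coverage_any_is_superset_of_all(rng):
    rows = []
    for i in range(200):
        for cond in ("WT", "KO"):
            lam = rng.uniform(20, 90)
            for rep in range(3):
                rows.append([f"e{i}", "SE", cond, f"rep{rep}", 0.5, int(rng.poisson(lam))])
    table = make_table(rows)
    any_set = set(coverage_filter(table, 50, "any_condition")["event_id"])
    all_set = set(coverage_filter(table, 50, "all_conditions")["event_id"])
    assert all_set <= any_set


def test_coverage_filter_commutes_with_row_shuffle(rng):
    rows = []
    for i in range(60):
        for cond in ("WT", "KO"):
            for rep in range(3):
                rows.append([f"e{i}", "SE", cond, f"rep{rep}", 0.5, int(rng.poisson(55))])
    table = make_table(rows)
    shuffled = table.sample(frac=1.0, random_state=1)
    assert set(coverage_filter(table, 50)["event_id"]) == set(
        coverage_filter(shuffled, 50)["event_id"]
    )


# ---------------------------------------------------------------------------
# delta inclusion


def test_delta_inclusion_mean_difference():
    table = make_table(
        event_rows("e1", {"a": [0.10, 0.12, 0.08], "b": [0.20, 0.22, 0.18]})
    )
    assert delta_inclusion(table, "e1", "a", "b") == pytest.approx(0.10)
    assert delta_inclusion(table, "e1", "a", "a") == 0.0
    # replicate permutation leaves the mean difference unchanged
    permuted = table.iloc[[2, 0, 1, 4, 5, 3]]
    assert delta_inclusion(permuted, "e1", "a", "b") == pytest.approx(0.10)


def test_delta_inclusion_missing_values():
    table = make_table(event_rows("e1", {"a": [0.1, np.nan, 0.3], "b": [np.nan, np.nan, np.nan]}))
    assert np.isnan(delta_inclusion(table, "e1", "a", "b"))  # all-missing condition flagged
    table2 = make_table(event_rows("e1", {"a": [0.1, np.nan, 0.3], "b": [0.4, 0.4, np.nan]}))
    assert delta_inclusion(table2, "e1", "a", "b") == pytest.approx(0.4 - 0.2)
    assert deltas_by_event(table2, "a", "b")["e1"] == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# IR t-test


def test_test_ir_identical_groups_not_significant():
    table = make_table(event_rows("e1", {"a": [0.1] * 3, "b": [0.1] * 3}, as_type="IR"))
    result = ir_ttest(table, "a", "b")
    row = result.iloc[0]
    assert row["delta_inclusion"] == 0.0
    assert row["p_value"] == 1.0
    assert not row["significant"]


def test_test_ir_delta_gate_blocks_small_effects():
    # tiny but extremely consistent shift: p is small, |delta| = 0.04 < 0.05
    table = make_table(
        event_rows("e1", {"a": [0.100, 0.101, 0.099], "b": [0.140, 0.141, 0.139]}, as_type="IR")
    )
    result = ir_ttest(table, "a", "b")
    row = result.iloc[0]
    assert row["p_value"] < 0.001
    assert abs(row["delta_inclusion"]) == pytest.approx(0.04, abs=1e-9)
    assert not row["significant"]


def test_test_ir_pooled_variance_matches_scipy_student():
    from scipy import stats

    rng = np.random.default_rng(7)
    a = rng.normal(0.3, 0.05, 3)
    b = rng.normal(0.42, 0.05, 3)
    table = make_table(event_rows("e1", {"a": list(a), "b": list(b)}, as_type="IR"))
    result = ir_ttest(table, "a", "b")
    expected = stats.ttest_ind(b, a, equal_var=True).pvalue
    assert result.iloc[0]["p_value"] == pytest.approx(expected, rel=1e-12)


def test_test_ir_zero_variance_unequal_means():
    table = make_table(event_rows("e1", {"a": [0.1] * 3, "b": [0.4] * 3}, as_type="IR"))
    row = ir_ttest(table, "a", "b").iloc[0]
    assert row["p_value"] == 0.0
    assert row["significant"]


def test_test_ir_skips_underreplicated_events():
    rows = event_rows("e1", {"a": [0.1], "b": [0.2, 0.3]}, as_type="IR")
    rows += event_rows("e2", {"a": [0.1, 0.2], "b": [0.2, 0.3]}, as_type="IR")
    result = ir_ttest(make_table(rows), "a", "b")
    assert list(result["event_id"]) == ["e2"]


def test_test_ir_null_pvalues_uniform(rng):
    """Exchangeable replicates: t-test p-values are uniform on [0, 1]."""
    from scipy import stats

    n_events = 600
    rows = []
    for i in range(n_events):
        psi = rng.uniform(0.2, 0.8)
        for cond in ("a", "b"):
            for rep in range(3):
                rows.append(
                    [f"e{i}", "IR", cond, f"rep{rep}", psi + rng.normal(0, 0.04), 100]
                )
    result = ir_ttest(make_table(rows), "a", "b")
    ks = stats.kstest(result["p_value"], "uniform")
    assert ks.pvalue > 0.01
    assert result["significant"].mean() <= 0.02


def test_significant_calls_reverify_their_thresholds(rng):
    rows = []
    for i in range(100):
        base = rng.uniform(0.2, 0.6)
        shift = rng.choice([0.0, 0.15])
        for cond, mu in (("a", base), ("b", base + shift)):
            for rep in range(3):
                rows.append([f"e{i}", "IR", cond, f"rep{rep}", mu + rng.normal(0, 0.02), 100])
    result = ir_ttest(make_table(rows), "a", "b")
    sig = result[result["significant"]]
    assert len(sig) > 0
    assert (sig["p_value"] < 0.01).all()
    assert (sig["delta_inclusion"].abs() >= 0.05).all()


# ---------------------------------------------------------------------------
# rMATS-style filtering


def _stats_frame(events):
    return pd.DataFrame(
        [{"event_id": e, "as_type": "SE", "p_value": p, "fdr": f} for e, p, f in events]
    )


def test_filter_rmats_threshold_logic():
    rows = event_rows("e1", {"a": [0.2] * 3, "b": [0.35] * 3}) + event_rows(
        "e2", {"a": [0.2] * 3, "b": [0.29] * 3}
    )
    stats_df = _stats_frame([("e1", 0.001, 0.005), ("e2", 0.001, 0.005)])
    result = filter_rmats(make_table(rows), stats_df, "a", "b").set_index("event_id")
    assert bool(result.loc["e1", "significant"])  # fdr 0.005, delta 0.15
    assert not bool(result.loc["e2", "significant"])  # delta 0.09 fails the gate


def test_filter_rmats_matches_brute_force(rng):
    rows, stats_rows, truth = [], [], []
    for i in range(100):
        delta = rng.uniform(-0.3, 0.3)
        fdr = rng.uniform(0, 0.05)
        rows += event_rows(f"e{i}", {"a": [0.4] * 3, "b": [0.4 + delta] * 3})
        stats_rows.append((f"e{i}", fdr / 2, fdr))
        truth.append((f"e{i}", fdr, delta))
    result = filter_rmats(make_table(rows), _stats_frame(stats_rows), "a", "b")
    got = set(result.loc[result["significant"], "event_id"])
    assert got == brute_force_rmats_filter(truth, 0.01, 0.1)


def test_filter_rmats_bh_within_type_when_fdr_missing(rng):
    rows, stats_rows = [], []
    pvals = {"SE": [], "RI": []}
    for i, as_type in enumerate(["SE"] * 40 + ["RI"] * 40):
        p = float(rng.uniform(0, 1)) ** 3
        rows += event_rows(f"e{i}", {"a": [0.2] * 3, "b": [0.5] * 3}, as_type=as_type)
        stats_rows.append({"event_id": f"e{i}", "as_type": as_type, "p_value": p, "fdr": np.nan})
        pvals[as_type].append(p)
    result = filter_rmats(make_table(rows), pd.DataFrame(stats_rows), "a", "b")
    # BH applied within each event type separately
    expected = np.concatenate(
        [multipletests(pvals["SE"], method="fdr_bh")[1],
         multipletests(pvals["RI"], method="fdr_bh")[1]]
    )
    assert np.allclose(result["fdr"].to_numpy(), expected)


def test_filter_rmats_requires_some_statistic():
    rows = event_rows("e1", {"a": [0.2] * 3, "b": [0.5] * 3})
    stats_df = pd.DataFrame([{"event_id": "e1", "as_type": "SE", "p_value": np.nan, "fdr": np.nan}])
    with pytest.raises(ValueError, match="neither"):
        filter_rmats(make_table(rows), stats_df, "a", "b")


# ---------------------------------------------------------------------------
# RI flanking-exon filter


def test_ri_exon_length_filter_rules():
    def with_flanks(rows, flanks):
        df = make_table(rows)
        df["flank_exon_lengths"] = flanks
        return df

    keep = with_flanks(event_rows("ri1", {"a": [0.5] * 2}, as_type="RI"), "120,480")
    drop = with_flanks(event_rows("ri2", {"a": [0.5] * 2}, as_type="RI"), "120,600")
    se = with_flanks(event_rows("se1", {"a": [0.5] * 2}, as_type="SE"), "2000,3000")
    missing = with_flanks(event_rows("ri3", {"a": [0.5] * 2}, as_type="RI"), np.nan)
    table = pd.concat([keep, drop, se, missing], ignore_index=True)
    kept = set(ri_exon_length_filter(table)["event_id"])
    assert kept == {"ri1", "se1"}  # long flank and missing geometry dropped, SE untouched


def test_ri_exon_length_filter_matches_brute_force(rng):
    frames, truth = [], []
    for i in range(150):
        as_type = "RI" if rng.random() < 0.5 else "SE"
        flanks = (int(rng.integers(50, 800)), int(rng.integers(50, 800)))
        df = make_table(event_rows(f"e{i}", {"a": [0.5] * 2}, as_type=as_type))
        df["flank_exon_lengths"] = f"{flanks[0]},{flanks[1]}"
        frames.append(df)
        truth.append((f"e{i}", as_type, flanks))
    table = pd.concat(frames, ignore_index=True)
    kept = set(ri_exon_length_filter(table, 500)["event_id"])
    assert kept == brute_force_ri_filter(truth, 500)


# ---------------------------------------------------------------------------
# I/O


def test_rmats_round_trip(rng):
    rows, stats_rows = [], []
    for i in range(12):
        psis = {
            "a": list(np.round(rng.uniform(0.2, 0.8, 3), 4)),
            "b": list(np.round(rng.uniform(0.2, 0.8, 3), 4)),
        }
        counts = {c: list(rng.integers(40, 200, 3)) for c in ("a", "b")}
        rows += event_rows(f"RI_{i}", psis, counts, as_type="RI")
        stats_rows.append({"event_id": f"RI_{i}", "as_type": "RI",
                           "p_value": float(rng.uniform(0, 1)), "fdr": float(rng.uniform(0, 1))})
    table = make_table(rows)
    table["flank_exon_lengths"] = "150,250"
    stats_df = pd.DataFrame(stats_rows)
    import io, tempfile, os

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "RI.MATS.JC.txt")
        write_rmats_like(table, stats_df, "a", "b", path, "RI")
        table2, stats2 = read_rmats(path, "RI", "a", "b")
    merged = table.merge(table2, on=["event_id", "condition", "replicate"], suffixes=("", "_r"))
    assert np.allclose(merged["inclusion_level"], merged["inclusion_level_r"], atol=1e-4)
    # read counts survive as IJC+SJC sums
    assert (merged["read_count"] == merged["read_count_r"]).all()
    assert (table2.loc[table2["as_type"] == "RI", "flank_exon_lengths"] == "150,250").all()
    m2 = stats_df.merge(stats2, on="event_id", suffixes=("", "_r"))
    assert np.allclose(m2["fdr"], m2["fdr_r"])


def test_ir_table_to_inclusion_parses_sample_ids():
    ir_table = pd.DataFrame(
        {
            "intron_id": ["i1", "i1"],
            "sample_id": ["WT_rep1", "KO_rep2"],
            "n_unspliced": [4, 2],
            "n_intronic": [0, 0],
            "n_spliced": [8, 8],
            "n_alt": [1, 0],
            "informative_reads": [12, 10],
            "ir_fraction": [0.2, 1 / 9],
        }
    )
    table = ir_table_to_inclusion(ir_table)
    assert list(table["condition"]) == ["WT", "KO"]
    assert list(table["replicate"]) == ["rep1", "rep2"]
    assert list(table["as_type"].unique()) == ["IR"]
    assert list(table["read_count"]) == [12, 10]
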