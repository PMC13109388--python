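"""Coverage filtering and significance calls for splicing-event tables.

Works on long-format inclusion tables: one row per (event, condition,
replicate) with an inclusion level (PSI) in [0, 1] (or missing) and a
supporting read count. Two kinds of calls are made:

* intron-retention events — per-event two-sample Student's t-test on
  replicate IR fractions, significant when p < 0.01 and |ΔPSI| >= 0.05;
* rMATS-quantified events — upstream FDR (or Benjamini–Hochberg within
  event type when only p-values are present), significant when
  FDR < 0.01 and |ΔPSI| >= 0.1, after the coverage filter and, for
  retained-intron events, the flanking-exon length filter (<= 500 nt).

Coverage requires a median of 50 supporting reads across replicates in at
least one condition (``any_condition``) or in every condition
(``all_conditions``; used for cross-condition comparisons).

Threshold boundary semantics throughout: |delta| >= threshold, p/FDR
strictly <, median >= cutoff; all configurable.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INCLUSION_COLUMNS",
    "validate_inclusion_table",
    "coverage_filter",
    "delta_inclusion",
    "deltas_by_event",
    "test_ir",
    "filter_rmats",
    "ri_exon_length_filter",
    "ir_table_to_inclusion",
    "read_rmats",
    "write_rmats_like",
    "write_comparison_table",
    "read_comparison_table",
]

logger = logging.getLogger(__name__)

AS_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI", "IR")

INCLUSION_COLUMNS = [
    "event_id",
    "as_type",
    "condition",
    "replicate",
    "inclusion_level",
    "read_count",
]

COMPARISON_COLUMNS = [
    "event_id",
    "as_type",
    "condition_a",
    "condition_b",
    "delta_inclusion",
    "p_value",
    "fdr",
    "significant",
]


def validate_inclusion_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INCLUSION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"inclusion table missing columns: {missing}")
    dup = table.duplicated(subset=["event_id", "condition", "replicate"])
    if dup.any():
        raise ValueError(
            f"inclusion table: {int(dup.sum())} duplicated (event_id, condition, replicate) rows"
        )
    return table


def coverage_filter(
    table: pd.DataFrame, min_median: int = 50, scope: str = "any_condition"
) -> pd.DataFrame:
    """Keep events whose per-condition median read count reaches the cutoff.

    ``any_condition`` keeps events passing in at least one condition;
    ``all_conditions`` (used before cross-condition comparisons) requires
    it in every condition the event was measured in. Rows of dropped
    events are removed entirely.
    """
    if scope not in ("any_condition", "all_conditions"):
        raise ValueError(f"unknown coverage scope {scope!r}")
    medians = table.groupby(["event_id", "condition"], sort=False)["read_count"].median()
    passed = medians >= min_median
    per_event = passed.groupby(level="event_id", sort=False)
    keep = per_event.any() if scope == "any_condition" else per_event.all()
    kept_ids = set(keep.index[keep])
    return table[table["event_id"].isin(kept_ids)].copy()


def _condition_mean(values: pd.Series) -> float:
    values = values.dropna()
    return float(values.mean()) if len(values) else float("nan")


def delta_inclusion(table: pd.DataFrame, event_id: str, cond_a: str, cond_b: str) -> float:
    """Inclusion-level difference mean(b) − mean(a) for one event.

    Missing replicate values are ignored; an all-missing condition yields
    NaN (the event is flagged by the caller).
    """
    rows = table[table["event_id"] == event_id]
    if rows.empty:
        raise KeyError(f"event {event_id!r} not present")
    mean_a = _condition_mean(rows.loc[rows["condition"] == cond_a, "inclusion_level"])
    mean_b = _condition_mean(rows.loc[rows["condition"] == cond_b, "inclusion_level"])
    return mean_b - mean_a


def deltas_by_event(table: pd.DataFrame, cond_a: str, cond_b: str) -> pd.Series:
    """Vectorised mean(b) − mean(a) per event, NaN where undefined."""
    sub = table[table["condition"].isin([cond_a, cond_b])]
    means = sub.groupby(["event_id", "condition"], sort=False)["inclusion_level"].mean().unstack()
    for cond in (cond_a, cond_b):
        if cond not in means.columns:
            means[cond] = np.nan
    out = means[cond_b] - means[cond_a]
    out.name = f"{cond_b}-{cond_a}"
    return out


def _student_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed pooled-variance (Student) two-sample t-test p-value.

    Both groups constant: p = 1 for equal means (no evidence against the
    null), p = 0 for unequal means (zero-variance separation).
    """
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(b, a, equal_var=True).pvalue)


def test_ir(
    table: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    p_threshold: float = 0.01,
    min_abs_delta: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-event t-test of replicate inclusion levels between two conditions.

    Events with fewer than two non-missing replicates in either condition
    are skipped (logged). Returns a comparison table with one row per
    tested event; ``significant`` is True iff p < ``p_threshold`` and
    |delta| >= ``min_abs_delta``. ``equal_var=False`` switches to Welch.
    """
    validate_inclusion_table(table)
    rows = []
    n_skipped = 0
    sub = table[table["condition"].isin([cond_a, cond_b])]
    for event_id, group in sub.groupby("event_id", sort=False):
        a = group.loc[group["condition"] == cond_a, "inclusion_level"].dropna().to_numpy(float)
        b = group.loc[group["condition"] == cond_b, "inclusion_level"].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            n_skipped += 1
            continue
        if equal_var:
            p = _student_t(a, b)
        else:
            p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
            if math.isnan(p) and np.ptp(a) == 0 and np.ptp(b) == 0:
                p = 1.0 if a[0] == b[0] else 0.0
        delta = float(b.mean() - a.mean())
        rows.append(
            {
                "event_id": event_id,
                "as_type": group["as_type"].iloc[0],
                "condition_a": cond_a,
                "condition_b": cond_b,
                "delta_inclusion": delta,
                "p_value": p,
                "fdr": np.nan,
                "significant": (p < p_threshold) and (abs(delta) >= min_abs_delta),
            }
        )
    if n_skipped:
        logger.info("test_ir: %d events skipped (<2 replicates in a condition)", n_skipped)
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def _bh_within_type(stats_df: pd.DataFrame) -> pd.Series:
    """Benjamini–Hochberg on p-values, separately within each event type."""
    from statsmodels.stats.multitest import multipletests

    fdr = pd.Series(np.nan, index=stats_df.index)
    for _, idx in stats_df.groupby("as_type", sort=False).groups.items():
        pvals = stats_df.loc[idx, "p_value"]
        mask = pvals.notna()
        if mask.any():
            fdr.loc[pvals.index[mask]] = multipletests(pvals[mask], method="fdr_bh")[1]
    return fdr


def filter_rmats(
    table: pd.DataFrame,
    event_stats: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    fdr_threshold: float = 0.01,
    min_abs_delta: float = 0.1,
) -> pd.DataFrame:
    """Significance calls for rMATS-quantified events.

    ``event_stats`` carries per-event ``p_value`` and/or ``fdr`` columns
    from the upstream quantifier (keyed by ``event_id``, with ``as_type``).
    When FDR is absent, Benjamini–Hochberg is applied to the p-values
    within each event type. Deltas are recomputed from the inclusion table
    as mean(b) − mean(a). Apply after :func:`coverage_filter`.
    """
    validate_inclusion_table(table)
    stats_df = event_stats.set_index("event_id") if "event_id" in event_stats.columns else event_stats
    has_fdr = "fdr" in stats_df.columns and stats_df["fdr"].notna().any()
    has_p = "p_value" in stats_df.columns and stats_df["p_value"].notna().any()
    if not has_fdr and not has_p:
        raise ValueError("filter_rmats: event stats carry neither FDR nor p-values")
    if has_fdr:
        fdr = stats_df["fdr"]
    else:
        fdr = _bh_within_type(stats_df)
    deltas = deltas_by_event(table, cond_a, cond_b)
    event_ids = [e for e in stats_df.index if e in deltas.index]
    out = pd.DataFrame(
        {
            "event_id": event_ids,
            "as_type": stats_df.loc[event_ids, "as_type"].to_numpy(),
            "condition_a": cond_a,
            "condition_b": cond_b,
            "delta_inclusion": deltas.loc[event_ids].to_numpy(),
            "p_value": (
                stats_df.loc[event_ids, "p_value"].to_numpy() if has_p else np.nan
            ),
            "fdr": fdr.loc[event_ids].to_numpy(),
        }
    )
    out["significant"] = (out["fdr"] < fdr_threshold) & (
        out["delta_inclusion"].abs() >= min_abs_delta
    )
    out.loc[out["fdr"].isna() | out["delta_inclusion"].isna(), "significant"] = False
    return out[COMPARISON_COLUMNS]


def _parse_flank_lengths(value) -> list[int] | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.split(",")
    try:
        return [int(v) for v in value]
    except (TypeError, ValueError):
        return None


def ri_exon_length_filter(table: pd.DataFrame, max_flank_exon: int = 500) -> pd.DataFrame:
    """Drop retained-intron events with any linked exon above the cutoff.

    Restores a typical exon architecture when the quantifier was run with
    an enlarged maximum exon length so long introns could be captured as
    the middle "exon" of an RI event. Only RI rows are touched; RI events
    lacking flank geometry are dropped (logged).
    """
    if "flank_exon_lengths" not in table.columns:
        table = table.copy()
        table["flank_exon_lengths"] = np.nan
    drop: set[str] = set()
    n_no_geometry = 0
    ri_rows = table[table["as_type"] == "RI"]
    for event_id, group in ri_rows.groupby("event_id", sort=False):
        flanks = _parse_flank_lengths(group["flank_exon_lengths"].iloc[0])
        if flanks is None:
            drop.add(event_id)
            n_no_geometry += 1
        elif any(f > max_flank_exon for f in flanks):
            drop.add(event_id)
    if n_no_geometry:
        logger.info("ri_exon_length_filter: %d RI events dropped for missing geometry", n_no_geometry)
    return table[~table["event_id"].isin(drop)].copy()


def ir_table_to_inclusion(
    ir_table: pd.DataFrame, sample_conditions: dict[str, tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Convert a quantify-ir output table into a long inclusion table.

    ``sample_conditions`` maps sample_id -> (condition, replicate); when
    omitted, sample ids of the form ``<condition>_rep<k>`` are parsed.
    The IR fraction becomes the inclusion level; informative reads
    (unspliced + spliced) the supporting read count.
    """
    def split(sample_id: str) -> tuple[str, str]:
        if sample_conditions is not None:
            return sample_conditions[sample_id]
        cond, _, rep = sample_id.rpartition("_")
        if not cond or not rep.startswith("rep"):
            raise ValueError(f"cannot parse condition/replicate from sample id {sample_id!r}")
        return cond, rep
    conds, reps = zip(*(split(s) for s in ir_table["sample_id"]))
    out = pd.DataFrame(
        {
            "event_id": ir_table["intron_id"].to_numpy(),
            "as_type": "IR",
            "condition": conds,
            "replicate": reps,
            "inclusion_level": ir_table["ir_fraction"].to_numpy(),
            "read_count": ir_table["informative_reads"].to_numpy(),
        }
    )
    return out


# ---------------------------------------------------------------------------
# rMATS-format I/O

_RI_GEOMETRY = ("riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE", "downstreamES", "downstreamEE")


def _split_counts(value: str) -> list[float]:
    return [float("nan") if v in ("NA", "", "nan") else float(v) for v in str(value).split(",")]


def read_rmats(
    path: str | Path,
    as_type: str,
    cond_a: str = "SAMPLE_1",
    cond_b: str = "SAMPLE_2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an rMATS JC/JCEC output file into (inclusion table, event stats).

    Per-replicate inclusion levels come from the IncLevel1/IncLevel2
    comma-lists and the supporting read count from the IJC + SJC sum of the
    matching replicate (the count the median-coverage rule is applied to).
    For RI events the upstream/downstream exon lengths are attached as
    ``flank_exon_lengths``. Note rMATS's IncLevelDifference is
    IncLevel1 − IncLevel2, i.e. the negative of this package's
    mean(b) − mean(a) convention.
    """
    wide = pd.read_csv(path, sep="\t")
    required = ["ID", "IncLevel1", "IncLevel2", "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2"]
    missing = [c for c in required if c not in wide.columns]
    if missing:
        raise ValueError(f"{path}: not an rMATS table, missing columns {missing}")
    rows = []
    stats_rows = []
    for _, rec in wide.iterrows():
        event_id = f"{as_type}_{rec['ID']}"
        flanks = np.nan
        if as_type == "RI" and all(c in wide.columns for c in _RI_GEOMETRY):
            up = int(rec["upstreamEE"]) - int(rec["upstreamES"])
            down = int(rec["downstreamEE"]) - int(rec["downstreamES"])
            flanks = f"{up},{down}"
        for cond, inc_col, ijc_col, sjc_col in (
            (cond_a, "IncLevel1", "IJC_SAMPLE_1", "SJC_SAMPLE_1"),
            (cond_b, "IncLevel2", "IJC_SAMPLE_2", "SJC_SAMPLE_2"),
        ):
            incs = _split_counts(rec[inc_col])
            ijcs = _split_counts(rec[ijc_col])
            sjcs = _split_counts(rec[sjc_col])
            for k, inc in enumerate(incs):
                count = (ijcs[k] if k < len(ijcs) else 0) + (sjcs[k] if k < len(sjcs) else 0)
                rows.append(
                    {
                        "event_id": event_id,
                        "as_type": as_type,
                        "condition": cond,
                        "replicate": f"rep{k + 1}",
                        "inclusion_level": inc,
                        "read_count": count,
                        "flank_exon_lengths": flanks,
                    }
                )
        stats_rows.append(
            {
                "event_id": event_id,
                "as_type": as_type,
                "p_value": float(rec["PValue"]) if "PValue" in wide.columns else np.nan,
                "fdr": float(rec["FDR"]) if "FDR" in wide.columns else np.nan,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(stats_rows)


def write_rmats_like(
    table: pd.DataFrame,
    event_stats: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    path: str | Path,
    as_type: str,
) -> None:
    """Write one event type of a long inclusion table in rMATS-like format.

    Inverse of :func:`read_rmats` for round-tripping and for emitting
    synthetic tables in the format downstream consumers expect. Inclusion
    and skipping junction counts are apportioned from the replicate read
    count by the replicate inclusion level.
    """
    sub = table[(table["as_type"] == as_type) & table["condition"].isin([cond_a, cond_b])]
    stats_df = event_stats.set_index("event_id")
    recs = []
    for raw_id, group in sub.groupby("event_id", sort=False):
        rec: dict = {"ID": str(raw_id).removeprefix(f"{as_type}_"), "GeneID": raw_id,
                     "geneSymbol": raw_id, "chr": "simchr1", "strand": "+"}
        inc_means = {}
        for cond, inc_col, ijc_col, sjc_col in (
            (cond_a, "IncLevel1", "IJC_SAMPLE_1", "SJC_SAMPLE_1"),
            (cond_b, "IncLevel2", "IJC_SAMPLE_2", "SJC_SAMPLE_2"),
        ):
            g = group[group["condition"] == cond].sort_values("replicate")
            incs, ijcs, sjcs = [], [], []
            for _, row in g.iterrows():
                psi = row["inclusion_level"]
                count = int(row["read_count"]) if pd.notna(row["read_count"]) else 0
                if pd.isna(psi):
                    incs.append("NA")
                    ijcs.append("0")
                    sjcs.append("0")
                else:
                    ijc = int(round(count * psi))
                    incs.append(f"{psi:.4f}")
                    ijcs.append(str(ijc))
                    sjcs.append(str(count - ijc))
            rec[inc_col] = ",".join(incs)
            rec[ijc_col] = ",".join(ijcs)
            rec[sjc_col] = ",".join(sjcs)
            vals = g["inclusion_level"].dropna()
            inc_means[cond] = vals.mean() if len(vals) else np.nan
        rec["IncFormLen"] = 100
        rec["SkipFormLen"] = 50
        if raw_id in stats_df.index:
            rec["PValue"] = stats_df.loc[raw_id, "p_value"]
            rec["FDR"] = stats_df.loc[raw_id, "fdr"]
        else:
            rec["PValue"] = np.nan
            rec["FDR"] = np.nan
        rec["IncLevelDifference"] = inc_means[cond_a] - inc_means[cond_b]
        if as_type == "RI":
            flanks = _parse_flank_lengths(group["flank_exon_lengths"].iloc[0]) or [100, 100]
            rec["upstreamES"] = 0
            rec["upstreamEE"] = flanks[0]
            rec["riExonStart_0base"] = flanks[0]
            rec["riExonEnd"] = flanks[0] + 200
            rec["downstreamES"] = flanks[0] + 200
            rec["downstreamEE"] = flanks[0] + 200 + flanks[-1]
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_comparison_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_comparison_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
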