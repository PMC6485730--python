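"""Post-DE transcriptome comparison between two denervated-muscle datasets.

The filter chain selects transcripts that are Wald-significant for a given
day (q <= alpha), members of the experiment-wide LRT-significant set, and
have at least a 2-fold change (|log2 FC| >= 1, boundary inclusive, either
direction). Derived outputs: pairwise overlap (Venn) counts, the count of
transcripts regulated in opposite directions, a per-transcript z-score
matrix of normalized TPM across conditions, the polar-expression filter
(strictly opposite day-3 signs between the two tissues), and a long-format
heatmap table.

z-scores use the sample standard deviation (ddof = 1) across the included
condition columns by default; a within-day mode (z computed per day across
arms) is available via ``zscore_matrix`` on the appropriate column subset.
Constant rows get z = 0 and a degenerate flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traceio import DETable, ValidationError


@dataclass
class FilterSpec:
    """Significance filter: Wald q-value threshold, minimum fold change and
    LRT membership requirement."""

    alpha_wt: float = 0.05
    fc_min: float = 2.0
    require_lrt: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_wt < 1:
            raise ValidationError("alpha_wt must lie in (0, 1)")
        if self.fc_min < 1:
            raise ValidationError("fc_min must be >= 1")

    @property
    def min_abs_log2fc(self) -> float:
        return float(np.log2(self.fc_min))


@dataclass
class VennCounts:
    common: int
    unique_a: int
    unique_b: int
    union: int
    members_common: list[str] = field(default_factory=list)
    members_unique_a: list[str] = field(default_factory=list)
    members_unique_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.common + self.unique_a + self.unique_b != self.union:
            raise ValidationError("Venn identity violated: common + uniques != union")


@dataclass
class ComparisonResult:
    """Bundle of all derived comparison outputs for two tissues."""

    sig_a: pd.Series  # sign of log2FC, indexed by transcript_id
    sig_b: pd.Series
    venn: VennCounts
    opposite_count: int
    zscores: pd.DataFrame  # transcript x condition
    degenerate_ids: list[str]
    polar_ids: list[str]

    def __post_init__(self) -> None:
        common = set(self.venn.members_common)
        polar = set(self.polar_ids)
        sig_any = set(self.sig_a.index) | set(self.sig_b.index)
        if not polar <= sig_any:
            raise ValidationError("polar transcripts must be significant in >= 1 dataset")
        if self.opposite_count > len(common):
            raise ValidationError("opposite-direction count exceeds the common set")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def filter_de(table: DETable, day, spec: FilterSpec | None = None) -> pd.Series:
    """Significant transcripts for ``day``: q <= alpha, LRT member (if
    required) and |log2 FC| >= log2(fc_min), boundary inclusive.

    Returns the sign of log2 FC indexed by transcript id, sorted by id.
    """
    fs = spec or FilterSpec()
    df = table.frame
    qcol = table.qval_column(day)
    keep = df[qcol].to_numpy(dtype=float) <= fs.alpha_wt
    keep &= np.abs(df["log2_fc"].to_numpy(dtype=float)) >= fs.min_abs_log2fc
    if fs.require_lrt:
        keep &= df["lrt_flag"].to_numpy(dtype=bool)
    out = df.loc[keep, ["transcript_id", "log2_fc"]].copy()
    out["sign"] = np.sign(out["log2_fc"]).astype(float)
    return out.sort_values("transcript_id").set_index("transcript_id")["sign"]


def venn(set_a, set_b) -> VennCounts:
    """Overlap counts and sorted membership lists of two id collections."""
    a = set(set_a.index) if isinstance(set_a, pd.Series) else set(set_a)
    b = set(set_b.index) if isinstance(set_b, pd.Series) else set(set_b)
    common = a & b
    return VennCounts(
        common=len(common),
        unique_a=len(a - b),
        unique_b=len(b - a),
        union=len(a | b),
        members_common=sorted(common),
        members_unique_a=sorted(a - b),
        members_unique_b=sorted(b - a),
    )


def opposite_direction_count(
    table_a: DETable, table_b: DETable, common_ids, fc_min: float = 2.0
) -> int:
    """Transcripts among ``common_ids`` regulated in opposite directions with
    at least ``fc_min`` fold change in both tables."""
    min_lfc = float(np.log2(fc_min))
    a = table_a.indexed()["log2_fc"]
    b = table_b.indexed()["log2_fc"]
    ids = list(common_ids)
    missing = [i for i in ids if i not in a.index or i not in b.index]
    if missing:
        raise ValidationError(
            "transcript(s) missing from a table: " + ", ".join(sorted(missing)[:5])
        )
    la = a.loc[ids].to_numpy(dtype=float)
    lb = b.loc[ids].to_numpy(dtype=float)
    return int(np.sum((np.sign(la) != np.sign(lb)) & (np.abs(la) >= min_lfc) & (np.abs(lb) >= min_lfc)))


def zscore_matrix(tpm: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, list[str]]:
    """Per-transcript z-scores across condition columns.

    Rows are transcripts, columns conditions (>= 2 required). Rows with
    zero dispersion get z = 0 and are returned in the degenerate list.
    """
    if tpm.shape[1] < 2:
        raise ValidationError("zscore_matrix needs >= 2 condition columns")
    vals = tpm.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = sd[:, 0] == 0
    safe_sd = np.where(degenerate[:, None], 1.0, sd)
    z = (vals - mean) / safe_sd
    z[degenerate, :] = 0.0
    zdf = pd.DataFrame(z, index=tpm.index, columns=tpm.columns)
    return zdf, sorted(np.asarray(tpm.index)[degenerate].tolist())


def polar_filter(
    values_a: pd.Series, values_b: pd.Series, significant_ids
) -> list[str]:
    """Transcripts significant in >= 1 dataset whose day-3 signed values
    (z-score or log2 FC) have strictly opposite signs; zero is not polar."""
    sig = set(significant_ids)
    out = []
    for tid in sorted(sig):
        if tid not in values_a.index or tid not in values_b.index:
            continue
        va, vb = float(values_a.loc[tid]), float(values_b.loc[tid])
        if va * vb < 0:
            out.append(tid)
    return out


def heatmap_table(
    zscores: pd.DataFrame,
    groups: dict[str, str] | None = None,
    reference_condition: str | None = None,
) -> pd.DataFrame:
    """Long-format (transcript, group, condition, z) table for rendering.

    Rows are ordered by group, then by descending |z| at the reference
    condition (default: the first column), then id. Transcripts without a
    group label fall into "other" with a warning.
    """
    import warnings

    ref = reference_condition or zscores.columns[0]
    if ref not in zscores.columns:
        raise ValidationError(f"reference condition {ref!r} not in z-score columns")
    glabels = {}
    for tid in zscores.index:
        if groups and tid in groups:
            glabels[tid] = groups[tid]
        else:
            if groups is not None:
                warnings.warn(f"no group label for {tid}; using 'other'", stacklevel=2)
            glabels[tid] = "other"
    order = sorted(
        zscores.index, key=lambda tid: (glabels[tid], -abs(float(zscores.loc[tid, ref])), tid)
    )
    rows = []
    for tid in order:
        for cond in zscores.columns:
            rows.append({
                "transcript_id": tid,
                "group": glabels[tid],
                "condition": cond,
                "z": float(zscores.loc[tid, cond]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def compare_tissues(
    table_a: DETable,
    table_b: DETable,
    spec: FilterSpec | None = None,
    day: int = 3,
    z_columns_a: list[str] | None = None,
    z_columns_b: list[str] | None = None,
    groups: dict[str, str] | None = None,
) -> ComparisonResult:
    """Full cross-tissue comparison at the matched time point (day 3).

    z-scores are computed per transcript across the included injured-arm
    TPM columns of both tissues (all whisker days plus soleus day 3 by
    default). The polar filter compares the day-3 columns of the two
    tissues.
    """
    fs = spec or FilterSpec()
    sig_a = filter_de(table_a, day, fs)
    sig_b = filter_de(table_b, day, fs)
    counts = venn(sig_a, sig_b)
    opposite = opposite_direction_count(table_a, table_b, counts.members_common, fs.fc_min)

    cols_a = z_columns_a or [
        c for c in table_a.tpm_columns() if c.endswith("_injured")
    ]
    cols_b = z_columns_b or [
        c for c in table_b.tpm_columns() if c.endswith("_injured")
    ]
    sig_any = sorted(set(sig_a.index) | set(sig_b.index))
    ia, ib = table_a.indexed(), table_b.indexed()
    shared = [t for t in sig_any if t in ia.index and t in ib.index]
    tpm = pd.concat([ia.loc[shared, cols_a], ib.loc[shared, cols_b]], axis=1)
    zs, degenerate = zscore_matrix(tpm)

    ref_a = _day_column(cols_a, day)
    ref_b = _day_column(cols_b, day)
    polar = polar_filter(zs[ref_a], zs[ref_b], shared)

    return ComparisonResult(
        sig_a=sig_a,
        sig_b=sig_b,
        venn=counts,
        opposite_count=opposite,
        zscores=zs,
        degenerate_ids=degenerate,
        polar_ids=polar,
    )


def _day_column(columns: list[str], day: int) -> str:
    matches = [c for c in columns if c.split("_")[2] == str(day)]
    if not matches:
        raise ValidationError(f"no TPM column for day {day} among {columns}")
    return matches[0]
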