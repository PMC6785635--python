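"""Uptake-screen bookkeeping: normalization, proportions, significance, counting.

A screen exposes oocytes expressing each transporter (plus water-injected
"Mock" controls) to a substrate mixture and quantifies internalized amounts
per replicate.  Activities are normalized per batch to a reference
transporter after mock subtraction, substrate preference is summarized as
per-transporter compound shares, and significance versus mock is labelled per
compound by one-way ANOVA followed by Holm–Šidák step-down adjustment of the
pairwise transporter-vs-mock comparisons.  A transporter counts as a bona
fide carrier of a substrate class when it is significant for at least one
compound of that class (e.g. the membrane non-permeating gibberellins, where
diffusion cannot explain accumulation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ClassificationError, NormalizationError

REQUIRED_COLUMNS = ("transporter", "compound", "batch", "replicate", "amount")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    if (records["amount"] < 0).any() or not np.isfinite(records["amount"]).all():
        raise ValueError("amounts must be finite and non-negative")
    return records


def normalize_to_reference(
    records: pd.DataFrame,
    reference: str = "NPF4.1",
    mock_label: str = "Mock",
    per_batch: bool = True,
    subtract_mock: bool = True,
) -> pd.DataFrame:
    """Normalized activity per transporter × compound (× batch).

    normalized = (transporter mean − mock mean) / (reference mean − mock mean),
    computed per batch when ``per_batch`` (the reference and mock must then be
    present in every batch), clamped below at 0.  Without ``subtract_mock``
    the plain ratio of means is used.  Returns a tidy frame with columns
    transporter, compound, batch, mean_amount, normalized; transporters
    present in several batches can be aggregated downstream with a mean.
    """
    records = _validate(records)
    group_cols = ["batch", "compound"] if per_batch else ["compound"]
    means = (
        records.groupby(group_cols + ["transporter"])["amount"].mean().reset_index()
    )
    out_rows = []
    for key, sub in means.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        batch = key[0] if per_batch else "all"
        by_t = sub.set_index("transporter")["amount"]
        if reference not in by_t.index:
            raise NormalizationError(
                f"reference {reference!r} missing from batch {batch!r}"
            )
        if subtract_mock and mock_label not in by_t.index:
            raise NormalizationError(
                f"mock {mock_label!r} missing from batch {batch!r}"
            )
        mock_mean = by_t.get(mock_label, 0.0) if subtract_mock else 0.0
        denom = by_t[reference] - mock_mean
        for transporter, mean_amount in by_t.items():
            if denom > 0:
                norm = max((mean_amount - mock_mean) / denom, 0.0)
            else:
                norm = np.nan
            out_rows.append(
                {
                    "transporter": transporter,
                    "compound": key[-1],
                    "batch": batch,
                    "mean_amount": mean_amount,
                    "normalized": norm,
                }
            )
    return pd.DataFrame(out_rows)


def substrate_proportions(
    records: pd.DataFrame, mock_label: str = "Mock"
) -> pd.DataFrame:
    """Per-transporter compound shares of total mock-subtracted uptake.

    share(compound) = mock-subtracted mean / Σ over compounds, with negative
    mock-subtracted means clamped to 0 before normalization.  Transporters
    whose clamped total is 0 are excluded with a warning.  Returns a frame
    transporter × compound of shares summing to 1 per transporter.
    """
    records = _validate(records)
    means = records.groupby(["transporter", "compound"])["amount"].mean().unstack(
        fill_value=0.0
    )
    mock = (
        means.loc[mock_label]
        if mock_label in means.index
        else pd.Series(0.0, index=means.columns)
    )
    net = (means.drop(index=mock_label, errors="ignore") - mock).clip(lower=0.0)
    totals = net.sum(axis=1)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        warnings.warn(f"transporters with no mock-exceeding uptake excluded: {zero}")
        net = net.drop(index=zero)
        totals = totals.drop(index=zero)
    return net.div(totals, axis=0)


def holm_sidak_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm–Šidák step-down adjustment.

    With raw p-values sorted ascending p_(1) ≤ … ≤ p_(m), the j-th step uses
    the Šidák multiplier for the remaining m − j + 1 hypotheses:
    adj_(i) = max_{j ≤ i} [1 − (1 − p_(j))^(m − j + 1)], capped at 1.
    Returned in the original order; adjusted values are ≥ raw and monotone
    along the sorted order.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for j, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - j)
        running = max(running, step)
        adj_sorted[j] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def holm_sidak_label(
    records: pd.DataFrame,
    alpha: float = 0.05,
    mock_label: str = "Mock",
    welch: bool = False,
) -> pd.DataFrame:
    """Significance flags per transporter × compound versus mock.

    Per compound: a one-way ANOVA across all transporters plus mock is
    reported, then every transporter is compared to mock with a two-sample
    t-test (classical pooled-variance by default; Welch optional) and the raw
    p-values are adjusted by Holm–Šidák step-down over the per-compound
    family of transporter-vs-mock contrasts.  ``significant`` flags
    adjusted p ≤ alpha.  Groups with fewer than 2 replicates are excluded
    with a warning.
    """
    records = _validate(records)
    rows = []
    for compound, sub in records.groupby("compound"):
        groups = {t: g["amount"].to_numpy() for t, g in sub.groupby("transporter")}
        small = [t for t, v in groups.items() if len(v) < 2]
        if small:
            warnings.warn(
                f"compound {compound!r}: groups with <2 replicates excluded: {small}"
            )
            for t in small:
                groups.pop(t)
        if mock_label not in groups:
            raise NormalizationError(
                f"mock {mock_label!r} missing for compound {compound!r}"
            )
        mock = groups[mock_label]
        transporters = [t for t in groups if t != mock_label]
        if len(groups) >= 2 and all(np.ptp(v) > 0 or len(v) > 1 for v in groups.values()):
            anova_p = float(stats.f_oneway(*groups.values()).pvalue)
        else:
            anova_p = np.nan
        raw = []
        for t in transporters:
            res = stats.ttest_ind(groups[t], mock, equal_var=not welch)
            p = float(res.pvalue)
            raw.append(1.0 if np.isnan(p) else p)
        adj = holm_sidak_adjust(raw)
        for t, p_raw, p_adj in zip(transporters, raw, adj):
            rows.append(
                {
                    "transporter": t,
                    "compound": compound,
                    "raw_p": p_raw,
                    "adjusted_p": float(p_adj),
                    "anova_p": anova_p,
                    "significant": bool(p_adj <= alpha),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    """Joined screen summary: per transporter × compound activity and flags."""

    table: pd.DataFrame  # transporter, compound, normalized, significant, ...


def analyze_screen(
    records: pd.DataFrame,
    reference: str = "NPF4.1",
    mock_label: str = "Mock",
    alpha: float = 0.05,
    per_batch: bool = True,
) -> ScreenResult:
    """Full screen pipeline: normalization + significance labels, joined."""
    norm = normalize_to_reference(
        records, reference=reference, mock_label=mock_label, per_batch=per_batch
    )
    norm_agg = (
        norm.groupby(["transporter", "compound"])["normalized"].mean().reset_index()
    )
    sig = holm_sidak_label(records, alpha=alpha, mock_label=mock_label)
    table = norm_agg.merge(
        sig[["transporter", "compound", "raw_p", "adjusted_p", "significant"]],
        on=["transporter", "compound"],
        how="left",
    )
    table["significant"] = table["significant"].eq(True)
    return ScreenResult(table=table)


def count_bona_fide(
    result: ScreenResult | pd.DataFrame,
    compound_classes: Mapping[str, str],
    target_class: str = "non-permeating",
) -> tuple[list[str], int]:
    """Transporters significant for ≥1 compound of the target permeability class.

    ``compound_classes`` maps every compound in the table to its permeability
    class; an unknown compound raises
    :class:`~npfcavity.errors.ClassificationError`.  The list is sorted by
    total normalized activity over target-class compounds, descending.
    """
    table = result.table if isinstance(result, ScreenResult) else result
    unknown = sorted(set(table["compound"]) - set(compound_classes))
    if unknown:
        raise ClassificationError(f"compounds with unknown permeability class: {unknown}")
    mask = table["compound"].map(compound_classes) == target_class
    hits = table[mask & table["significant"]]
    if hits.empty:
        return [], 0
    activity = (
        table[mask]
        .groupby("transporter")["normalized"]
        .sum()
        .reindex(hits["transporter"].unique())
        .fillna(0.0)
    )
    ordered = activity.sort_values(ascending=False).index.tolist()
    return ordered, len(ordered)
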