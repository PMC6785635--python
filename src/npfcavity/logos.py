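"""Per-position residue frequencies, information content and group contrasts.

Sequence-logo statistics over binding-site fingerprints: a position's letter
heights are its residue frequencies scaled by the Shannon information content
IC = log2(20) − H(freqs) in bits.  Gaps are excluded from the frequency
denominator (logo convention) rather than treated as a 21st symbol.

Substrate-discriminating positions are flagged by the per-position
Jensen–Shannon divergence (base 2, hence bounded by 1 bit) between the
frequency profiles of two sequence groups, e.g. transporters with and without
activity towards a substrate class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, GAP, UNKNOWN, BindingSiteFingerprint
from .errors import ConfigurationError

_AA = list(AMINO_ACIDS)
LOG2_20 = float(np.log2(20.0))


@dataclass
class LogoProfile:
    """Residue frequencies, information content and effective counts per position."""

    frequencies: pd.DataFrame       # positions × 20 residues; NaN rows = all-gap
    information: pd.Series          # bits per position
    effective_counts: pd.Series     # non-gap sequences per position
    all_gap_positions: list[str] = field(default_factory=list)


@dataclass
class PositionContrast:
    """Per-position divergence between two group profiles."""

    table: pd.DataFrame  # columns: jsd_bits, rank, consensus_a, consensus_b

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")


def _freq_matrix(
    fps: Sequence[BindingSiteFingerprint], pseudocount: float
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    positions = fps[0].positions
    for fp in fps:
        if fp.positions != positions:
            raise ConfigurationError(
                f"fingerprint {fp.sequence_id!r} has a different position configuration"
            )
    counts = np.zeros((len(positions), 20))
    eff = np.zeros(len(positions))
    for fp in fps:
        for j, aa in enumerate(fp.residues):
            if aa in (GAP, UNKNOWN):
                continue
            counts[j, _AA.index(aa)] += 1
            eff[j] += 1
    all_gap = [positions[j] for j in range(len(positions)) if eff[j] == 0]
    freqs = counts + pseudocount
    denom = freqs.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom > 0, freqs / denom, np.nan)
    frame = pd.DataFrame(freqs, index=positions, columns=_AA)
    frame.index.name = "position"
    return frame, pd.Series(eff, index=positions, name="n_eff"), all_gap


def _entropy_bits(freqs: np.ndarray) -> float:
    f = freqs[freqs > 0]
    return float(-(f * np.log2(f)).sum())


def column_frequencies(
    fps: Sequence[BindingSiteFingerprint], pseudocount: float = 0.0
) -> LogoProfile:
    """Per-position residue frequency vectors with information content.

    ``pseudocount`` is added to every residue count before normalization.
    Positions where every sequence has a gap are flagged, their frequency
    vector left undefined (NaN) and information content reported as 0 with a
    warning.
    """
    if not fps:
        raise ValueError("at least one fingerprint is required")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    frame, eff, all_gap = _freq_matrix(fps, pseudocount)
    if all_gap:
        warnings.warn(
            f"positions with all-gap columns (information content set to 0): {all_gap}"
        )
    info = pd.Series(
        [
            0.0 if np.isnan(row).all() else LOG2_20 - _entropy_bits(row)
            for row in frame.to_numpy()
        ],
        index=frame.index,
        name="information_bits",
    )
    return LogoProfile(
        frequencies=frame,
        information=info,
        effective_counts=eff,
        all_gap_positions=all_gap,
    )


def information_content(
    profile: LogoProfile, correction: str = "none"
) -> pd.Series:
    """Information content per position in bits.

    IC = log2(20) − H(frequencies).  With ``correction="small-sample"`` the
    standard approximation (20 − 1) / (2·ln2·n) is subtracted per position
    (n = effective count) and the result floored at 0.
    """
    if correction not in ("none", "small-sample"):
        raise ValueError(f"unknown correction {correction!r}")
    ic = profile.information.copy()
    if correction == "small-sample":
        n = profile.effective_counts.replace(0, np.nan)
        penalty = (20 - 1) / (2 * np.log(2) * n)
        ic = (ic - penalty.fillna(0.0)).clip(lower=0.0)
    return ic


def _jsd_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence in bits between two frequency vectors."""
    m = 0.5 * (p + q)
    return _entropy_bits(m) - 0.5 * _entropy_bits(p) - 0.5 * _entropy_bits(q)


def compare_groups(
    fps_a: Sequence[BindingSiteFingerprint],
    fps_b: Sequence[BindingSiteFingerprint],
    pseudocount: float = 0.5,
) -> PositionContrast:
    """Per-position Jensen–Shannon divergence between two fingerprint groups.

    Both groups must share the position configuration.  Positions are ranked
    by divergence descending (rank 1 = most discriminating); the per-group
    consensus (modal) residue is reported.  The default pseudocount of 0.5
    stabilizes small groups.
    """
    if not fps_a or not fps_b:
        raise ValueError("both groups must be non-empty")
    if fps_a[0].positions != fps_b[0].positions:
        raise ConfigurationError("groups have mismatched position configurations")
    fa, _, _ = _freq_matrix(fps_a, pseudocount)
    fb, _, _ = _freq_matrix(fps_b, pseudocount)
    jsd = []
    cons_a, cons_b = [], []
    for pos in fa.index:
        pa, pb = fa.loc[pos].to_numpy(), fb.loc[pos].to_numpy()
        if np.isnan(pa).all() or np.isnan(pb).all():
            jsd.append(np.nan)
            cons_a.append("")
            cons_b.append("")
            continue
        jsd.append(_jsd_bits(pa, pb))
        cons_a.append(fa.loc[pos].idxmax())
        cons_b.append(fb.loc[pos].idxmax())
    table = pd.DataFrame(
        {"jsd_bits": jsd, "consensus_a": cons_a, "consensus_b": cons_b},
        index=fa.index,
    )
    table["rank"] = table["jsd_bits"].rank(ascending=False, method="first").astype("Int64")
    return PositionContrast(table=table[["jsd_bits", "rank", "consensus_a", "consensus_b"]])


@dataclass
class UniquenessReport:
    """(position, residue) pairs whose consensus is confined to one cluster,
    or shared exactly by a chosen cluster subset."""

    unique: pd.DataFrame               # columns: position, residue, cluster
    subset_shared: pd.DataFrame        # columns: position, residue (may be empty)


def cluster_logos(
    assignment: pd.Series,
    fps: Sequence[BindingSiteFingerprint],
    consensus_threshold: float = 0.7,
    pseudocount: float = 0.0,
    subset: Sequence[int] | None = None,
) -> tuple[dict[int, LogoProfile], UniquenessReport]:
    """Per-cluster logo profiles plus a consensus-uniqueness report.

    A (position, residue) pair is a cluster's *consensus* when the residue
    frequency within the cluster is >= ``consensus_threshold``.  Pairs that
    are consensus in exactly one cluster are reported as unique to it.  With
    ``subset`` given (e.g. clusters [1, 2]), pairs that are consensus in every
    subset cluster and in no cluster outside it are reported as subset-shared.
    Empty clusters are skipped with a warning.
    """
    by_cluster: dict[int, list[BindingSiteFingerprint]] = {}
    index = {fp.sequence_id: fp for fp in fps}
    for sid, cl in assignment.items():
        if sid not in index:
            raise ConfigurationError(f"assigned sequence {sid!r} has no fingerprint")
        by_cluster.setdefault(int(cl), []).append(index[sid])
    profiles: dict[int, LogoProfile] = {}
    consensus: dict[int, set[tuple[str, str]]] = {}
    for cl in sorted(by_cluster):
        members = by_cluster[cl]
        if not members:
            warnings.warn(f"cluster {cl} is empty; skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = column_frequencies(members, pseudocount=pseudocount)
        profiles[cl] = prof
        pairs = set()
        for pos in prof.frequencies.index:
            row = prof.frequencies.loc[pos]
            if row.isna().all():
                continue
            aa = row.idxmax()
            if row[aa] >= consensus_threshold:
                pairs.add((pos, aa))
        consensus[cl] = pairs
    all_pairs = set().union(*consensus.values()) if consensus else set()
    unique_rows = []
    for pair in sorted(all_pairs):
        holders = [cl for cl, pairs in consensus.items() if pair in pairs]
        if len(holders) == 1:
            unique_rows.append(
                {"position": pair[0], "residue": pair[1], "cluster": holders[0]}
            )
    unique = pd.DataFrame(unique_rows, columns=["position", "residue", "cluster"])
    shared_rows = []
    if subset:
        subset_set = set(int(c) for c in subset)
        for pair in sorted(all_pairs):
            holders = {cl for cl, pairs in consensus.items() if pair in pairs}
            if holders == subset_set:
                shared_rows.append({"position": pair[0], "residue": pair[1]})
    shared = pd.DataFrame(shared_rows, columns=["position", "residue"])
    return profiles, UniquenessReport(unique=unique, subset_shared=shared)
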