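"""z-scale encoding, PCA of binding-site fingerprints, and score-space clustering.

A fingerprint set of N sequences over P cavity positions becomes an N × 3P
descriptor matrix by replacing each residue with its (z1, z2, z3) triple.
The matrix is mean-centered (no unit-variance scaling — the z-scales are
already standardized descriptors on a common footing) and decomposed by PCA.
Score-space cluster structure is made reproducible with seeded k-means on the
leading components, replacing by-eye ellipse grouping; labels are renumbered
by cluster size, largest first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .alignment import GAP, UNKNOWN, BindingSiteFingerprint
from .errors import EncodingError
from .zscales import DEFAULT_TABLE, ZScaleTable

_SCALES = ("z1", "z2", "z3")


@dataclass
class ZScaleMatrix:
    """Sequences × (positions·3) descriptor matrix with labelled columns."""

    data: pd.DataFrame          # rows: sequence ids, cols: "Pos16.z1", ...
    table_version: str
    gap_policy: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class PCAResult:
    scores: pd.DataFrame              # sequences × PC1..PCk
    loadings: pd.DataFrame            # descriptor columns × PC1..PCk
    explained_variance: np.ndarray    # fractions, non-increasing
    eigenvalues: np.ndarray
    mean: pd.Series                   # column means used for centering


@dataclass
class ClusterSummary:
    assignment: pd.Series                       # sequence id → cluster label (int)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)  # cluster × annotation value
    members: dict[int, list[str]] = field(default_factory=dict)


def encode_zscales(
    fps: Sequence[BindingSiteFingerprint],
    table: ZScaleTable = DEFAULT_TABLE,
    gap_policy: str = "column-mean",
) -> ZScaleMatrix:
    """Encode fingerprints as a sequences × (3 · positions) descriptor matrix.

    Gaps (``-``) and unknowns (``X``) have no descriptors; per ``gap_policy``
    they are imputed with the column mean over non-gap rows ("column-mean")
    or with zero ("zero").  Column labels carry position and scale, e.g.
    ``Pos16.z1``.
    """
    if gap_policy not in ("column-mean", "zero"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    if not fps:
        raise ValueError("no fingerprints to encode")
    positions = fps[0].positions
    columns = [f"{p}.{s}" for p in positions for s in _SCALES]
    rows = np.full((len(fps), len(columns)), np.nan)
    ids = []
    for i, fp in enumerate(fps):
        ids.append(fp.sequence_id)
        for j, (pos, aa) in enumerate(zip(fp.positions, fp.residues)):
            if aa in (GAP, UNKNOWN):
                continue
            if aa not in table:
                raise EncodingError(
                    f"no z-scale entry for residue {aa!r} "
                    f"(sequence {fp.sequence_id!r}, position {pos})"
                )
            rows[i, 3 * j : 3 * j + 3] = table[aa]
    frame = pd.DataFrame(rows, index=ids, columns=columns)
    frame.index.name = "sequence_id"
    if gap_policy == "zero":
        frame = frame.fillna(0.0)
    else:
        frame = frame.fillna(frame.mean()).fillna(0.0)  # all-gap column → 0
    return ZScaleMatrix(data=frame, table_version=table.version, gap_policy=gap_policy)


def run_pca(m: ZScaleMatrix | pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the mean-centered descriptor matrix.

    Components are eigenvectors of the covariance matrix in decreasing
    eigenvalue order, computed via SVD of the centered data.  A deterministic
    sign convention is applied: each loading vector's largest-magnitude
    element is made positive.  ``explained_variance`` holds fractions of the
    total centered variance.
    """
    frame = m.data if isinstance(m, ZScaleMatrix) else m
    n, p = frame.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 rows")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for a {n}×{p} matrix"
        )
    mean = frame.mean()
    x = frame.to_numpy(dtype=float) - mean.to_numpy()
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = (s**2) / (n - 1)
    total_var = eigvals.sum()
    if total_var <= 1e-300:
        warnings.warn("constant matrix: all components have zero variance")
        scores = np.zeros((n, n_components))
        loadings = np.zeros((p, n_components))
        ev = np.zeros(n_components)
        eig = np.zeros(n_components)
    else:
        loadings = vt[:n_components].T
        # sign convention: largest-|loading| entry positive per component
        flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
        flip[flip == 0] = 1.0
        loadings = loadings * flip
        scores = x @ loadings
        eig = eigvals[:n_components]
        ev = eig / total_var
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=frame.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=frame.columns, columns=pcs),
        explained_variance=ev,
        eigenvalues=eig,
        mean=mean,
    )


def cluster_scores(
    p: PCAResult,
    k: int = 4,
    n_components_used: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Seeded k-means on the leading PCA scores.

    Best of ``n_restarts`` initialisations by within-cluster sum of squares;
    cluster labels are renumbered 1..k by descending cluster size (ties broken
    by first occurrence).  Returns a Series sequence id → cluster label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(p.scores)
    if n == 0:
        raise ValueError("empty score matrix")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of sequences ({n})")
    x = p.scores.iloc[:, : min(n_components_used, p.scores.shape[1])].to_numpy()
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda lbl: (-sizes[lbl], np.flatnonzero(raw == lbl)[0]))
    relabel = {old: i + 1 for i, old in enumerate(order)}
    out = pd.Series([relabel[r] for r in raw], index=p.scores.index, name="cluster")
    return out


def summarize_clusters(
    assignment: pd.Series, labels: pd.DataFrame | None = None
) -> ClusterSummary:
    """Cross-tabulate cluster membership against annotation values.

    ``labels`` is indexed by sequence id; each column is one annotation
    (e.g. substrate "GA+"/"GA−", subclade).  Unannotated sequences count as
    "unlabeled" rather than being dropped.  Returns per-cluster counts and
    membership lists.
    """
    members: dict[int, list[str]] = {}
    for sid, cl in assignment.items():
        members.setdefault(int(cl), []).append(str(sid))
    if labels is None or labels.empty:
        counts = pd.DataFrame(
            {"unlabeled": {cl: len(ms) for cl, ms in members.items()}}
        ).sort_index()
        counts.index.name = "cluster"
        return ClusterSummary(assignment=assignment, counts=counts, members=members)
    rows = []
    for sid, cl in assignment.items():
        if sid in labels.index:
            for col in labels.columns:
                rows.append({"cluster": int(cl), "value": str(labels.loc[sid, col])})
        else:
            rows.append({"cluster": int(cl), "value": "unlabeled"})
    tidy = pd.DataFrame(rows)
    counts = tidy.pivot_table(
        index="cluster", columns="value", aggfunc="size", fill_value=0
    )
    counts.columns.name = None
    return ClusterSummary(assignment=assignment, counts=counts, members=members)
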