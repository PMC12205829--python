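"""Self-concept fragmentation: UPGMA dendrograms over trait-rating distances.

For each participant and condition the residualized self-ratings of the
(<= 30) traits in that condition define a 1-D Euclidean distance matrix,
``d(i, j) = |r_i - r_j|``.  Average-linkage (UPGMA) agglomeration over that
matrix yields ``n - 1`` merge heights; the *fragmentation index* is their
mean — the mean distance between all detected clusters.  A second statistic
counts clusters under a grid of height cutoffs (default 0.1 to 1.5, step
0.1) and reports the mean count divided by the number of rated traits.

Design notes: inter-cluster distance is the unweighted mean over all
cross-pair leaf distances; minimum-distance ties break toward the lowest
(left-most) cluster-index pair, where indices are assigned in creation
order (leaves first, then merged clusters).  UPGMA is reducible, so merge
heights are non-decreasing; this is asserted on every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import CONDITIONS, filter_rated

DEFAULT_CUTOFFS = tuple(np.round(np.arange(1, 16) * 0.1, 10))


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.isnan(self.d).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")
        if (self.d < 0).any():
            raise ValueError("negative distance")


@dataclass
class Merge:
    left: int
    right: int
    height: float
    size: int


@dataclass
class Dendrogram:
    merges: list          # of Merge; cluster i's index is n_leaves + position
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])


def pairwise_distances(residuals, labels) -> DistanceMatrix:
    """1-D Euclidean distances between residualized ratings: |r_i - r_j|."""
    r = np.asarray(residuals, dtype=float)
    if len(r) < 2:
        raise ValueError("need >= 2 rated traits")
    if len(r) != len(labels):
        raise ValueError("labels/residuals length mismatch")
    return DistanceMatrix(labels=list(labels), d=np.abs(r[:, None] - r[None, :]))


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration with deterministic lowest-index-pair tie-breaks."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need >= 2 leaves")
    total = 2 * n - 1
    big = np.inf
    D = np.full((total, total), big)
    D[:n, :n] = dm.d
    np.fill_diagonal(D, big)
    sizes = np.zeros(total)
    sizes[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges = []
    prev_h = 0.0
    for step in range(n - 1):
        # first row-major minimum of the symmetric matrix is the
        # lexicographically lowest active pair (i, j), i < j
        k = int(np.argmin(D))
        i, j = divmod(k, total)
        h = float(D[i, j])
        assert h >= prev_h - 1e-9, "UPGMA reducibility violated"
        prev_h = max(prev_h, h)
        new = n + step
        # Lance-Williams update for unweighted average linkage
        active[i] = active[j] = False
        others = np.flatnonzero(active)
        if len(others):
            D[new, others] = D[others, new] = (
                sizes[i] * D[i, others] + sizes[j] * D[j, others]
            ) / (sizes[i] + sizes[j])
        sizes[new] = sizes[i] + sizes[j]
        D[i, :] = D[:, i] = big
        D[j, :] = D[:, j] = big
        active[new] = True
        merges.append(Merge(left=int(i), right=int(j), height=h,
                            size=int(sizes[new])))
    return Dendrogram(merges=merges, n_leaves=n)


def fragmentation_index(dn: Dendrogram) -> float:
    """Mean distance between all detected clusters: mean of merge heights."""
    return float(dn.heights.mean())


def count_clusters(dn: Dendrogram, cutoff: float) -> int:
    """Clusters remaining when merges with height > cutoff are cut."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return int(dn.n_leaves - np.count_nonzero(dn.heights <= cutoff))


def cluster_count_proportion(dn: Dendrogram, cutoffs=DEFAULT_CUTOFFS) -> float:
    """Mean cluster count over the cutoff grid, divided by the leaf count."""
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.size == 0:
        raise ValueError("empty cutoff grid")
    counts = [count_clusters(dn, c) for c in cutoffs]
    return float(np.mean(counts) / dn.n_leaves)


def _cell_result(res: np.ndarray, labels, cutoffs, standardize) -> dict:
    if standardize:
        sd = res.std(ddof=1)
        res = (res - res.mean()) / sd if sd > 0 else res - res.mean()
    dn = average_linkage(pairwise_distances(res, labels))
    return {
        "mean_cluster_distance": fragmentation_index(dn),
        "n_rated": dn.n_leaves,
        "cluster_count_proportion": cluster_count_proportion(dn, cutoffs),
    }


def fragmentation_by_condition(residuals: pd.DataFrame,
                               cutoffs=DEFAULT_CUTOFFS,
                               assignment: pd.DataFrame | None = None,
                               standardize: bool = False) -> pd.DataFrame:
    """Per participant x condition fragmentation statistics.

    ``target='self'`` rows give the main analysis.  As a semantic control,
    friend ratings are re-clustered within the trait subsets later assigned
    to each condition (``target='friend_control'`` rows).  ``assignment``
    optionally supplies the full trait -> condition design (an unfiltered
    rating table), so friend controls include traits whose self-rating timed
    out; by default the assignment is read off the rated self rows.  Cells
    with fewer than 2 rated traits are excluded with a warning.
    ``standardize`` z-scores each cell's residuals before computing
    distances (sensitivity analysis for the fixed cutoff grid; default off).
    """
    if "residual" not in residuals.columns:
        raise ValueError("expected a residualized rating table")
    residuals = residuals.copy()
    residuals.attrs = {}  # drop heavyweight provenance before slicing
    rows, skipped = [], []
    selfr = residuals[residuals["target"] == "self"]
    friendr = residuals[residuals["target"] == "friend"]
    assign_src = assignment if assignment is not None else selfr
    assign_self = assign_src[assign_src["target"] == "self"]
    self_cells = {k: g for k, g in
                  selfr.groupby(["participant_id", "condition"], sort=True)}
    friend_res = {pid: dict(zip(g["trait_id"], g["residual"]))
                  for pid, g in friendr.groupby("participant_id", sort=True)}
    assign_cells = {k: g["trait_id"].tolist() for k, g in
                    assign_self.groupby(["participant_id", "condition"],
                                        sort=True)}
    pids = sorted(selfr["participant_id"].unique())
    for pid in pids:
        fres = friend_res.get(pid, {})
        for cond in CONDITIONS:
            cell = self_cells.get((pid, cond))
            if cell is not None and len(cell) >= 2:
                rows.append({"participant_id": pid, "condition": cond,
                             "target": "self",
                             **_cell_result(cell["residual"].to_numpy(),
                                            cell["trait_id"].tolist(),
                                            cutoffs, standardize)})
            else:
                skipped.append((pid, cond, "self"))
            ftraits = [t for t in assign_cells.get((pid, cond), []) if t in fres]
            if len(ftraits) >= 2:
                fvals = np.array([fres[t] for t in ftraits])
                rows.append({"participant_id": pid, "condition": cond,
                             "target": "friend_control",
                             **_cell_result(fvals, ftraits, cutoffs, standardize)})
            else:
                skipped.append((pid, cond, "friend_control"))
    if skipped:
        warnings.warn(f"excluded {len(skipped)} cells with < 2 rated traits: "
                      f"{skipped[:3]}...")
    return pd.DataFrame(rows)
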