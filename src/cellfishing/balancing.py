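"""Class balancing by hierarchical-clustering undersampling.

Per-cell-line training sets are usually skewed: a cell line may have many
more resistant than sensitive compounds (or vice versa).  A set is deemed
unbalanced when the majority class exceeds 1.2x the minority class.  The
majority class is then reduced to exactly the minority count Nm while
preserving its chemical diversity:

* compounds are clustered by Ward's minimum-variance agglomeration on the
  Tanimoto distance matrix, cutting the tree at a fixed height;
* if the number of clusters Nc < Nm, compounds are drawn from each cluster
  proportionally to its size (largest-remainder apportionment, most central
  compounds of each cluster first) until Nm are selected;
* if Nc > Nm, the majority class is re-clustered into exactly Nm clusters
  and each cluster contributes its single most central compound;
* at the Nc == Nm boundary each existing cluster contributes its most
  central compound, which both branches reduce to.

"Most central" is the medoid: the compound minimizing the summed Tanimoto
distance to its cluster members (a mean bit vector is not a compound); ties
break by lexicographic compound id, so selection is deterministic.

Ward linkage formally assumes Euclidean geometry while Tanimoto distance is
not Euclidean; the procedure applies Ward to the Tanimoto matrix regardless,
which is a well-known pragmatic usage in cheminformatics.  Cut heights are
therefore on the scale scipy's Ward criterion produces for 0-1 distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DimensionError
from .fingerprints import Fingerprint, tanimoto_distance_matrix

__all__ = [
    "BalancingReport",
    "is_balanced",
    "ward_clusters",
    "ward_n_clusters",
    "cluster_medoid",
    "reduce_majority",
    "balance_classes",
]

DEFAULT_BALANCE_RATIO = 1.2
DEFAULT_WARD_HEIGHT = 4.5


@dataclass
class BalancingReport:
    """Record of one cell line's balancing outcome."""

    cell_line_id: str
    n_sensitive: int
    n_resistant: int
    balanced: bool
    branch: str  # none | proportional | centroid
    n_clusters: int  # Nc (0 when no reduction ran)
    n_minority: int  # Nm
    selected_ids: list[str] = field(default_factory=list)


def is_balanced(
    n_majority: int, n_minority: int, ratio: float = DEFAULT_BALANCE_RATIO
) -> bool:
    """True unless the majority class has MORE than ratio x the minority."""
    if n_majority < 1 or n_minority < 1:
        raise ValueError("both classes must be non-empty")
    if n_majority < n_minority:
        raise ValueError("majority count smaller than minority count")
    return n_majority <= ratio * n_minority


def _check_distance_matrix(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise DimensionError(f"distance matrix must be square, got {dm.shape}")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise DimensionError("distance matrix must be symmetric")
    return dm


def _ward_linkage(dm: np.ndarray) -> np.ndarray:
    return linkage(squareform(dm, checks=False), method="ward")


def ward_clusters(distance_matrix: np.ndarray, height: float = DEFAULT_WARD_HEIGHT) -> np.ndarray:
    """Ward agglomeration cut at a height; returns integer labels (1-based)."""
    dm = _check_distance_matrix(distance_matrix)
    if dm.shape[0] == 1:
        return np.ones(1, dtype=int)
    tree = _ward_linkage(dm)
    return fcluster(tree, t=height, criterion="distance")


def ward_n_clusters(distance_matrix: np.ndarray, n_clusters: int) -> np.ndarray:
    """Ward agglomeration cut to exactly n_clusters groups."""
    dm = _check_distance_matrix(distance_matrix)
    if dm.shape[0] == 1:
        return np.ones(1, dtype=int)
    tree = _ward_linkage(dm)
    return fcluster(tree, t=n_clusters, criterion="maxclust")


def cluster_medoid(dm: np.ndarray, members: np.ndarray, ids: list[str]) -> int:
    """Index (into the full set) of the member minimizing summed distance.

    Ties break by lexicographic compound id.
    """
    sub = dm[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    order = sorted(range(len(members)), key=lambda i: (sums[i], ids[members[i]]))
    return int(members[order[0]])


def _central_order(dm: np.ndarray, members: np.ndarray, ids: list[str]) -> list[int]:
    """Members sorted most-central-first (ascending summed distance, then id)."""
    sub = dm[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return [
        int(members[i])
        for i in sorted(range(len(members)), key=lambda i: (sums[i], ids[members[i]]))
    ]


def _largest_remainder_quotas(sizes: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` picks across clusters proportionally to size."""
    ideal = sizes * total / sizes.sum()
    quotas = np.floor(ideal).astype(int)
    remainder = total - quotas.sum()
    # distribute leftovers to the largest fractional parts; ties to larger
    # clusters first, then lower cluster index, for determinism
    frac = ideal - quotas
    order = sorted(range(len(sizes)), key=lambda i: (-frac[i], -sizes[i], i))
    for i in order:
        if remainder == 0:
            break
        if quotas[i] < sizes[i]:
            quotas[i] += 1
            remainder -= 1
    # cap at cluster size (can only matter after the +1 step) and backfill
    while remainder > 0:
        for i in order:
            if remainder == 0:
                break
            if quotas[i] < sizes[i]:
                quotas[i] += 1
                remainder -= 1
    return quotas


def reduce_majority(
    ids: list[str],
    fps: list[Fingerprint],
    n_minority: int,
    height: float = DEFAULT_WARD_HEIGHT,
    cell_line_id: str = "",
    n_sensitive: int = 0,
    n_resistant: int = 0,
) -> BalancingReport:
    """Select exactly Nm = n_minority majority-class compounds.

    Parameters
    ----------
    ids, fps
        The majority-class compound ids and their fingerprints (radius 8,
        1024 bits in the standard configuration), in matching order.
    n_minority
        Target size Nm; must be smaller than the majority size.
    height
        Ward tree cut height defining the initial clusters.
    """
    n = len(ids)
    if not 1 <= n_minority < n:
        raise ValueError(f"need 1 <= Nm < majority size, got Nm={n_minority}, n={n}")
    dm = tanimoto_distance_matrix(fps)
    labels = ward_clusters(dm, height=height)
    nc = int(labels.max())

    if nc < n_minority:
        branch = "proportional"
        clusters = [np.flatnonzero(labels == c) for c in range(1, nc + 1)]
        sizes = np.array([len(m) for m in clusters])
        quotas = _largest_remainder_quotas(sizes, n_minority)
        selected: list[int] = []
        for members, q in zip(clusters, quotas):
            selected.extend(_central_order(dm, members, ids)[:q])
    else:
        # Nc > Nm: re-cluster to exactly Nm groups and take each medoid;
        # Nc == Nm reduces to one medoid per existing cluster
        branch = "centroid"
        if nc > n_minority:
            labels = ward_n_clusters(dm, n_minority)
        selected = [
            cluster_medoid(dm, np.flatnonzero(labels == c), ids)
            for c in range(1, int(labels.max()) + 1)
        ]

    picked = sorted(ids[i] for i in selected)
    assert len(picked) == len(set(picked)) == n_minority
    return BalancingReport(
        cell_line_id=cell_line_id,
        n_sensitive=n_sensitive,
        n_resistant=n_resistant,
        balanced=False,
        branch=branch,
        n_clusters=nc,
        n_minority=n_minority,
        selected_ids=picked,
    )


def balance_classes(
    sensitive_ids: list[str],
    resistant_ids: list[str],
    fp_lookup: dict[str, Fingerprint],
    ratio: float = DEFAULT_BALANCE_RATIO,
    height: float = DEFAULT_WARD_HEIGHT,
    cell_line_id: str = "",
) -> tuple[list[str], list[str], BalancingReport]:
    """Balance one cell line's two classes; returns (sensitive, resistant, report).

    The untouched minority class passes through; when the 1.2 rule already
    holds no reduction runs at all.
    """
    ns, nr = len(sensitive_ids), len(resistant_ids)
    maj_ids, maj_label = (sensitive_ids, "sensitive") if ns >= nr else (resistant_ids, "resistant")
    n_majority, n_min = max(ns, nr), min(ns, nr)
    if is_balanced(n_majority, n_min, ratio=ratio):
        report = BalancingReport(
            cell_line_id=cell_line_id,
            n_sensitive=ns,
            n_resistant=nr,
            balanced=True,
            branch="none",
            n_clusters=0,
            n_minority=n_min,
        )
        return list(sensitive_ids), list(resistant_ids), report
    report = reduce_majority(
        list(maj_ids),
        [fp_lookup[c] for c in maj_ids],
        n_min,
        height=height,
        cell_line_id=cell_line_id,
        n_sensitive=ns,
        n_resistant=nr,
    )
    if maj_label == "sensitive":
        return report.selected_ids, list(resistant_ids), report
    return list(sensitive_ids), report.selected_ids, report
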