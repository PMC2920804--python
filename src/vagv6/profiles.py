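"""Compositional community profiles: proportions, the Fisher-Rao angular
distance between samples, the sample neighbor-joining tree, and major-cluster
extraction.

The distance between two community compositions p and q is the generalized
angle theta = arccos(sum_i sqrt(p_i q_i)) between their square-root images
on the unit sphere (the Bhattacharyya angle; geodesic Fisher-Rao distance up
to a factor of 2). Small angles mean near-identical communities; disjoint
communities are maximally distinct at pi/2. A plain Euclidean-cosine variant
on raw proportions is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

#: Default average-linkage cutoff (radians) for major-cluster extraction;
#: calibrated once on the default synthetic cohort (see docs/methods.md).
DEFAULT_LINKAGE_CUTOFF = 0.35
MIN_MAJOR_SIZE = 11  # "major" = more than 10 samples


def to_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a samples x OTUs count table to proportions."""
    totals = counts.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    return counts.div(totals, axis=0)


def angular_distance(p, q, sqrt_geometry: bool = True) -> float:
    """Generalized angle between two proportion vectors.

    With ``sqrt_geometry`` (default) this is the Bhattacharyya angle
    ``arccos(sum sqrt(p q))``; otherwise the angle between the raw vectors
    under the Euclidean inner product.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("proportion vectors differ in length")
    if sqrt_geometry:
        cos = float(np.sqrt(p * q).sum())
    else:
        cos = float(p @ q / (np.linalg.norm(p) * np.linalg.norm(q)))
    return float(np.arccos(np.clip(cos, 0.0, 1.0)))


def distance_matrix(props: pd.DataFrame, sqrt_geometry: bool = True):
    """All-pairs angular distances as a scikit-bio DistanceMatrix."""
    from skbio import DistanceMatrix

    x = props.to_numpy(float)
    if sqrt_geometry:
        root = np.sqrt(x)
        cos = np.clip(root @ root.T, 0.0, 1.0)
    else:
        norm = x / np.linalg.norm(x, axis=1, keepdims=True)
        cos = np.clip(norm @ norm.T, 0.0, 1.0)
    theta = np.arccos(cos)
    np.fill_diagonal(theta, 0.0)
    theta = (theta + theta.T) / 2
    return DistanceMatrix(theta, [str(i) for i in props.index])


def sample_nj_tree(dm):
    """Neighbor-joining tree over the sample distance matrix (Newick via
    ``str(tree)``)."""
    from skbio.tree import nj

    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains NaN")
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    return nj(dm)


def extract_clusters(dm, props: pd.DataFrame,
                     linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF,
                     min_size: int = MIN_MAJOR_SIZE) -> pd.DataFrame:
    """Major community clusters by average-linkage agglomeration.

    Groups of at least ``min_size`` samples below the cutoff are "major"
    clusters, labeled by the taxon with the highest mean proportion inside
    the cluster; everything else is "minor". Returns a frame indexed by
    sample id with columns ``cluster`` (label or "minor") and ``component``.
    """
    if not 0 <= linkage_cutoff <= np.pi / 2:
        raise ValueError("cutoff must lie in [0, pi/2]")
    ids = list(dm.ids)
    props = props.copy()
    props.index = props.index.astype(str)
    condensed = squareform(dm.data, checks=False)
    z = linkage(condensed, method="average")
    comp = fcluster(z, t=linkage_cutoff, criterion="distance")
    comp_series = pd.Series(comp, index=ids, name="component")
    labels = {}
    used = {}
    # deterministic label order: components by size desc then index
    sizes = comp_series.value_counts()
    for c in sorted(sizes.index, key=lambda c: (-sizes[c], c)):
        members = comp_series.index[comp_series == c]
        if len(members) < min_size:
            for m in members:
                labels[m] = "minor"
            continue
        sub = props.loc[list(members)]
        top = sub.mean(axis=0).idxmax()
        name = str(top)
        if name in used:
            used[name] += 1
            name = f"{name} ({used[str(top)]})"
        else:
            used[name] = 1
        for m in members:
            labels[m] = name
    out = pd.DataFrame({"cluster": pd.Series(labels),
                        "component": comp_series})
    out.index.name = "sample_id"
    return out.loc[ids]
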