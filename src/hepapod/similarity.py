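"""Biological-response similarity: BMC-set overlaps and signature clustering.

Two complementary views of cross-substance similarity. (1) Set overlap of the
gene- or pathway-level BMC identities: a core "shared X of possible Y"
summary (intersection over union of all sets) plus pairwise Jaccard indices.
(2) A signed rank-score signature per substance/run — the union of the top-N
most potent and top-N highest fold-change features, scored by descending
potency and signed by response direction — clustered with Ward's method on
Euclidean distance, missing features scored 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


def bmc_overlap(sets: dict[str, set], mode: str = "core") -> dict:
    """Overlap of feature-ID sets across substances.

    mode='core': shared = |intersection of all sets|, possible = |union|,
    with the percentage rounded to the nearest integer. mode='pairwise':
    a symmetric Jaccard matrix over substances.
    """
    if not sets:
        raise ValueError("need at least one feature set")
    names = sorted(sets)
    as_sets = {k: set(v) for k, v in sets.items()}
    if mode == "core":
        inter = set.intersection(*as_sets.values())
        union = set.union(*as_sets.values())
        possible = len(union)
        pct = int(round(len(inter) / possible * 100)) if possible else 0
        return {
            "level_names": names,
            "shared": len(inter),
            "possible": possible,
            "percentage": pct,
        }
    if mode == "pairwise":
        mat = pd.DataFrame(1.0, index=names, columns=names)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                u = as_sets[a] | as_sets[b]
                j = len(as_sets[a] & as_sets[b]) / len(u) if u else 1.0
                mat.loc[a, b] = mat.loc[b, a] = j
        return {"level_names": names, "jaccard": mat}
    raise ValueError("mode must be 'core' or 'pairwise'")


def build_signature(
    results: pd.DataFrame, top_n: int = 100
) -> pd.Series:
    """Signed rank-score signature for one substance/run.

    Selects the union of the ``top_n`` lowest-BMC features and the ``top_n``
    highest max-fold-change features from a filtered results table (columns
    probe_id, bmc, max_fold_change, direction). With K features selected,
    the feature ranked r by ascending BMC (stable ties by probe_id) scores
    K - r + 1, signed + for up- and - for down-regulation. Unselected
    features are absent (treated as 0 when signatures are merged).
    """
    if results.empty:
        import warnings

        warnings.warn("empty results table; returning empty signature")
        return pd.Series(dtype=float)
    tbl = results.sort_values(["bmc", "probe_id"], kind="stable")
    potent = set(tbl["probe_id"].head(top_n))
    by_fc = results.sort_values(
        ["max_fold_change", "probe_id"], ascending=[False, True], kind="stable"
    )
    effective = set(by_fc["probe_id"].head(top_n))
    chosen = tbl[tbl["probe_id"].isin(potent | effective)].reset_index(drop=True)
    k = len(chosen)
    scores = (k - np.arange(k)).astype(float)
    signs = np.where(chosen["direction"].to_numpy() == "down", -1.0, 1.0)
    return pd.Series(scores * signs, index=chosen["probe_id"], name="score")


def merge_signatures(signatures: dict[str, pd.Series]) -> pd.DataFrame:
    """Union-align signatures into a matrix (rows = substance/run labels),
    absent features exactly 0, features sorted lexicographically."""
    features = sorted(set().union(*(s.index for s in signatures.values())))
    mat = pd.DataFrame(0.0, index=sorted(signatures), columns=features)
    for label, sig in signatures.items():
        mat.loc[label, sig.index] = sig.to_numpy(dtype=float)
    return mat


def merge_and_cluster(
    signatures: dict[str, pd.Series], k: int = 5
) -> tuple[pd.Series, np.ndarray, pd.DataFrame]:
    """Ward hierarchical clustering of signed rank-score signatures.

    Features and leaf labels are sorted lexicographically before linkage so
    the result is invariant to input ordering. Returns (cluster assignment
    per label, the scipy linkage matrix, the aligned signature matrix).
    """
    if len(signatures) < k:
        raise ValueError(f"need at least k={k} signatures, got {len(signatures)}")
    mat = merge_signatures(signatures)
    linkage = hierarchy.ward(mat.to_numpy())
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=mat.index, name="cluster"), linkage, mat


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, labels)
    return str(tree).strip()
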