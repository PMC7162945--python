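"""Weighted coexpression network construction and module detection.

Expressed, Z-scored series are correlated (Pearson), raised to a soft
thresholding power to form an unsigned weighted adjacency, and converted
to a topological-overlap dissimilarity.  Average-linkage clustering with
a static cut yields initial modules; because an unsigned network groups
anti-correlated series together, each module is then split by
correlation sign, given a median representative series, merged with
close modules (representative dissimilarity <= a threshold), and finally
pruned by a minimum mean intramodular adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Network and module-detection parameters.

    beta : soft thresholding power applied to |r| (18 in the study).
    cut_height : static cut height on the clustering dissimilarity.
    merge_dissim_max : modules whose representatives have
        1 - Pearson <= this are merged (0.25 in the study).
    adjacency_min : members need at least this mean adjacency to the
        rest of their module to be retained (0.175 in the study).
    """

    beta: float = 18.0
    merge_dissim_max: float = 0.25
    adjacency_min: float = 0.175
    min_module_size: int = 10
    cut_height: float = 0.9
    linkage_method: str = "average"
    use_tom: bool = True

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise NetworkError("beta must be >= 1")
        for name in ("merge_dissim_max", "adjacency_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise NetworkError(f"{name} must be in [0, 1], got {v}")
        if self.min_module_size < 1:
            raise NetworkError("min_module_size must be >= 1")


@dataclass
class CoexpressionModule:
    """A (sign-split) coexpression module within one organ."""

    module_id: str
    organ: str
    member_ids: tuple[str, ...]
    sign: str  # "plus" | "minus"
    representative: np.ndarray
    eligible: bool = True

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise NetworkError("module must have at least one member")


def correlation_matrix(values: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between transcript rows; rejects constant rows."""
    if values.shape[0] < 2:
        raise NetworkError("need at least 2 transcripts")
    sd = values.std(axis=1, ddof=1)
    bad = values.index[(sd == 0.0) | ~np.isfinite(sd)]
    if len(bad):
        raise NetworkError(f"constant series {bad[0]!r} has no defined correlation")
    corr = np.corrcoef(values.to_numpy(dtype=float))
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def soft_adjacency(corr: np.ndarray, beta: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency |r|^beta with zero diagonal."""
    if np.any(np.abs(corr) > 1.0 + 1e-12):
        raise NetworkError("correlations must lie in [-1, 1]")
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity 1 - TOM, zero diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    the standard unsigned formulation with connectivities k = row sums.
    """
    a = np.asarray(adjacency, dtype=float)
    if np.any(a < 0):
        raise NetworkError("adjacency entries must be non-negative")
    if not np.allclose(a, a.T):
        raise NetworkError("adjacency must be symmetric")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    return np.clip(dissim, 0.0, 1.0)


def hierarchical_modules(
    dissimilarity: np.ndarray, ids: list[str], config: NetworkConfig
) -> tuple[dict[int, list[str]], list[str]]:
    """Average-linkage tree with a static cut.

    Returns ``(clusters, unassigned)``; clusters smaller than
    ``min_module_size`` go to the unassigned pool.  Cluster keys are
    renumbered 1..K by decreasing size (ties by smallest member id) so
    labelling is deterministic.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.size == 0:
        raise NetworkError("empty dissimilarity matrix")
    if len(ids) != d.shape[0]:
        raise NetworkError("ids do not match dissimilarity size")
    if len(ids) == 1:
        return {}, list(ids)
    tree = linkage(squareform(d, checks=False), method=config.linkage_method)
    flat = fcluster(tree, t=config.cut_height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for label, tid in zip(flat, ids):
        groups.setdefault(int(label), []).append(tid)
    kept = [sorted(g) for g in groups.values() if len(g) >= config.min_module_size]
    kept.sort(key=lambda g: (-len(g), g[0]))
    unassigned = sorted(
        tid for g in groups.values() if len(g) < config.min_module_size for tid in g
    )
    return {i + 1: g for i, g in enumerate(kept)}, unassigned


def split_by_sign(zscored: pd.DataFrame) -> dict[str, list[str]]:
    """Split a module's members into positively/negatively tracking groups.

    The seed is the member most correlated in absolute value with the
    module mean series; members correlating >= 0 with the seed form the
    "plus" group, the rest the "minus" group.  Empty groups are dropped.
    """
    if zscored.shape[0] == 0:
        raise NetworkError("empty module")
    if zscored.shape[0] == 1:
        return {"plus": list(zscored.index)}
    x = zscored.to_numpy(dtype=float)
    mean_series = x.mean(axis=0)
    if np.ptp(mean_series) == 0.0:
        # perfectly balanced anti-phase module: seed on the first member
        seed_idx = 0
    else:
        with np.errstate(invalid="ignore"):
            r_mean = _corr_with(x, mean_series)
        seed_idx = int(np.nanargmax(np.abs(r_mean)))
    r_seed = _corr_with(x, x[seed_idx])
    plus = [tid for tid, r in zip(zscored.index, r_seed) if r >= 0]
    minus = [tid for tid, r in zip(zscored.index, r_seed) if r < 0]
    out = {}
    if plus:
        out["plus"] = plus
    if minus:
        out["minus"] = minus
    return out


def _corr_with(rows: np.ndarray, target: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rc @ tc) / denom


def module_representative(zscored_members: pd.DataFrame) -> np.ndarray:
    """Typical series of a module: pointwise median across members."""
    if zscored_members.shape[0] == 0:
        raise NetworkError("empty module")
    return np.median(zscored_members.to_numpy(dtype=float), axis=0)


def build_modules(
    zscored: pd.DataFrame, config: NetworkConfig, organ: str
) -> tuple[list[CoexpressionModule], pd.DataFrame, list[str]]:
    """Network -> tree -> sign-split modules with representatives.

    Returns the sign-split modules, the adjacency matrix (as a
    DataFrame, needed later for the membership filter) and the
    unassigned pool.
    """
    ids = list(zscored.index)
    corr = correlation_matrix(zscored)
    adj = soft_adjacency(corr, config.beta)
    dissim = topological_overlap(adj) if config.use_tom else 1.0 - adj
    clusters, unassigned = hierarchical_modules(dissim, ids, config)
    adj_df = pd.DataFrame(adj, index=ids, columns=ids)
    modules: list[CoexpressionModule] = []
    sign_tag = {"plus": "+", "minus": "-"}
    for num, members in clusters.items():
        sub = zscored.loc[members]
        for sign, group in split_by_sign(sub).items():
            rep = module_representative(zscored.loc[group])
            modules.append(
                CoexpressionModule(
                    module_id=f"{organ}.M{num:02d}{sign_tag[sign]}",
                    organ=organ,
                    member_ids=tuple(sorted(group)),
                    sign=sign,
                    representative=rep,
                )
            )
    modules.sort(key=lambda m: m.module_id)
    return modules, adj_df, unassigned


def _rep_dissim(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson between representatives (range [0, 2], not clipped)."""
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def merge_close_modules(
    modules: list[CoexpressionModule],
    merge_dissim_max: float,
    zscored: pd.DataFrame,
) -> list[CoexpressionModule]:
    """Greedily merge the closest pair of modules while it is close enough.

    Dissimilarity is 1 - Pearson between representatives; after each
    merge the union's representative is recomputed before the next
    round.  The merged module keeps the lexicographically smaller id and
    the sign of the larger member group (ties -> plus).  Anti-correlated
    representatives (dissimilarity near 2) never merge.
    """
    mods = {m.module_id: m for m in modules}
    while len(mods) > 1:
        keys = sorted(mods)
        best_pair = None
        best_d = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                d = _rep_dissim(mods[ka].representative, mods[kb].representative)
                if best_d is None or d < best_d - 1e-12:
                    best_d, best_pair = d, (ka, kb)
        if best_d is None or best_d > merge_dissim_max:
            break
        ka, kb = best_pair
        a, b = mods.pop(ka), mods.pop(kb)
        members = tuple(sorted(set(a.member_ids) | set(b.member_ids)))
        bigger = a if len(a.member_ids) >= len(b.member_ids) else b
        merged = CoexpressionModule(
            module_id=min(ka, kb),
            organ=a.organ,
            member_ids=members,
            sign=bigger.sign,
            representative=module_representative(zscored.loc[list(members)]),
        )
        mods[merged.module_id] = merged
    return [mods[k] for k in sorted(mods)]


def apply_adjacency_threshold(
    modules: list[CoexpressionModule],
    adjacency: pd.DataFrame,
    adjacency_min: float,
) -> list[CoexpressionModule]:
    """Membership filter: keep members well connected inside their module.

    A member is retained iff its mean adjacency to the *other* members
    of its module is >= ``adjacency_min`` (boundary kept).  Modules
    emptied by pruning (including singletons, whose mean over no
    neighbours is taken as 0) are dropped.
    """
    out: list[CoexpressionModule] = []
    for mod in modules:
        ids = list(mod.member_ids)
        if len(ids) == 1:
            continue
        sub = adjacency.loc[ids, ids].to_numpy(dtype=float)
        mean_adj = sub.sum(axis=1) / (len(ids) - 1)
        kept = [tid for tid, a in zip(ids, mean_adj) if a >= adjacency_min]
        if not kept:
            continue
        out.append(replace(mod, member_ids=tuple(sorted(kept)), eligible=True))
    return out
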