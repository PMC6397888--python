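"""Weighted co-expression network core (WGCNA-style).

Unsigned adjacency a_ij = |cor(x_i, x_j)|^beta with the soft-threshold
power beta chosen by the scale-free topology criterion, topological
overlap, average-linkage module detection on 1-TOM, module eigengenes
(first principal component of the standardized module expression), and
eigengene-trait correlation against the 1/2/3 fruit-color score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNASSIGNED = "unassigned"
FALLBACK_POWER = 6


@dataclass
class CoexprParams:
    #: candidate soft-threshold powers; capped at 12 because with few
    #: samples the scale-free criterion can be met spuriously at very
    #: high powers, which sharpen correlation noise into the network
    power_grid: tuple = tuple(range(1, 13))
    scale_free_r2_cutoff: float = 0.8
    #: static dendrogram cut height; None selects the height yielding
    #: the largest number of clusters of at least min_module_size
    cut_height: float | None = None
    min_module_size: int = 10
    n_degree_bins: int = 10
    top_n_features: int = 5000


@dataclass
class Module:
    module_id: str
    members: list[str]
    eigengene: pd.Series | None = None
    variance_explained: float | None = None
    trait_correlation: float | None = None
    trait_p: float | None = None


def log_transform(fpkm: pd.DataFrame) -> pd.DataFrame:
    return np.log2(fpkm.astype(float) + 1.0)


def select_top_variance(expr: pd.DataFrame, top_n: int) -> pd.DataFrame:
    variances = expr.var(axis=1)
    keep = variances.sort_values(ascending=False).index[:top_n]
    return expr.loc[expr.index.intersection(keep, sort=False)]


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    if (expr.var(axis=1) == 0).any():
        raise ValueError("zero-variance features must be removed first")
    return np.clip(np.corrcoef(expr.values), -1.0, 1.0)


def adjacency(expr: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned WGCNA adjacency |cor|^beta; symmetric with unit diagonal."""
    adj = np.abs(correlation_matrix(expr)) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of an adjacency matrix.

    Connectivity k_i = sum_j a_ij (self excluded) is binned on log10
    scale; R^2 of log10(freq) ~ log10(mean k) is returned with WGCNA's
    sign convention: positive only when the slope is negative.  NaN for
    degenerate (single-bin) connectivity distributions.
    """
    k = adj.sum(axis=1) - np.diag(adj)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        in_bin = idx == b
        if in_bin.sum() == 0:
            continue
        log_freq.append(np.log10(in_bin.mean()))
        log_k.append(np.log10(k[in_bin].mean()))
    if len(log_k) < 3:
        return np.nan
    fit = stats.linregress(log_k, log_freq)
    return -np.sign(fit.slope) * fit.rvalue**2


def pick_soft_threshold(
    expr: pd.DataFrame, params: CoexprParams | None = None
) -> tuple[int, pd.DataFrame]:
    """Smallest power reaching the scale-free R^2 cutoff, else 6."""
    params = params or CoexprParams()
    if expr.shape[0] < 20:
        raise ValueError("need >= 20 features for soft-threshold selection")
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples for soft-threshold selection")
    cor_abs = np.abs(correlation_matrix(expr))
    rows = []
    chosen = None
    for power in params.power_grid:
        adj = cor_abs**power
        np.fill_diagonal(adj, 1.0)
        r2 = scale_free_fit(adj, params.n_degree_bins)
        mean_k = float((adj.sum(axis=1) - 1.0).mean())
        rows.append((power, r2, mean_k))
        if chosen is None and np.isfinite(r2) and r2 >= params.scale_free_r2_cutoff:
            chosen = int(power)
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_connectivity"])
    if chosen is None:
        warnings.warn(
            f"no power reached scale-free R^2 >= "
            f"{params.scale_free_r2_cutoff}; falling back to "
            f"{FALLBACK_POWER}"
        )
        chosen = FALLBACK_POWER
    return chosen, table


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), diagonal 1."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)  # self-adjacency excluded from k and l
    k = a.sum(axis=1)
    l = a @ a
    min_k = np.minimum.outer(k, k)
    tom = (l + a) / (min_k + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def _select_cut_height(
    linkage: np.ndarray, min_module_size: int, n_candidates: int = 1000
) -> float:
    """Static cut height yielding the most clusters >= min_module_size.

    Candidate heights are the merge heights themselves (subsampled for
    large trees); of the heights tied for the maximal count the largest
    is chosen, so each module absorbs its satellites while distinct
    modules stay separate.
    """
    heights = np.unique(linkage[:, 2])
    if heights.size > n_candidates:
        take = np.linspace(0, heights.size - 1, n_candidates).astype(int)
        heights = heights[take]
    best_height, best_count = float(heights[-1]), -1
    for height in heights:
        labels = hierarchy.fcluster(
            linkage, t=height + 1e-12, criterion="distance"
        )
        count = int((np.bincount(labels) >= min_module_size).sum())
        if count >= best_count:
            best_height, best_count = float(height + 1e-12), count
    return best_height


def cluster_modules(
    tom: np.ndarray,
    feature_ids: list[str],
    params: CoexprParams | None = None,
) -> dict[str, str]:
    """Average-linkage clustering of 1-TOM with a static height cut.

    Returns feature_id -> module_id ("M1", "M2", ... by decreasing size;
    features in clusters below min_module_size go to "unassigned").
    """
    params = params or CoexprParams()
    n = len(feature_ids)
    if n != tom.shape[0]:
        raise ValueError("feature ids do not match TOM dimension")
    if n < params.min_module_size:
        return {fid: UNASSIGNED for fid in feature_ids}
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    linkage = hierarchy.average(squareform(diss, checks=False))
    cut = (
        params.cut_height
        if params.cut_height is not None
        else _select_cut_height(linkage, params.min_module_size)
    )
    labels = hierarchy.fcluster(linkage, t=cut, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    keep = [lab for lab in sizes.index if sizes[lab] >= params.min_module_size]
    # name modules M1.. by decreasing size, ties broken by first feature
    order = sorted(
        keep, key=lambda lab: (-sizes[lab], int(np.nonzero(labels == lab)[0][0]))
    )
    rename = {lab: f"M{i + 1}" for i, lab in enumerate(order)}
    return {
        fid: rename.get(lab, UNASSIGNED) for fid, lab in zip(feature_ids, labels)
    }


def eigengene(expr: pd.DataFrame, member_ids: list[str]) -> tuple[pd.Series, float]:
    """Module eigengene: first PC over samples of standardized expression.

    The sign is fixed so the eigengene correlates positively with the
    module's mean standardized profile.  Also returns the fraction of
    variance explained.
    """
    if len(member_ids) < 2:
        raise ValueError("module eigengene needs >= 2 members")
    sub = expr.loc[member_ids].values
    sd = sub.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance feature in module")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(eig, index=expr.columns), var_explained


def module_trait_correlation(
    modules: list[Module], trait: pd.Series
) -> pd.DataFrame:
    """Pearson r (and Student-t p) of each eigengene with the trait."""
    if trait.nunique() < 2:
        raise ValueError("trait is constant; correlation undefined")
    rows = []
    for mod in modules:
        if mod.eigengene is None:
            raise ValueError(f"module {mod.module_id} lacks an eigengene")
        aligned = trait.reindex(mod.eigengene.index)
        if aligned.isna().any():
            raise ValueError("trait vector does not cover all samples")
        r, p = stats.pearsonr(mod.eigengene.values, aligned.values.astype(float))
        mod.trait_correlation, mod.trait_p = float(r), float(p)
        rows.append((mod.module_id, len(mod.members), float(r), float(p)))
    return pd.DataFrame(rows, columns=["module_id", "size", "trait_r", "trait_p"])


def build_modules(
    fpkm: pd.DataFrame,
    trait: pd.Series | None = None,
    params: CoexprParams | None = None,
    power: int | None = None,
) -> tuple[list[Module], pd.DataFrame, pd.DataFrame | None]:
    """Full co-expression pass: transform, threshold, TOM, modules, trait.

    Returns (modules incl. eigengenes, soft-threshold table or empty if a
    power was supplied, module-trait table or None without a trait).
    """
    params = params or CoexprParams()
    expr = log_transform(fpkm)
    expr = expr.loc[expr.var(axis=1) > 0]
    expr = select_top_variance(expr, params.top_n_features)
    if power is None:
        power, sft = pick_soft_threshold(expr, params)
    else:
        sft = pd.DataFrame(columns=["power", "signed_r2", "mean_connectivity"])
    adj = adjacency(expr, power)
    tom = topological_overlap(adj)
    assignment = cluster_modules(tom, list(expr.index), params)
    modules: list[Module] = []
    for module_id in sorted(
        {m for m in assignment.values() if m != UNASSIGNED},
        key=lambda m: int(m[1:]),
    ):
        members = sorted(fid for fid, m in assignment.items() if m == module_id)
        eig, ve = eigengene(expr, members)
        modules.append(
            Module(module_id, members, eigengene=eig, variance_explained=ve)
        )
    unassigned = sorted(fid for fid, m in assignment.items() if m == UNASSIGNED)
    if unassigned:
        modules.append(Module(UNASSIGNED, unassigned))
    trait_table = None
    if trait is not None:
        assigned = [m for m in modules if m.module_id != UNASSIGNED]
        trait_table = module_trait_correlation(assigned, trait)
    return modules, sft, trait_table
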