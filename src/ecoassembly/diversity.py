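"""Rarefaction, alpha diversity, Bray-Curtis beta diversity and distance-decay.

Alpha indices follow the classic estimators used throughout the amplicon
literature: Shannon entropy in nats, Gini-Simpson (1 - sum p_i^2), Pielou
evenness H/ln(S), classic Chao1 (S + F1^2 / 2 F2, with the F2 = 0 fallback
S + F1 (F1 - 1) / 2), ACE with the standard rare/abundant cutoff of 10, and
Faith's phylogenetic diversity including the path to the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import ace as _skbio_ace

from ecoassembly.containers import CommunityTable, SampleMetadata

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int | None = None, seed=None) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    A single multivariate-hypergeometric draw per sample (one rarefaction, not
    an average). ``depth`` defaults to the minimum sample total.
    """
    totals = table.sample_totals
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    too_small = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if too_small:
        raise ValueError(
            f"rarefaction depth {depth} exceeds totals of samples: {too_small}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return CommunityTable(out, table.taxon_ids, table.sample_ids)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _chao1(counts: np.ndarray) -> float:
    s = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    return s + f1 * (f1 - 1) / 2.0


def faith_pd(tree: TreeNode, taxa, include_root: bool = True) -> float:
    """Total branch length of the subtree spanning ``taxa`` (and the root).

    With ``include_root`` (default), the paths from the observed tips up to the
    tree root are included, the convention of picante's ``pd``; with
    ``include_root=False`` only branches below the most recent common ancestor
    of the observed taxa count, so a single-taxon sample has PD 0.
    """
    taxa = [t for t in taxa]
    if not taxa:
        return 0.0
    tip_index = {t.name: t for t in tree.tips()}
    missing = [t for t in taxa if t not in tip_index]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    edges = set()  # nodes whose branch (to parent) is on some tip->root path
    for name in taxa:
        node = tip_index[name]
        while node.parent is not None and node not in edges:
            edges.add(node)
            node = node.parent
    total = sum(n.length or 0.0 for n in edges)
    if include_root:
        total += tree.length or 0.0
    else:
        # peel the shared stem: edges above the MRCA lie on every path
        node = tree.lca([tip_index[t] for t in taxa]) if len(taxa) > 1 else tip_index[taxa[0]]
        while node.parent is not None:
            total -= node.length or 0.0
            node = node.parent
    return float(total)


def alpha_diversity(table: CommunityTable, tree: TreeNode = None,
                    include_root: bool = True) -> pd.DataFrame:
    """Per-sample alpha-diversity indices.

    Returns a DataFrame indexed by sample with columns richness, shannon
    (nats), simpson (Gini-Simpson), pielou, chao1, ace, and faith_pd when a
    tree is supplied. A sample of a single taxon has undefined evenness
    (reported as NaN).
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("empty sample")
    p = table.relative_abundance()
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=0)
    simpson = 1.0 - (p ** 2).sum(axis=0)
    richness = (counts > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(richness > 1, shannon / np.log(richness), np.nan)
    rows = {
        "richness": richness.astype(float),
        "shannon": shannon,
        "simpson": simpson,
        "pielou": pielou,
        "chao1": np.array([_chao1(counts[:, j]) for j in range(table.n_samples)]),
        "ace": np.array([_ace(counts[:, j]) for j in range(table.n_samples)]),
    }
    if tree is not None:
        taxa = np.asarray(table.taxon_ids)
        rows["faith_pd"] = np.array(
            [
                faith_pd(tree, taxa[counts[:, j] > 0], include_root=include_root)
                for j in range(table.n_samples)
            ]
        )
    return pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample_id"))


def _ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    present = counts[counts > 0]
    try:
        return float(_skbio_ace(present, rare_threshold=rare_threshold))
    except (ValueError, ZeroDivisionError, FloatingPointError):
        return float("nan")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples, on counts as given.

    Scale-invariance across samples only holds at equal depth, so the usual
    input is the rarefied table.
    """
    if table.n_samples < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    totals = table.sample_totals
    if (totals == 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero samples")
    cond = pdist(table.counts.T.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(cond, checks=False), ids=table.sample_ids)


# ---------------------------------------------------------------------------
# geographic distance and distance-decay
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geographic_distance(meta: SampleMetadata, sample_ids=None) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between sample coordinates."""
    coords = meta.coordinates(sample_ids)
    lat = coords["latitude"].to_numpy()
    lon = coords["longitude"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(coords.index))


@dataclass
class DistanceDecayResult:
    """Spearman distance-decay of community similarity with geographic distance."""

    spearman_rho: float
    p_value: float
    ols_slope: float
    ols_intercept: float
    ols_r2: float
    n_pairs: int
    n_permutations: int

    def __str__(self) -> str:
        return (
            f"distance-decay: Spearman rho = {self.spearman_rho:.3f} "
            f"(p = {self.p_value:.4g}, {self.n_permutations} permutations), "
            f"turnover slope = {self.ols_slope:.3g} per km (R^2 = {self.ols_r2:.3f})"
        )


def distance_decay(community: DistanceMatrix, meta: SampleMetadata,
                   n_perm: int = 9999, seed=None) -> DistanceDecayResult:
    """Decay of community similarity (1 - Bray-Curtis) with geographic distance.

    Spearman rho over sample pairs with a Mantel-style permutation p-value
    (rows and columns permuted jointly, two-sided); the OLS slope of similarity
    on distance is the spatial turnover rate per km.
    """
    from ecoassembly.matrix_stats import mantel

    if len(community.ids) < 3:
        raise ValueError("distance-decay needs at least 3 samples")
    geo = geographic_distance(meta, community.ids)
    if np.allclose(geo.data, 0.0):
        raise ValueError("all samples co-located: distance-decay undefined")
    res = mantel(community, geo, method="spearman", n_perm=n_perm,
                 alternative="two-sided", seed=seed)
    sim = 1.0 - community.condensed_form()
    dist = geo.condensed_form()
    slope, intercept = np.polyfit(dist, sim, 1)
    fitted = slope * dist + intercept
    ss_res = float(((sim - fitted) ** 2).sum())
    ss_tot = float(((sim - sim.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    # similarity = 1 - dissimilarity, so the rank correlation flips sign exactly
    return DistanceDecayResult(
        spearman_rho=-res.statistic,
        p_value=res.p_value,
        ols_slope=float(slope),
        ols_intercept=float(intercept),
        ols_r2=r2,
        n_pairs=len(sim),
        n_permutations=n_perm,
    )
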