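"""Distance-matrix hypothesis tests: PERMANOVA, SIMPER, Mantel, partial Mantel, MRM.

All permutation tests permute whole samples — a joint permutation of rows and
columns of one matrix — never individual triangle elements, which is what
exchangeability on distance matrices requires. p-values use the add-one rule
p = (1 + #{null at least as extreme}) / (n_perm + 1), so p >= 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from skbio import DistanceMatrix

from ecoassembly.containers import CommunityTable, SampleMetadata


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    statistic_name: str
    alternative: str = "greater"

    def __str__(self) -> str:
        return (
            f"{self.statistic_name} = {self.statistic:.4f}, "
            f"p = {self.p_value:.4g} ({self.n_permutations} permutations, "
            f"{self.alternative})"
        )


# ---------------------------------------------------------------------------
# shared permutation machinery
# ---------------------------------------------------------------------------

def _align(*dms: DistanceMatrix) -> list[DistanceMatrix]:
    ref = list(dms[0].ids)
    out = [dms[0]]
    for dm in dms[1:]:
        if set(dm.ids) != set(ref):
            raise ValueError("distance matrices have mismatched labels")
        out.append(dm.filter(ref))
    return out

def _condensed_index(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    lut = np.zeros((n, n), dtype=np.int64)
    lut[iu, ju] = lut[ju, iu] = np.arange(len(iu))
    return iu, ju, lut

def _perm_condensed_indices(n: int, n_perm: int, rng) -> np.ndarray:
    """Condensed-vector index array for n_perm joint row/column permutations."""
    iu, ju, lut = _condensed_index(n)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    return lut[perms[:, iu], perms[:, ju]]

def _pvalue(obs: float, null: np.ndarray, alternative: str) -> float:
    if alternative == "greater":
        extreme = np.sum(null >= obs)
    elif alternative == "less":
        extreme = np.sum(null <= obs)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(null) >= abs(obs))
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return float((1 + extreme) / (len(null) + 1))

def _corr_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with ``y``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (yc ** 2).sum())
    return (rc @ yc) / denom


# ---------------------------------------------------------------------------
# Mantel and partial Mantel
# ---------------------------------------------------------------------------

def mantel(dx: DistanceMatrix, dy: DistanceMatrix, method: str = "spearman",
           n_perm: int = 9999, alternative: str = "greater",
           seed=None) -> PermutationTestResult:
    """Mantel test between two distance matrices.

    The statistic is the (Spearman by default) correlation of the
    off-diagonal upper-triangle vectors; the null jointly permutes the rows
    and columns of ``dx``. One-sided 'greater' by default, the ecological
    convention for association between dissimilarity matrices.
    """
    dx, dy = _align(dx, dy)
    x = dx.condensed_form()
    y = dy.condensed_form()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Mantel statistic undefined for a constant matrix")
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")
    obs = float(_corr_rows(x[np.newaxis, :], y)[0])
    rng = np.random.default_rng(seed)
    idx = _perm_condensed_indices(len(dx.ids), n_perm, rng)
    # ranks commute with a joint permutation: the multiset is unchanged
    null = _corr_rows(x[idx], y)
    name = f"mantel_r ({method})"
    return PermutationTestResult(obs, _pvalue(obs, null, alternative), n_perm, name, alternative)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(z, v, rcond=None)
    return v - z @ beta


def partial_mantel(dx: DistanceMatrix, dy: DistanceMatrix, controls,
                   method: str = "spearman", n_perm: int = 9999,
                   alternative: str = "greater", seed=None) -> PermutationTestResult:
    """Partial Mantel: correlation of dx and dy given control matrices.

    Vectors are rank-transformed (Spearman), each is residualized on the
    ranked control vectors by least squares, and the statistic is the Pearson
    correlation of the residuals. The permutation scheme permutes dx's rows
    and columns jointly and recomputes the residuals each time. With no
    controls this reduces exactly to :func:`mantel`.
    """
    controls = list(controls)
    if not controls:
        return mantel(dx, dy, method=method, n_perm=n_perm,
                      alternative=alternative, seed=seed)
    dms = _align(dx, dy, *controls)
    dx, dy, controls = dms[0], dms[1], dms[2:]
    vecs = [dm.condensed_form() for dm in (dx, dy, *controls)]
    if any(v.std() == 0 for v in vecs[:2]):
        raise ValueError("partial Mantel undefined for a constant matrix")
    if method == "spearman":
        vecs = [rankdata(v) for v in vecs]
    x, y, *zs = vecs
    z = np.column_stack([np.ones_like(x)] + zs)
    if np.linalg.matrix_rank(z) < z.shape[1]:
        bad = []
        for i in range(len(zs)):
            if np.linalg.matrix_rank(z[:, : 2 + i]) < 2 + i:
                bad.append(i)
        raise ValueError(f"collinear control matrices at positions: {bad}")
    ey = _residualize(y, z)
    name = f"partial_mantel_r ({method}, {len(zs)} controls)"
    if np.linalg.norm(ey) <= 1e-10 * np.linalg.norm(y - y.mean()):
        # controls explain dy completely: nothing left to correlate
        return PermutationTestResult(0.0, 1.0, n_perm, name, alternative)
    hat = z @ np.linalg.pinv(z)          # projection onto the control space
    resid_proj = np.eye(len(x)) - hat
    obs = float(_corr_rows((resid_proj @ x)[np.newaxis, :], ey)[0])
    rng = np.random.default_rng(seed)
    idx = _perm_condensed_indices(len(dx.ids), n_perm, rng)
    null = _corr_rows(x[idx] @ resid_proj.T, ey)
    return PermutationTestResult(obs, _pvalue(obs, null, alternative), n_perm, name, alternative)


# ---------------------------------------------------------------------------
# MRM
# ---------------------------------------------------------------------------

@dataclass
class MrmResult:
    """Multiple regression on distance matrices.

    coefficients include the intercept; p_per_coefficient is two-sided on the
    permutation distribution of each coefficient under joint row/column
    permutation of the response matrix; p_model is one-sided on R^2.
    """

    coefficients: pd.Series
    r2: float
    p_model: float
    p_per_coefficient: pd.Series
    n_permutations: int

    def __str__(self) -> str:
        rows = [f"MRM: R^2 = {self.r2:.4f}, p_model = {self.p_model:.4g} "
                f"({self.n_permutations} permutations)"]
        for name in self.coefficients.index:
            p = self.p_per_coefficient.get(name, float("nan"))
            rows.append(f"  {name:<20s} b = {self.coefficients[name]: .5g}   p = {p:.4g}")
        return "\n".join(rows)


def _as_named_matrices(dx) -> dict:
    if isinstance(dx, dict):
        return dict(dx)
    return {f"x{i + 1}": dm for i, dm in enumerate(dx)}


def mrm(dy: DistanceMatrix, dx, n_perm: int = 999, seed=None) -> MrmResult:
    """OLS of dy's triangle vector on explanatory triangle vectors + intercept.

    ``dx`` is a list of DistanceMatrix or a name -> DistanceMatrix mapping.
    Inference permutes the response matrix's rows/columns jointly and refits.
    """
    named = _as_named_matrices(dx)
    if not named:
        raise ValueError("MRM needs at least one explanatory matrix")
    dms = _align(dy, *named.values())
    dy, xs = dms[0], dms[1:]
    y = dy.condensed_form()
    x_mat = np.column_stack([np.ones_like(y)] + [dm.condensed_form() for dm in xs])
    names = ["intercept"] + list(named.keys())
    if np.linalg.matrix_rank(x_mat) < x_mat.shape[1]:
        raise ValueError("rank-deficient MRM design (collinear explanatory matrices)")
    pinv = np.linalg.pinv(x_mat)
    beta = pinv @ y
    fitted = x_mat @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    rng = np.random.default_rng(seed)
    idx = _perm_condensed_indices(len(dy.ids), n_perm, rng)
    y_perm = y[idx]                              # (n_perm, n_pairs)
    b_null = y_perm @ pinv.T                     # (n_perm, k+1)
    fitted_null = b_null @ x_mat.T
    ss_res_null = ((y_perm - fitted_null) ** 2).sum(axis=1)
    r2_null = 1.0 - ss_res_null / ss_tot
    p_model = _pvalue(r2, r2_null, "greater")
    p_coef = {"intercept": float("nan")}
    for i, name in enumerate(names[1:], start=1):
        p_coef[name] = _pvalue(beta[i], b_null[:, i], "two-sided")
    return MrmResult(
        coefficients=pd.Series(beta, index=names),
        r2=r2,
        p_model=p_model,
        p_per_coefficient=pd.Series(p_coef),
        n_permutations=n_perm,
    )


@dataclass
class StepwiseMrmResult:
    """Final MRM after stepwise removal, with the removal order."""

    final: MrmResult | None
    removed: list = field(default_factory=list)  # (name, p at removal)

    @property
    def empty(self) -> bool:
        return self.final is None


def mrm_stepwise(dy: DistanceMatrix, dx_named: dict, alpha: float = 0.05,
                 n_perm: int = 999, seed=None) -> StepwiseMrmResult:
    """Backward elimination for MRM: drop the least significant matrix until
    all remaining coefficient p-values are <= alpha.

    One variable is removed per iteration (largest p first; ties broken by
    input order). An empty final model is allowed and flagged via ``empty``.
    """
    remaining = dict(_as_named_matrices(dx_named))
    removed = []
    while remaining:
        res = mrm(dy, remaining, n_perm=n_perm, seed=seed)
        pvals = res.p_per_coefficient.drop("intercept")
        worst = None
        worst_p = -1.0
        for name in remaining:  # input order is the deterministic tie-break
            p = float(pvals[name])
            if p > alpha and p > worst_p:
                worst, worst_p = name, p
        if worst is None:
            return StepwiseMrmResult(final=res, removed=removed)
        removed.append((worst, worst_p))
        del remaining[worst]
    return StepwiseMrmResult(final=None, removed=removed)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult(PermutationTestResult):
    r2: float = float("nan")
    df_between: int = 0
    df_within: int = 0

    def __str__(self) -> str:
        return (
            f"PERMANOVA pseudo-F = {self.statistic:.4f} "
            f"(df {self.df_between}, {self.df_within}), R^2 = {self.r2:.4f}, "
            f"p = {self.p_value:.4g} ({self.n_permutations} permutations)"
        )


def permanova(d: DistanceMatrix, groups, n_perm: int = 9999, seed=None) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with label-permutation inference.

    SS_total = sum of squared distances / N; SS_within sums each group's
    squared within-group distances divided by its size; the pseudo-F compares
    between- and within-group mean squares. A zero within-group SS yields an
    infinite F with the p-value still taken from the permutations.
    """
    if isinstance(groups, dict):
        labels = [groups[s] for s in d.ids]
    else:
        ser = pd.Series(groups)
        labels = list(ser.loc[list(d.ids)]) if set(d.ids) <= set(ser.index) else list(ser)
    codes, uniques = pd.factorize(np.asarray(labels, dtype=object))
    a = len(uniques)
    n = len(codes)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if a >= n:
        raise ValueError("PERMANOVA needs more samples than groups")
    sizes = np.bincount(codes).astype(float)
    iu, ju, _ = _condensed_index(n)
    d2 = d.condensed_form() ** 2
    ss_total = d2.sum() / n

    def f_stat(c: np.ndarray) -> tuple[float, float]:
        same = c[:, iu] == c[:, ju]
        ss_within = np.where(same, d2[np.newaxis, :] / sizes[c[:, iu]], 0.0).sum(axis=1)
        ss_between = ss_total - ss_within
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_between / (a - 1)) / (ss_within / (n - a))
        return f, ss_within

    f_obs_arr, ssw = f_stat(codes[np.newaxis, :])
    f_obs = float(f_obs_arr[0])
    r2 = float((ss_total - ssw[0]) / ss_total) if ss_total > 0 else float("nan")
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    f_null, _ = f_stat(codes[perms])
    p = _pvalue(f_obs, f_null, "greater")
    return PermanovaResult(
        statistic=f_obs, p_value=p, n_permutations=n_perm,
        statistic_name="pseudo-F", alternative="greater",
        r2=r2, df_between=a - 1, df_within=n - a,
    )


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def simper(table: CommunityTable, groups) -> pd.DataFrame:
    """Similarity-percentage decomposition of between-group Bray-Curtis.

    For every between-group sample pair the per-taxon contribution is
    |x_ij - x_ik| / sum_i (x_ij + x_ik); contributions are averaged over all
    between-group pairs, so they sum exactly to the mean between-group
    Bray-Curtis dissimilarity (stored in ``result.attrs``). The returned table
    is sorted by contribution (percent of the between-group dissimilarity)
    with group mean relative abundances in percent, Table-style.
    """
    if isinstance(groups, dict):
        labels = np.asarray([groups[s] for s in table.sample_ids], dtype=object)
    else:
        ser = pd.Series(groups)
        labels = ser.loc[table.sample_ids].to_numpy(dtype=object)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"SIMPER needs exactly 2 groups, got {list(uniq)}")
    g1_idx = np.flatnonzero(labels == uniq[0])
    g2_idx = np.flatnonzero(labels == uniq[1])
    if len(g1_idx) == 0 or len(g2_idx) == 0:
        raise ValueError("SIMPER group is empty")
    x = table.counts.astype(float)
    contrib = np.zeros(table.n_taxa)
    n_pairs = 0
    for j in g1_idx:
        diff = np.abs(x[:, [j]] - x[:, g2_idx])            # taxa x |g2|
        denom = (x[:, [j]] + x[:, g2_idx]).sum(axis=0)     # |g2|
        contrib += (diff / denom[np.newaxis, :]).sum(axis=1)
        n_pairs += len(g2_idx)
    contrib /= n_pairs
    mean_bc = float(contrib.sum())
    rel = table.relative_abundance() * 100.0
    order = np.argsort(-contrib, kind="stable")
    pct = contrib / mean_bc * 100.0 if mean_bc > 0 else np.full_like(contrib, np.nan)
    out = pd.DataFrame(
        {
            "taxon_id": np.asarray(table.taxon_ids, dtype=object)[order],
            f"mean_abund_{uniq[0]}": rel[:, g1_idx].mean(axis=1)[order],
            f"mean_abund_{uniq[1]}": rel[:, g2_idx].mean(axis=1)[order],
            "contribution": pct[order],
            "cumulative": np.cumsum(pct[order]),
        }
    ).reset_index(drop=True)
    out.attrs["mean_between_group_dissimilarity"] = mean_bc
    out.attrs["groups"] = (uniq[0], uniq[1])
    return out


# ---------------------------------------------------------------------------
# environmental distance
# ---------------------------------------------------------------------------

def environmental_distance(meta: SampleMetadata, columns=None, sample_ids=None,
                           standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance between samples on (z-scored) environmental covariates."""
    env = meta.env(columns, sample_ids)
    vals = env.to_numpy(dtype=float)
    if standardize:
        sd = vals.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [c for c, s in zip(env.columns, sd) if s == 0]
            raise ValueError(f"constant environmental covariates: {bad}")
        vals = (vals - vals.mean(axis=0)) / sd
    from scipy.spatial.distance import squareform

    return DistanceMatrix(squareform(pdist(vals), checks=False), ids=list(env.index))
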