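"""Null-model partitioning of community assembly processes.

The core computation: phylogenetic turnover (beta mean nearest taxon distance,
betaMNTD) is compared against a null distribution obtained by shuffling taxa
across the tips of the phylogeny, giving the beta nearest taxon index (betaNTI)
as a z-score. Pairs not dominated by selection (|betaNTI| <= 2) are further
partitioned with the Bray-Curtis-based Raup-Crick index (RC_bray), whose null
assembles random communities that preserve each sample's richness and read
total while drawing taxa by occurrence frequency and reads by metacommunity
relative abundance.

Classification of a sample pair:

* betaNTI > 2            -> heterogeneous selection
* betaNTI < -2           -> homogeneous selection
* else RC_bray > 0.95    -> dispersal limitation
* else RC_bray < -0.95   -> homogenizing dispersal
* otherwise              -> undominated (drift and weak/mixed processes)

Threshold comparisons are strict: values exactly at a threshold fall to the
less extreme category. Pairs whose betaNTI null distribution has zero spread
are reported as ``undefined`` and excluded from process fractions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from ecoassembly.containers import CommunityTable, SampleMetadata

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

_BNTI_THRESHOLD = 2.0
_RC_THRESHOLD = 0.95
_TIE_EPS = 1e-12


@dataclass
class NullModelConfig:
    """Settings shared by the betaNTI and RC_bray null models.

    n_null : int
        Null iterations per model (999 by default, the field standard).
    seed : int or None
        Root seed. Every pair's RC_bray null consumes an independent stream
        derived from (seed, pair index), so results do not depend on the
        order pairs are visited.
    abundance_weighted : bool
        Weight betaMNTD by relative abundance (True) or by presence (False).
    rc_rescale : bool
        Rescale the Raup-Crick index from [0, 1] to [-1, 1].
    """

    n_null: int = 999
    seed: int | None = None
    abundance_weighted: bool = True
    rc_rescale: bool = True

    def __post_init__(self):
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")


def _stream(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# patristic distances and betaMNTD
# ---------------------------------------------------------------------------

def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Sum of branch lengths along the path between every pair of tips."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                f"missing branch length above {node.name or 'internal node'}"
            )
    return tree.tip_tip_distances()


def _aligned_taxon_distances(taxon_distances, table: CommunityTable) -> np.ndarray:
    if isinstance(taxon_distances, TreeNode):
        taxon_distances = patristic_distances(taxon_distances)
    missing = set(table.taxon_ids) - set(taxon_distances.ids)
    if missing:
        raise ValueError(f"taxa not in tree/distance matrix: {sorted(missing)}")
    # extra tips are pruned here; table taxa missing above are a hard error
    return taxon_distances.filter(table.taxon_ids).data


def _weights(table: CommunityTable, abundance_weighted: bool) -> tuple[np.ndarray, np.ndarray]:
    presence = table.counts > 0
    if abundance_weighted:
        w = table.relative_abundance()
    else:
        w = presence / presence.sum(axis=0)[np.newaxis, :]
    return w, presence


def _beta_mntd_matrix(d: np.ndarray, weights: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given a taxon distance matrix.

    d is taxa x taxa, weights/presence are taxa x samples. For each sample k,
    dmin[i, k] is the distance from taxon i to its nearest taxon present in k
    (zero if i itself is present: conspecifics count).
    """
    n_taxa, n_samples = weights.shape
    dmin = np.empty((n_taxa, n_samples))
    for k in range(n_samples):
        dmin[:, k] = d[:, presence[:, k]].min(axis=1)
    half = weights.T @ dmin  # half[j, k] = sum_i w[i, j] * dmin[i, k]
    out = 0.5 * (half + half.T)
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(table: CommunityTable, taxon_distances,
              abundance_weighted: bool = True) -> DistanceMatrix:
    """Observed beta mean nearest taxon distance between all sample pairs.

    betaMNTD(j, k) averages, over the taxa of each community (weighted by
    relative abundance unless ``abundance_weighted=False``), the phylogenetic
    distance to the nearest taxon of the other community.

    ``taxon_distances`` may be a tree (patristic distances are computed and
    extra tips pruned) or a precomputed taxon DistanceMatrix.
    """
    d = _aligned_taxon_distances(taxon_distances, table)
    w, presence = _weights(table, abundance_weighted)
    mat = _beta_mntd_matrix(d, w, presence)
    mat = np.maximum(mat, 0.0)
    mat = (mat + mat.T) / 2.0
    return DistanceMatrix(mat, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------

@dataclass
class BntiResult:
    """betaNTI z-scores plus the observed betaMNTD and null moments."""

    bnti: pd.DataFrame            # NaN where the null spread is zero (undefined)
    beta_mntd_obs: DistanceMatrix
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    n_null: int


def bnti(table: CommunityTable, taxon_distances, config: NullModelConfig | None = None) -> BntiResult:
    """Beta nearest taxon index for every sample pair.

    The null model shuffles taxon labels across all tips of the (pruned)
    phylogeny — a joint random permutation of the rows and columns of the
    patristic distance matrix — and recomputes betaMNTD each iteration.
    betaNTI(j, k) = (obs - mean(null)) / sd(null). Pairs with a null standard
    deviation of zero (e.g. identical samples, or a star phylogeny whose
    shuffles change nothing) are undefined and returned as NaN, never as
    +/-inf or silently 0.
    """
    config = config or NullModelConfig()
    if config.n_null < 2:
        raise ValueError("betaNTI needs n_null >= 2 to estimate the null spread")
    d = _aligned_taxon_distances(taxon_distances, table)
    w, presence = _weights(table, config.abundance_weighted)
    obs = _beta_mntd_matrix(d, w, presence)

    rng = _stream(config.seed, 2)
    n = table.n_samples
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    n_taxa = table.n_taxa
    for _ in range(config.n_null):
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_matrix(d[np.ix_(perm, perm)], w, presence)
        acc += null
        acc2 += null ** 2
    mean = acc / config.n_null
    var = (acc2 - config.n_null * mean ** 2) / (config.n_null - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > _TIE_EPS, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    np.fill_diagonal(z, np.nan)
    ids = table.sample_ids
    return BntiResult(
        bnti=pd.DataFrame(z, index=ids, columns=ids),
        beta_mntd_obs=DistanceMatrix(np.maximum((obs + obs.T) / 2, 0.0), ids=ids),
        null_mean=pd.DataFrame(mean, index=ids, columns=ids),
        null_sd=pd.DataFrame(sd, index=ids, columns=ids),
        n_null=config.n_null,
    )


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def _bray_curtis_vec(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).sum() / (a + b).sum())


def _null_sample(rng: np.random.Generator, log_occ: np.ndarray, meta_p: np.ndarray,
                 richness: int, total: int) -> np.ndarray:
    """One null community: richness taxa by occurrence frequency, reads by
    metacommunity abundance (each drawn taxon seeded with one read).

    Weighted sampling without replacement uses Gumbel-top-k keys, which draws
    exactly the successive-sampling distribution with probabilities
    proportional to occurrence frequency.
    """
    keys = log_occ + rng.gumbel(size=log_occ.size)
    drawn = np.sort(np.argpartition(keys, -richness)[-richness:])
    p = meta_p[drawn]
    counts = np.zeros(log_occ.size)
    counts[drawn] = 1.0 + rng.multinomial(total - richness, p / p.sum())
    return counts


def raup_crick_bray(table: CommunityTable, config: NullModelConfig | None = None) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick index for every sample pair.

    For each pair and null iteration both communities are reassembled
    independently from the metacommunity (all samples in the table): the
    observed richness is drawn without replacement with probability
    proportional to occurrence frequency, then the observed read total is
    allocated by a multinomial proportional to metacommunity relative
    abundance after giving each drawn taxon one read. The index is the
    position of the observed Bray-Curtis within the null distribution (ties
    weighted 1/2), rescaled to [-1, 1] when ``config.rc_rescale``.

    Each pair consumes an RNG stream derived from (seed, pair index), so the
    result is independent of iteration order and parallelization.
    """
    config = config or NullModelConfig()
    counts = table.counts
    pool = counts.sum(axis=1) > 0
    occ = (counts > 0).sum(axis=1)[pool].astype(float)
    meta_p = counts.sum(axis=1)[pool].astype(float)
    meta_p /= meta_p.sum()
    log_occ = np.log(occ)
    sub = counts[pool].astype(float)

    n = table.n_samples
    richness = (sub > 0).sum(axis=0)
    totals = sub.sum(axis=0).astype(int)
    assert (richness <= pool.sum()).all()

    rc = np.zeros((n, n))
    for pair_index, (j, k) in enumerate(itertools.combinations(range(n), 2)):
        obs = _bray_curtis_vec(sub[:, j], sub[:, k])
        rng = _stream(config.seed, 1, pair_index)
        n_less = 0
        n_tie = 0
        for _ in range(config.n_null):
            nj = _null_sample(rng, log_occ, meta_p, int(richness[j]), int(totals[j]))
            nk = _null_sample(rng, log_occ, meta_p, int(richness[k]), int(totals[k]))
            null = _bray_curtis_vec(nj, nk)
            if abs(null - obs) <= _TIE_EPS:
                n_tie += 1
            elif null < obs:
                n_less += 1
        raw = (n_less + 0.5 * n_tie) / config.n_null
        val = 2.0 * (raw - 0.5) if config.rc_rescale else raw
        rc[j, k] = rc[k, j] = val
    ids = table.sample_ids
    return pd.DataFrame(rc, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# classification and partitioning
# ---------------------------------------------------------------------------

def classify_pair(bnti_value: float, rc_value: float) -> str:
    """Assign the assembly process for one sample pair (strict thresholds)."""
    if bnti_value is None or np.isnan(bnti_value):
        return "undefined"
    if bnti_value > _BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti_value < -_BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value is None or np.isnan(rc_value):
        return "undefined"
    if rc_value > _RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -_RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def partition_fractions(pairs: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-group fractions of each assembly process among within-group pairs.

    ``pairs`` needs columns sample_i, sample_j, process. ``groups`` maps
    sample -> group label. Undefined pairs are excluded from the fractions
    (which sum to 1 over classified pairs) and counted in ``n_undefined``.
    """
    groups = dict(groups) if not isinstance(groups, dict) else groups
    labels = sorted(set(groups.values()))
    counts = {g: list(groups.values()).count(g) for g in labels}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    rows = []
    for g in labels:
        sel = pairs[
            (pairs["sample_i"].map(groups) == g) & (pairs["sample_j"].map(groups) == g)
        ]
        classified = sel[sel["process"] != "undefined"]
        row = {"group": g, "n_pairs": len(classified), "n_undefined": int((sel["process"] == "undefined").sum())}
        for proc in PROCESSES:
            row[proc] = (
                float((classified["process"] == proc).sum() / len(classified))
                if len(classified)
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class AssemblyModel:
    """Community-assembly null-model analysis of a table + phylogeny (+ metadata).

    Parameters
    ----------
    table : CommunityTable
        Taxa x samples read counts.
    tree : skbio.TreeNode
        Rooted phylogeny whose tips cover the table's taxa (extra tips are
        pruned).
    metadata : SampleMetadata, optional
        Needs a ``group`` column (or ``group_col``) for per-group process
        fractions; without metadata only per-pair results are produced.
    config : NullModelConfig, optional
    rarefy_to : int, "auto" or None
        Depth to rarefy to before analysis; "auto" (default) uses the minimum
        sample total, None skips rarefaction.

    Examples
    --------
    >>> model = AssemblyModel(table, tree, metadata,
    ...                       config=NullModelConfig(n_null=999, seed=1))
    >>> res = model.fit()
    >>> res.fractions        # per-group process fractions (Fig-4-style)
    >>> print(res.summary())
    """

    def __init__(self, table: CommunityTable, tree, metadata: SampleMetadata = None,
                 group_col: str = "group", config: NullModelConfig | None = None,
                 rarefy_to="auto"):
        if table.n_samples < 2:
            raise ValueError("assembly analysis needs at least 2 samples")
        self.table = table
        self.tree = tree
        self.metadata = metadata
        self.group_col = group_col
        self.config = config or NullModelConfig()
        self.rarefy_to = rarefy_to

    @classmethod
    def from_files(cls, table_path, tree_path, metadata_path=None, **kwargs) -> "AssemblyModel":
        from ecoassembly import io as _io

        table = _io.read_community_table(table_path)
        tree = _io.read_tree(tree_path)
        meta = _io.read_metadata(metadata_path) if metadata_path else None
        return cls(table, tree, meta, **kwargs)

    def fit(self) -> "AssemblyResults":
        from ecoassembly.diversity import rarefy
        from ecoassembly.io import validate_dataset

        config = self.config
        if config.seed is None:
            # draw an explicit root seed so the run is reportable/replayable
            config = replace(config, seed=int(np.random.SeedSequence().generate_state(1)[0] // 2))
        report = validate_dataset(self.table, self.tree, self.metadata)
        if not report.ok:
            raise ValueError(f"dataset failed validation:\n{report}")

        table = self.table
        if self.rarefy_to is not None:
            depth = None if self.rarefy_to == "auto" else int(self.rarefy_to)
            table = rarefy(table, depth, seed=np.random.SeedSequence(config.seed, spawn_key=(3,)))
            table = table.drop_absent_taxa()

        bres = bnti(table, self.tree, config)
        rc = raup_crick_bray(table, config)

        ids = table.sample_ids
        rows = []
        for j, k in itertools.combinations(range(len(ids)), 2):
            b = float(bres.bnti.iat[j, k])
            r = float(rc.iat[j, k])
            rows.append(
                {
                    "sample_i": ids[j],
                    "sample_j": ids[k],
                    "beta_mntd_obs": float(bres.beta_mntd_obs[j, k]),
                    "bnti": b,
                    "rc_bray": r,
                    "process": classify_pair(b, r),
                }
            )
        pairs = pd.DataFrame(rows)

        fractions = None
        if self.metadata is not None and self.group_col in self.metadata.frame.columns:
            groups = self.metadata.frame[self.group_col].astype(str).to_dict()
            groups = {s: groups[s] for s in ids}
            fractions = partition_fractions(pairs, groups)
        return AssemblyResults(
            model=self,
            config=config,
            pairs=pairs,
            bnti_matrix=bres.bnti,
            rc_matrix=rc,
            beta_mntd=bres.beta_mntd_obs,
            fractions=fractions,
            rarefied_table=table,
        )


@dataclass
class AssemblyResults:
    """Fitted assembly null models: per-pair indices, classes and fractions."""

    model: AssemblyModel
    config: NullModelConfig
    pairs: pd.DataFrame
    bnti_matrix: pd.DataFrame
    rc_matrix: pd.DataFrame
    beta_mntd: DistanceMatrix
    fractions: pd.DataFrame | None
    rarefied_table: CommunityTable = field(repr=False, default=None)

    @property
    def process_counts(self) -> pd.Series:
        return self.pairs["process"].value_counts()

    def summary(self) -> str:
        lines = []
        bar = "=" * 64
        lines.append(bar)
        lines.append("Community assembly null models".center(64))
        lines.append(bar)
        t = self.rarefied_table or self.model.table
        lines.append(f"samples: {t.n_samples}    taxa: {t.n_taxa}    pairs: {len(self.pairs)}")
        lines.append(
            f"n_null: {self.config.n_null}    seed: {self.config.seed}    "
            f"abundance weighted: {self.config.abundance_weighted}"
        )
        lines.append("-" * 64)
        lines.append("pairs per process (all pairs):")
        for proc, cnt in self.process_counts.items():
            lines.append(f"  {proc:<26s} {cnt:5d}  ({cnt / len(self.pairs):6.1%})")
        if self.fractions is not None:
            lines.append("-" * 64)
            lines.append("within-group process fractions:")
            for g, row in self.fractions.iterrows():
                lines.append(f"  group {g} (n_pairs={int(row['n_pairs'])}, "
                             f"undefined={int(row['n_undefined'])}):")
                for proc in PROCESSES:
                    lines.append(f"    {proc:<26s} {row[proc]:6.1%}")
        lines.append(bar)
        return "\n".join(lines)

    def to_files(self, out_dir) -> None:
        """Write pairs.tsv, fractions.tsv and fractions.json under out_dir."""
        import json
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
        if self.fractions is not None:
            self.fractions.to_csv(out / "fractions.tsv", sep="\t")
            payload = {
                g: {k: (None if pd.isna(v) else v) for k, v in row.items()}
                for g, row in self.fractions.to_dict("index").items()
            }
            (out / "fractions.json").write_text(json.dumps(payload, indent=2))
        (out / "summary.txt").write_text(self.summary() + "\n")
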