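"""Core in-memory containers: community count table, sample metadata, validation report.

Distance matrices use :class:`skbio.DistanceMatrix`; phylogenies use
:class:`skbio.TreeNode`. Only the amplicon-specific containers live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file or in-memory object violates a format contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


class CommunityTable:
    """Taxa x samples table of nonnegative integer read counts.

    Rows are taxa (OTUs/ASVs), columns are samples — the common amplicon
    orientation. Orientation is a contract of the format, not guessed.

    Parameters
    ----------
    counts : array-like of shape (n_taxa, n_samples)
        Nonnegative integers.
    taxon_ids, sample_ids : sequences of unique strings.
    """

    def __init__(self, counts, taxon_ids, sample_ids):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D taxa x samples matrix")
        if counts.shape != (len(taxon_ids), len(sample_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(taxon_ids)} taxa x {len(sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at taxon {taxon_ids[bad[0]]!r}, "
                    f"sample {sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at taxon {taxon_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        _check_unique(taxon_ids, "taxon ID")
        _check_unique(sample_ids, "sample ID")
        if counts.shape[1] and (counts.sum(axis=0) == 0).any():
            empty = [s for s, tot in zip(sample_ids, counts.sum(axis=0)) if tot == 0]
            raise FormatError(f"samples with zero total reads: {empty}")
        self.counts = counts.astype(np.int64)
        self.taxon_ids = list(taxon_ids)
        self.sample_ids = list(sample_ids)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityTable":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])

    # -- views ------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances, columns summing to 1."""
        return self.counts / self.sample_totals[np.newaxis, :]

    def select_samples(self, sample_ids) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityTable(self.counts[:, idx], self.taxon_ids, list(sample_ids))

    def drop_absent_taxa(self) -> "CommunityTable":
        """Drop taxa with zero total count (e.g. after subsetting samples)."""
        keep = self.counts.sum(axis=1) > 0
        return CommunityTable(
            self.counts[keep], [t for t, k in zip(self.taxon_ids, keep) if k], self.sample_ids
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CommunityTable({self.n_taxa} taxa x {self.n_samples} samples)"


class SampleMetadata:
    """Per-sample metadata: group label, coordinates and environmental covariates.

    Wraps a DataFrame indexed by sample ID. Recognised columns are ``group``,
    ``latitude`` and ``longitude``; every other numeric column is treated as an
    environmental covariate.
    """

    RESERVED = ("group", "latitude", "longitude")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df.index = df.index.astype(str)
        _check_unique(df.index, "sample ID")
        if "latitude" in df.columns:
            lat = df["latitude"].astype(float)
            if ((lat < -90) | (lat > 90)).any():
                raise FormatError("latitude outside [-90, 90]")
        if "longitude" in df.columns:
            lon = df["longitude"].astype(float)
            if ((lon < -180) | (lon > 180)).any():
                raise FormatError("longitude outside [-180, 180]")
        self.frame = df

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def env_columns(self) -> list:
        return [
            c
            for c in self.frame.columns
            if c not in self.RESERVED and pd.api.types.is_numeric_dtype(self.frame[c])
        ]

    def groups(self, sample_ids=None) -> pd.Series:
        if "group" not in self.frame.columns:
            raise FormatError("metadata has no 'group' column")
        s = self.frame["group"].astype(str)
        return s.loc[list(sample_ids)] if sample_ids is not None else s

    def coordinates(self, sample_ids=None) -> pd.DataFrame:
        for c in ("latitude", "longitude"):
            if c not in self.frame.columns:
                raise FormatError(f"metadata has no {c!r} column")
        out = self.frame[["latitude", "longitude"]].astype(float)
        return out.loc[list(sample_ids)] if sample_ids is not None else out

    def env(self, columns=None, sample_ids=None) -> pd.DataFrame:
        cols = list(columns) if columns is not None else self.env_columns
        out = self.frame[cols].astype(float)
        return out.loc[list(sample_ids)] if sample_ids is not None else out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SampleMetadata({len(self.frame)} samples, env={self.env_columns})"


@dataclass
class ValidationReport:
    """Outcome of cross-file consistency checks. Report-only: callers decide severity."""

    fatal: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    info: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    @property
    def issues(self) -> list:
        return self.fatal + self.warnings + self.info

    def __str__(self) -> str:
        if not self.issues:
            return "OK: no issues"
        lines = [f"FATAL: {m}" for m in self.fatal]
        lines += [f"WARNING: {m}" for m in self.warnings]
        lines += [f"INFO: {m}" for m in self.info]
        return "\n".join(lines)
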