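"""Community-level statistics: relative abundance, Z-scores, diet contrasts.

The central object is a genomes x samples abundance matrix with a two-group
sample design (e.g. fiber-rich vs starch-rich diets). Differential abundance
uses the two-sided Wilcoxon rank-sum test per genome with Benjamini-Hochberg
FDR control across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .acetogen_screen import ScreenVerdict

_REL_TOL = 1e-9


@dataclass(frozen=True)
class CommunityMatrix:
    """Genomes x samples abundances plus the sample -> group mapping."""

    abundance: pd.DataFrame          # index: genome ids, columns: sample ids
    sample_groups: pd.Series         # index: sample ids, values: group labels
    normalization: str = "raw"       # "raw" or "relative"

    def __post_init__(self) -> None:
        if self.normalization not in ("raw", "relative"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = set(self.abundance.columns) - set(self.sample_groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        if self.normalization == "relative":
            sums = self.abundance.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=_REL_TOL):
                raise ValueError("relative matrix columns must sum to 1")

    @property
    def genomes(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def groups(self) -> list[str]:
        return sorted(self.sample_groups.loc[self.samples].unique())


def to_relative(matrix: CommunityMatrix) -> CommunityMatrix:
    """Column-normalize to relative abundances (idempotent)."""
    if matrix.normalization == "relative":
        return matrix
    sums = matrix.abundance.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"zero-sum sample column(s): {bad}")
    rel = matrix.abundance.div(sums, axis=1)
    return replace(matrix, abundance=rel, normalization="relative")


def acsb_fraction(
    matrix: CommunityMatrix, verdicts: Mapping[str, ScreenVerdict]
) -> pd.Series:
    """Per-sample summed relative abundance of acsB-positive genomes.

    This is the MAG-mass estimate of community acsB abundance: the fraction
    of the community carried by genomes flagged acsB-positive.
    """
    rel = to_relative(matrix)
    missing = [g for g in rel.genomes if g not in verdicts]
    if missing:
        raise KeyError(f"genomes without a screen verdict: {missing[:5]}")
    positive = [g for g in rel.genomes if verdicts[g].is_acsB_positive]
    frac = rel.abundance.loc[positive].sum(axis=0)
    frac.name = "acsB_fraction"
    return frac


def zscore(matrix: CommunityMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise Z-scores, Z = (X - mu) / sigma with population (n) sigma.

    Rows with zero variance are mapped to all-zero Z rows and flagged in the
    returned boolean series rather than propagating NaNs.
    """
    if matrix.abundance.shape[1] < 2:
        raise ValueError("Z-scores need at least two samples")
    X = matrix.abundance.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sigma = X.std(axis=1, ddof=0, keepdims=True)  # population SD
    constant = sigma[:, 0] == 0.0
    safe = np.where(sigma == 0.0, 1.0, sigma)
    Z = (X - mu) / safe
    Z[constant, :] = 0.0
    zdf = pd.DataFrame(Z, index=matrix.abundance.index, columns=matrix.abundance.columns)
    flags = pd.Series(constant, index=matrix.abundance.index, name="constant_row")
    return zdf, flags


def _rank_sum_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values for each row of a vs b.

    Exact null distribution when the combined sample size is at most 20 and
    the row has no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    n1, n2 = a.shape[1], b.shape[1]
    combined = np.concatenate([a, b], axis=1)
    has_ties = np.array([
        len(np.unique(row)) < row.size for row in combined
    ])
    pvals = np.empty(a.shape[0])
    exact_rows = (~has_ties) & (n1 + n2 <= 20)
    if exact_rows.any():
        res = stats.mannwhitneyu(
            a[exact_rows], b[exact_rows], axis=1,
            alternative="two-sided", method="exact",
        )
        pvals[exact_rows] = np.atleast_1d(res.pvalue)
    rest = ~exact_rows
    if rest.any():
        res = stats.mannwhitneyu(
            a[rest], b[rest], axis=1,
            alternative="two-sided", method="asymptotic",
        )
        pvals[rest] = np.atleast_1d(res.pvalue)
    return pvals


def diet_contrast(
    matrix: CommunityMatrix, groups: Sequence[str] | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-genome two-group Wilcoxon rank-sum contrast with BH correction.

    Returns a table with the U statistic, raw and BH-adjusted p-values, the
    direction (group with the larger median; empty on exact median ties), and
    the significance call at the given FDR level.
    """
    rel = to_relative(matrix)
    if groups is None:
        groups = rel.groups()
    if len(groups) != 2:
        raise ValueError(f"diet contrast needs exactly two groups, got {list(groups)}")
    g1, g2 = groups
    labels = rel.sample_groups.loc[rel.samples]
    cols1 = [s for s in rel.samples if labels[s] == g1]
    cols2 = [s for s in rel.samples if labels[s] == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs at least two samples")
    a = rel.abundance[cols1].to_numpy(dtype=float)
    b = rel.abundance[cols2].to_numpy(dtype=float)

    stat = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                              method="asymptotic").statistic
    pvals = _rank_sum_pvalues(a, b)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    med1, med2 = np.median(a, axis=1), np.median(b, axis=1)
    direction = np.where(med1 > med2, g1, np.where(med2 > med1, g2, ""))
    return pd.DataFrame(
        {
            "genome_id": rel.genomes,
            "statistic": np.atleast_1d(stat),
            "p_value": pvals,
            "p_adjusted": p_adj,
            "direction": direction,
            "significant": p_adj < alpha,
        }
    ).set_index("genome_id")


def bray_curtis(matrix: CommunityMatrix) -> pd.DataFrame:
    """Samples x samples Bray-Curtis dissimilarity of relative abundances."""
    rel = to_relative(matrix)
    D = squareform(pdist(rel.abundance.to_numpy(dtype=float).T, metric="braycurtis"))
    return pd.DataFrame(D, index=rel.samples, columns=rel.samples)


def shannon_diversity(matrix: CommunityMatrix) -> pd.Series:
    """Per-sample Shannon index (natural log) on relative abundances.

    Provided as the package's alpha-diversity convention.
    """
    rel = to_relative(matrix)
    H = rel.abundance.apply(lambda col: stats.entropy(col.to_numpy()), axis=0)
    H.name = "shannon"
    return H


def load_community(abundance_path: str | Path, metadata_path: str | Path) -> CommunityMatrix:
    """Read an abundance TSV (genome rows x sample columns) and sample metadata."""
    ab = pd.read_csv(abundance_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"sample_id", "group"} <= set(meta.columns):
        raise ValueError("metadata needs sample_id and group columns")
    groups = meta.set_index("sample_id")["group"]
    sums = ab.sum(axis=0).to_numpy()
    norm = "relative" if np.allclose(sums, 1.0, atol=_REL_TOL) else "raw"
    return CommunityMatrix(abundance=ab, sample_groups=groups, normalization=norm)


def write_community(matrix: CommunityMatrix, abundance_path: str | Path,
                    metadata_path: str | Path) -> None:
    matrix.abundance.to_csv(abundance_path, sep="\t")
    meta = matrix.sample_groups.rename("group").rename_axis("sample_id").reset_index()
    meta.to_csv(metadata_path, sep="\t", index=False)
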