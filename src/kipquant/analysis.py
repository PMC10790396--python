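"""Downstream kinome analyses.

Serial-depletion enrichment metrics, dilution linearity, technical-replicate
averaging with minimum-observation filtering, per-gene two-sample t-tests
(Student's or Welch's) with Benjamini-Hochberg correction, sample clustering
(correlation-distance hierarchical, or k-means on z-scored genes),
cross-dataset correlation, phosphosite rollup and the RNA log-median-ratio
transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import ProteinQuantMatrix


@dataclass
class DepletionMetrics:
    """Round-wise recovery of a serial-depletion experiment (round 0 = 1.0)."""

    rounds: list[str]
    identified_counts: list[int]
    identification_fraction: list[float]
    abundance_fraction: list[float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": self.rounds,
                "identified": self.identified_counts,
                "identification_fraction": self.identification_fraction,
                "abundance_fraction": self.abundance_fraction,
            }
        )


def depletion_metrics(
    matrix: ProteinQuantMatrix, detection_floor: float | None = None
) -> DepletionMetrics:
    """Identification and abundance recovery per depletion round vs round 0.

    A gene counts as identified in a round when its value is non-missing
    (and at or above ``detection_floor`` when given); abundance fractions
    compare summed identified abundance per round with round 0.
    """
    df = matrix.data
    rounds = list(df.columns)
    base = df[rounds[0]]
    if base.dropna().empty:
        raise ValueError("round 0 has no identified genes")

    counts, id_frac, ab_frac = [], [], []
    base_identified = base.notna() if detection_floor is None else (base >= detection_floor)
    base_count = int(base_identified.sum())
    base_sum = float(base[base_identified].sum())
    for r in rounds:
        col = df[r]
        identified = col.notna() if detection_floor is None else (col >= detection_floor)
        counts.append(int(identified.sum()))
        id_frac.append(int(identified.sum()) / base_count)
        ab_frac.append(float(col[identified].sum()) / base_sum if base_sum > 0 else np.nan)
    return DepletionMetrics(rounds, counts, id_frac, ab_frac)


def dilution_linearity(
    totals: Mapping[float, float] | pd.Series,
    per_gene: ProteinQuantMatrix | None = None,
    r2_threshold: float = 0.95,
) -> tuple[float, float, pd.Series | None]:
    """Zero-intercept fit of total signal against input amount.

    Returns (slope, R2, per-gene saturation flags).  A gene is flagged
    saturating when its own zero-intercept R2 falls below ``r2_threshold``
    (lack of fit to proportionality).
    """
    s = pd.Series(totals) if not isinstance(totals, pd.Series) else totals
    x = np.asarray([float(k) for k in s.index], dtype=float)
    y = s.to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 input levels")
    slope, r2 = _zero_intercept_fit(x, y)

    flags = None
    if per_gene is not None:
        xs = np.asarray([float(c) for c in per_gene.samples])
        out = {}
        for gene in per_gene.genes:
            yy = per_gene.data.loc[gene].to_numpy(dtype=float)
            ok = np.isfinite(yy)
            if ok.sum() < 3:
                out[gene] = False
                continue
            _, g_r2 = _zero_intercept_fit(xs[ok], yy[ok])
            out[gene] = bool(g_r2 < r2_threshold)
        flags = pd.Series(out, name="saturating")
    return slope, r2, flags


def _zero_intercept_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope = float(np.sum(x * y) / np.sum(x * x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return slope, r2


# ---------------------------------------------------------------------------
# Replicate averaging and filtering
# ---------------------------------------------------------------------------


def prepare_samples(
    matrix: ProteinQuantMatrix,
    replicate_map: Mapping[str, str],
    min_samples: int = 10,
) -> ProteinQuantMatrix:
    """Average technical replicates (log2 scale) and drop sparse genes.

    ``replicate_map`` maps each matrix column to its biological sample id.
    Genes observed in fewer than ``min_samples`` biological samples are
    dropped.  Expects a log2-scale matrix (replicate averaging is done on
    log values, matching the replicate-mean convention used downstream).
    """
    if matrix.scale != "log2":
        raise ValueError("prepare_samples expects a log2-scale matrix")
    missing_cols = [c for c in matrix.samples if c not in replicate_map]
    if missing_cols:
        raise ValueError(f"replicate map does not cover column(s) {missing_cols}")
    groups: dict[str, list[str]] = {}
    for col, bio in replicate_map.items():
        if col in matrix.data.columns:
            groups.setdefault(bio, []).append(col)
    if any(len(cols) == 0 for cols in groups.values()):
        raise ValueError("empty replicate group")

    averaged = pd.DataFrame(
        {bio: matrix.data[cols].mean(axis=1, skipna=True) for bio, cols in groups.items()}
    )
    observed = averaged.notna().sum(axis=1)
    kept = averaged.loc[observed >= min_samples]
    return ProteinQuantMatrix(kept, "log2")


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    matrix: ProteinQuantMatrix,
    groups: Mapping[str, str],
    group_a: str = "basal",
    group_b: str = "luminal",
    test: str = "student",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided t-test between two sample groups, BH-corrected.

    ``groups`` maps sample id to group label; samples labelled anything else
    (e.g. claudin-low) are ignored.  The matrix must be log2 scale so the
    mean difference is a log2 fold change.  Genes with fewer than two
    non-missing values in either group are reported as untested (NaN
    statistics).  Returns a table with group means, log2 and linear fold
    change, t, p, BH-adjusted p, direction and a significance flag at
    ``alpha`` (uncorrected, the convention used for panel-level counts).
    """
    if matrix.scale != "log2":
        raise ValueError("differential_expression expects a log2-scale matrix")
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    a_cols = [s for s in matrix.samples if groups.get(s) == group_a]
    b_cols = [s for s in matrix.samples if groups.get(s) == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples in each group")

    A = matrix.data[a_cols].to_numpy(dtype=float)
    B = matrix.data[b_cols].to_numpy(dtype=float)

    rows = []
    pvals, testable = [], []
    for i, gene in enumerate(matrix.genes):
        a = A[i][np.isfinite(A[i])]
        b = B[i][np.isfinite(B[i])]
        if a.size < 2 or b.size < 2:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, "untested"))
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        lfc = mean_a - mean_b
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # zero-variance guard: identical groups get p=1, else p=0 direction by sign
            t_stat = np.nan
            p = 1.0 if lfc == 0 else 0.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=(test == "student"))
            t_stat, p = float(t_stat), float(p)
        direction = "undefined" if lfc == 0 else (f"up_{group_a}" if lfc > 0 else f"up_{group_b}")
        rows.append((gene, mean_a, mean_b, lfc, 2.0 ** lfc, t_stat, p, direction))
        pvals.append(p)
        testable.append(len(rows) - 1)

    df = pd.DataFrame(
        rows,
        columns=[
            "gene", f"mean_{group_a}", f"mean_{group_b}", "log2_fc", "fold_change",
            "t", "p_value", "direction",
        ],
    ).set_index("gene")
    df["p_adjusted"] = np.nan
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        df.iloc[testable, df.columns.get_loc("p_adjusted")] = adj
    df["significant"] = df["p_value"] < alpha
    return df


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (convenience wrapper)."""
    return multipletests(list(pvals), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_samples(
    matrix: ProteinQuantMatrix,
    method: str = "hierarchical",
    k: int = 2,
    seed: int = 0,
):
    """Cluster samples of a log2 matrix.

    Missing values are imputed to the per-gene minimum (absence means low
    abundance) for distance computation only.  Hierarchical clustering uses
    1 - Pearson correlation between samples with average linkage and returns
    (labels at a k-cut, linkage matrix); k-means runs on per-gene z-scored
    values with a fixed seed and multiple restarts and returns (labels, None).
    """
    df = matrix.data.copy()
    if df.notna().sum(axis=0).eq(0).any():
        raise ValueError("matrix contains an all-missing sample")
    if k > len(df.columns):
        raise ValueError(f"k={k} exceeds number of samples {len(df.columns)}")
    gene_min = df.min(axis=1)
    filled = df.apply(lambda row: row.fillna(gene_min[row.name]), axis=1)
    # genes with zero variance carry no clustering signal and break z-scoring
    filled = filled.loc[filled.std(axis=1) > 0]

    X = filled.to_numpy(dtype=float).T  # samples x genes
    if method == "hierarchical":
        corr = np.corrcoef(X)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        return pd.Series(labels, index=df.columns, name="cluster"), Z
    if method == "kmeans":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xz = (X - mu) / sd
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(Xz) + 1
        return pd.Series(labels, index=df.columns, name="cluster"), None
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Cross-dataset agreement and harmonisation transforms
# ---------------------------------------------------------------------------


def cross_dataset_correlation(
    matrix_a: ProteinQuantMatrix,
    matrix_b: ProteinQuantMatrix,
    min_shared: int = 3,
) -> tuple[pd.Series, float]:
    """Per-gene Pearson correlation across shared samples, plus the median.

    Genes with fewer than ``min_shared`` pairwise-complete shared samples are
    excluded from the summary.
    """
    genes = [g for g in matrix_a.genes if g in set(matrix_b.genes)]
    samples = [s for s in matrix_a.samples if s in set(matrix_b.samples)]
    if not genes or not samples:
        raise ValueError("no shared genes/samples between datasets")
    out = {}
    for g in genes:
        a = matrix_a.data.loc[g, samples].to_numpy(dtype=float)
        b = matrix_b.data.loc[g, samples].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_shared:
            continue
        if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            continue
        out[g] = float(stats.pearsonr(a[ok], b[ok])[0])
    r = pd.Series(out, name="pearson_r")
    return r, float(r.median()) if not r.empty else float("nan")


def phospho_rollup(
    site_matrix: pd.DataFrame, site_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Average phosphosite values per gene per sample (missing sites skipped)."""
    missing = [s for s in site_matrix.index if s not in site_to_gene]
    if missing:
        raise KeyError(f"site(s) without gene mapping: {missing[:5]}")
    gene_index = pd.Series({s: site_to_gene[s] for s in site_matrix.index})
    return site_matrix.groupby(gene_index).mean()


def rna_transform(tpm: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """log2 median-ratio transform of a TPM matrix (genes x samples).

    Each value becomes log2((tpm + pc) / median_over_samples(tpm + pc)), so
    every gene's row median is zero.
    """
    if (tpm < 0).any().any():
        raise ValueError("TPM values must be >= 0")
    shifted = tpm + pseudocount
    med = shifted.median(axis=1)
    if (med <= 0).any():
        raise ValueError("gene(s) with non-positive median; use a pseudocount")
    return np.log2(shifted.div(med, axis=0))
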