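"""Poly(A)-tag digital gene expression.

Tag counts per gene are proxies for mRNA abundance.  The workflow is:

1. normalize counts to tags per million (tpm) within each sample;
2. drop genes not exceeding 5 tpm in at least one sample (strictly greater);
3. add a pseudocount of 1 to every retained tpm value;
4. form expression ratios and their log2 for the six genotype comparisons
   wt/oxt6, C30G/oxt6, wt/C30GM, C30G/C30GM, C30GM/oxt6, wt/C30G.

Downstream of the ratios:

* :func:`cam_dependent_filter` — the six-comparison screen for genes whose
  expression depends on the calmodulin interaction of CPSF30: fold change
  (max(r, 1/r), i.e. the "absolute" expression ratio) above the cutoff in the
  four discriminating comparisons (wt/oxt6, C30G/oxt6, wt/C30GM, C30G/C30GM)
  and below it in the two controls (C30GM/oxt6, wt/C30G).
* :func:`wilcoxon_bin_test` — per functional bin, a two-sided Wilcoxon
  rank-sum test of member genes' log2 ratios against all non-members;
  uncorrected p-values are reported (plus a clearly separate
  Benjamini-Hochberg column) together with log10(1/p) for plotting.
* :func:`baggerly_proportions_test` — a weighted t-type test on
  per-replicate tag proportions with a beta-binomial-style variance
  (within-library binomial plus between-library component estimated by the
  method of moments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

#: numerator/denominator sample pairs, in the order they are reported
SIX_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("wt", "oxt6"),
    ("c30g", "oxt6"),
    ("wt", "c30gm"),
    ("c30g", "c30gm"),
    ("c30gm", "oxt6"),
    ("wt", "c30g"),
)
DISCRIMINATING = SIX_COMPARISONS[:4]
CONTROLS = SIX_COMPARISONS[4:]


def comparison_label(num: str, den: str) -> str:
    return f"{num}/{den}"


def counts_to_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (column) to tags per million."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InputError(f"zero-total sample(s): {bad}")
    return counts.div(totals, axis=1) * 1e6


def filter_expressed(tpm: pd.DataFrame, threshold: float = 5.0) -> pd.Index:
    """Genes strictly exceeding ``threshold`` tpm in at least one sample."""
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    keep = (tpm > threshold).any(axis=1)
    return tpm.index[keep]


def log2_ratio_matrix(
    tpm: pd.DataFrame,
    pseudocount: float = 1.0,
    comparisons: Sequence[tuple[str, str]] = SIX_COMPARISONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ratios (tpm_num + c) / (tpm_den + c) and their log2, per comparison."""
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    ratios = {}
    for num, den in comparisons:
        if num not in tpm.columns or den not in tpm.columns:
            raise InputError(f"missing sample for comparison {num}/{den}")
        ratios[comparison_label(num, den)] = (tpm[num] + pseudocount) / (
            tpm[den] + pseudocount
        )
    ratio_df = pd.DataFrame(ratios, index=tpm.index)
    return ratio_df, np.log2(ratio_df)


@dataclass(frozen=True)
class RatioFilterResult:
    gene_id: str
    fold_changes: dict[str, float]
    passed: bool


def cam_dependent_filter(
    ratios: pd.DataFrame, cutoff: float = 2.0
) -> pd.DataFrame:
    """Six-comparison screen for calmodulin-dependent expression.

    ``ratios`` must contain the six comparison columns (plain ratios, not
    log2).  The "absolute value of the expression ratio" is read as the
    symmetric fold change max(r, 1/r) — equivalently |log2 r| > log2(cutoff)
    — since ratios of positive tpm values cannot be negative.  A gene passes
    iff all four discriminating fold changes exceed ``cutoff`` and both
    control fold changes stay below it.
    """
    needed = [comparison_label(n, d) for n, d in SIX_COMPARISONS]
    missing = [c for c in needed if c not in ratios.columns]
    if missing:
        raise InputError(f"missing comparison column(s): {missing}")
    fold = ratios[needed].where(ratios[needed] >= 1.0, 1.0 / ratios[needed])
    disc = [comparison_label(n, d) for n, d in DISCRIMINATING]
    ctrl = [comparison_label(n, d) for n, d in CONTROLS]
    passed = (fold[disc] > cutoff).all(axis=1) & (fold[ctrl] < cutoff).all(axis=1)
    out = fold.add_prefix("fold:")
    out["pass"] = passed
    return out


# ---------------------------------------------------------------------------
# Rank-sum bin enrichment


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when min(n1, n2) <= 8 and there are no ties;
    otherwise the normal approximation with average ranks for ties and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_bin_test(
    log2_ratios: pd.Series,
    bin_map: pd.DataFrame,
    min_bin_size: int = 1,
) -> pd.DataFrame:
    """Per-bin rank-sum enrichment of log2 ratios vs all non-member genes.

    ``bin_map`` has columns ``gene_id`` and ``bin_id`` (many-to-many
    allowed).  Bins with no member among the filtered genes are skipped with
    a warning.  Reports the uncorrected p, log10(1/p) for plotting, and a
    Benjamini-Hochberg adjusted column (not part of the original workflow,
    provided for convenience).
    """
    if not {"gene_id", "bin_id"} <= set(bin_map.columns):
        raise InputError("bin_map needs columns gene_id and bin_id")
    values = log2_ratios.dropna()
    rows = []
    skipped = []
    for bin_id, group in bin_map.groupby("bin_id"):
        members = values.index.intersection(pd.Index(group["gene_id"].unique()))
        if len(members) < max(min_bin_size, 1):
            skipped.append(bin_id)
            continue
        rest = values.index.difference(members)
        if len(rest) == 0:
            skipped.append(bin_id)
            continue
        stat, p = rank_sum_test(values.loc[members].values, values.loc[rest].values)
        rows.append(
            {
                "bin_id": bin_id,
                "n_members": len(members),
                "statistic": stat,
                "p_value": p,
                "log10_inverse_p": math.log10(1.0 / p),
            }
        )
    if skipped:
        import warnings

        warnings.warn(f"skipped empty bin(s): {skipped}", stacklevel=2)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_bh"] = _benjamini_hochberg(df["p_value"].values)
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# Baggerly's proportions test


def baggerly_proportions_test(
    counts_a: Sequence[float],
    lib_sizes_a: Sequence[float],
    counts_b: Sequence[float],
    lib_sizes_b: Sequence[float],
) -> tuple[float, float]:
    """Weighted t-type test on per-replicate tag proportions.

    Each group's proportion is estimated as the library-size-weighted mean of
    per-replicate proportions (equivalently the pooled proportion).  Its
    variance combines a within-library binomial term p(1-p)/n_i with a
    between-library component sigma_b^2 estimated by the method of moments
    from the weighted dispersion of the replicate proportions (clipped at
    zero).  The statistic is

        t = (pA - pB) / sqrt(V(pA) + V(pB)),

    referred to Student's t with (kA - 1) + (kB - 1) degrees of freedom; with
    a single replicate in each group the between-library term is structurally
    zero and the normal reference is used instead (documented limitation).
    Returns (statistic, two-sided p).
    """
    stat, p, _ = _baggerly_full(counts_a, lib_sizes_a, counts_b, lib_sizes_b)
    return stat, p


def _group_moments(counts: np.ndarray, sizes: np.ndarray) -> tuple[float, float, int]:
    """(weighted proportion, variance of that proportion, n replicates)."""
    if (sizes <= 0).any():
        raise InputError("library sizes must be positive")
    if counts.size == 0:
        raise InputError("each group needs at least one replicate")
    k = counts.size
    w = sizes / sizes.sum()
    props = counts / sizes
    p_hat = float((w * props).sum())
    pq = p_hat * (1.0 - p_hat)
    if k == 1:
        return p_hat, pq / float(sizes[0]), k
    s0 = float((w * (props - p_hat) ** 2).sum())
    denom = float((w * (1.0 - w)).sum())
    binom_part = pq * float((w * (1.0 - w) / sizes).sum())
    sigma_b2 = max(0.0, (s0 - binom_part) / denom)
    var = float((w**2 * (pq / sizes + sigma_b2)).sum())
    return p_hat, var, k


def _baggerly_full(
    counts_a, lib_sizes_a, counts_b, lib_sizes_b
) -> tuple[float, float, float]:
    xa = np.asarray(counts_a, dtype=float)
    na = np.asarray(lib_sizes_a, dtype=float)
    xb = np.asarray(counts_b, dtype=float)
    nb = np.asarray(lib_sizes_b, dtype=float)
    pa, va, ka = _group_moments(xa, na)
    pb, vb, kb = _group_moments(xb, nb)
    delta = pa - pb
    v = va + vb
    if v <= 0.0:
        if delta == 0.0:
            return 0.0, 1.0, float("inf")
        return math.copysign(math.inf, delta), 0.0, float("inf")
    t = delta / math.sqrt(v)
    df = (ka - 1) + (kb - 1)
    if df >= 1:
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = 2.0 * float(stats.norm.sf(abs(t)))
    return float(t), min(p, 1.0), float(df)


def baggerly_table(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Apply the proportions test per gene; library sizes are column totals."""
    sizes_a = counts[list(group_a)].sum(axis=0).values
    sizes_b = counts[list(group_b)].sum(axis=0).values
    rows = []
    for gene, row in counts.iterrows():
        stat, p = baggerly_proportions_test(
            row[list(group_a)].values, sizes_a, row[list(group_b)].values, sizes_b
        )
        rows.append({"gene_id": gene, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Matrix container + I/O


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with tpm, adjusted values and six-way ratios.

    ``tpm`` is computed over all mapped tags *before* the expression filter,
    so its column sums are exactly 1e6; ``adjusted`` (tpm + pseudocount) and
    the ratio tables cover only the genes that pass the tpm filter.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    adjusted: pd.DataFrame
    ratios: pd.DataFrame
    log2_ratios: pd.DataFrame

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        tpm_threshold: float = 5.0,
        pseudocount: float = 1.0,
        comparisons: Sequence[tuple[str, str]] = SIX_COMPARISONS,
    ) -> "ExpressionMatrix":
        tpm = counts_to_tpm(counts)
        kept = filter_expressed(tpm, tpm_threshold)
        tpm_kept = tpm.loc[kept]
        adjusted = tpm_kept + pseudocount
        ratios, log2r = log2_ratio_matrix(tpm_kept, pseudocount, comparisons)
        return cls(counts, tpm, adjusted, ratios, log2r)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_bin_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "bin_id"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "bin_id"])
    return df
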