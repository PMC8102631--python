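"""Two-class differential-expression marker selection for count matrices.

The stage mirrors a conventional bulk RNA-seq workflow: low-expression
filtering on counts-per-million (CPM), trimmed-mean-of-M-values (TMM)
between-sample normalization, a log2-CPM transform, a Welch t statistic per
gene, permutation calibration of p-values, Benjamini-Hochberg FDR control,
and threshold-based marker selection (p <= 0.05, FDR <= 0.1, ~twofold).

Already-log-scale matrices (e.g. normalized microarray intensities) skip the
count-specific steps and enter directly at :func:`two_class_test`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "DEThresholds",
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "two_class_test",
    "permutation_pvalues",
    "bh_fdr",
    "select_degs",
    "run_de",
    "read_counts_tsv",
    "read_design_tsv",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Entries are
        raw counts (``scale="counts"``) or log2-scale intensities
        (``scale="log2"``).
    scale
        Either ``"counts"`` or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.scale == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


@dataclass
class SampleDesign:
    """Two-class sample annotation with a designated reference (control) label."""

    labels: Mapping[str, str]
    reference: str

    def __post_init__(self) -> None:
        classes = sorted(set(self.labels.values()))
        if len(classes) != 2:
            raise ValueError(f"design must have exactly two classes, got {classes}")
        if self.reference not in classes:
            raise ValueError(f"reference label {self.reference!r} not among {classes}")
        counts = pd.Series(list(self.labels.values())).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"classes with < 2 samples: {small}")
        if (counts < 3).any():
            # datasets below the 3-replicate inclusion rule still compute,
            # but the design is flagged
            import logging

            logging.getLogger(__name__).warning(
                "class(es) with < 3 replicates: %s",
                counts[counts < 3].index.tolist(),
            )

    @property
    def case(self) -> str:
        return next(c for c in set(self.labels.values()) if c != self.reference)

    def split(self, sample_ids: Iterable[str]) -> tuple[list[str], list[str]]:
        """Return (case sample ids, control sample ids) in matrix order."""
        case_ids, ctrl_ids = [], []
        for s in sample_ids:
            if s not in self.labels:
                raise ValueError(f"sample {s!r} has no class label")
            (ctrl_ids if self.labels[s] == self.reference else case_ids).append(s)
        return case_ids, ctrl_ids


@dataclass
class DEThresholds:
    """Selection gates: uncorrected p, BH FDR, absolute log2 fold change,
    and the CPM low-expression filter."""

    p_max: float = 0.05
    fdr_max: float = 0.1
    min_abs_log2fc: float = 1.0
    cpm_min: float = 0.5
    cpm_min_samples: int = 3

    def __post_init__(self) -> None:
        for name in ("p_max", "fdr_max", "min_abs_log2fc", "cpm_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cpm_min_samples < 1:
            raise ValueError("cpm_min_samples must be >= 1")


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def filter_low_expression(m: ExpressionMatrix, t: DEThresholds | None = None) -> ExpressionMatrix:
    """Keep genes with CPM > ``t.cpm_min`` in at least ``t.cpm_min_samples`` samples.

    Gene order is preserved; the sample set is unchanged.
    """
    t = t or DEThresholds()
    if m.scale != "counts":
        raise ValueError("low-expression filter applies to count matrices only")
    lib = m.library_sizes
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    cpm = m.values / lib * 1e6
    keep = (cpm > t.cpm_min).sum(axis=1) >= t.cpm_min_samples
    if not keep.any():
        raise ValueError("no genes pass filter")
    return ExpressionMatrix(m.values.loc[keep].copy(), scale="counts")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, m_trim: float, a_trim: float) -> float:
    """Weighted trimmed mean of M-values for one sample against the reference."""
    n_obs, n_ref = obs.sum(), ref.sum()
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise ValueError("sample shares no co-expressed genes with the reference")
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M, used as precision weight
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 1.0
    if np.allclose(m, m[0]):
        # degenerate: identical composition, e.g. scaled columns
        return float(2.0 ** m[0]) if abs(m[0]) > 1e-10 else 1.0
    m_lo, m_hi = np.quantile(m, [m_trim, 1 - m_trim])
    a_lo, a_hi = np.quantile(a, [a_trim, 1 - a_trim])
    keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(
    m: ExpressionMatrix,
    ref: str = "auto",
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors, one per sample, geometric mean 1.

    The reference sample (``ref="auto"``) is the one whose 75th percentile of
    CPM is closest to the mean of those percentiles across samples. Trim
    fractions follow the published TMM defaults (30% on M, 5% on A, two-sided).
    """
    if m.scale != "counts":
        raise ValueError("TMM applies to count matrices only")
    x = m.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(lib <= 0)]
        raise ValueError(f"zero library size in sample(s): {bad}")
    if ref == "auto":
        f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if ref not in m.sample_ids:
            raise ValueError(f"reference sample {ref!r} not in matrix")
        ref_idx = m.sample_ids.index(ref)
    factors = np.array(
        [
            1.0 if j == ref_idx else _tmm_pair(x[:, j], x[:, ref_idx], m_trim, a_trim)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.sample_ids, name="tmm_factor")


def log_cpm(
    m: ExpressionMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> ExpressionMatrix:
    """log2 CPM with effective (TMM-scaled) library sizes.

    ``value[g, s] = log2((count + pseudocount) / (libsize_s * factor_s + 1) * 1e6)``
    """
    if m.scale != "counts":
        raise ValueError("log_cpm applies to count matrices only")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("negative counts")
    lib = m.library_sizes.to_numpy(dtype=float)
    f = np.ones_like(lib) if factors is None else factors.reindex(m.sample_ids).to_numpy(dtype=float)
    eff = lib * f + 1.0
    vals = np.log2((m.values.to_numpy(dtype=float) + pseudocount) / eff * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.values.index, columns=m.values.columns), scale="log2"
    )


# ---------------------------------------------------------------------------
# Testing
# ---------------------------------------------------------------------------

def _welch_stats(
    x: np.ndarray, case_cols: np.ndarray, ctrl_cols: np.ndarray, sd_floor_q: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (log2 fold change, Welch t) for a genes x samples array.

    Group standard deviations are floored at the ``sd_floor_q`` quantile of
    per-gene pooled SDs so genes with vanishing within-group variance do not
    produce infinite statistics.
    """
    a, b = x[:, case_cols], x[:, ctrl_cols]
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    pooled_sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    floor = np.quantile(pooled_sd, sd_floor_q)
    s1 = np.maximum(np.sqrt(v1), floor)
    s2 = np.maximum(np.sqrt(v2), floor)
    lfc = m1 - m2
    se = np.sqrt(s1**2 / n1 + s2**2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    return lfc, t


def two_class_test(m: ExpressionMatrix, d: SampleDesign) -> pd.DataFrame:
    """Per-gene log2 fold change (case minus control) and Welch t on log2 values."""
    if m.scale != "log2":
        raise ValueError("two_class_test expects a log2-scale matrix")
    case_ids, ctrl_ids = d.split(m.sample_ids)
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each class needs >= 2 samples")
    cols = {s: i for i, s in enumerate(m.sample_ids)}
    lfc, t = _welch_stats(
        m.values.to_numpy(dtype=float),
        np.array([cols[s] for s in case_ids]),
        np.array([cols[s] for s in ctrl_ids]),
    )
    return pd.DataFrame({"log2_fold_change": lfc, "statistic": t}, index=m.values.index)


def permutation_pvalues(
    m: ExpressionMatrix, d: SampleDesign, B: int = 999, seed: int = 0
) -> pd.Series:
    """Class-label permutation p-values for the Welch statistic.

    When the number of distinct label assignments C(n, n_case) does not
    exceed ``max(B, 1000)`` the full enumeration is used and the p-value is
    exact (#assignments with |T| >= |T_obs| over the total, the identity
    included); small designs are always enumerated since that is both exact
    and cheaper than sampling. Otherwise ``B`` random permutations are drawn
    and the add-one estimator ``(1 + #{|T_b| >= |T_obs|}) / (B + 1)`` is
    used.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    case_ids, ctrl_ids = d.split(m.sample_ids)
    n1, n = len(case_ids), len(case_ids) + len(ctrl_ids)
    cols = {s: i for i, s in enumerate(m.sample_ids)}
    all_cols = np.array([cols[s] for s in case_ids + ctrl_ids])
    x = m.values.to_numpy(dtype=float)[:, all_cols]  # case block first
    obs_abs = np.abs(_welch_stats(x, np.arange(n1), np.arange(n1, n))[1])

    from math import comb

    n_distinct = comb(n, n1)
    if n_distinct <= max(B, 1000):
        ge = np.zeros(x.shape[0], dtype=int)
        for case_idx in combinations(range(n), n1):
            ci = np.array(case_idx)
            ki = np.setdiff1d(np.arange(n), ci)
            perm_abs = np.abs(_welch_stats(x, ci, ki)[1])
            ge += perm_abs >= obs_abs - 1e-12
        p = ge / n_distinct
    else:
        rng = np.random.default_rng(seed)
        ge = np.zeros(x.shape[0], dtype=int)
        for _ in range(B):
            perm = rng.permutation(n)
            perm_abs = np.abs(_welch_stats(x, perm[:n1], perm[n1:])[1])
            ge += perm_abs >= obs_abs - 1e-12
        p = (1 + ge) / (B + 1)
    return pd.Series(p, index=m.values.index, name="p_value")


def bh_fdr(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_degs(
    stats: pd.DataFrame,
    p: pd.Series,
    fdr: pd.Series | np.ndarray | None = None,
    t: DEThresholds | None = None,
) -> pd.DataFrame:
    """Apply the selection gates and return the marker (DEG) table.

    A gene is selected iff ``p <= p_max`` and ``fdr <= fdr_max`` and
    ``|log2fc| >= min_abs_log2fc``; selected genes are directioned up/down by
    the sign of the fold change, everything else is ``ns``.
    """
    t = t or DEThresholds()
    if len(stats) != len(p):
        raise ValueError("stats and p-values are misaligned")
    fdr_vals = bh_fdr(p) if fdr is None else np.asarray(fdr, dtype=float)
    if len(fdr_vals) != len(stats):
        raise ValueError("stats and fdr are misaligned")
    lfc = stats["log2_fold_change"].to_numpy()
    p_vals = np.asarray(p, dtype=float)
    selected = (p_vals <= t.p_max) & (fdr_vals <= t.fdr_max) & (np.abs(lfc) >= t.min_abs_log2fc)
    direction = np.where(selected, np.where(lfc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "stat": stats["statistic"].to_numpy(),
            "p": p_vals,
            "fdr": fdr_vals,
            "direction": direction,
            "selected": selected,
        },
        index=stats.index.rename("gene"),
    )


def run_de(
    m: ExpressionMatrix,
    d: SampleDesign,
    t: DEThresholds | None = None,
    B: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Full marker-selection stage: filter, TMM, log-CPM, test, permute, select.

    Log-scale inputs (microarray) skip filtering and normalization.
    """
    t = t or DEThresholds()
    if m.scale == "counts":
        m = filter_low_expression(m, t)
        factors = tmm_factors(m)
        m = log_cpm(m, factors)
    stats = two_class_test(m, d)
    p = permutation_pvalues(m, d, B=B, seed=seed)
    return select_degs(stats, p, None, t)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path, scale: str = "counts") -> ExpressionMatrix:
    """Read a counts TSV (first column gene id, header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, scale=scale)


#: class labels recognised as the reference (control) group when none is named
_CONTROL_LABELS = {"control", "ctrl", "reference", "ref", "normal", "healthy", "wt"}


def read_design_tsv(path: str | Path, reference: str | None = None) -> SampleDesign:
    """Read a two-column design TSV (sample_id, class).

    If ``reference`` is None, a label matching a conventional control name
    (control/ctrl/reference/ref/normal/healthy/wt, case-insensitive) is the
    reference; otherwise the lexicographically smaller label is used.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    labels = dict(zip(df["sample_id"], df["label"]))
    if reference is None:
        classes = sorted(set(labels.values()))
        ctrl_like = [c for c in classes if c.lower() in _CONTROL_LABELS]
        reference = ctrl_like[0] if ctrl_like else classes[0]
    return SampleDesign(labels, reference)


def write_deg_tsv(degs: pd.DataFrame, path: str | Path) -> None:
    degs.to_csv(path, sep="\t", float_format="%.6g")
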