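"""Per-gene differential expression: log2 fold changes and moderated t-tests.

The edge score downstream needs, for every measured gene, a log2 fold change
between the two phenotype groups and a p-value for that change.  Both are
computed here with an empirical-Bayes *moderated* t-test: each gene's sample
variance s2_g (pooled across the two groups, df residual degrees of freedom)
is shrunk toward a prior variance s0^2 carrying d0 prior degrees of freedom,

    s2_post = (d0 * s0^2 + df * s2_g) / (d0 + df),

and the t-statistic built on s2_post is referred to a t distribution with
d0 + df degrees of freedom.  The prior (d0, s0^2) is estimated from the whole
collection of gene variances by the method of moments on log s2: under the
model the s2_g are scaled-F distributed, so log s2_g has mean
log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2) and excess variance
psi'(d0/2) beyond the sampling term psi'(df/2) (psi, psi' digamma/trigamma).
Equal observed variances force d0 = +inf (complete shrinkage); d0 = 0 recovers
the ordinary pooled two-sample t-test.

The per-gene statistics table (the lingua franca of the rest of the package)
is a :class:`pandas.DataFrame` indexed by gene id with columns ``log2fc``,
``t_stat``, ``p_value``, ``df_total``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ExpressionDataset",
    "ModeratedPrior",
    "EstimationError",
    "group_stats",
    "fit_prior",
    "moderated_t_test",
    "read_expression",
    "write_expression",
    "read_stats_table",
    "write_stats_table",
]

STAT_COLUMNS = ("log2fc", "t_stat", "p_value", "df_total")

CASE, CONTROL = "case", "control"


class EstimationError(RuntimeError):
    """Raised when the variance prior cannot be estimated from the data."""


@dataclass
class ExpressionDataset:
    """A genes x samples matrix of log-scale intensities plus group labels.

    ``values``: DataFrame, rows = genes (unique ids), columns = samples.
    ``groups``: Series mapping each sample to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control', got {sorted(bad)}")
        for label in (CASE, CONTROL):
            if (self.groups == label).sum() < 2:
                raise ValueError(f"need >=2 samples in group {label!r}")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")

    @property
    def case_columns(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_columns(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    def swap_groups(self) -> "ExpressionDataset":
        flipped = self.groups.map({CASE: CONTROL, CONTROL: CASE})
        return ExpressionDataset(self.values, flipped)


@dataclass
class ModeratedPrior:
    """Prior degrees of freedom d0 (may be ``inf``) and prior variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0 when d0 > 0")


def group_stats(data: ExpressionDataset) -> pd.DataFrame:
    """Per-gene group means, pooled variance and residual degrees of freedom.

    ``pooled_var`` is the usual two-sample pooled variance with
    ``df = n_case + n_control - 2`` residual degrees of freedom.
    """
    case = data.values[data.case_columns].to_numpy(float)
    ctrl = data.values[data.control_columns].to_numpy(float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    ss1 = ((case - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((ctrl - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled = (ss1 + ss2) / df
    return pd.DataFrame(
        {
            "mean_case": m1,
            "mean_control": m2,
            "log2fc": m1 - m2,
            "pooled_var": pooled,
            "df": float(df),
        },
        index=data.values.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_prior(variances, df) -> ModeratedPrior:
    """Method-of-moments fit of (d0, s0^2) from gene-wise variances.

    ``df`` may be a scalar (same residual df for every gene) or an array.
    Zero variances are excluded from the fit; if every variance is zero the
    caller must apply a variance floor first.
    """
    s2 = np.asarray(variances, float)
    df_arr = np.broadcast_to(np.asarray(df, float), s2.shape).copy()
    keep = s2 > 0
    if keep.sum() < 2:
        raise EstimationError(
            "need >=2 genes with positive variance to fit the prior; "
            "apply a variance floor (e.g. the smallest positive s2) first"
        )
    s2, df_arr = s2[keep], df_arr[keep]

    z = np.log(s2)
    e = z - special.digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(
        np.mean(special.polygamma(1, df_arr / 2.0))
    )
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return ModeratedPrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    data: ExpressionDataset,
    prior: ModeratedPrior | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t-test for every gene.

    When ``prior`` is not supplied it is fitted from this dataset's variances.
    Genes with zero pooled variance receive a variance floor (the smallest
    positive observed variance) before shrinkage; a gene whose variance and
    mean difference are both zero gets t = 0, p = 1.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t_stat``,
    ``p_value``, ``df_total`` (two-sided p-values).
    """
    gs = group_stats(data)
    s2 = gs["pooled_var"].to_numpy().copy()
    df = gs["df"].to_numpy()

    positive = s2[s2 > 0]
    if positive.size:
        s2[s2 == 0] = positive.min()

    if prior is None:
        prior = fit_prior(s2, df)

    d0, s0_sq = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    n1, n2 = len(data.case_columns), len(data.control_columns)
    se_factor = 1.0 / n1 + 1.0 / n2
    diff = gs["log2fc"].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * se_factor)
    t = np.where((diff == 0) & ~(s2_post > 0), 0.0, t)

    if np.isinf(df_total).all():
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "log2fc": diff,
            "t_stat": t,
            "p_value": p,
            "df_total": df_total,
        },
        index=gs.index,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_expression(matrix_path, groups_path) -> ExpressionDataset:
    """Read a TSV/CSV expression matrix (first column = gene id) and a
    two-column sample -> group file (no header required)."""
    sep = "," if str(matrix_path).endswith(".csv") else "\t"
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    raw = pd.read_csv(groups_path, sep="\t", header=None, dtype=str, comment="#")
    if raw.shape[1] < 2:
        raise ValueError("group file needs two columns: sample, group")
    if set(raw.iloc[0]) & {"sample", "group"}:
        raw = raw.iloc[1:]
    groups = pd.Series(raw.iloc[:, 1].values, index=raw.iloc[:, 0].values)
    return ExpressionDataset(values=values, groups=groups)


def write_expression(data: ExpressionDataset, matrix_path, groups_path) -> None:
    data.values.to_csv(matrix_path, sep="\t", index_label="gene")
    data.groups.rename("group").to_csv(groups_path, sep="\t", header=False)


def read_stats_table(source) -> pd.DataFrame:
    """Read a precomputed per-gene statistics TSV (columns gene, log2fc, p_value)."""
    tab = pd.read_csv(source, sep="\t")
    required = {"gene", "log2fc", "p_value"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"stats table is missing column(s): {sorted(missing)}")
    bad = tab[(tab["p_value"] < 0) | (tab["p_value"] > 1)]
    if len(bad):
        genes = list(bad["gene"].head())
        raise ValueError(f"p-values outside [0,1] for gene(s): {genes}")
    out = tab.set_index("gene")
    for col in ("t_stat", "df_total"):
        if col not in out.columns:
            out[col] = np.nan
    return out[list(STAT_COLUMNS)]


def write_stats_table(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index_label="gene")
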