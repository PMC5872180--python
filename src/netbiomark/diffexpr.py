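"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene g with pooled within-group variance s²_g on df_g residual degrees of
freedom, the variances are modelled as draws from a scaled inverse-chi-square
prior, σ²_g ~ s0²·d0/χ²(d0). The prior hyperparameters (d0, s0²) are estimated
across genes by the method of moments on log s² using digamma/trigamma
identities; the posterior variance

    s̃²_g = (d0·s0² + df_g·s²_g) / (d0 + df_g)

replaces s²_g in the t-statistic, which is then referred to a t distribution
with d0 + df_g degrees of freedom (standard normal when d0 = ∞). Shrinking
toward the common prior stabilises variance estimates when per-group sample
sizes are small, the regime of typical microarray series. d0 = 0 disables
moderation and recovers the ordinary pooled-variance two-sample t exactly.

P-values are two-sided and corrected by Benjamini–Hochberg step-up FDR; genes
with adjusted p < alpha are called Up or Down by the sign of the log2 fold
change (case minus control), all others NS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"

__all__ = [
    "ExpressionDataset",
    "VariancePrior",
    "fit_group_contrast",
    "estimate_variance_prior",
    "moderated_t",
    "bh_adjust",
    "call_de",
    "run_de",
    "collapse_probes_max_t",
]


@dataclass
class ExpressionDataset:
    """A genes × samples log2-scale expression matrix with binary group labels.

    ``groups`` maps each sample (column) to ``"control"`` (e.g. primary tumor)
    or ``"case"`` (e.g. metastasis). Both groups need at least two samples.
    """

    dataset_id: str
    matrix: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [c for c in self.matrix.columns if c not in self.groups.index]
        if missing:
            raise ValueError(f"{self.dataset_id}: samples without group label: {missing}")
        self.groups = self.groups.loc[self.matrix.columns]
        bad = set(self.groups.unique()) - {CONTROL, CASE}
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown group labels {sorted(bad)}")
        counts = self.groups.value_counts()
        for grp in (CONTROL, CASE):
            if counts.get(grp, 0) < 2:
                raise ValueError(
                    f"{self.dataset_id}: group {grp!r} has "
                    f"{counts.get(grp, 0)} samples, need >= 2"
                )
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"{self.dataset_id}: duplicate gene identifiers {dupes[:5]}")
        values = self.matrix.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError(f"{self.dataset_id}: non-finite expression values")
        if values.size and values.max() > 50:
            logger.warning(
                "%s: matrix maximum %.3g exceeds 50 — values look unlogged; "
                "expression is assumed to be on the log2 scale",
                self.dataset_id,
                values.max(),
            )

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior: d0 degrees of freedom (may be ``inf``)
    and prior variance s0²."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0, got {self.d0}")
        if not (self.s0_sq > 0) and self.d0 > 0:
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


def fit_group_contrast(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-gene two-group contrast: log2 fold change (case − control), pooled
    within-group variance, and residual degrees of freedom n1 + n2 − 2."""
    case = dataset.matrix[dataset.case_samples].to_numpy(dtype=float)
    control = dataset.matrix[dataset.control_samples].to_numpy(dtype=float)
    n1, n2 = control.shape[1], case.shape[1]
    log_fc = case.mean(axis=1) - control.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (control - control.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    return pd.DataFrame(
        {
            "log_fc": log_fc,
            "s_sq": ss / df,
            "df": float(df),
            "n_control": n1,
            "n_case": n2,
        },
        index=dataset.matrix.index.rename("gene"),
    )


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = np.where(x > 1e7, 1.0 / np.sqrt(x), 0.5 + 1.0 / x)
    for _ in range(75):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + step
        if np.all(np.abs(step) < 1e-10 * np.maximum(y, 1.0)):
            break
    # tiny x: trigamma(y) ~ 1/y
    return np.where(x < 1e-6, 1.0 / x, y)


def estimate_variance_prior(
    s_sq: Sequence[float],
    df: float | Sequence[float],
    min_genes: int = 30,
) -> VariancePrior:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Works on z = log s²: under the model, e = z − ψ(df/2) + log(df/2) has mean
    log s0² − ψ(d0/2) + log(d0/2) and variance ψ'(df/2) + ψ'(d0/2), so the
    excess of the empirical variance of e over the mean theoretical sampling
    term ψ'(df/2) identifies d0 through the trigamma inverse, and the mean of e
    then identifies s0². When the empirical variance does not exceed the
    sampling term, d0 = ∞ (complete shrinkage) and s0² = exp(mean z).

    Genes with s² = 0 are excluded with a logged count.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s_sq.shape)
    usable = s_sq > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("excluded %d zero-variance genes from prior estimation", n_dropped)
    s_sq, df = s_sq[usable], df[usable]
    if s_sq.size < min_genes:
        raise ValueError(
            f"only {s_sq.size} genes with positive variance (< {min_genes}); "
            "too few to estimate the prior — use the ordinary-t fallback"
        )
    e = np.log(s_sq) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if e_var <= 0:
        # complete shrinkage: with d0 = inf every gene shares one variance, and
        # the raw-scale moment E[s²] = σ² estimates it (exactly the common
        # value when all s² are equal)
        return VariancePrior(d0=math.inf, s0_sq=float(s_sq.mean()))
    d0 = 2.0 * float(_trigamma_inverse(e_var))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    log_fc: np.ndarray | float,
    s_sq: np.ndarray | float,
    df: np.ndarray | float,
    prior: VariancePrior,
    n1: int,
    n2: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t-statistic, total degrees of freedom, and two-sided p-value.

    Posterior variance s̃² = (d0·s0² + df·s²)/(d0 + df); t = logFC /
    sqrt(s̃²(1/n1 + 1/n2)) on d0 + df degrees of freedom. d0 = 0 gives the
    ordinary pooled t; d0 = ∞ gives s̃² = s0² with a normal reference.
    Genes with s̃² = 0 get t = NaN and p = 1 (flagged NS downstream).
    """
    log_fc = np.atleast_1d(np.asarray(log_fc, dtype=float))
    s_sq = np.broadcast_to(np.asarray(s_sq, dtype=float), log_fc.shape)
    df = np.broadcast_to(np.asarray(df, dtype=float), log_fc.shape)
    scale = 1.0 / n1 + 1.0 / n2
    if math.isinf(prior.d0):
        s_tilde = np.full_like(log_fc, prior.s0_sq)
        df_total = np.full_like(log_fc, np.inf)
    elif prior.d0 == 0:
        s_tilde = s_sq.astype(float)
        df_total = df.astype(float)
    else:
        s_tilde = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = prior.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / np.sqrt(s_tilde * scale)
    undefined = s_tilde <= 0
    t_mod = np.where(undefined, np.nan, t_mod)
    p_raw = np.ones_like(t_mod)
    ok = ~undefined
    finite_df = ok & np.isfinite(df_total)
    p_raw[finite_df] = 2.0 * stats.t.sf(np.abs(t_mod[finite_df]), df_total[finite_df])
    inf_df = ok & ~np.isfinite(df_total)
    p_raw[inf_df] = 2.0 * stats.norm.sf(np.abs(t_mod[inf_df]))
    return t_mod, df_total, p_raw


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Direction calls from a table with ``log_fc``, ``p_raw`` (and flags).

    Adds ``p_adj`` (BH) and ``direction`` in {Up, Down, NS}; significance is
    strict, p_adj < alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    out = results.copy()
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    significant = (out["p_adj"] < alpha) & out["log_fc"].ne(0)
    if "zero_variance" in out.columns:
        significant &= ~out["zero_variance"]
    out["direction"] = np.where(
        significant, np.where(out["log_fc"] > 0, "Up", "Down"), "NS"
    )
    return out


def run_de(
    dataset: ExpressionDataset,
    alpha: float = 0.05,
    method: Literal["moderated", "ordinary"] = "moderated",
) -> pd.DataFrame:
    """Full per-dataset differential expression chain.

    Fits the group contrast, estimates the variance prior (skipped for the
    ordinary pooled t), computes moderated t/p, adjusts by BH and calls
    directions. Returns a gene-indexed table with columns log_fc, s_sq, df,
    t_mod, df_total, p_raw, p_adj, direction, zero_variance.
    """
    fit = fit_group_contrast(dataset)
    if method == "moderated":
        prior = estimate_variance_prior(fit["s_sq"].to_numpy(), fit["df"].to_numpy())
    elif method == "ordinary":
        prior = VariancePrior(d0=0.0, s0_sq=1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    n1 = len(dataset.control_samples)
    n2 = len(dataset.case_samples)
    t_mod, df_total, p_raw = moderated_t(
        fit["log_fc"].to_numpy(), fit["s_sq"].to_numpy(), fit["df"].to_numpy(),
        prior, n1, n2,
    )
    out = fit.copy()
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p_raw"] = p_raw
    out["zero_variance"] = ~np.isfinite(t_mod)
    out.attrs["prior"] = prior
    out.attrs["dataset_id"] = dataset.dataset_id
    return call_de(out, alpha=alpha)


def collapse_probes_max_t(
    de_table: pd.DataFrame, probe_to_gene: pd.Series
) -> pd.DataFrame:
    """Collapse multiple probes per gene keeping the row with the largest |t|.

    Plumbing utility for platforms with probe-level rows; probes without a
    mapping are dropped.
    """
    table = de_table.join(probe_to_gene.rename("gene"), how="inner")
    order = table["t_mod"].abs().fillna(-np.inf)
    table = table.loc[order.sort_values(ascending=False).index]
    return table.drop_duplicates(subset="gene").set_index("gene")
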