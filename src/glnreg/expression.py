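"""Nitrogen-response expression filtering and regulator-dependence calls.

The expression matrix is a pandas DataFrame of log2 intensities with genes
as the index and a three-level column MultiIndex ``(strain, timepoint,
replicate)``.  Strains are e.g. ``WT``, ``glnR``, ``glnRII``; timepoints are
``T0`` (nitrogen-replete mid-log), ``T30`` (30 min after transfer to
nitrogen-free medium) and ``T45`` (15 min after ammonium re-addition).

The dual response filter keeps genes induced more than ``theta``-fold by
nitrogen starvation (T30 vs T0) *and* repressed more than ``theta``-fold by
ammonium re-addition (T30 vs T45).  A gene is regulator-dependent when the
wild type passes this filter but the deletion mutant fails it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

TIMEPOINTS = ("T0", "T30", "T45")
COLUMN_NAMES = ("strain", "timepoint", "replicate")


def _validate(matrix: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(matrix.columns, pd.MultiIndex) or \
            matrix.columns.nlevels != 3:
        raise ValueError("expression matrix needs (strain, timepoint, "
                         "replicate) column MultiIndex")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return matrix


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample log2 matrix whose header is ``strain:timepoint:rep``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = []
    for c in df.columns:
        parts = c.split(":")
        if len(parts) != 3:
            raise ValueError(f"bad sample header {c!r}: "
                             "expected strain:timepoint:rep")
        cols.append(tuple(parts))
    df.columns = pd.MultiIndex.from_tuples(cols, names=COLUMN_NAMES)
    return _validate(df)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.columns = [":".join(map(str, c)) for c in matrix.columns]
    out.to_csv(path, sep="\t", index_label="gene_id")


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Normalise per gene to the median: subtract each row's median (log2)."""
    _validate(matrix)
    return matrix.sub(matrix.median(axis=1), axis=0)


def _cell_means(matrix: pd.DataFrame, strain: str,
                timepoints: Sequence[str] = TIMEPOINTS) -> pd.DataFrame:
    """Per-gene mean log2 per timepoint for one strain."""
    if strain not in matrix.columns.get_level_values("strain"):
        raise ValueError(f"strain {strain!r} absent from matrix")
    sub = matrix.xs(strain, axis=1, level="strain")
    means = {}
    for tp in timepoints:
        if tp not in sub.columns.get_level_values("timepoint"):
            raise ValueError(f"strain {strain!r} has no samples at {tp}")
        means[tp] = sub.xs(tp, axis=1, level="timepoint").mean(axis=1)
    return pd.DataFrame(means)


def fold_changes(matrix: pd.DataFrame, strain: str,
                 theta: float = 2.0) -> pd.DataFrame:
    """Per-gene linear fold induction/repression and the dual response filter.

    Replicates are summarised by the mean of log2 values, then

    * ``fold_induction``  = 2 ** (mean log2 T30 - mean log2 T0)
    * ``fold_repression`` = 2 ** (mean log2 T30 - mean log2 T45)

    and ``passes`` is true iff both exceed ``theta``.
    """
    _validate(matrix)
    m = _cell_means(matrix, strain)
    out = pd.DataFrame(index=matrix.index)
    out["fold_induction"] = 2.0 ** (m["T30"] - m["T0"])
    out["fold_repression"] = 2.0 ** (m["T30"] - m["T45"])
    out["passes"] = (out["fold_induction"] > theta) & \
                    (out["fold_repression"] > theta)
    out["theta"] = theta
    return out


def dependence(matrix: pd.DataFrame,
               wt_strain: str = "WT",
               mutant_strain: str = "glnR",
               theta_wt: float = 2.0,
               theta_responsive_mutant: float = 2.0) -> pd.DataFrame:
    """Call regulator-dependent genes: responsive in WT, non-responsive in mutant.

    "Non-responsive" is operationalised as failing the dual filter at
    ``theta_responsive_mutant`` (either arm <= threshold).  Both the WT and
    mutant calls are returned so alternative definitions can be audited.
    """
    wt = fold_changes(matrix, wt_strain, theta_wt)
    mut = fold_changes(matrix, mutant_strain, theta_responsive_mutant)
    out = pd.DataFrame(index=matrix.index)
    out["wt_fold_induction"] = wt["fold_induction"]
    out["wt_fold_repression"] = wt["fold_repression"]
    out["wt_passes"] = wt["passes"]
    out["mutant_fold_induction"] = mut["fold_induction"]
    out["mutant_fold_repression"] = mut["fold_repression"]
    out["mutant_passes"] = mut["passes"]
    out["dependent"] = out["wt_passes"] & ~out["mutant_passes"]
    return out


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

def _is_balanced(strains: np.ndarray, times: np.ndarray) -> bool:
    counts = pd.crosstab(pd.Series(strains), pd.Series(times)).to_numpy()
    return counts.min() == counts.max() and counts.min() >= 2


def two_way_anova_bh(matrix: pd.DataFrame,
                     strains: Sequence[str] | None = None,
                     timepoints: Sequence[str] | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Classical fixed-effects two-way ANOVA (genotype x time) per gene, with BH.

    For balanced replicated designs the sums of squares are computed
    vectorised over all genes; unbalanced designs fall back to a per-gene
    type-II OLS ANOVA via statsmodels.  Benjamini-Hochberg step-up is
    applied per effect across genes.  Genes with zero total variance get
    F = 0 and p = 1 by convention, so they can never be significant.

    Returns a frame with columns ``F_<effect>``, ``p_<effect>``,
    ``q_<effect>`` and ``sig_<effect>`` for effects ``genotype``, ``time``
    and ``interaction``.
    """
    _validate(matrix)
    cols = matrix.columns
    strain_lab = cols.get_level_values("strain").to_numpy()
    time_lab = cols.get_level_values("timepoint").to_numpy()
    if strains is not None or timepoints is not None:
        keep = np.ones(len(cols), dtype=bool)
        if strains is not None:
            keep &= np.isin(strain_lab, list(strains))
        if timepoints is not None:
            keep &= np.isin(time_lab, list(timepoints))
        matrix = matrix.loc[:, keep]
        strain_lab, time_lab = strain_lab[keep], time_lab[keep]
    if len(np.unique(strain_lab)) < 2 or len(np.unique(time_lab)) < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels per factor")

    if _is_balanced(strain_lab, time_lab):
        res = _anova_balanced(matrix.to_numpy(dtype=float),
                              strain_lab, time_lab)
    else:
        res = _anova_unbalanced(matrix.to_numpy(dtype=float),
                                strain_lab, time_lab)
    out = pd.DataFrame(res, index=matrix.index)
    for effect in ("genotype", "time", "interaction"):
        q = multipletests(out[f"p_{effect}"], method="fdr_bh")[1]
        out[f"q_{effect}"] = q
        out[f"sig_{effect}"] = q < alpha
    return out


def _anova_balanced(y: np.ndarray, strains: np.ndarray,
                    times: np.ndarray) -> dict[str, np.ndarray]:
    a_levels = np.unique(strains)
    b_levels = np.unique(times)
    a, b = len(a_levels), len(b_levels)
    n_cells = a * b
    r = y.shape[1] // n_cells

    grand = y.mean(axis=1, keepdims=True)
    ss_total = ((y - grand) ** 2).sum(axis=1)

    mean_a = np.stack([y[:, strains == lv].mean(axis=1) for lv in a_levels],
                      axis=1)
    mean_b = np.stack([y[:, times == lv].mean(axis=1) for lv in b_levels],
                      axis=1)
    ss_a = r * b * ((mean_a - grand) ** 2).sum(axis=1)
    ss_b = r * a * ((mean_b - grand) ** 2).sum(axis=1)

    ss_cells = np.zeros_like(ss_a)
    ss_err = np.zeros_like(ss_a)
    for i, la in enumerate(a_levels):
        for j, lb in enumerate(b_levels):
            sel = (strains == la) & (times == lb)
            cell = y[:, sel]
            cm = cell.mean(axis=1)
            ss_cells += r * (cm - grand[:, 0]) ** 2
            ss_err += ((cell - cm[:, None]) ** 2).sum(axis=1)
    ss_ab = ss_cells - ss_a - ss_b

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = n_cells * (r - 1)

    def f_and_p(ss: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            ms_err = ss_err / df_err
            f = np.where(ms_err > 0, (ss / df) / ms_err, 0.0)
        # numerical floor: treat tiny negative SS from cancellation as 0
        f = np.clip(f, 0.0, None)
        p = scipy.stats.f.sf(f, df, df_err)
        zero_var = ss_total <= 1e-12
        f = np.where(zero_var, 0.0, f)
        p = np.where(zero_var | (ms_err <= 0), 1.0, p)
        return f, p

    out: dict[str, np.ndarray] = {}
    for name, ss, df in (("genotype", ss_a, df_a), ("time", ss_b, df_b),
                         ("interaction", ss_ab, df_ab)):
        f, p = f_and_p(ss, df)
        out[f"F_{name}"] = f
        out[f"p_{name}"] = p
    return out


def _anova_unbalanced(y: np.ndarray, strains: np.ndarray,
                      times: np.ndarray) -> dict[str, np.ndarray]:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    n_genes = y.shape[0]
    out = {f"{k}_{e}": np.ones(n_genes)
           for k in ("F", "p") for e in ("genotype", "time", "interaction")}
    for e in ("genotype", "time", "interaction"):
        out[f"F_{e}"][:] = 0.0
    base = pd.DataFrame({"g": strains, "t": times})
    for i in range(n_genes):
        if np.ptp(y[i]) <= 1e-12:
            continue
        data = base.assign(y=y[i])
        fit = smf.ols("y ~ C(g) * C(t)", data=data).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        for e, row in (("genotype", "C(g)"), ("time", "C(t)"),
                       ("interaction", "C(g):C(t)")):
            out[f"F_{e}"][i] = tab.loc[row, "F"]
            out[f"p_{e}"][i] = tab.loc[row, "PR(>F)"]
    return out


def top_table(calls: pd.DataFrame, n: int = 20,
              annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """The n passing genes with the greatest fold induction.

    ``calls`` is the output of :func:`fold_changes` (or the WT columns of
    :func:`dependence`).  Ties in fold induction break by gene id.  When an
    annotation frame (indexed by gene id, e.g. with ``homologue`` /
    ``product`` columns) is supplied its columns are joined in.
    """
    passing = calls[calls["passes"]].copy()
    passing["_gid"] = passing.index.astype(str)
    passing = passing.sort_values(["fold_induction", "_gid"],
                                  ascending=[False, True],
                                  kind="mergesort").drop(columns="_gid")
    top = passing.head(n)
    if annotation is not None:
        top = top.join(annotation, how="left")
    return top
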