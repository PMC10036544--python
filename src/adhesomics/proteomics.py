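"""Label-free proteome processing: filter, normalise, impute, test.

The stage order is fixed: replication filter -> (log2 if linear input) ->
global robust-linear-regression normalisation -> first-pass minimum
imputation of group-wise all-missing rows -> second-pass predictive mean
matching -> variance-gated t-tests with Benjamini-Hochberg correction.
Proteins changing at least ``fold``-fold with q below ``q_thr`` are
called significantly differentially enriched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats_core import bh_adjust, variance_gated_t
from .synthio import AbundanceMatrix

__all__ = [
    "filter_replication",
    "log2_transform",
    "rlr_normalize",
    "impute_mnar_min",
    "impute_pmm",
    "differential_abundance",
    "run_prep",
]


def filter_replication(m: AbundanceMatrix, min_present: int = 2) -> AbundanceMatrix:
    """Keep proteins quantified in >= ``min_present`` replicates of some group."""
    sizes = {g: len(m.samples_of_group(g)) for g in m.group_labels}
    if min_present > max(sizes.values()):
        raise ValueError(
            f"min_present={min_present} exceeds every group size {sizes}"
        )
    keep = pd.Series(False, index=m.values.index)
    for g in m.group_labels:
        cols = m.samples_of_group(g)
        keep |= m.values[cols].notna().sum(axis=1) >= min_present
    return AbundanceMatrix(m.values.loc[keep].copy(), dict(m.groups))


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Binary-logarithm transform of linear-scale intensities (NaN preserved)."""
    vals = m.values.where(m.values > 0)
    return AbundanceMatrix(np.log2(vals), dict(m.groups))


def rlr_normalize(
    m: AbundanceMatrix,
    huber_t: float = 1.345,
    maxiter: int = 50,
    tol: float = 1e-8,
    min_overlap: int = 10,
) -> AbundanceMatrix:
    """Global robust-linear-regression normalisation against the median profile.

    The reference is the row-wise median across samples (observed values
    only). Each sample is regressed on the reference over co-observed rows
    with an iteratively reweighted Huber fit (tuning constant ``huber_t``),
    and the fitted systematic deviation is subtracted:
    ``normalised = raw - (fitted - reference)``. Missing cells stay missing.
    """
    if m.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    ref = m.values.median(axis=1, skipna=True)
    out = m.values.copy()
    for s in m.values.columns:
        col = m.values[s]
        co = col.notna() & ref.notna()
        if int(co.sum()) < min_overlap:
            raise ValueError(
                f"sample {s!r} shares only {int(co.sum())} observed rows with the reference"
            )
        X = sm.add_constant(ref[co].to_numpy())
        fit = sm.RLM(col[co].to_numpy(), X, M=sm.robust.norms.HuberT(t=huber_t)).fit(
            maxiter=maxiter, tol=tol
        )
        fitted_all = fit.params[0] + fit.params[1] * ref
        out[s] = col - (fitted_all - ref)
    return AbundanceMatrix(out, dict(m.groups))


def impute_mnar_min(m: AbundanceMatrix) -> AbundanceMatrix:
    """First-pass imputation for rows missing in all replicates of a group.

    Only cells belonging to a (row, group) block with zero observations are
    filled, each with the minimum observed value of its own sample column —
    emulating intensities censored below the detection floor. All other
    missing cells are left for the second pass.
    """
    out = m.values.copy()
    col_min = m.values.min(axis=0, skipna=True)
    if col_min.isna().any():
        empty = list(col_min.index[col_min.isna()])
        raise ValueError(f"columns with no observed values: {empty}")
    for g in m.group_labels:
        cols = m.samples_of_group(g)
        all_missing = m.values[cols].isna().all(axis=1)
        for s in cols:
            out.loc[all_missing, s] = col_min[s]
    return AbundanceMatrix(out, dict(m.groups))


def impute_pmm(
    m: AbundanceMatrix,
    donors: int = 5,
    chains_iters: int = 10,
    seed: int = 0,
) -> AbundanceMatrix:
    """Second-pass predictive mean matching by chained equations over samples.

    For each column with missing cells, the column is regressed on all other
    columns using its observed rows; regression coefficients are perturbed
    by a draw from their estimated sampling distribution; and each missing
    cell copies the observed value of one of the ``donors`` rows with the
    nearest perturbed prediction (uniform seeded choice). Sweeps repeat
    ``chains_iters`` times. Every imputed value is therefore an observed
    value of its own column.
    """
    X = m.values.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return m.copy()
    n_rows, n_cols = X.shape
    rng = np.random.default_rng(seed)

    # initial fill: column means of observed values
    for j in range(n_cols):
        obs = ~miss[:, j]
        if obs.sum() < donors + 1:
            raise ValueError(
                f"column {m.values.columns[j]!r} has fewer than donors+1 observed values"
            )
        X[miss[:, j], j] = X[obs, j].mean()

    for _ in range(chains_iters):
        for j in range(n_cols):
            mj = miss[:, j]
            if not mj.any():
                continue
            obs = ~mj
            others = [k for k in range(n_cols) if k != j]
            A = np.column_stack([np.ones(n_rows), X[:, others]])
            y = X[obs, j]
            Ao = A[obs]
            beta, *_ = np.linalg.lstsq(Ao, y, rcond=None)
            resid = y - Ao @ beta
            dof = max(1, Ao.shape[0] - Ao.shape[1])
            sigma2 = float(resid @ resid) / dof
            cov = sigma2 * np.linalg.pinv(Ao.T @ Ao)
            beta_star = rng.multivariate_normal(beta, cov, method="svd")
            pred = A @ beta_star
            pred_obs = pred[obs]
            y_obs = X[obs, j]
            k = min(donors, pred_obs.size)
            for i in np.flatnonzero(mj):
                d = np.abs(pred_obs - pred[i])
                cand = np.argpartition(d, k - 1)[:k]
                X[i, j] = y_obs[cand[rng.integers(k)]]
    out = pd.DataFrame(X, index=m.values.index, columns=m.values.columns)
    return AbundanceMatrix(out, dict(m.groups))


def differential_abundance(
    m: AbundanceMatrix,
    fold: float = 2.0,
    q_thr: float = 0.05,
    alpha_f: float = 0.05,
) -> pd.DataFrame:
    """Per-protein variance-gated t-tests with BH correction and fold gating.

    Returns a table with columns id, log2fc (second group minus first),
    t, df, variant, p, q, significant; ``significant`` requires both
    q < ``q_thr`` and |log2fc| >= log2(``fold``).
    """
    if m.values.isna().any().any():
        raise ValueError("matrix must be fully imputed before testing")
    labels = m.group_labels
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    g1 = m.values[m.samples_of_group(labels[0])].to_numpy()
    g2 = m.values[m.samples_of_group(labels[1])].to_numpy()
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")

    rows = []
    for i, pid in enumerate(m.values.index):
        res = variance_gated_t(g2[i], g1[i], alpha_f=alpha_f)
        rows.append(
            {
                "id": pid,
                "log2fc": float(g2[i].mean() - g1[i].mean()),
                "t": res.statistic,
                "df": res.df,
                "variant": res.variant.value,
                "p": res.p,
            }
        )
    table = pd.DataFrame(rows).set_index("id")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = (table["q"] < q_thr) & (
        table["log2fc"].abs() >= np.log2(fold)
    )
    return table


def run_prep(
    m: AbundanceMatrix,
    linear_scale: bool = False,
    min_present: int = 2,
    fold: float = 2.0,
    q_thr: float = 0.05,
    donors: int = 5,
    chains_iters: int = 10,
    seed: int = 0,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Full proteomics chain; returns the imputed matrix and the test table."""
    m = filter_replication(m, min_present=min_present)
    if linear_scale:
        m = log2_transform(m)
    m = rlr_normalize(m)
    m = impute_mnar_min(m)
    m = impute_pmm(m, donors=donors, chains_iters=chains_iters, seed=seed)
    table = differential_abundance(m, fold=fold, q_thr=q_thr)
    return m, table


# ---------------------------------------------------------------------------
# TSV interchange (empty cell = missing)

def read_abundance_tsv(path, groups: dict[str, str]) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceMatrix(df.astype(float), groups)


def write_abundance_tsv(m: AbundanceMatrix, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        m.values.to_csv(fh, sep="\t", na_rep="")
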