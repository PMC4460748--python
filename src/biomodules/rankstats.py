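"""Per-gene statistics feeding biomodule discovery.

Two genome-wide statistics are computed on the preprocessed log2 matrix:

* differential expression (DE) between two sample groups, as a moderated
  two-sample t-statistic — per-gene variances are shrunk toward a common
  prior estimated by matching moments of log sample variances (trigamma
  inversion), which adds ``prior_df`` pseudo-degrees of freedom and
  stabilises small-sample inference;
* co-expression (CE) with a chosen seed gene, as the Pearson correlation
  across all samples with the usual t-transform p-value.

P-values are converted to FDR q-values (Benjamini-Hochberg, or a Storey-type
variant that rescales BH by an estimate of the null proportion pi0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DataError
from .expression import ExpressionMatrix


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment estimates (prior_df d0, prior variance s0^2) from sample variances.

    Uses the log-variance representation: if s^2/s0^2 ~ F(df, d0), then
    var(log s^2) = trigamma(df/2) + trigamma(d0/2) and the mean identifies
    log s0^2.  Returns d0 = inf when the observed spread is at or below what
    sampling alone explains.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise DataError("not enough positive sample variances to estimate the prior")
    z = np.log(s2[ok])
    excess = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s02 = z.mean() - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        log_s02 = (
            z.mean()
            - special.polygamma(0, df / 2.0)
            + np.log(df / 2.0)
            + special.polygamma(0, d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    return float(d0), float(np.exp(log_s02))


def moderated_t(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t per gene (group_a is the case group).

    Returns a DataFrame with columns ``t``, ``logfc``, ``p``, ``s2``,
    ``flagged`` (zero variance in both groups); ``logfc`` is
    mean(group_a) - mean(group_b) on the log2 scale.  ``prior_df``
    overrides the estimated d0 (0 gives the ordinary t exactly; inf fully
    pools variances).  Estimated hyperparameters are stored in
    ``result.attrs['prior_df']`` and ``result.attrs['prior_var']``.
    """
    if m.phenotype is None:
        raise DataError("phenotype labels are required for differential expression")
    pheno = m.phenotype.astype(str)
    mask_a = (pheno == group_a).to_numpy()
    mask_b = (pheno == group_b).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise DataError(f"need >= 2 samples per group, got {n_a} vs {n_b}")

    Y = m.values.to_numpy(dtype=float)
    ya, yb = Y[:, mask_a], Y[:, mask_b]
    logfc = ya.mean(axis=1) - yb.mean(axis=1)
    df_resid = n_a + n_b - 2
    ss = ((ya - ya.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (yb - yb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    flagged = s2 <= 0

    if prior_df is None:
        if (s2 > 0).sum() < 2:
            d0, s02 = 0.0, 1.0  # prior inestimable: fall back to ordinary t
        else:
            d0, s02 = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s02 = (
            estimate_variance_prior(s2, df_resid)
            if np.isfinite(d0) and d0 > 0
            else (None, float(np.median(s2[~flagged])) if (~flagged).any() else 1.0)
        )
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = float(d0 + df_resid)

    c = np.sqrt(1.0 / n_a + 1.0 / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_post) * c)
    t = np.where(flagged & (logfc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(flagged & (logfc == 0), 1.0, p)
    if np.any(flagged & (logfc != 0) & ~np.isfinite(t)):
        # all-constant gene with a group offset: infinite evidence; p -> 0
        p = np.where(flagged & (logfc != 0) & ~np.isfinite(t), 0.0, p)

    out = pd.DataFrame(
        {"t": t, "logfc": logfc, "p": p, "s2": s2, "flagged": flagged},
        index=m.values.index,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s02
    out.attrs["df_residual"] = df_resid
    return out


# ---------------------------------------------------------------------------
# Seed correlation
# ---------------------------------------------------------------------------

def seed_correlation(m: ExpressionMatrix, seed_gene: str) -> pd.DataFrame:
    """Pearson correlation of every gene with ``seed_gene`` across samples."""
    if seed_gene not in m.values.index:
        raise DataError(f"seed gene {seed_gene!r} is not in the expression matrix")
    Y = m.values.to_numpy(dtype=float)
    n = Y.shape[1]
    if n < 3:
        raise DataError("seed correlation needs >= 3 samples")
    seed = m.values.loc[seed_gene].to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sc = seed - seed.mean()
    denom = np.sqrt((Yc**2).sum(axis=1) * (sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ sc) / denom
    r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return pd.DataFrame({"r": r, "p": p}, index=m.values.index)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def qvalues(p, method: str = "bh") -> np.ndarray:
    """FDR q-values: ``bh`` (Benjamini-Hochberg) or ``storey``.

    The Storey variant rescales BH by pi0 = min(1, mean(p > 0.5)/0.5)
    (single fixed lambda = 0.5), so storey q <= bh q genewise.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q_bh, *_ = multipletests(p, method="fdr_bh")
    if method == "bh":
        return q_bh
    if method == "storey":
        pi0 = min(1.0, float((p > 0.5).mean()) / 0.5)
        return np.minimum(1.0, pi0 * q_bh)
    raise ValueError(f"method must be bh or storey, got {method!r}")


# ---------------------------------------------------------------------------
# Assembled per-gene statistics
# ---------------------------------------------------------------------------

def ranked_gene_stats(
    m: ExpressionMatrix,
    seed_gene: str,
    group_a: str,
    group_b: str,
    q_method: str = "bh",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Joint DE + CE table: de_stat, logfc, de_p, de_q, ce_r, ce_p, ce_q."""
    de = moderated_t(m, group_a, group_b, prior_df=prior_df)
    ce = seed_correlation(m, seed_gene)
    out = pd.DataFrame(
        {
            "de_stat": de["t"],
            "logfc": de["logfc"],
            "de_p": de["p"],
            "de_q": qvalues(de["p"].to_numpy(), method=q_method),
            "ce_r": ce["r"],
            "ce_p": ce["p"],
            "ce_q": qvalues(ce["p"].to_numpy(), method=q_method),
        },
        index=m.values.index,
    )
    out.attrs["seed_gene"] = seed_gene
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    out.attrs["prior_df"] = de.attrs["prior_df"]
    return out


def select_de_genes(
    stats: pd.DataFrame, q_max: float = 0.05, fc_min: float = 2.0
) -> tuple[set[str], set[str]]:
    """Significant genes split by direction: q < q_max and FC >= fc_min (or <= 1/fc_min)."""
    fc = np.power(2.0, stats["logfc"].to_numpy(dtype=float))
    sig = stats["de_q"].to_numpy(dtype=float) < q_max
    up = set(stats.index[sig & (fc >= fc_min)])
    down = set(stats.index[sig & (fc <= 1.0 / fc_min)])
    return up, down
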