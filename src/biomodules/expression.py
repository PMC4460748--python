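"""Expression-matrix preprocessing.

Covers the steps between a normalized log2 expression matrix and the
per-gene statistics: collapsing probes to genes (max-mean probe per gene),
removing dataset batch effects with a parametric empirical-Bayes
location-scale adjustment, and keeping the most variable half of genes by
interquartile range.

The batch model follows the standard parametric scheme: per gene, data are
standardized against a design containing batch indicators (plus the
phenotype when it is protected), batch location effects gamma and scale
effects delta^2 are estimated per batch, shrunk toward normal /
inverse-gamma priors whose hyperparameters come from moments across genes,
and the shrunken effects are removed.  Protecting the phenotype keeps true
group differences out of the batch estimates; it is on by default because
case/control membership is typically unbalanced across datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError


@dataclass
class ExpressionMatrix:
    """genes x samples log2 expression with per-sample phenotype and batch."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    phenotype: pd.Series | None = None
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        for name in ("phenotype", "batch"):
            s = getattr(self, name)
            if s is not None:
                s = s.reindex(self.values.columns)
                if s.isna().any():
                    missing = list(s.index[s.isna()][:5])
                    raise ValidationError(f"{name} missing for samples {missing}")
                setattr(self, name, s)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, phenotype=self.phenotype, batch=self.batch)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-in-rows TSV matrix (first column = gene id header row = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_matrix(values: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> Path:
    path = Path(path)
    values.to_csv(path, sep="\t", index_label=index_label)
    return path


def read_sample_sheet(path: str | Path) -> tuple[pd.Series, pd.Series]:
    """Read a 3-column sample sheet TSV (sample_id, group, batch)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample_id", "group", "batch"]
    if list(df.columns[:3]) != expected:
        raise DataError(f"sample sheet must have columns {expected}, got {list(df.columns)}")
    df = df.set_index("sample_id")
    return df["group"], df["batch"]


def write_sample_sheet(phenotype: pd.Series, batch: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": phenotype.index, "group": phenotype.values, "batch": batch.values}).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# Probe collapse
# ---------------------------------------------------------------------------

def collapse_probes(
    probe_values: pd.DataFrame, probe_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes by max mean expression.

    For each gene the retained row is the mapped probe with the largest row
    mean (ties broken by probe id, lexically).  Unmapped probes are dropped.
    """
    mapped = [p for p in probe_values.index if p in probe_map]
    if not mapped:
        raise DataError("no probe in the matrix is present in the probe map")
    sub = probe_values.loc[mapped]
    means = sub.mean(axis=1)
    choice: dict[str, str] = {}
    for probe in sorted(mapped):  # lexical order makes ties deterministic
        gene = probe_map[probe]
        if gene not in choice or means[probe] > means[choice[gene]]:
            choice[gene] = probe
    genes = sorted(choice)
    out = sub.loc[[choice[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene_id")
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes batch correction
# ---------------------------------------------------------------------------

def correct_batches(m: ExpressionMatrix, protect: bool = True) -> ExpressionMatrix:
    """Remove additive/multiplicative batch effects by parametric empirical Bayes.

    With ``protect`` the phenotype enters the design as a covariate so group
    differences survive the correction; a batch confounded 1:1 with the
    phenotype is then inestimable and raises :class:`DataError`.
    A single batch returns the input unchanged.
    """
    if m.batch is None:
        raise DataError("batch labels are required for batch correction")
    batches = m.batch.astype(str)
    levels = sorted(batches.unique())
    if len(levels) == 1:
        return m.copy_with(m.values.copy())
    sizes = batches.value_counts()
    small = [b for b in levels if sizes[b] < 2]
    if small:
        raise DataError(f"each batch needs >= 2 samples; too small: {small}")

    Y = m.values.to_numpy(dtype=float)  # genes x samples
    n_genes, n_samples = Y.shape

    batch_onehot = np.column_stack(
        [(batches == b).to_numpy(dtype=float) for b in levels]
    )
    covariates = np.empty((n_samples, 0))
    if protect:
        if m.phenotype is None:
            raise DataError("protect=True requires phenotype labels")
        pheno = m.phenotype.astype(str)
        plevels = sorted(pheno.unique())
        covariates = np.column_stack(
            [(pheno == p).to_numpy(dtype=float) for p in plevels[1:]]
        ) if len(plevels) > 1 else covariates
    X = np.hstack([batch_onehot, covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError(
            "design is confounded: a batch coincides with a phenotype group; "
            "batch effects are inestimable with protect=True"
        )

    B_hat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p x genes)
    n_b = np.array([sizes[b] for b in levels], dtype=float)
    grand = (n_b / n_samples) @ B_hat[: len(levels)]  # weighted grand mean per gene
    stand_mean = np.outer(grand, np.ones(n_samples))
    if covariates.shape[1]:
        stand_mean += (covariates @ B_hat[len(levels):]).T
    resid = Y - (X @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    if np.any(var_pooled <= 0):
        raise DataError("genes with zero residual variance cannot be standardized")
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    corrected = Z.copy()
    # per-batch location/scale estimates across genes
    gamma_hat = np.column_stack(
        [Z[:, (batches == b).to_numpy()].mean(axis=1) for b in levels]
    )  # genes x batches
    delta_hat = np.column_stack(
        [Z[:, (batches == b).to_numpy()].var(axis=1, ddof=1) for b in levels]
    )
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    # inverse-gamma moments for the scale prior
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)

    for k, b in enumerate(levels):
        mask = (batches == b).to_numpy()
        nb = mask.sum()
        if d_var[k] <= 1e-12 and tau2[k] <= 1e-12:
            # degenerate priors (identical effects across genes): no shrinkage
            g_star = gamma_hat[:, k]
            d_star = delta_hat[:, k]
        else:
            a_prior = (2 * d_var[k] + d_mean[k] ** 2) / d_var[k] if d_var[k] > 1e-12 else None
            b_prior = (
                (d_mean[k] * d_var[k] + d_mean[k] ** 3) / d_var[k] if d_var[k] > 1e-12 else None
            )
            g_star, d_star = _it_sol(
                Z[:, mask], gamma_hat[:, k], delta_hat[:, k],
                gamma_bar[k], tau2[k], a_prior, b_prior,
            )
        corrected[:, mask] = (Z[:, mask] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = corrected * sd + stand_mean
    return m.copy_with(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def _it_sol(Zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior, conv=1e-4, max_iter=200):
    """Iterate the EB posterior for one batch's location/scale effects."""
    nb = Zb.shape[1]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    for _ in range(max_iter):
        if t2 > 1e-12:
            g_new = (nb * t2 * g_hat + d_old * g_bar) / (nb * t2 + d_old)
        else:
            g_new = np.full_like(g_hat, g_bar)
        sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        if a_prior is None:
            d_new = d_old
        else:
            d_new = (0.5 * sum2 + b_prior) / (nb / 2 + a_prior - 1)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


# ---------------------------------------------------------------------------
# IQR filter
# ---------------------------------------------------------------------------

def iqr_filter(
    m: ExpressionMatrix, keep_fraction: float = 0.5, always_keep: set | frozenset = frozenset()
) -> ExpressionMatrix:
    """Keep the ceil(keep_fraction * G) genes with the largest IQR.

    The IQR uses linear-interpolation quantiles (numpy's default, R type 7).
    Ties in IQR are broken by gene id so the retained set is deterministic.
    Genes in ``always_keep`` (e.g. the seed gene under study) are retained
    regardless of their IQR, in addition to the quota.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if m.n_samples < 2:
        raise DataError("IQR filtering needs at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    q75, q25 = np.percentile(vals, [75, 25], axis=1)
    iqr = q75 - q25
    n_keep = math.ceil(keep_fraction * m.n_genes)
    order = sorted(range(m.n_genes), key=lambda i: (-iqr[i], m.values.index[i]))
    kept = set(order[:n_keep])
    kept |= {i for i in range(m.n_genes) if m.values.index[i] in always_keep}
    return m.copy_with(m.values.iloc[sorted(kept)].copy())
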