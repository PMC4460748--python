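"""Biomodule discovery from two independently ordered gene lists.

Two genome-wide statistics — co-expression with a seed gene and
case/control differential expression — each order the gene universe.  If
the seed sits in a co-regulated, disease-associated program, the two
orders agree at their informative extremes far more than chance allows.
The agreement is measured by the overlap step function
O(n) = |top-n(A) ∩ top-n(B)| and summarised by an exponentially
rank-weighted score sum_n exp(-beta*n) * O(n); under independence O(n) is
Hypergeometric(N, n, n) with mean n^2/N.  Significance comes from an
empirical permutation null (one list's order shuffled), and the biomodule
itself is the intersection of the two top-n prefixes (default n = 150).
Top and bottom ends of the lists are scored separately, since agreement is
typically one-sided (e.g. genes both up in cases and positively correlated
with the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

DEFAULT_N_TOP = 150
DEFAULT_PERMUTATIONS = 1000


@dataclass
class OrderedList:
    """Gene ids sorted best-first by a statistic (ties broken by gene id)."""

    genes: np.ndarray  # object array of gene ids, best first
    values: np.ndarray  # statistic aligned with `genes`

    @classmethod
    def from_stats(cls, gene_ids, values, descending: bool = True) -> "OrderedList":
        gene_ids = np.asarray(list(gene_ids), dtype=object)
        values = np.asarray(values, dtype=float)
        if gene_ids.shape != values.shape:
            raise ValueError("gene_ids and values must have equal length")
        key = -values if descending else values
        order = np.lexsort((gene_ids, key))
        return cls(genes=gene_ids[order], values=values[order])

    def __len__(self) -> int:
        return len(self.genes)

    def ranks(self) -> dict:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class OverlapCurve:
    n: np.ndarray  # 1..n_max
    top: np.ndarray  # O(n) over the top prefixes
    bottom: np.ndarray  # O(n) over the bottom prefixes
    universe_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n, "overlap_top": self.top, "overlap_bottom": self.bottom})


@dataclass
class SimilarityResult:
    score: float
    empirical_p: float
    n_permutations: int
    direction: str  # top | bottom | two-sided
    beta: float
    n_max: int
    seed: int | None
    null_scores: np.ndarray | None = None


@dataclass
class Biomodule:
    genes: set
    n_top: int
    seed_gene: str | None
    similarity: SimilarityResult | None

    def __len__(self) -> int:
        return len(self.genes)

    def summary(self) -> dict:
        out = dict(n_genes=len(self.genes), n_top=self.n_top, seed_gene=self.seed_gene)
        if self.similarity is not None:
            out.update(
                similarity_score=self.similarity.score,
                empirical_p=self.similarity.empirical_p,
                n_permutations=self.similarity.n_permutations,
                direction=self.similarity.direction,
            )
        return out


# ---------------------------------------------------------------------------
# Overlap machinery
# ---------------------------------------------------------------------------

def _check_universe(a: OrderedList, b: OrderedList) -> int:
    set_a, set_b = set(a.genes), set(b.genes)
    if set_a != set_b or len(a) != len(b):
        offending = sorted(map(str, set_a ^ set_b))[:10]
        raise DataError(f"ordered lists differ in gene universe: {offending}")
    return len(a)


def _max_ranks(a: OrderedList, b: OrderedList, from_bottom: bool = False) -> np.ndarray:
    """For each gene, 1-based max of its ranks in the two lists."""
    ranks_b = b.ranks()
    idx_b = np.fromiter((ranks_b[g] for g in a.genes), count=len(a), dtype=np.int64)
    idx_a = np.arange(len(a), dtype=np.int64)
    if from_bottom:
        n = len(a)
        idx_a = n - 1 - idx_a
        idx_b = n - 1 - idx_b
    return np.maximum(idx_a, idx_b) + 1


def _curve_from_max_ranks(max_ranks: np.ndarray, n_max: int) -> np.ndarray:
    counts = np.bincount(max_ranks[max_ranks <= n_max], minlength=n_max + 1)
    return np.cumsum(counts[1:])


def overlap_curve(a: OrderedList, b: OrderedList, n_max: int | None = None) -> OverlapCurve:
    """Overlap step function O(n) for n = 1..n_max, top and bottom prefixes."""
    N = _check_universe(a, b)
    if n_max is None:
        n_max = N
    if not 1 <= n_max <= N:
        raise ValueError(f"n_max must be in [1, {N}]")
    top = _curve_from_max_ranks(_max_ranks(a, b), n_max)
    bottom = _curve_from_max_ranks(_max_ranks(a, b, from_bottom=True), n_max)
    return OverlapCurve(n=np.arange(1, n_max + 1), top=top, bottom=bottom, universe_size=N)


def expected_overlap_ci(N: int, n: int) -> tuple[float, float, float]:
    """Mean and central 95% interval of the chance overlap at rank n.

    Under independent orders, O(n) ~ Hypergeometric(N, n, n): drawing the
    top-n of one list and asking how many fall in the other's top-n.
    """
    if not 1 <= n <= N:
        raise ValueError("need 1 <= n <= N")
    dist = stats.hypergeom(N, n, n)
    lo, hi = dist.ppf(0.025), dist.ppf(0.975)
    return n * n / N, float(lo), float(hi)


def _weights(beta: float, n_max: int) -> np.ndarray:
    # suffix sums of e^{-beta*n}: a gene first counted at rank m contributes
    # sum_{n=m}^{n_max} e^{-beta n} to the score
    w = np.exp(-beta * np.arange(1, n_max + 1, dtype=float))
    return np.cumsum(w[::-1])[::-1]


def _score_from_max_ranks(max_ranks: np.ndarray, weights: np.ndarray, n_max: int) -> float:
    sel = max_ranks[max_ranks <= n_max]
    return float(weights[sel - 1].sum())


def similarity_score(
    a: OrderedList,
    b: OrderedList,
    beta: float | None = None,
    n_max: int = DEFAULT_N_TOP,
) -> dict[str, float]:
    """Exponentially rank-weighted overlap score, top and bottom separately.

    score = sum_{n=1..n_max} exp(-beta*n) * O(n); beta defaults to 1/n_max
    (e-fold decay at the rank threshold), beta = 0 gives the plain sum of
    the overlap curve.
    """
    N = _check_universe(a, b)
    n_max = min(n_max, N)
    if beta is None:
        beta = 1.0 / n_max
    if beta < 0:
        raise ValueError("beta must be >= 0")
    w = _weights(beta, n_max)
    return {
        "top": _score_from_max_ranks(_max_ranks(a, b), w, n_max),
        "bottom": _score_from_max_ranks(_max_ranks(a, b, from_bottom=True), w, n_max),
    }


def permutation_pvalue(
    a: OrderedList,
    b: OrderedList,
    B: int = DEFAULT_PERMUTATIONS,
    beta: float | None = None,
    n_max: int = DEFAULT_N_TOP,
    seed: int | None = None,
    direction: str = "top",
    keep_null: bool = False,
) -> SimilarityResult:
    """Empirical p-value of the similarity score under permuted gene order.

    List ``b``'s order is permuted uniformly B times (equivalent in
    distribution to permuting both).  The add-one estimator
    p = (1 + #{null >= observed}) / (B + 1) keeps p strictly positive.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if direction not in ("top", "bottom", "two-sided"):
        raise ValueError("direction must be top, bottom or two-sided")
    N = _check_universe(a, b)
    n_max = min(n_max, N)
    if beta is None:
        beta = 1.0 / n_max
    w = _weights(beta, n_max)

    def scores(idx_b: np.ndarray) -> tuple[float, float]:
        idx_a = np.arange(N)
        top = _score_from_max_ranks(np.maximum(idx_a, idx_b) + 1, w, n_max)
        bot = _score_from_max_ranks(np.maximum(N - 1 - idx_a, N - 1 - idx_b) + 1, w, n_max)
        return top, bot

    ranks_b = b.ranks()
    idx_b_obs = np.fromiter((ranks_b[g] for g in a.genes), count=N, dtype=np.int64)
    obs_top, obs_bot = scores(idx_b_obs)

    rng = np.random.default_rng(seed)
    perms = np.empty((B, N), dtype=np.int64)
    base = np.arange(N, dtype=np.int64)
    for i in range(B):
        perms[i] = rng.permutation(base)
    idx_a = np.arange(N, dtype=np.int64)
    mx_top = np.maximum(idx_a[None, :], perms) + 1
    mx_bot = np.maximum(N - 1 - idx_a[None, :], N - 1 - perms) + 1
    w_ext = np.concatenate([w, [0.0]])
    null_top = w_ext[np.minimum(mx_top, n_max + 1) - 1].sum(axis=1)
    null_bot = w_ext[np.minimum(mx_bot, n_max + 1) - 1].sum(axis=1)

    if direction == "top":
        obs, null = obs_top, null_top
    elif direction == "bottom":
        obs, null = obs_bot, null_bot
    else:
        obs = max(obs_top, obs_bot)
        null = np.maximum(null_top, null_bot)
    p = (1.0 + float(np.sum(null >= obs))) / (B + 1.0)
    return SimilarityResult(
        score=float(obs),
        empirical_p=float(p),
        n_permutations=B,
        direction=direction,
        beta=float(beta),
        n_max=int(n_max),
        seed=seed,
        null_scores=null.copy() if keep_null else None,
    )


# ---------------------------------------------------------------------------
# Biomodule extraction
# ---------------------------------------------------------------------------

def ordered_lists_from_stats(
    stats_df: pd.DataFrame, direction: str = "up-positive"
) -> tuple[OrderedList, OrderedList]:
    """CE and DE ordered lists from a ranked_gene_stats table.

    ``up-positive``: both lists best-first for positive correlation with the
    seed and up-regulation in the case group; ``down-negative`` reverses
    both.
    """
    if direction not in ("up-positive", "down-negative"):
        raise ValueError("direction must be up-positive or down-negative")
    descending = direction == "up-positive"
    ce = OrderedList.from_stats(stats_df.index, stats_df["ce_r"].to_numpy(), descending=descending)
    de = OrderedList.from_stats(stats_df.index, stats_df["de_stat"].to_numpy(), descending=descending)
    return ce, de


def extract_biomodule(
    stats_df: pd.DataFrame,
    n_top: int = DEFAULT_N_TOP,
    direction: str = "up-positive",
    B: int = DEFAULT_PERMUTATIONS,
    beta: float | None = None,
    seed: int | None = None,
) -> Biomodule:
    """Genes in the top-n of both orderings, with permutation significance.

    Rank-based throughout, hence invariant to strictly monotone transforms
    of either statistic.
    """
    N = len(stats_df)
    if n_top > N:
        raise DataError(f"n_top={n_top} exceeds the {N}-gene universe")
    ce, de = ordered_lists_from_stats(stats_df, direction=direction)
    module = set(ce.genes[:n_top]) & set(de.genes[:n_top])
    similarity = permutation_pvalue(
        ce, de, B=B, beta=beta, n_max=n_top, seed=seed, direction="top"
    )
    return Biomodule(
        genes=module,
        n_top=n_top,
        seed_gene=stats_df.attrs.get("seed_gene"),
        similarity=similarity,
    )
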