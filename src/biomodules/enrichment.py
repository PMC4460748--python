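"""Gene-set over-representation with a restricted ("true") background.

The biomodule is tested against a GMT collection with a hypergeometric
upper-tail test whose universe is conditioned on the genes that are both
covered by the experiment and present somewhere in the collection — the
only genes that could ever have appeared in either margin of the 2x2
table.  Using the full genome as background would overstate significance
for sets of well-measured genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, FormatError
from .rankstats import qvalues

DEFAULT_P_MAX = 0.001
DEFAULT_MIN_COUNT = 6  # "count > 5"


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset
    category: str = ""


class GeneSetCollection:
    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._sets:
                raise DataError(f"duplicate gene-set name {gs.name!r}")
            if not gs.members:
                raise DataError(f"gene set {gs.name!r} has no members")
            self._sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def all_members(self) -> set:
        out: set = set()
        for gs in self:
            out |= gs.members
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, members...); members deduplicated."""
    path = Path(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=name, description=desc, members=members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")
    return path


@dataclass
class EnrichmentResult:
    name: str
    category: str
    description: str
    set_size: int  # full set size
    set_size_background: int  # K, after background restriction
    module_size: int  # m, after background restriction
    background_size: int  # N
    count: int  # a = overlap
    p: float
    q: float
    odds_ratio: float


def hypergeom_tail(a: int, N: int, K: int, m: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, m)."""
    return float(stats.hypergeom.sf(a - 1, N, K, m))


def _odds_ratio(a: int, K: int, m: int, N: int) -> float:
    b = K - a  # in set, not module
    c = m - a  # in module, not set
    d = N - K - m + a
    if b == 0 and c == 0:
        return float("inf")  # module == set within background
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane-Anscombe
        return (a_ * d_) / (b_ * c_)
    return (a * d) / (b * c)


def enrich(
    module: set,
    collection: GeneSetCollection,
    assay_genes: set,
    p_max: float = DEFAULT_P_MAX,
    min_count: int = DEFAULT_MIN_COUNT,
    q_max: float | None = None,
    filtered: bool = True,
) -> list[EnrichmentResult]:
    """Conditional hypergeometric over-representation of ``module``.

    The background N is ``assay_genes`` intersected with the union of all
    collection members; each set's size K and the module size m are also
    restricted to the background before testing.  Results are filtered to
    p <= p_max and count >= min_count (or by BH q when ``q_max`` is given)
    and sorted by p; ``filtered=False`` returns every testable set.  BH q
    over all testable sets is always reported alongside.
    """
    module, assay_genes = set(module), set(assay_genes)
    if not module <= assay_genes:
        raise DataError("module must be a subset of the assayed genes")
    background = assay_genes & collection.all_members()
    if not background:
        raise DataError("empty background: no assayed gene appears in the collection")
    N = len(background)
    m_genes = module & background
    m = len(m_genes)

    rows = []
    for gs in collection:
        members_bg = gs.members & background
        K = len(members_bg)
        if K == 0:
            continue
        a = len(m_genes & members_bg)
        rows.append((gs, K, a, hypergeom_tail(a, N, K, m)))
    if not rows:
        raise DataError("no gene set overlaps the background")
    qs = qvalues(np.array([r[3] for r in rows]), method="bh")
    results = [
        EnrichmentResult(
            name=gs.name,
            category=gs.category,
            description=gs.description,
            set_size=len(gs.members),
            set_size_background=K,
            module_size=m,
            background_size=N,
            count=a,
            p=p,
            q=float(q),
            odds_ratio=_odds_ratio(a, K, m, N),
        )
        for (gs, K, a, p), q in zip(rows, qs)
    ]
    if filtered:
        if q_max is not None:
            results = [r for r in results if r.q <= q_max and r.count >= min_count]
        else:
            results = [r for r in results if r.p <= p_max and r.count >= min_count]
    results.sort(key=lambda r: (r.p, r.name))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as a DataFrame (TSV-ready, Table-style columns)."""
    return pd.DataFrame(
        [
            dict(
                name=r.name,
                category=r.category,
                description=r.description,
                size=r.set_size,
                size_background=r.set_size_background,
                count=r.count,
                module_size=r.module_size,
                background_size=r.background_size,
                p=r.p,
                q=r.q,
                odds_ratio=r.odds_ratio,
            )
            for r in results
        ],
        columns=[
            "name", "category", "description", "size", "size_background",
            "count", "module_size", "background_size", "p", "q", "odds_ratio",
        ],
    )
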