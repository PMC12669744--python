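"""Hypergeometric gene-set enrichment of outlier gene lists.

The test asks: drawing the outlier list (size n) uniformly from the
universe of N analysed genes, of which K belong to the set, how likely is
an overlap of at least the observed k?  The p-value is the upper tail
P(X >= k) of Hypergeom(N, K, n) — a one-sided, enrichment-only test.
K is always computed within the universe (genes with at least one
qualifying variant), not the nominal set size: only genes that could have
been called outliers belong in the null.

P-values from all tests in a run are adjusted together, by
Benjamini-Hochberg (default) or Bonferroni; a result is flagged
significant at adjusted p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05
ADJUST_METHODS = {"bh": "fdr_bh", "bonferroni": "bonferroni"}


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    list_name: str
    set_name: str
    universe_size: int  # N
    set_in_universe: int  # K
    list_size: int  # n
    overlap: int  # k
    p_value: float
    adjusted_p: float | None = None
    significant: bool | None = None

    def to_dict(self) -> dict:
        return {
            "list": self.list_name,
            "set": self.set_name,
            "N": self.universe_size,
            "K": self.set_in_universe,
            "n": self.list_size,
            "k": self.overlap,
            "p": self.p_value,
            "adj_p": self.adjusted_p,
            "significant": self.significant,
        }


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, K, n).

    X counts set members in a uniform draw of n genes from a universe of
    N genes containing K set members.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_list: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    *,
    list_name: str = "outliers",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of one gene list against each gene set.

    Symbols are matched exactly after upper-casing.  List members absent
    from the universe are dropped with a warning (they could never have
    been drawn); set sizes K are likewise intersected with the universe.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise UsageError("enrichment universe is empty")
    listed = [g.upper() for g in gene_list]
    in_universe = [g for g in listed if g in universe_set]
    dropped = len(listed) - len(in_universe)
    if dropped:
        logger.warning(
            "%s: %d gene(s) not in the universe dropped from the list",
            list_name,
            dropped,
        )
    list_set = set(in_universe)
    N, n = len(universe_set), len(list_set)
    results = []
    for gs in sets:
        members = {m.upper() for m in gs.members}
        K = len(members & universe_set)
        k = len(members & list_set)
        results.append(
            EnrichmentResult(
                list_name=list_name,
                set_name=gs.name,
                universe_size=N,
                set_in_universe=K,
                list_size=n,
                overlap=k,
                p_value=hypergeometric_tail(N, K, n, k),
            )
        )
    return results


def adjust_pvalues(
    results: Sequence[EnrichmentResult], method: str = "bh"
) -> list[EnrichmentResult]:
    """Fill adjusted p-values across all results of a run (one family)."""
    if not results:
        raise UsageError("no enrichment results to adjust")
    if method not in ADJUST_METHODS:
        raise UsageError(f"unknown adjustment method {method!r}; use bh or bonferroni")
    pvals = [r.p_value for r in results]
    _, adjusted, _, _ = multipletests(pvals, method=ADJUST_METHODS[method])
    return [
        replace(r, adjusted_p=float(p), significant=bool(p < SIGNIFICANCE_LEVEL))
        for r, p in zip(results, adjusted)
    ]


def load_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file, or one set from a one-symbol-per-line file.

    GMT lines are ``name<TAB>description<TAB>member...``.  Symbols are
    upper-cased; duplicates within a set are dropped with a warning.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: no gene sets found")
    is_gmt = path.suffix.lower() == ".gmt" or any("\t" in ln for ln in lines)
    sets: list[GeneSet] = []
    if is_gmt:
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: GMT line needs name, description and >= 1 member: {ln!r}"
                )
            name, _desc, *members = fields
            sets.append(_build_set(name, members, path))
    else:
        sets.append(_build_set(path.stem, lines, path))
    return sets


def _build_set(name: str, raw_members: Iterable[str], path: Path) -> GeneSet:
    cleaned = [m.strip().upper() for m in raw_members if m.strip()]
    unique = set(cleaned)
    if len(unique) < len(cleaned):
        logger.warning(
            "%s: set %r had %d duplicate symbol(s) after case-folding",
            path,
            name,
            len(cleaned) - len(unique),
        )
    if not unique:
        raise FormatError(f"{path}: gene set {name!r} is empty after parsing")
    return GeneSet(name=name, members=frozenset(unique))


def write_gmt(sets: Sequence[GeneSet], path: str | Path, *, description: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.members)]) + "\n")


def results_table(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in results])
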