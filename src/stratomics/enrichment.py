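"""Fisher-exact gene-set enrichment and metabolite composition summaries.

The test is one-sided (enrichment): with a = |hits in set|, b = |set not
hit|, c = |hits outside set|, d = |rest|, the p-value is the upper
hypergeometric tail P(X >= a) and the odds ratio is a*d / (b*c) without
continuity correction (infinite when b*c = 0 and a*d > 0).  GO-style
collections are size-filtered to sets with 10-500 in-universe genes;
KEGG-style collections are not filtered.  Pathway p-values are reported raw
against the 0.05 cutoff; a BH column is emitted for information only.

The gene universe is the unique gene symbols of the post-QC analytes of the
analyzed stratum; a gene is a hit if any of its aptamers is called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DegenerateInputError, GeneSetCollection, StratomicsError
from .stratified_association import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentConfig:
    go_min_size: int = 10
    go_max_size: int = 500
    p_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.go_min_size < self.go_max_size:
            raise StratomicsError("need 0 < go_min_size < go_max_size")


@dataclass
class EnrichmentResult:
    set_name: str
    a: int                 # hits in set
    b: int                 # set members not hit
    c: int                 # hits outside set
    d: int                 # neither
    odds_ratio: float
    p: float
    size_in_universe: int
    passed: bool = False


def fisher_gene_set_test(hits: set[str], gene_set: set[str],
                         universe: set[str],
                         set_name: str = "") -> EnrichmentResult:
    """One-sided (greater) Fisher test of hit enrichment in a gene set.

    ``gene_set`` is intersected with the universe before counting; ``hits``
    must be a subset of the universe.
    """
    if not universe:
        raise StratomicsError("empty gene universe")
    hits = set(hits)
    if not hits <= set(universe):
        stray = sorted(hits - set(universe))[:5]
        raise StratomicsError(f"hits outside universe: {stray}")
    in_set = set(gene_set) & set(universe)
    n_universe = len(universe)
    a = len(hits & in_set)
    b = len(in_set) - a
    c = len(hits) - a
    d = n_universe - a - b - c
    p = float(stats.hypergeom.sf(a - 1, n_universe, len(in_set), len(hits)))
    if b * c > 0:
        odds = a * d / (b * c)
    elif a * d > 0:
        odds = np.inf
    else:
        odds = np.nan
    return EnrichmentResult(set_name=set_name, a=a, b=b, c=c, d=d,
                            odds_ratio=odds, p=min(p, 1.0),
                            size_in_universe=len(in_set))


def enrich_collection(hits: set[str], collection: GeneSetCollection,
                      universe: set[str],
                      config: EnrichmentConfig | None = None,
                      mode: str = "go") -> pd.DataFrame:
    """Test every set of a collection; GO mode applies the [min, max]
    in-universe size filter, KEGG mode tests all sets.

    Results are sorted ascending by p (ties by set name) with ``passed``
    marking p <= cutoff and an informational BH column.
    """
    config = config or EnrichmentConfig()
    if mode not in ("go", "kegg"):
        raise StratomicsError(f"unknown enrichment mode {mode!r}")
    if len(collection) == 0:
        raise DegenerateInputError("empty gene-set collection")
    rows = []
    for name, _, members in collection:
        res = fisher_gene_set_test(hits, set(members), universe, set_name=name)
        if mode == "go" and not (config.go_min_size <= res.size_in_universe
                                 <= config.go_max_size):
            continue
        rows.append((res.set_name, res.size_in_universe, res.a, res.b,
                     res.c, res.d, res.odds_ratio, res.p))
    table = pd.DataFrame(rows, columns=["set", "size_in_universe", "a", "b",
                                        "c", "d", "odds_ratio", "p"])
    if len(table) == 0:
        table["bh"] = []
        table["passed"] = []
        return table
    table["bh"] = bh_fdr(table["p"].to_numpy())
    table["passed"] = table["p"] <= config.p_cutoff
    table = table.sort_values(["p", "set"], kind="mergesort")
    return table.reset_index(drop=True)


def composition_summary(called: pd.DataFrame,
                        annotation: pd.Series | dict) -> pd.DataFrame:
    """Per-super-pathway composition of the called metabolites, split by
    direction.

    ``called`` needs columns ``analyte_id`` and ``direction``; ``annotation``
    maps analyte id to super-pathway.  Unannotated metabolites fall into an
    ``unknown`` bucket with a warning.  Fractions sum to 1 within each
    direction group.
    """
    if len(called) == 0:
        raise DegenerateInputError("no called metabolites to summarize")
    ann = pd.Series(annotation)
    mapped = called["analyte_id"].map(ann)
    n_unknown = int(mapped.isna().sum())
    if n_unknown:
        logger.warning("%d called metabolites lack a super-pathway annotation",
                       n_unknown)
    frame = pd.DataFrame({
        "direction": called["direction"].to_numpy(),
        "super_pathway": mapped.fillna("unknown").to_numpy(),
    })
    counts = (frame.groupby(["direction", "super_pathway"], sort=True)
              .size().rename("count").reset_index())
    totals = counts.groupby("direction")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts
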