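"""Gene-set over-representation analysis.

For each gene set, a 2x2 table is built from: nf flagged genes in the set,
n genes in the set (after intersection with the universe), Nf flagged genes
in the universe, N universe genes.  Significance comes from the two-sided
Fisher exact test (hypergeometric) or a chi-square test with continuity
correction; the enrichment ratio is

    Re = (nf / n) / (Nf / N)

i.e. the flagged fraction inside the set relative to the array-wide flagged
fraction.  BH FDR is computed across all sets of a collection.  The
enrichment universe defaults to the whole array (every feature on the
platform); pass a restricted ``universe`` to change that.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from cernanet.diffexpr import bh_fdr
from cernanet.io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["set_id", "description", "nf", "n", "Nf", "N", "Re", "p", "fdr"]


def enrichment_ratio(nf: int, n: int, Nf: int, N: int) -> float:
    """Re = (nf/n)/(Nf/N); undefined (nan) when the set or flag pool is empty."""
    if n == 0 or Nf == 0 or N == 0:
        return float("nan")
    return (nf / n) / (Nf / N)


def _two_by_two(nf: int, n: int, Nf: int, N: int) -> np.ndarray:
    # rows: in set / not in set; columns: flagged / not flagged
    return np.array([[nf, n - nf], [Nf - nf, (N - n) - (Nf - nf)]])


def fisher_p(nf: int, n: int, Nf: int, N: int) -> float:
    """Two-sided Fisher exact p for the over-representation table."""
    return float(stats.fisher_exact(_two_by_two(nf, n, Nf, N), alternative="two-sided")[1])


def chi2_p(nf: int, n: int, Nf: int, N: int) -> float:
    """Chi-square p with continuity correction; falls back to Fisher when
    any expected cell count is below 5 (small-table validity)."""
    table = _two_by_two(nf, n, Nf, N)
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        return fisher_p(nf, n, Nf, N)
    return float(stats.chi2_contingency(table, correction=True)[1])


def enrich(
    flagged: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    test: str = "fisher",
) -> pd.DataFrame:
    """Over-representation of ``flagged`` features in each gene set.

    Each set is intersected with the universe before counting; sets with an
    empty intersection are reported with Re and p missing.  Output is sorted
    by (p, set_id) and carries BH FDR across the tested sets.
    """
    flagged = set(flagged)
    universe = set(universe)
    if not universe:
        raise ValueError("empty enrichment universe")
    stray = flagged - universe
    if stray:
        raise ValueError(f"flagged features outside the universe: {sorted(stray)[:5]}")
    if test not in ("fisher", "chi2"):
        raise ValueError(f"unknown test {test!r}")
    pfun = fisher_p if test == "fisher" else chi2_p

    N, Nf = len(universe), len(flagged)
    rows = []
    for set_id, (desc, members) in sets:
        in_universe = universe.intersection(members)
        n = len(in_universe)
        nf = len(flagged.intersection(in_universe))
        if n == 0:
            logger.info("set %s has no members in the universe; reported as missing", set_id)
            rows.append((set_id, desc, 0, 0, Nf, N, np.nan, np.nan))
            continue
        rows.append((set_id, desc, nf, n, Nf, N, enrichment_ratio(nf, n, Nf, N), pfun(nf, n, Nf, N)))
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    tested = out["p"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out = out.sort_values(["p", "set_id"], kind="mergesort", na_position="last").reset_index(drop=True)
    return out


def significant_term_gene_union(
    go_results: pd.DataFrame,
    kegg_results: pd.DataFrame,
    de_features: Iterable[str],
    go_sets: GeneSetCollection,
    kegg_sets: GeneSetCollection,
    max_p: float = 0.05,
    max_fdr: float = 0.05,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """DE features belonging to >=1 significant GO term AND >=1 significant
    pathway (intersection semantics), both at p < ``max_p`` and
    fdr < ``max_fdr``.

    Returns a DataFrame with feature_id and, when ``directions`` is given,
    the up/down partition preserved.
    """
    de_features = set(de_features)

    def _members_of_significant(results: pd.DataFrame, sets: GeneSetCollection) -> set[str]:
        sig = results[(results["p"] < max_p) & (results["fdr"] < max_fdr)]
        pool: set[str] = set()
        for set_id in sig["set_id"]:
            pool.update(sets.members(set_id))
        return pool

    in_go = _members_of_significant(go_results, go_sets)
    in_kegg = _members_of_significant(kegg_results, kegg_sets)
    kept = sorted(de_features & in_go & in_kegg)
    out = pd.DataFrame({"feature_id": kept})
    if directions is not None:
        out["direction"] = [directions[f] for f in kept]
    return out
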