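"""Hypergeometric over-representation analysis against a pathway library.

For each pathway, membership is intersected with the measured-metabolite
universe (the targeted panel is the correct background for a targeted assay),
and the upper-tail hypergeometric probability P(X >= k) of observing k
selected members tests over-representation; BH-FDR corrects across pathways.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PathwayLibrary
from .univariate import bh_fdr

logger = logging.getLogger("aerometab")


def ora_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k), X ~ Hypergeom(N, K, n).

    N = universe size, K = pathway size within the universe, n = selected
    size, k = hits.  k = 0 returns exactly 1.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich(selected, library: PathwayLibrary, universe) -> pd.DataFrame:
    """One over-representation test per pathway with >= 1 universe member.

    ``selected`` must be a subset of ``universe``; pathway member sets are
    intersected with the universe before testing.  Returns a table sorted by
    p (ties broken by pathway name) with BH-FDR q-values.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected metabolites outside the universe: {sorted(stray)}")
    N, n = len(universe), len(selected)
    rows = []
    for name, members in sorted(library.pathways.items()):
        in_universe = members & universe
        if not in_universe:
            logger.info("pathway %s shares no members with the universe; skipped", name)
            continue
        K = len(in_universe)
        k = len(in_universe & selected)
        rows.append(
            {
                "pathway": name,
                "universe_size": N,
                "pathway_size": K,
                "selected_size": n,
                "hits": k,
                "expected": n * K / N,
                "p_value": ora_pvalue(N, K, n, k),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["pathway", "universe_size", "pathway_size", "selected_size",
                 "hits", "expected", "p_value"],
    )
    if len(table):
        table["fdr_q"] = bh_fdr(table["p_value"].to_numpy())
        table = table.sort_values(["p_value", "pathway"], kind="stable",
                                  ignore_index=True)
    else:
        table["fdr_q"] = np.nan
    return table
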