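"""Over-representation analysis for gene sets.

Upper-tail hypergeometric test of a selected gene set against term
memberships within a stated universe, with Benjamini-Hochberg control
across terms.  Applied to DE sets, lncRNA target sets, and co-expression
module memberships.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .expression import bh_adjust


def hypergeom_enrich(
    selected: set[str],
    universe: set[str],
    term_map: dict[str, set[str]],
    descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term over-representation of ``selected`` within ``universe``.

    For a term with K members in a universe of N genes and a selection
    of n genes, k of which are term members, the p-value is the
    hypergeometric upper tail P(X >= k).  Term memberships are clipped
    to the universe before testing.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    stray = selected - universe
    if stray:
        raise ValueError(
            f"selected genes outside the universe: {sorted(stray)[:5]}"
        )
    n_universe = len(universe)
    n_selected = len(selected)
    rows = []
    for term_id in sorted(term_map):
        members = term_map[term_id] & universe
        n_term = len(members)
        overlap = len(members & selected)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(
            stats.hypergeom.sf(overlap - 1, n_universe, n_term, n_selected)
        )
        rows.append(
            (
                term_id,
                (descriptions or {}).get(term_id, ""),
                overlap,
                n_selected,
                n_term,
                n_universe,
                p,
            )
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "n", "K", "N", "p_value"]
    )
    if len(result):
        result["adjusted_p"] = bh_adjust(result["p_value"].values)
    else:
        result["adjusted_p"] = []
    return result
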