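"""Hypergeometric over-representation of gene sets in a DEG list.

For a universe of N genes (all genes on the platform, not the genome), a
term annotating K of them and a query of n genes overlapping the term in k,
the enrichment p-value is the upper hypergeometric tail P(X >= k).
Benjamini-Hochberg q-values are reported across the tested terms alongside
the raw p-values.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import CholnetError

logger = logging.getLogger("cholnet")

ENRICHMENT_COLUMNS = ["term", "k", "K", "n", "N", "p", "q"]


def enrich(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` against every term in ``sets``.

    Query and term memberships are intersected with the universe first;
    terms with no member in the universe are skipped (logged).  Rows are
    sorted by p-value, ties by term id.
    """
    uni = set(universe)
    if not uni:
        raise CholnetError("empty gene universe")
    q = set(query) & uni
    rows = []
    for term in sets:
        members = set(sets[term]) & uni
        if not members:
            logger.info("term %s has no members in the universe; skipped", term)
            continue
        k = len(q & members)
        # upper tail P(X >= k); sf(k-1) so k = 0 gives exactly 1
        p = float(hypergeom.sf(k - 1, len(uni), len(members), len(q)))
        rows.append({"term": term, "k": k, "K": len(members),
                     "n": len(q), "N": len(uni), "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out
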