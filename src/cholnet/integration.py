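"""Cross-dataset integration: ortholog mapping and sign-concordance grouping.

Two differential-expression results measured in different systems (here a
mouse in-vivo diet comparison and a human in-vitro cholesterol-depletion
time course) are intersected through an ortholog map.  Every gene called in
BOTH datasets gets a concordance record whose group is one of four sign
combinations: both_up, both_down, mouse_up_human_down, mouse_down_human_up.
The two mixed groups form the discordant set — genes pushed in opposite
directions by cholesterol excess in vivo and cholesterol depletion in
vitro, i.e. candidate cholesterol sensors (ATF3 is the canonical example:
repressed by the hypercholesterolemic diet, induced by depletion).
"""

from __future__ import annotations

import pandas as pd

from .io import CholnetError, OrthologMap

CONCORDANCE_COLUMNS = ["mouse_gene", "human_gene", "sign_mouse", "sign_human",
                       "group", "discordant"]


def _human_call(calls: pd.DataFrame, gene: str,
                early: str = "3h", late: str = "16h") -> tuple[bool, str]:
    """(called?, direction) for a time-course gene.

    A gene counts as differentially expressed when called at either
    timepoint.  Direction comes from the late timepoint when called there
    (the late response dominates), else the early one; should the two
    timepoints disagree, the one with the larger |log2fc| wins.
    """
    if gene not in calls.index:
        return False, "none"
    row = calls.loc[gene]
    s_early, s_late = row[f"state_{early}"], row[f"state_{late}"]
    if s_early == "none" and s_late == "none":
        return False, "none"
    if s_late == "none":
        return True, s_early
    if s_early == "none" or s_early == s_late:
        return True, s_late
    fc_e, fc_l = abs(row[f"log2fc_{early}"]), abs(row[f"log2fc_{late}"])
    return True, s_late if fc_l >= fc_e else s_early


def _deg_call(table: pd.DataFrame, gene: str) -> tuple[bool, str]:
    if gene not in table.index or not bool(table.loc[gene, "is_deg"]):
        return False, "none"
    return True, str(table.loc[gene, "direction"])


def _classify(sign_mouse: str, sign_human: str) -> str:
    if sign_mouse == sign_human:
        return f"both_{sign_mouse}"
    return f"mouse_{sign_mouse}_human_{sign_human}"


def map_and_intersect(
    degs_mouse: pd.DataFrame,
    calls_human: pd.DataFrame,
    omap: OrthologMap,
    early: str = "3h",
    late: str = "16h",
) -> pd.DataFrame:
    """Concordance records for genes called DEG in both datasets.

    ``degs_mouse`` is a two-group DEG table (is_deg/direction columns);
    ``calls_human`` is either a time-course call table (state_*/log2fc_*
    columns, resolved by the union-of-timepoints rule) or another DEG
    table.  One-to-many ortholog pairs are collapsed by the map's
    resolution policy before classification, so each surviving mouse and
    human gene appears in at most one record.
    """
    if not omap.pairs:
        raise CholnetError("ortholog map is empty")
    is_timecourse = any(c.startswith("state_") for c in calls_human.columns)

    candidates = []
    for mouse_gene, human_gene in omap.pairs:
        m_called, m_sign = _deg_call(degs_mouse, mouse_gene)
        if not m_called:
            continue
        if is_timecourse:
            h_called, h_sign = _human_call(calls_human, human_gene, early, late)
            h_fc = _human_fc(calls_human, human_gene, early, late) if h_called else 0.0
        else:
            h_called, h_sign = _deg_call(calls_human, human_gene)
            h_fc = float(calls_human.loc[human_gene, "log2fc"]) if h_called else 0.0
        if not h_called:
            continue
        m_fc = float(degs_mouse.loc[mouse_gene, "log2fc"])
        candidates.append((mouse_gene, human_gene, m_sign, h_sign, m_fc, h_fc))

    resolved = _resolve_multimappings(candidates, omap.resolution_policy)
    records = [
        {
            "mouse_gene": m, "human_gene": h,
            "sign_mouse": ms, "sign_human": hs,
            "group": _classify(ms, hs),
            "discordant": ms != hs,
        }
        for m, h, ms, hs, _, _ in resolved
    ]
    return pd.DataFrame(records, columns=CONCORDANCE_COLUMNS).astype({"discordant": bool})


def _human_fc(calls: pd.DataFrame, gene: str, early: str, late: str) -> float:
    row = calls.loc[gene]
    return float(max(abs(row[f"log2fc_{early}"]), abs(row[f"log2fc_{late}"])))


def _resolve_multimappings(candidates, policy: str):
    """Collapse one-to-many mappings so every symbol appears at most once.

    ``max_abs_fc`` prefers the partner with the stronger fold change in the
    other dataset (alphabetical tiebreak); ``first_alphabetical`` simply
    keeps the alphabetically first partner.
    """
    def partner_key(fc):
        return (-abs(fc)) if policy == "max_abs_fc" else 0.0

    # greedy, deterministic: best candidate pairs claim their symbols first
    ranked = sorted(
        candidates,
        key=lambda c: (partner_key(c[4]) + partner_key(c[5]), c[0], c[1]),
    )
    used_mouse: set[str] = set()
    used_human: set[str] = set()
    kept = []
    for cand in ranked:
        m, h = cand[0], cand[1]
        if m in used_mouse or h in used_human:
            continue
        used_mouse.add(m)
        used_human.add(h)
        kept.append(cand)
    kept.sort(key=lambda c: (c[0], c[1]))
    return kept


def discordant_records(records: pd.DataFrame) -> pd.DataFrame:
    """Rows of the concordance table with opposite signs in the two systems."""
    return records[records["discordant"]].reset_index(drop=True)


def discordant_set(records: pd.DataFrame, namespace: str = "human") -> set[str]:
    """Symbols of the discordant genes in one namespace.

    ``namespace`` is "human" (default; the namespace the interaction
    network is usually built in), "mouse", or "pairs" for the full
    (mouse, human) tuples.
    """
    disc = records[records["discordant"]]
    if namespace == "human":
        return set(disc["human_gene"])
    if namespace == "mouse":
        return set(disc["mouse_gene"])
    if namespace == "pairs":
        return set(zip(disc["mouse_gene"], disc["human_gene"]))
    raise CholnetError(f"unknown namespace {namespace!r}")
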