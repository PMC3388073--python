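"""Synthetic data with the statistical structure the pipeline assumes.

Three generators mirror the three experimental substrates:

* a replicated two-group comparison (hypercholesterolemic vs
  normocholesterolemic diet, two biological repeats per group),
* an unreplicated 0/3/16 h time course (cholesterol-depleted medium),
* a KEGG/NCBI-style interaction edge list with planted high-degree
  regulators wired to DEG targets.

Baseline log2 expression is Normal(7, 1.5) — a conventional
microarray-like scale — and noise is Gaussian on the log2 scale.  Planted
effects are mean shifts of +-effect_size log2 units.  The background
interaction graph is Erdos-Renyi (expected degrees are then analytic); the
planted hubs supply the heavy tail that matters for the ranking tests.
Every generator is bit-reproducible from its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CholnetError, ExpressionMatrix, InteractionNetwork, OrthologMap
from .timecourse import PATTERNS

BASELINE_MEAN = 7.0
BASELINE_SD = 1.5


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    deg_mouse: dict[str, str] = field(default_factory=dict)        # gene -> up/down/none
    deg_human: dict[str, dict[str, str]] = field(default_factory=dict)  # gene -> tp -> state
    shared_discordant: set[str] = field(default_factory=set)
    hub_regulators: dict[str, int] = field(default_factory=dict)   # regulator -> DEG-degree
    effect_size: float = 0.0
    noise_sd: float = 0.0

    def truth_frame(self) -> pd.DataFrame:
        genes = sorted(set(self.deg_mouse) | set(self.deg_human))
        rows = []
        for g in genes:
            human = self.deg_human.get(g, {})
            rows.append({
                "gene": g,
                "mouse": self.deg_mouse.get(g, "none"),
                "human": ";".join(f"{tp}:{s}" for tp, s in sorted(human.items())) or "none",
                "shared_discordant": g in self.shared_discordant,
            })
        return pd.DataFrame(rows)


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Replicated two-group design
# ---------------------------------------------------------------------------

def simulate_two_group(
    n_genes: int = 1000,
    n_per_group: int = 2,
    frac_deg: float = 0.05,
    effect_size: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    group_labels: tuple[str, str] = ("Hyper", "Normo"),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-group log2 expression matrix with planted differential genes.

    The first ``round(frac_deg * n_genes)`` genes are shifted by
    +-``effect_size`` in the first group, directions split 50/50 ("up"
    means higher in the first group).  Defaults emulate the motivating
    design: 2 biological repeats per diet group, 5% true DEGs, 2 log2-unit
    effects over 0.25 log2-unit noise.
    """
    if n_per_group < 2:
        raise CholnetError("n_per_group must be >= 2")
    if not 0.0 <= frac_deg < 1.0:
        raise CholnetError(f"frac_deg must be in [0, 1), got {frac_deg}")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    la, lb = group_labels
    samples = [f"{la}_{i+1}" for i in range(n_per_group)] + \
              [f"{lb}_{i+1}" for i in range(n_per_group)]
    design = {s: (la if s.startswith(f"{la}_") else lb) for s in samples}

    base = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    values = np.tile(base[:, None], (1, 2 * n_per_group))
    n_deg = int(round(frac_deg * n_genes))
    signs = np.ones(n_deg)
    signs[1::2] = -1.0  # alternate up/down for an exact 50/50 split
    values[:n_deg, :n_per_group] += (signs * effect_size)[:, None]
    values += rng.normal(0.0, noise_sd, size=values.shape)

    truth = SyntheticTruth(
        deg_mouse={
            g: ("up" if i < n_deg and signs[i] > 0 else
                "down" if i < n_deg else "none")
            for i, g in enumerate(genes)
        },
        effect_size=effect_size,
        noise_sd=noise_sd,
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), design=design)
    return matrix, truth


# ---------------------------------------------------------------------------
# Unreplicated time course
# ---------------------------------------------------------------------------

def simulate_timecourse(
    n_genes: int = 1000,
    pattern_mix: dict | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    timepoints: tuple[str, str, str] = ("0h", "3h", "16h"),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Single-sample baseline/early/late time course with planted patterns.

    ``pattern_mix`` maps a pattern — a (state_early, state_late) tuple or
    its 1..8 pattern id — to the fraction of genes carrying it; fractions
    must sum to at most 1.  A planted "up"/"down" state shifts the gene by
    +-``effect_size`` at that timepoint.
    """
    pattern_mix = pattern_mix or {}
    id_to_pair = {v: k for k, v in PATTERNS.items()}
    mix: dict[tuple[str, str], float] = {}
    for key, frac in pattern_mix.items():
        pair = id_to_pair.get(key) if isinstance(key, int) else tuple(key)
        if pair not in PATTERNS:
            raise CholnetError(f"unknown pattern key {key!r}")
        mix[pair] = mix.get(pair, 0.0) + float(frac)
    if sum(mix.values()) > 1.0 + 1e-12:
        raise CholnetError("pattern fractions sum to more than 1")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    base_tp, early, late = timepoints
    samples = list(timepoints)
    design = {s: s for s in samples}

    base = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    values = np.tile(base[:, None], (1, 3))
    shift = {"up": effect_size, "none": 0.0, "down": -effect_size}

    truth = SyntheticTruth(effect_size=effect_size, noise_sd=noise_sd)
    start = 0
    for pair in sorted(mix, key=lambda p: PATTERNS[p]):
        count = int(round(mix[pair] * n_genes))
        for i in range(start, min(start + count, n_genes)):
            values[i, 1] += shift[pair[0]]
            values[i, 2] += shift[pair[1]]
            truth.deg_human[genes[i]] = {early: pair[0], late: pair[1]}
        start += count
    for g in genes:
        truth.deg_human.setdefault(g, {early: "none", late: "none"})
    values += rng.normal(0.0, noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), design=design)
    return matrix, truth


# ---------------------------------------------------------------------------
# Interactome with planted hub regulators
# ---------------------------------------------------------------------------

def simulate_interactome(
    n_background: int = 200,
    degs: set[str] | None = None,
    hubs: dict[str, int] | None = None,
    background_edge_prob: float = 0.005,
    seed: int = 0,
) -> tuple[InteractionNetwork, SyntheticTruth]:
    """Interaction edge list with hubs wired to a set number of DEG targets.

    Node set = DEGs + hub regulators + ``n_background`` filler nodes.  Each
    hub gets protein-DNA edges to exactly its stated number of distinct DEG
    nodes (never itself); all other pairs receive protein-protein edges
    independently with ``background_edge_prob`` (Erdos-Renyi).
    """
    degs = set(degs or ())
    hubs = dict(hubs or {})
    rng = np.random.default_rng(seed)
    for hub, k in hubs.items():
        avail = len(degs - {hub})
        if k > avail:
            raise CholnetError(
                f"hub {hub!r} requests degree {k} but only {avail} DEG targets exist")

    background = _gene_names(n_background, prefix="BG")
    nodes = sorted(degs | set(hubs) | set(background))
    net = InteractionNetwork()
    net.graph.add_nodes_from(nodes)

    hub_edges = set()
    for hub in sorted(hubs):
        targets = sorted(degs - {hub})
        pick = rng.choice(len(targets), size=hubs[hub], replace=False)
        for i in sorted(pick.tolist()):
            net.add_edge(hub, targets[i], kind="protein_dna")
            hub_edges.add(frozenset((hub, targets[i])))

    if background_edge_prob > 0:
        arr = nodes
        for i in range(len(arr)):
            draws = rng.random(len(arr) - i - 1)
            for off in np.nonzero(draws < background_edge_prob)[0]:
                u, v = arr[i], arr[i + 1 + off]
                if frozenset((u, v)) not in hub_edges:
                    net.add_edge(u, v, kind="ppi")

    truth = SyntheticTruth(hub_regulators=dict(hubs))
    return net, truth


# ---------------------------------------------------------------------------
# Composed study: two datasets + map + interactome + gene sets
# ---------------------------------------------------------------------------

def simulate_study(
    n_genes: int = 1000,
    frac_shared_discordant: float = 0.03,
    frac_shared_concordant: float = 0.01,
    frac_mouse_only: float = 0.01,
    frac_human_only: float = 0.01,
    effect_size: float = 2.0,
    noise_sd: float = 0.25,
    hub_degree: int = 5,
    n_background: int = 200,
    background_edge_prob: float = 0.005,
    n_terms: int = 10,
    seed: int = 0,
) -> dict:
    """End-to-end fixture: mouse + human matrices, ortholog map, interactome,
    gene sets and the planted truth.

    Mouse symbols are capitalized-lowercase ("Gene0001"-style) and human
    symbols upper-case, joined 1:1 by the ortholog map.  Shared discordant
    genes are split between the two mixed sign patterns; the first
    discordant gene doubles as the planted hub regulator wired to
    ``hub_degree`` other discordant DEGs in the interactome (the ATF3
    motif).  Gene sets are a random partition of the human namespace into
    ``n_terms`` terms.
    """
    rng = np.random.default_rng(seed)
    mouse_genes = [f"Gene{i:04d}" for i in range(1, n_genes + 1)]
    human_genes = [g.upper() for g in mouse_genes]
    omap = OrthologMap(pairs=list(zip(mouse_genes, human_genes)))

    n_disc = int(round(frac_shared_discordant * n_genes))
    n_conc = int(round(frac_shared_concordant * n_genes))
    n_mo = int(round(frac_mouse_only * n_genes))
    n_ho = int(round(frac_human_only * n_genes))

    # layout: [discordant | concordant | mouse-only | human-only | null...]
    mouse_dirs = {}
    human_states = {}
    shared_discordant: set[str] = set()
    idx = 0
    for i in range(n_disc):
        m, h = mouse_genes[idx], human_genes[idx]
        if i % 2 == 0:   # mouse down / human up (the ATF3 pattern)
            mouse_dirs[m] = "down"
            human_states[h] = {"3h": "up", "16h": "up"}
        else:
            mouse_dirs[m] = "up"
            human_states[h] = {"3h": "down", "16h": "down"}
        shared_discordant.add(h)
        idx += 1
    for i in range(n_conc):
        m, h = mouse_genes[idx], human_genes[idx]
        d = "up" if i % 2 == 0 else "down"
        mouse_dirs[m] = d
        human_states[h] = {"3h": d, "16h": d}
        idx += 1
    for i in range(n_mo):
        mouse_dirs[mouse_genes[idx]] = "up" if i % 2 == 0 else "down"
        idx += 1
    for i in range(n_ho):
        human_states[human_genes[idx]] = {"3h": "none",
                                          "16h": "up" if i % 2 == 0 else "down"}
        idx += 1

    # mouse matrix (2 vs 2)
    base = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    mvals = np.tile(base[:, None], (1, 4))
    for i, g in enumerate(mouse_genes):
        d = mouse_dirs.get(g)
        if d:
            mvals[i, :2] += effect_size if d == "up" else -effect_size
    mvals += rng.normal(0.0, noise_sd, size=mvals.shape)
    mouse = ExpressionMatrix(
        values=pd.DataFrame(mvals, index=mouse_genes,
                            columns=["Hyper_1", "Hyper_2", "Normo_1", "Normo_2"]),
        design={"Hyper_1": "Hyper", "Hyper_2": "Hyper",
                "Normo_1": "Normo", "Normo_2": "Normo"})

    # human time course (single samples, tighter noise: no replication to average)
    hbase = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    hvals = np.tile(hbase[:, None], (1, 3))
    shift = {"up": effect_size, "none": 0.0, "down": -effect_size}
    for i, h in enumerate(human_genes):
        st = human_states.get(h)
        if st:
            hvals[i, 1] += shift[st["3h"]]
            hvals[i, 2] += shift[st["16h"]]
    hvals += rng.normal(0.0, noise_sd / 2.0, size=hvals.shape)
    human = ExpressionMatrix(
        values=pd.DataFrame(hvals, index=human_genes, columns=["0h", "3h", "16h"]),
        design={"0h": "0h", "3h": "3h", "16h": "16h"})

    disc_sorted = sorted(shared_discordant)
    hub = disc_sorted[0] if disc_sorted else None
    hubs = {hub: min(hub_degree, len(disc_sorted) - 1)} if hub else {}
    interactome, _ = simulate_interactome(
        n_background=n_background, degs=set(disc_sorted), hubs=hubs,
        background_edge_prob=background_edge_prob, seed=seed + 1)

    # gene sets: a partition of the human namespace
    perm = rng.permutation(n_genes)
    sets = {}
    bounds = np.linspace(0, n_genes, n_terms + 1).astype(int)
    for t in range(n_terms):
        members = {human_genes[j] for j in perm[bounds[t]:bounds[t + 1]]}
        sets[f"TERM:{t+1:03d}"] = members

    truth = SyntheticTruth(
        deg_mouse={g: mouse_dirs.get(g, "none") for g in mouse_genes},
        deg_human={h: human_states.get(h, {"3h": "none", "16h": "none"})
                   for h in human_genes},
        shared_discordant=shared_discordant,
        hub_regulators=hubs,
        effect_size=effect_size,
        noise_sd=noise_sd,
    )
    return {
        "mouse": mouse, "human": human, "ortholog_map": omap,
        "interactome": interactome, "gene_sets": sets, "truth": truth,
    }
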