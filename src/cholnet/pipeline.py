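"""End-to-end orchestration: both datasets -> integration -> enrichment ->
network -> regulator ranking, with every stage output written to disk and a
machine-readable run summary."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import deg, enrichment, integration, network, timecourse
from .io import (
    CholnetError, ExpressionMatrix, InteractionNetwork, OrthologMap, RunConfig,
    write_deg_table, write_graphml,
)

logger = logging.getLogger("cholnet")


def run_pipeline(
    mouse: ExpressionMatrix,
    human: ExpressionMatrix,
    ortholog_map: OrthologMap,
    interactome: InteractionNetwork,
    gene_sets: dict[str, set[str]],
    regulators: set[str] | None,
    config: RunConfig,
    out_dir: str | Path,
    human_baseline: str = "0h",
    human_timepoints: tuple[str, str] = ("3h", "16h"),
) -> dict:
    """Run the full analysis and write every stage output under ``out_dir``.

    Returns the run summary (also serialized to ``summary.yaml``):
    DEG counts per dataset, intersection/discordance counts, the head of
    the regulator ranking, and an echo of the configuration.  The run is
    deterministic given inputs, configuration and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d alpha=%g fc>%g",
                config.rng_seed, config.alpha, config.fc_threshold)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CholnetError as exc:
            raise CholnetError(f"stage {name!r} failed: {exc}") from exc

    mouse_table = _stage("deg-two-group", deg.run_integrative_test, mouse, config)
    write_deg_table(mouse_table, out / "deg_mouse.tsv")

    calls = _stage("deg-timecourse", timecourse.call_timecourse,
                   human, human_baseline, config)
    calls = _stage("deg-timecourse", timecourse.assign_patterns,
                   calls, list(human_timepoints))
    calls.reset_index().to_csv(out / "deg_human_timecourse.tsv", sep="\t", index=False)

    records = _stage("integrate", integration.map_and_intersect,
                     mouse_table, calls, ortholog_map,
                     early=human_timepoints[0], late=human_timepoints[1])
    records.to_csv(out / "concordance.tsv", sep="\t", index=False)
    disc = integration.discordant_set(records, namespace="human")

    universe = set(human.gene_ids)
    enr = _stage("enrich", enrichment.enrich, disc, gene_sets, universe) \
        if disc else pd.DataFrame(columns=enrichment.ENRICHMENT_COLUMNS)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    summary: dict = {
        "n_deg_mouse": int(mouse_table["is_deg"].sum()),
        "n_deg_mouse_up": int((mouse_table["direction"] == "up").sum()),
        "n_deg_mouse_down": int((mouse_table["direction"] == "down").sum()),
        "n_deg_human_per_timepoint": {
            tp: int((calls[f"state_{tp}"] != "none").sum()) for tp in human_timepoints
        },
        "n_intersection": int(len(records)),
        "n_discordant": int(records["discordant"].sum()),
        "n_concordant": int((~records["discordant"]).sum()),
        "config": {
            "alpha": config.alpha, "fc_threshold": config.fc_threshold,
            "permutation_cap": config.permutation_cap,
            "rng_seed": config.rng_seed, "null_mode": config.null_mode,
        },
    }

    if disc:
        try:
            net = _stage("network", network.build_initial_network, disc, interactome)
        except CholnetError as exc:
            logger.warning("network stage skipped: %s", exc)
            net = None
        if net is not None:
            pruned = _stage("network", network.prune_network, net)
            mouse_dir = _direction_map(records)
            for n in pruned.graph.nodes():
                pruned.graph.nodes[n]["direction_human"] = _human_dir(records, n)
                pruned.graph.nodes[n]["direction_mouse"] = mouse_dir.get(n, "none")
            network.assign_modules(pruned, enr, gene_sets, alpha=config.alpha)
            regs = regulators & set(pruned.graph.nodes()) if regulators else set()
            if regs:
                ranking = _stage("rank", network.rank_regulators, pruned, regs)
                ranking.to_csv(out / "regulator_ranking.tsv", sep="\t", index=False)
                summary["top_regulators"] = ranking.head(10).to_dict("records")
            write_graphml(pruned, out / "network.graphml")
            summary["network_nodes"] = int(pruned.graph.number_of_nodes())
            summary["network_edges"] = int(pruned.graph.number_of_edges())

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    logger.info("pipeline done: %d mouse DEGs, %d intersection, %d discordant",
                summary["n_deg_mouse"], summary["n_intersection"], summary["n_discordant"])
    return summary


def _direction_map(records: pd.DataFrame) -> dict[str, str]:
    return dict(zip(records["human_gene"], records["sign_mouse"]))


def _human_dir(records: pd.DataFrame, node: str) -> str:
    hit = records[records["human_gene"] == node]
    return str(hit["sign_human"].iloc[0]) if len(hit) else "none"
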