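"""Command-line interface and scripted experiment harnesses.

The sweep harnesses reproduce the benchmark experiments: build pyramids from
ensembles of nested random networks while varying either the network density
(by random link removal) or the z-score threshold, and report mean per-level
NMI per condition. All randomness flows from one master seed through
per-task derived seeds, and every report embeds its full configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np

from .enrichment import AnnotationTable, proximity_signtest
from .evaluation import density, evaluate_hierarchy
from .generator import GeneratorSpec, generate, planted_partition, thin_to_density
from .network_io import (
    read_annotations,
    read_edge_list,
    read_membership,
    read_pyramid,
    write_edge_list,
    write_pyramid,
)
from .pyramid import build_pyramid

logger = logging.getLogger("pyramabs")

__all__ = ["run_density_sweep", "run_threshold_sweep", "main"]


def _task_seed(master: int, task: int) -> int:
    """Derived per-task seed, kept below 2**31."""
    return int((master * 100003 + task * 7919 + 1) % (2**31 - 1))


def run_density_sweep(
    spec: GeneratorSpec,
    densities: list[float],
    n_seeds: int = 10,
    z_threshold: float = 0.0,
) -> dict:
    """Generate, thin to each density, build, and score against the truth."""
    if not densities:
        raise ValueError("densities must be non-empty")
    if any(d > spec.target_density + 1e-12 for d in densities):
        raise ValueError("sweep densities must not exceed the generator density")
    report: dict = {
        "config": {
            "spec": dataclasses.asdict(spec),
            "densities": list(densities),
            "n_seeds": n_seeds,
            "z_threshold": z_threshold,
        },
        "conditions": [],
    }
    for di, dens in enumerate(densities):
        per_seed = []
        for s in range(n_seeds):
            seed = _task_seed(spec.seed, di * n_seeds + s)
            net, truth = generate(dataclasses.replace(spec, seed=seed))
            # sampling noise can leave a network just below the requested
            # density; it is then used as-is
            if dens < density(net):
                thin = thin_to_density(net, dens, seed=_task_seed(seed, 1))
            else:
                thin = net
            pyr = build_pyramid(thin, z_threshold=z_threshold)
            res = evaluate_hierarchy(pyr, truth)
            per_seed.append({"seed": seed, "mean_nmi": res.mean_nmi})
        scores = [r["mean_nmi"] for r in per_seed]
        report["conditions"].append(
            {
                "density": dens,
                "mean_nmi": float(np.mean(scores)),
                "sd_nmi": float(np.std(scores)),
                "per_seed": per_seed,
            }
        )
    return report


def run_threshold_sweep(
    spec: GeneratorSpec, thresholds: list[float], n_seeds: int = 10
) -> dict:
    """Build pyramids at several z-score thresholds at the spec's density."""
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(not np.isfinite(t) for t in thresholds):
        raise ValueError("thresholds must be finite")
    report: dict = {
        "config": {
            "spec": dataclasses.asdict(spec),
            "thresholds": list(thresholds),
            "n_seeds": n_seeds,
        },
        "conditions": [],
    }
    nets = []
    for s in range(n_seeds):
        seed = _task_seed(spec.seed, s)
        nets.append((seed, *generate(dataclasses.replace(spec, seed=seed))))
    for thr in thresholds:
        per_seed = []
        for seed, net, truth in nets:
            pyr = build_pyramid(net, z_threshold=thr)
            res = evaluate_hierarchy(pyr, truth)
            per_seed.append(
                {
                    "seed": seed,
                    "mean_nmi": res.mean_nmi,
                    "isolated_supernodes": pyr.n_isolated_supernodes,
                }
            )
        scores = [r["mean_nmi"] for r in per_seed]
        report["conditions"].append(
            {
                "z_threshold": thr,
                "mean_nmi": float(np.mean(scores)),
                "sd_nmi": float(np.std(scores)),
                "isolated_supernodes": int(
                    sum(r["isolated_supernodes"] for r in per_seed)
                ),
                "per_seed": per_seed,
            }
        )
    return report


# -- CLI -------------------------------------------------------------------


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level: str):
    """Pyramabs: abstraction pyramids from weighted networks."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))


@main.command()
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--directed", is_flag=True, default=False)
@click.option("--z-threshold", default=0.0, show_default=True)
@click.option("--max-levels", default=50, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--dump-proximity", is_flag=True, default=False)
@click.option("--dump-backbone", is_flag=True, default=False)
def build(input_path, directed, z_threshold, max_levels, out_dir, dump_proximity, dump_backbone):
    """Build an abstraction pyramid from an edge-list file."""
    net = read_edge_list(input_path, directed=directed)
    pyr = build_pyramid(net, z_threshold=z_threshold, max_levels=max_levels)
    write_pyramid(pyr, out_dir)
    if dump_proximity or dump_backbone:
        from .backbone_partition import maximum_spanning_forest, symmetrize
        from .proximity import compute_proximity, zscore_filter

        pnet = zscore_filter(compute_proximity(net), z_threshold)
        if dump_proximity:
            with (Path(out_dir) / "proximity.tsv").open("w") as fh:
                fh.write("# source\ttarget\tproximity\n")
                for u, v, p in pnet.items():
                    fh.write(f"{u}\t{v}\t{p:.10g}\n")
        if dump_backbone:
            weights = symmetrize(pnet)
            backbone = maximum_spanning_forest(weights, frozenset(net.nodes))
            with (Path(out_dir) / "backbone.tsv").open("w") as fh:
                fh.write("# node_a\tnode_b\tweight\n")
                for _, edges in backbone.trees:
                    for u, v, w in edges:
                        fh.write(f"{u}\t{v}\t{w:.10g}\n")
    click.echo(
        f"pyramid with {pyr.n_levels} level(s); module counts bottom-up: "
        f"{pyr.module_counts()}"
    )
    if pyr.stalled:
        click.echo("warning: pyramid stalled before reaching a single supernode")
        sys.exit(3)


@main.command("generate")
@click.option("--branching", default="4,4,4", show_default=True)
@click.option("--leaf-size", default=10, show_default=True)
@click.option("--density", "target_density", default=0.0225, show_default=True)
@click.option("--rho", default=0.25, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def generate_cmd(branching, leaf_size, target_density, rho, seed, out_dir):
    """Generate a nested random network plus its planted-truth memberships."""
    spec = GeneratorSpec(
        branching=tuple(int(b) for b in branching.split(",")),
        leaf_size=leaf_size,
        target_density=target_density,
        rho=rho,
        seed=seed,
    )
    net, truth = generate(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(net, out / "edges.tsv")
    for depth, level in enumerate(truth.levels, start=1):
        with (out / f"truth_level{depth}.tsv").open("w") as fh:
            fh.write("# node_id\tmodule_id\n")
            for node in truth.nodes:
                fh.write(f"{node}\t{level[node]}\n")
    (out / "generator.json").write_text(
        json.dumps({"spec": dataclasses.asdict(spec), "density": density(net)}, indent=1)
    )
    click.echo(f"generated {net.n_nodes} nodes, {net.n_links} links -> {out}")


@main.command()
@click.option("--pred-dir", required=True, type=click.Path(exists=True))
@click.option("--truth-dir", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def evaluate(pred_dir, truth_dir, out_path):
    """Score a written pyramid against planted-truth membership TSVs."""
    from .generator import NestedPartition

    pyr = read_pyramid(pred_dir)
    truth_files = sorted(Path(truth_dir).glob("truth_level*.tsv"))
    if not truth_files:
        raise click.ClickException(f"no truth_level*.tsv files in {truth_dir}")
    levels = [read_membership(f) for f in truth_files]
    truth = NestedPartition(
        levels=levels,
        branching=(),
        leaf_size=0,
        nodes=tuple(sorted(levels[0])),
    )
    res = evaluate_hierarchy(pyr, truth)
    doc = {
        "levels": res.levels,
        "mean_nmi": res.mean_nmi,
        "pred_module_counts": res.pred_module_counts,
        "flagged": res.flagged,
    }
    Path(out_path).write_text(json.dumps(doc, indent=1))
    click.echo(f"mean NMI {res.mean_nmi:.4f} -> {out_path}")


@main.command()
@click.option("--pyramid", "pyramid_dir", required=True, type=click.Path(exists=True))
@click.option("--annotations", "ann_path", required=True, type=click.Path(exists=True))
@click.option("--level", "level_no", default=None, type=int,
              help="Level number (1 = top); default: all levels.")
@click.option("--signtest", is_flag=True, default=False)
@click.option("--alpha", default=0.01, show_default=True)
@click.option("--bonferroni", is_flag=True, default=False)
@click.option("--out", "out_path", required=True, type=click.Path())
def enrich(pyramid_dir, ann_path, level_no, signtest, alpha, bonferroni, out_path):
    """Annotation enrichment (and optional proximity sign test) per level."""
    from .enrichment import module_enrichment

    pyr = read_pyramid(pyramid_dir)
    table = AnnotationTable(read_annotations(ann_path))
    flat = pyr.flattened_memberships()
    doc: dict = {"alpha": alpha, "levels": []}
    n = pyr.n_levels
    for internal, level in enumerate(pyr.levels):
        depth = n - internal  # 1 = top
        if level_no is not None and depth != level_no:
            continue
        members: dict[str, set[str]] = {}
        for node, mid in flat[internal].items():
            members.setdefault(mid, set()).add(node)
        mods = []
        for mid in sorted(members):
            res = module_enrichment(members[mid], table, bonferroni=bonferroni)
            mods.append(
                {
                    "module": mid,
                    "size": len(members[mid]),
                    "best_category": res.best_category,
                    "best_pvalue": res.best_pvalue,
                }
            )
        entry: dict = {"level": depth, "modules": mods}
        if signtest:
            # score modules on original-node composition
            from .backbone_partition import ModuleSet
            from .pyramid import PyramidLevel

            ms = ModuleSet(
                [frozenset(members[mid]) for mid in sorted(members)],
                module_ids=sorted(members),
            )
            flat_level = PyramidLevel(
                input_network=pyr.levels[0].input_network,
                module_set=ms,
                abstract_network=level.abstract_network,
                parent_of=flat[internal],
            )
            st = proximity_signtest(flat_level, table, alpha=alpha)
            entry["signtest"] = dataclasses.asdict(st)
        doc["levels"].append(entry)
    Path(out_path).write_text(json.dumps(doc, indent=1))
    click.echo(f"enrichment report -> {out_path}")


def _spec_from_options(branching, leaf_size, target_density, rho, seed) -> GeneratorSpec:
    return GeneratorSpec(
        branching=tuple(int(b) for b in branching.split(",")),
        leaf_size=leaf_size,
        target_density=target_density,
        rho=rho,
        seed=seed,
    )


@main.command("sweep-density")
@click.option("--branching", default="4,4,4", show_default=True)
@click.option("--leaf-size", default=10, show_default=True)
@click.option("--density", "target_density", default=0.0225, show_default=True)
@click.option("--rho", default=0.25, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--densities", default="0.0225,0.0169,0.0141,0.0098", show_default=True)
@click.option("--n-seeds", default=10, show_default=True,
              help="Networks per condition (the full protocol uses 30).")
@click.option("--z-threshold", default=0.0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def sweep_density(branching, leaf_size, target_density, rho, seed, densities,
                  n_seeds, z_threshold, out_path):
    """Mean NMI versus network density (random link removal)."""
    spec = _spec_from_options(branching, leaf_size, target_density, rho, seed)
    report = run_density_sweep(
        spec, [float(d) for d in densities.split(",")], n_seeds, z_threshold
    )
    Path(out_path).write_text(json.dumps(report, indent=1))
    _echo_sweep(report, "density")


@main.command("sweep-threshold")
@click.option("--branching", default="4,4,4", show_default=True)
@click.option("--leaf-size", default=10, show_default=True)
@click.option("--density", "target_density", default=0.0225, show_default=True)
@click.option("--rho", default=0.25, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--thresholds", default="-2,-1,-0.5,0,2", show_default=True)
@click.option("--n-seeds", default=10, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def sweep_threshold(branching, leaf_size, target_density, rho, seed, thresholds,
                    n_seeds, out_path):
    """Mean NMI and isolated-supernode counts versus z-score threshold."""
    spec = _spec_from_options(branching, leaf_size, target_density, rho, seed)
    report = run_threshold_sweep(
        spec, [float(t) for t in thresholds.split(",")], n_seeds
    )
    Path(out_path).write_text(json.dumps(report, indent=1))
    _echo_sweep(report, "z_threshold")


def _echo_sweep(report: dict, key: str):
    for cond in report["conditions"]:
        click.echo(f"{key}={cond[key]}: mean NMI {cond['mean_nmi']:.4f}")


if __name__ == "__main__":  # pragma: no cover
    main()
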