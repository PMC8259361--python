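"""End-to-end analysis runner.

``run_all`` reproduces the full island-community analysis from the three
input files: the per-habitat diversity/metric table, the network report,
the three similarity trees, every single-habitat removal, gradual-loss
trajectories and the attack-sequence robustness comparison, all written
into one results directory.  A single master seed fans out to named
substreams (generator, modularity, gradual loss, attack sequences) so
re-running with the same seed reproduces every stochastic output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import read_dataset
from .coextinction_sim import (
    STRATEGIES,
    attack_sequence,
    compare_robustness,
    gradual_loss,
    remove_habitats,
    summarize_trajectories,
)
from .diversity_metrics import diversity_report, richness_area_correlation
from .network_metrics import network_report
from .similarity_clustering import similarity_trees

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("coralnet")


@dataclass(frozen=True)
class RunConfig:
    matrix_path: Path
    species_meta_path: Path
    habitat_meta_path: Path
    out_dir: Path
    seed: int = 42
    replicates: int = 50
    gradual_replicates: int = 10
    gradual_fractions: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 11), 10))
    modularity_restarts: int = 20
    trajectory_restarts: int = 5
    metric: str = "bray_curtis"
    linkage: str = "average"

    def __post_init__(self) -> None:
        for name in ("matrix_path", "species_meta_path", "habitat_meta_path", "out_dir"):
            object.__setattr__(self, name, Path(getattr(self, name)))
        for p in (self.matrix_path, self.species_meta_path, self.habitat_meta_path):
            if not p.exists():
                raise FileNotFoundError(p)


def _stream_seeds(seed: int) -> dict[str, int]:
    """Named 31-bit substream seeds derived from the master seed."""
    ss = np.random.SeedSequence(seed)
    names = ("modularity", "gradual", "attack")
    state = ss.generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(s) for s in state)))


def run_all(config: RunConfig) -> Path:
    """Run the complete analysis; returns the results directory."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)
    (out / "removal").mkdir(exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        seeds = _stream_seeds(config.seed)
        log.info(
            "coralnet %s | master seed %d | streams %s",
            __version__, config.seed, seeds,
        )

        stage = "read_dataset"
        try:
            dataset = read_dataset(
                config.matrix_path,
                config.species_meta_path,
                config.habitat_meta_path,
            )
            log.info("dataset: %s", dataset.summary())

            stage = "diversity + network metrics"
            div = diversity_report(dataset)
            net = network_report(
                dataset.matrix,
                seed=seeds["modularity"],
                restarts=config.modularity_restarts,
            )
            div.join(net.per_habitat).T.to_csv(out / "table1.csv")
            corr = richness_area_correlation(div, dict(dataset.habitat_meta))
            (out / "network.json").write_text(
                json.dumps(
                    {**net.to_dict(), "richness_area_correlation": corr},
                    indent=2,
                )
            )

            stage = "similarity trees"
            trees = similarity_trees(
                dataset, metric=config.metric, linkage=config.linkage
            )
            merge_rows = []
            for name, tree in trees.items():
                (out / "trees" / f"{name}.nwk").write_text(tree.to_newick() + "\n")
                mt = tree.merge_table()
                mt.insert(0, "tree", name)
                merge_rows.append(mt)
            pd.concat(merge_rows).to_csv(out / "trees" / "merges.csv", index=False)

            stage = "single-habitat removals"
            removal_rows = []
            for hab in dataset.matrix.habitat_labels:
                res = remove_habitats(
                    dataset, [hab],
                    seed=seeds["modularity"],
                    modularity_restarts=config.modularity_restarts,
                )
                assert res.metrics is not None
                row = {
                    "removed": hab,
                    "n_extinct": len(res.extinct_species),
                    "extinct_resident": len(res.extinct_by_residency("resident")),
                    "extinct_migrant": len(res.extinct_by_residency("migrant")),
                    "extinct_species": ";".join(res.extinct_species),
                }
                for variant, mets in res.metrics.items():
                    row.update({f"{k}_{variant}": v for k, v in mets.items()})
                removal_rows.append(row)
                log.info("removed %s -> %d extinct", hab, row["n_extinct"])
            pd.DataFrame(removal_rows).to_csv(
                out / "removal" / "single_removals.csv", index=False
            )

            stage = "gradual loss"
            all_traj = []
            for hab in dataset.matrix.habitat_labels:
                traj = gradual_loss(
                    dataset, hab,
                    loss_fractions=list(config.gradual_fractions),
                    rng_seed=seeds["gradual"],
                    replicates=config.gradual_replicates,
                    modularity_restarts=config.trajectory_restarts,
                )
                all_traj.append(traj)
            traj = pd.concat(all_traj, ignore_index=True)
            traj.to_csv(out / "removal" / "gradual_trajectories.csv", index=False)
            summarize_trajectories(traj).to_csv(
                out / "removal" / "gradual_summary.csv", index=False
            )

            stage = "attack sequences"
            results = []
            rob_rows = []
            for strategy in STRATEGIES:
                rr = attack_sequence(
                    dataset, strategy,
                    replicates=config.replicates,
                    rng_seed=seeds["attack"],
                )
                results.append(rr)
                for rep, (order, r50) in enumerate(
                    zip(rr.removal_orders, rr.r50)
                ):
                    rob_rows.append(
                        {
                            "strategy": strategy,
                            "replicate": rep,
                            "r50": r50,
                            "order": ";".join(order),
                        }
                    )
                    log.info(
                        "attack %s rep %d order %s r50 %.2f",
                        strategy, rep, ">".join(order), r50,
                    )
            pd.DataFrame(rob_rows).to_csv(out / "robustness.csv", index=False)
            comparison = compare_robustness(results)
            (out / "robustness_comparison.json").write_text(
                json.dumps(comparison, indent=2)
            )
            log.info("robustness comparison: %s", comparison)
        except Exception as exc:
            log.exception("stage failed: %s", stage)
            raise RuntimeError(f"pipeline failed at stage: {stage}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
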