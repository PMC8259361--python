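"""Habitat-loss experiments on the bird-habitat network.

Secondary extinctions follow the binary rule: birds cannot switch
habitats after loss, so a species goes extinct exactly when every
habitat it uses has been removed (no partial-occupancy threshold).
Three experiment families are provided:

* whole-habitat deletion with metric recomputation on the survivors,
* gradual loss of a chosen habitat (a fraction of its individual
  observations, or of its links, removed at random) with mean +/- sd
  metric trajectories over replicates,
* attack sequences removing habitats one at a time under a strategy
  (random, most/least connected, largest/smallest area), scored by the
  survival curve and the R50 robustness statistic, with one-way ANOVA
  plus Tukey grouping to compare strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    CommunityDataset,
    InteractionMatrix,
    Residency,
    drop_excluded,
)
from .diversity_metrics import pielou, shannon
from .network_metrics import barber_modularity, connectance, nodf

__all__ = [
    "STRATEGIES",
    "RemovalResult",
    "RobustnessResult",
    "remove_habitats",
    "community_metrics",
    "gradual_loss",
    "summarize_trajectories",
    "attack_sequence",
    "compare_robustness",
]

STRATEGIES = (
    "random",
    "most_connected",
    "least_connected",
    "largest_area",
    "smallest_area",
)

TRAJECTORY_METRICS = (
    "species_number",
    "resident_number",
    "migrant_number",
    "shannon",
    "pielou",
    "connectance",
    "modularity",
    "nodf",
)


# ---------------------------------------------------------------------------
# single removals


@dataclass(frozen=True)
class RemovalResult:
    removed_habitats: tuple[str, ...]
    surviving: CommunityDataset
    extinct_species: tuple[str, ...]
    extinct_residency: dict[str, Residency] = field(repr=False)
    metrics: dict | None = None

    def extinct_by_residency(self, residency: Residency | str) -> list[str]:
        residency = Residency(residency)
        return [
            s for s in self.extinct_species
            if self.extinct_residency[s] is residency
        ]


def _surviving_dataset(
    dataset: CommunityDataset, matrix: InteractionMatrix
) -> tuple[CommunityDataset, tuple[str, ...]]:
    """Drop extinct (zero-column) species; keep habitat rows."""
    col = matrix.col_sums()
    extinct = tuple(
        s for s, c in zip(matrix.species_labels, col) if c == 0
    )
    surv_matrix = matrix.drop_species(extinct)
    empty = tuple(
        lab
        for lab, s in zip(surv_matrix.habitat_labels, surv_matrix.row_sums())
        if s == 0
    )
    surv = CommunityDataset(
        surv_matrix,
        {s: dataset.species_meta[s] for s in surv_matrix.species_labels},
        {h: dataset.habitat_meta[h] for h in surv_matrix.habitat_labels},
        empty_habitats=empty,
    )
    return surv, extinct


def remove_habitats(
    dataset: CommunityDataset,
    habitats: Iterable[str],
    compute_metrics: bool = True,
    seed: int = 0,
    modularity_restarts: int = 20,
) -> RemovalResult:
    """Delete whole habitats and apply the binary extinction rule.

    Species whose remaining column sum is zero are extinct; survivors
    keep their counts unchanged (no rewiring).  When ``compute_metrics``
    is set, diversity and network metrics are recomputed on the
    surviving community, with and without the flagged colonial species.
    """
    habitats = list(habitats)
    matrix = dataset.matrix.drop_habitats(habitats)
    surv, extinct = _surviving_dataset(dataset, matrix)
    metrics = None
    if compute_metrics:
        metrics = {
            "included": community_metrics(
                surv, seed=seed, modularity_restarts=modularity_restarts
            ),
            "excluded": community_metrics(
                drop_excluded(surv),
                seed=seed,
                modularity_restarts=modularity_restarts,
            ),
        }
    return RemovalResult(
        removed_habitats=tuple(habitats),
        surviving=surv,
        extinct_species=extinct,
        extinct_residency={
            s: dataset.species_meta[s].residency for s in extinct
        },
        metrics=metrics,
    )


def community_metrics(
    dataset: CommunityDataset,
    seed: int = 0,
    modularity_restarts: int = 20,
) -> dict[str, float]:
    """Diversity and network metrics of a (possibly shrunken) community.

    Community Shannon and Pielou pool abundances over habitats; network
    metrics are computed after dropping all-zero rows and columns (a
    4-habitat network remains after removing one of five habitats).
    Degenerate shapes (fewer than 2 rows or columns, or no links) yield
    NaN for the affected network metrics.
    """
    m = dataset.matrix
    pooled = m.col_sums()
    pooled = pooled[pooled > 0]
    out: dict[str, float] = {
        "species_number": float(pooled.size),
        "resident_number": float(
            sum(
                1
                for s, c in zip(m.species_labels, m.col_sums())
                if c > 0
                and dataset.species_meta[s].residency is Residency.RESIDENT
            )
        ),
        "migrant_number": float(
            sum(
                1
                for s, c in zip(m.species_labels, m.col_sums())
                if c > 0
                and dataset.species_meta[s].residency is Residency.MIGRANT
            )
        ),
    }
    out["shannon"] = shannon(pooled) if pooled.size else float("nan")
    out["pielou"] = pielou(pooled) if pooled.size else float("nan")

    # shrink to the realized network
    keep_rows = [
        lab for lab, s in zip(m.habitat_labels, m.row_sums()) if s > 0
    ]
    keep_cols = [
        lab for lab, c in zip(m.species_labels, m.col_sums()) if c > 0
    ]
    nan = float("nan")
    if not keep_rows or not keep_cols:
        out.update(connectance=nan, nodf=nan, modularity=nan)
        return out
    net = m.drop_habitats(
        [h for h in m.habitat_labels if h not in set(keep_rows)]
    ).select_species(keep_cols)
    out["connectance"] = connectance(net)
    out["nodf"] = (
        nodf(net) if net.n_habitats >= 2 and net.n_species >= 2 else nan
    )
    out["modularity"] = (
        barber_modularity(net, seed=seed, restarts=modularity_restarts).q
        if net.total() > 0
        else nan
    )
    return out


# ---------------------------------------------------------------------------
# gradual loss


def _partial_row_removal(
    row: np.ndarray, fraction: float, rng: np.random.Generator, unit: str
) -> np.ndarray:
    """Remove a fraction of a habitat row at random, without replacement.

    ``unit='individual'`` removes floor(f * rowsum) observation units (a
    multivariate hypergeometric draw of the survivors); ``unit='link'``
    removes floor(f * degree) whole links.
    """
    row = row.copy()
    if unit == "individual":
        total = int(row.sum())
        n_remove = math.floor(fraction * total)
        if n_remove >= total:
            return np.zeros_like(row)
        keep = rng.multivariate_hypergeometric(row, total - n_remove)
        return np.asarray(keep, dtype=row.dtype)
    if unit == "link":
        links = np.nonzero(row > 0)[0]
        n_remove = math.floor(fraction * links.size)
        gone = rng.choice(links, size=n_remove, replace=False)
        row[gone] = 0
        return row
    raise ValueError("unit must be 'individual' or 'link'")


def gradual_loss(
    dataset: CommunityDataset,
    habitat: str,
    loss_fractions: Sequence[float] | None = None,
    rng_seed: int = 0,
    replicates: int = 10,
    unit: str = "individual",
    modularity_restarts: int = 5,
) -> pd.DataFrame:
    """Metric trajectories under partial random loss of one habitat.

    For each fraction f the habitat's row loses floor(f * rowsum)
    individuals (or floor(f * degree) links) uniformly at random; a
    species goes extinct when all of its cells reach zero.  Returns a
    tidy frame (habitat, fraction, replicate, excluded, metric, value)
    over ``replicates`` independent draws, computed both with the full
    community and with flagged species excluded.
    """
    if loss_fractions is None:
        loss_fractions = np.round(np.linspace(0, 1, 11), 10)
    fractions = [float(f) for f in loss_fractions]
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("loss fractions must lie in [0, 1]")
    if sorted(fractions) != fractions:
        raise ValueError("loss fractions must be sorted ascending")
    i_row = dataset.matrix.habitat_index(habitat)
    master = np.random.SeedSequence(rng_seed)
    records = []
    for rep, child in enumerate(master.spawn(replicates)):
        rng = np.random.default_rng(child)
        for f in fractions:
            counts = dataset.matrix.counts.copy()
            counts[i_row] = _partial_row_removal(
                dataset.matrix.counts[i_row], f, rng, unit
            )
            state = CommunityDataset(
                dataset.matrix.with_counts(counts),
                dict(dataset.species_meta),
                dict(dataset.habitat_meta),
            )
            for excluded, ds in (
                (False, state),
                (True, drop_excluded(state)),
            ):
                mets = community_metrics(
                    ds, seed=rep, modularity_restarts=modularity_restarts
                )
                for metric, value in mets.items():
                    records.append(
                        {
                            "habitat": habitat,
                            "fraction": f,
                            "replicate": rep,
                            "excluded": excluded,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame.from_records(records)


def summarize_trajectories(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of each metric per (habitat, fraction, excluded)."""
    return (
        trajectories.groupby(["habitat", "fraction", "excluded", "metric"])[
            "value"
        ]
        .agg(["mean", "std"])
        .reset_index()
    )


# ---------------------------------------------------------------------------
# attack sequences and robustness


@dataclass(frozen=True)
class RobustnessResult:
    strategy: str
    removal_orders: tuple[tuple[str, ...], ...]
    # survival_curves[r, s] = fraction of species surviving after s steps
    survival_curves: np.ndarray = field(repr=False)
    r50: np.ndarray = field(repr=False)

    @property
    def removed_fractions(self) -> np.ndarray:
        n = self.survival_curves.shape[1] - 1
        return np.arange(n + 1) / n


def _strategy_order(
    dataset: CommunityDataset, strategy: str, rng: np.random.Generator
) -> list[str]:
    m = dataset.matrix
    labels = list(m.habitat_labels)
    if strategy == "random":
        return [labels[i] for i in rng.permutation(len(labels))]
    deg = dict(zip(labels, m.degrees()))
    tot = dict(zip(labels, m.row_sums()))
    if strategy == "most_connected":
        return sorted(labels, key=lambda h: (-deg[h], -tot[h], h))
    if strategy == "least_connected":
        return sorted(labels, key=lambda h: (deg[h], tot[h], h))
    areas = dataset.areas()
    if strategy == "largest_area":
        return sorted(labels, key=lambda h: (-areas[h], h))
    if strategy == "smallest_area":
        return sorted(labels, key=lambda h: (areas[h], h))
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def attack_sequence(
    dataset: CommunityDataset,
    strategy: str,
    replicates: int = 50,
    rng_seed: int = 0,
) -> RobustnessResult:
    """Remove habitats one at a time and score robustness as R50.

    The survival curve tracks the fraction of species still holding at
    least one habitat after each whole-habitat removal, until all nodes
    are lost.  R50 is the smallest fraction of habitats removed at which
    no more than half of the original species survive; with n habitats
    it takes values in {1/n, ..., 1}.  Deterministic strategies repeat
    the same order across replicates; the random strategy reshuffles per
    replicate from an independent stream of the master seed.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if strategy in ("largest_area", "smallest_area") and not dataset.habitat_meta:
        raise ValueError("area strategies require habitat metadata")
    n_hab = dataset.matrix.n_habitats
    n_sp = dataset.matrix.n_species
    master = np.random.SeedSequence(rng_seed)
    streams = master.spawn(replicates)
    orders = []
    curves = np.ones((replicates, n_hab + 1))
    r50 = np.empty(replicates)
    counts = dataset.matrix.counts
    for rep in range(replicates):
        rng = np.random.default_rng(streams[rep])
        order = _strategy_order(dataset, strategy, rng)
        orders.append(tuple(order))
        alive_rows = np.ones(n_hab, dtype=bool)
        r50[rep] = np.nan
        for step, hab in enumerate(order, start=1):
            alive_rows[dataset.matrix.habitat_index(hab)] = False
            surviving = int(
                np.count_nonzero(counts[alive_rows].sum(axis=0) > 0)
            )
            curves[rep, step] = surviving / n_sp
            if np.isnan(r50[rep]) and surviving <= 0.5 * n_sp:
                r50[rep] = step / n_hab
    return RobustnessResult(
        strategy=strategy,
        removal_orders=tuple(orders),
        survival_curves=curves,
        r50=r50,
    )


# ---------------------------------------------------------------------------
# strategy comparison


def _compact_letter_display(
    groups: Sequence[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Piepho insert-and-absorb compact letter display.

    ``significant`` holds unordered pairs that differ; groups sharing a
    letter are not significantly different.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant):
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                col_a = col - {b}
                col_b = col - {a}
                # absorb: keep only maximal columns
                for new in (col_a, col_b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    letters = {g: "" for g in groups}
    # stable letter order: columns sorted by their first member's position
    pos = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(pos[g] for g in col) if col else 1e9)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in groups}


def compare_robustness(
    results: Sequence[RobustnessResult], alpha: float = 0.05
) -> dict:
    """One-way ANOVA on R50 across attack strategies with Tukey letters.

    Returns the ANOVA p-value, per-strategy mean R50 and a compact
    letter display from Tukey HSD at ``alpha`` (strategies sharing no
    letter differ significantly).  When every replicate of every
    strategy produced the same R50 there is nothing to test and a
    degenerate flag is returned instead of a p-value.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 strategies to compare")
    samples = {r.strategy: np.asarray(r.r50, dtype=float) for r in results}
    if any(len(v) < 2 for v in samples.values()):
        raise ValueError("each strategy needs at least 2 replicate R50 values")
    values = np.concatenate(list(samples.values()))
    means = {s: float(v.mean()) for s, v in samples.items()}
    if np.ptp(values) == 0:
        return {
            "degenerate": True,
            "anova_p": None,
            "means": means,
            "letters": {s: "a" for s in samples},
        }
    anova = stats.f_oneway(*samples.values())
    strategies = list(samples)
    significant: set[tuple[str, str]] = set()
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate(
        [[s] * len(v) for s, v in samples.items()]
    )
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    res = tukey.summary().data[1:]
    for row in res:
        a, b, reject = str(row[0]), str(row[1]), bool(row[-1])
        if reject:
            significant.add(tuple(sorted((a, b))))
    letters = _compact_letter_display(
        sorted(strategies, key=lambda s: means[s]), significant
    )
    return {
        "degenerate": False,
        "anova_p": float(anova.pvalue),
        "means": means,
        "letters": letters,
    }
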