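"""Network-level and per-habitat metrics of the bipartite network.

Network level: connectance C, nestedness NODF (Almeida-Neto overlap and
decreasing fill, on the presence-absence matrix) and Barber's bipartite
modularity Q maximised by restarted simulated annealing.

Per habitat: strength (sum of species' dependences on the habitat),
interaction asymmetry (signed push-pull imbalance, positive when the
habitat influences species more than it is influenced), nested rank
(normalised position in the degree-packed matrix) and a standardised
specialization index d' (Kullback-Leibler divergence of the habitat's
usage distribution from overall species availability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import InteractionMatrix, binarize

__all__ = [
    "connectance",
    "nodf",
    "barber_modularity",
    "ModularityResult",
    "habitat_strength",
    "interaction_asymmetry",
    "nested_rank",
    "specificity",
    "network_report",
    "NetworkReport",
]


def connectance(matrix: InteractionMatrix) -> float:
    """Realized links over possible links, L / (I * J)."""
    if matrix.n_habitats == 0 or matrix.n_species == 0:
        raise ValueError("empty matrix")
    return matrix.link_count() / (matrix.n_habitats * matrix.n_species)


def _nodf_axis(b: np.ndarray) -> tuple[float, int]:
    """Summed paired overlap over ordered row pairs of a binary matrix.

    A pair (u, v) with fill(u) > fill(v) > 0 contributes
    ``100 * |ones(u) & ones(v)| / fill(v)``; equal fills (decreasing-fill
    condition violated) and empty rows contribute zero.
    """
    fills = b.sum(axis=1)
    overlap = b @ b.T
    n = b.shape[0]
    total = 0.0
    for u in range(n):
        for v in range(n):
            if u != v and fills[u] > fills[v] > 0:
                total += 100.0 * overlap[u, v] / fills[v]
    return total, n * (n - 1) // 2


def nodf(matrix: InteractionMatrix) -> float:
    """NODF nestedness in [0, 100] of the binarized matrix."""
    if matrix.n_habitats < 2 or matrix.n_species < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")
    b = (matrix.counts > 0).astype(np.int64)
    row_sum, row_pairs = _nodf_axis(b)
    col_sum, col_pairs = _nodf_axis(b.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


# ---------------------------------------------------------------------------
# Barber bipartite modularity


@dataclass(frozen=True)
class ModularityResult:
    """Best partition found and its Q; optimizer metadata for replay."""

    q: float
    habitat_modules: tuple[int, ...]
    species_modules: tuple[int, ...]
    seed: int
    restarts: int
    restart_scores: tuple[float, ...] = field(repr=False, default=())

    @property
    def n_modules(self) -> int:
        return len(set(self.habitat_modules) | set(self.species_modules))


def modularity_score(
    matrix: InteractionMatrix,
    habitat_modules,
    species_modules,
) -> float:
    """Barber's bipartite Q of a given partition.

    Q = (1/m) * sum_ij (A_ij - k_i d_j / m) * delta(g_i, g_j), with m the
    total interaction weight, k the habitat (row) weights and d the
    species (column) weights.
    """
    a = matrix.counts.astype(float)
    m = a.sum()
    if m == 0:
        raise ValueError("empty matrix")
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    gh = np.asarray(habitat_modules)
    gs = np.asarray(species_modules)
    same = gh[:, None] == gs[None, :]
    null = np.outer(k, d) / m
    return float(((a - null) * same).sum() / m)


def _anneal_once(
    a: np.ndarray,
    rng: np.random.Generator,
    t0: float,
    cooling: float,
    t_min: float,
    moves_per_temp: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One simulated-annealing run over joint habitat+species labels."""
    n_h, n_s = a.shape
    m = a.sum()
    k = a.sum(axis=1)  # habitat weights
    d = a.sum(axis=0)  # species weights
    n_mod = min(n_h, n_s) + 1  # extra slot lets nodes sit alone at no cost

    gh = rng.integers(0, n_mod, size=n_h)
    gs = rng.integers(0, n_mod, size=n_s)

    # within-module weight seen by each node, per module
    w_h = np.zeros((n_h, n_mod))  # w_h[i, c] = sum_{j in c} A_ij
    w_s = np.zeros((n_s, n_mod))
    for c in range(n_mod):
        w_h[:, c] = a[:, gs == c].sum(axis=1)
        w_s[:, c] = a[gh == c].sum(axis=0)
    mod_k = np.bincount(gh, weights=k, minlength=n_mod)
    mod_d = np.bincount(gs, weights=d, minlength=n_mod)

    q = (
        sum(w_h[i, gh[i]] for i in range(n_h)) - mod_k @ mod_d / m
    ) / m

    best_q, best = q, (gh.copy(), gs.copy())
    t = t0
    n_tot = n_h + n_s
    while t > t_min:
        nodes = rng.integers(0, n_tot, size=moves_per_temp)
        targets = rng.integers(0, n_mod, size=moves_per_temp)
        accept_u = rng.random(size=moves_per_temp)
        for node, b, u in zip(nodes, targets, accept_u):
            if node < n_h:
                i = node
                c = gh[i]
                if b == c:
                    continue
                dq = (
                    (w_h[i, b] - w_h[i, c])
                    - k[i] * (mod_d[b] - mod_d[c]) / m
                ) / m
                if dq > 0 or u < math.exp(dq / t):
                    gh[i] = b
                    mod_k[c] -= k[i]
                    mod_k[b] += k[i]
                    w_s[:, c] -= a[i]
                    w_s[:, b] += a[i]
                    q += dq
            else:
                j = node - n_h
                c = gs[j]
                if b == c:
                    continue
                dq = (
                    (w_s[j, b] - w_s[j, c])
                    - d[j] * (mod_k[b] - mod_k[c]) / m
                ) / m
                if dq > 0 or u < math.exp(dq / t):
                    gs[j] = b
                    mod_d[c] -= d[j]
                    mod_d[b] += d[j]
                    w_h[:, c] -= a[:, j]
                    w_h[:, b] += a[:, j]
                    q += dq
            if q > best_q + 1e-12:
                best_q = q
                best = (gh.copy(), gs.copy())
        t *= cooling
    return best_q, best[0], best[1]


def barber_modularity(
    matrix: InteractionMatrix,
    seed: int = 0,
    restarts: int = 20,
    weighted: bool = True,
    t0: float = 0.05,
    cooling: float = 0.9,
    t_min: float = 1e-4,
    moves_per_node: int = 10,
) -> ModularityResult:
    """Maximise Barber's bipartite Q by restarted simulated annealing.

    Counts are used as weights by default (``weighted=False`` binarizes
    first).  The 62-node scale of an island community network is small
    enough that annealing with a handful of restarts reliably finds the
    optimum; ``seed`` makes the whole run reproducible and the best of
    ``restarts`` independent runs is returned.
    """
    if matrix.total() == 0:
        raise ValueError("empty matrix")
    work = matrix if weighted else binarize(matrix)
    a = work.counts.astype(float)
    rng = np.random.default_rng(seed)
    moves = moves_per_node * (matrix.n_habitats + matrix.n_species)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    scores = []
    for _ in range(restarts):
        q, gh, gs = _anneal_once(a, rng, t0, cooling, t_min, moves)
        scores.append(q)
        if best is None or q > best[0]:
            best = (q, gh, gs)
    assert best is not None
    q, gh, gs = best
    # relabel modules consecutively for stable output
    labels = {}
    for g in list(gh) + list(gs):
        if g not in labels:
            labels[g] = len(labels)
    q_check = modularity_score(work, gh, gs)
    return ModularityResult(
        q=q_check,
        habitat_modules=tuple(labels[g] for g in gh),
        species_modules=tuple(labels[g] for g in gs),
        seed=seed,
        restarts=restarts,
        restart_scores=tuple(scores),
    )


# ---------------------------------------------------------------------------
# per-habitat (species-level) indices


def habitat_strength(matrix: InteractionMatrix) -> pd.Series:
    """Sum over species of their dependence on each habitat.

    strength_i = sum_j A_ij / colsum_j.  Each species' dependences sum
    to one, so strengths sum to the species count.
    """
    col = matrix.col_sums().astype(float)
    if (col == 0).any():
        bad = [
            s for s, c in zip(matrix.species_labels, col) if c == 0
        ]
        raise ValueError(f"species with zero column sum: {bad}")
    dep = matrix.counts / col  # dependence of species j on habitat i
    return pd.Series(
        dep.sum(axis=1), index=list(matrix.habitat_labels), name="strength"
    )


def interaction_asymmetry(matrix: InteractionMatrix) -> pd.Series:
    """Mean signed dependence imbalance over each habitat's links.

    For a realized link (i, j), the habitat's pull on the species is
    e_ij = A_ij / colsum_j and the species' pull on the habitat is
    d_ij = A_ij / rowsum_i; the link asymmetry (e - d) / max(e, d) lies
    in [-1, 1] and is positive when the habitat exerts more influence
    than it receives.  The habitat value averages over its links.
    """
    a = matrix.counts.astype(float)
    row = a.sum(axis=1, keepdims=True)
    col = a.sum(axis=0, keepdims=True)
    values = []
    for i, hab in enumerate(matrix.habitat_labels):
        links = np.nonzero(a[i] > 0)[0]
        if links.size == 0:
            raise ValueError(f"habitat {hab!r} has no links")
        e = a[i, links] / col[0, links]
        d = a[i, links] / row[i, 0]
        asym = (e - d) / np.maximum(e, d)
        values.append(asym.mean())
    return pd.Series(
        values, index=list(matrix.habitat_labels), name="asymmetry"
    )


def nested_rank(matrix: InteractionMatrix) -> pd.Series:
    """Normalised habitat position in the degree-packed matrix.

    Habitats sorted by decreasing degree (species links) take ranks
    0, 1/(n-1), ..., 1; low rank marks the generalist core.  Ties break
    by decreasing total abundance, then by label order.
    """
    n = matrix.n_habitats
    if n < 2:
        raise ValueError("nested rank needs at least 2 habitats")
    deg = matrix.degrees()
    tot = matrix.row_sums()
    order = sorted(
        range(n),
        key=lambda i: (-deg[i], -tot[i], matrix.habitat_labels[i]),
    )
    ranks = np.empty(n)
    for r, i in enumerate(order):
        ranks[i] = r / (n - 1)
    return pd.Series(
        ranks, index=list(matrix.habitat_labels), name="nested_rank"
    )


def specificity(matrix: InteractionMatrix) -> pd.Series:
    """Standardised specialization d' of each habitat, in [0, 1].

    Raw specialization is the Kullback-Leibler divergence of the
    habitat's usage distribution p'_ij = A_ij / rowsum_i from overall
    species availability q_j = colsum_j / total.  Given the margins, the
    divergence is bounded by ln(total / rowsum_i) — attained when the
    habitat's species occur nowhere else — so d' = d / ln(total/rowsum)
    maps opportunistic use to 0 and full specialization to 1.
    """
    a = matrix.counts.astype(float)
    total = a.sum()
    if total == 0:
        raise ValueError("empty matrix")
    q = a.sum(axis=0) / total
    values = []
    for i, hab in enumerate(matrix.habitat_labels):
        r = a[i].sum()
        if r == 0:
            raise ValueError(f"habitat {hab!r} has an empty row")
        links = a[i] > 0
        p = a[i, links] / r
        d_raw = float((p * np.log(p / q[links])).sum())
        d_max = math.log(total / r)
        values.append(min(d_raw / d_max, 1.0) if d_max > 0 else 0.0)
    return pd.Series(
        values, index=list(matrix.habitat_labels), name="specificity"
    )


# ---------------------------------------------------------------------------
# report bundle


@dataclass(frozen=True)
class NetworkReport:
    connectance: float
    nodf: float
    modularity: ModularityResult
    per_habitat: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "connectance": self.connectance,
            "nodf": self.nodf,
            "modularity": {
                "Q": self.modularity.q,
                "n_modules": self.modularity.n_modules,
                "seed": self.modularity.seed,
                "restarts": self.modularity.restarts,
            },
            "per_habitat": self.per_habitat.round(6).to_dict(orient="index"),
        }


def network_report(
    matrix: InteractionMatrix,
    seed: int = 0,
    restarts: int = 20,
    weighted_modularity: bool = True,
) -> NetworkReport:
    """Compute the full network-level and per-habitat metric bundle."""
    mod = barber_modularity(
        matrix, seed=seed, restarts=restarts, weighted=weighted_modularity
    )
    per_habitat = pd.concat(
        [
            habitat_strength(matrix),
            interaction_asymmetry(matrix),
            nested_rank(matrix),
            specificity(matrix),
        ],
        axis=1,
    )
    return NetworkReport(
        connectance=connectance(matrix),
        nodf=nodf(matrix),
        modularity=mod,
        per_habitat=per_habitat,
    )
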