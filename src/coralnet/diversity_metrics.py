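"""Per-habitat and community diversity statistics.

Richness S, Shannon-Wiener H (natural log) and Pielou evenness
J = H / ln S, plus the Pearson test of the richness-area relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CommunityDataset, HabitatInfo, InteractionMatrix, Residency

__all__ = [
    "richness",
    "shannon",
    "pielou",
    "diversity_report",
    "richness_area_correlation",
]


def richness(matrix: InteractionMatrix, habitat: str) -> int:
    """Number of species with a positive count in ``habitat``."""
    return int(np.count_nonzero(matrix.row(habitat)))


def shannon(abundances) -> float:
    """Shannon-Wiener index H = -sum p_k ln p_k, in nats.

    Zero counts are ignored; an all-zero vector raises.
    """
    x = np.asarray(abundances, dtype=float)
    if x.size and x.min() < 0:
        raise ValueError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("at least one positive abundance is required")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def pielou(abundances) -> float:
    """Pielou evenness J = H / ln S; defined as 0 for a single species."""
    x = np.asarray(abundances, dtype=float)
    s = int(np.count_nonzero(x > 0))
    if s == 0:
        raise ValueError("at least one positive abundance is required")
    if s == 1:
        return 0.0
    return shannon(x) / np.log(s)


@dataclass(frozen=True)
class HabitatDiversity:
    habitat: str
    richness: int
    richness_pct: float
    resident_richness: int
    resident_pct: float
    migrant_richness: int
    migrant_pct: float
    shannon: float
    pielou: float


def diversity_report(dataset: CommunityDataset) -> pd.DataFrame:
    """Per-habitat diversity table.

    Percentages are relative to the community totals of the matching
    class (all species, residents, migrants); they can sum past 100
    because species use several habitats.  Rows follow matrix habitat
    order; an all-zero habitat row yields richness 0 and NaN H and J.
    """
    m = dataset.matrix
    n_total = m.n_species
    residents = set(dataset.species_by_residency(Residency.RESIDENT))
    migrants = set(dataset.species_by_residency(Residency.MIGRANT))
    rows = []
    for hab in m.habitat_labels:
        counts = m.row(hab)
        present = {
            s for s, c in zip(m.species_labels, counts) if c > 0
        }
        s_all = len(present)
        s_res = len(present & residents)
        s_mig = len(present & migrants)
        rows.append(
            HabitatDiversity(
                habitat=hab,
                richness=s_all,
                richness_pct=round(100 * s_all / n_total, 2) if n_total else 0.0,
                resident_richness=s_res,
                resident_pct=round(100 * s_res / len(residents), 2)
                if residents
                else 0.0,
                migrant_richness=s_mig,
                migrant_pct=round(100 * s_mig / len(migrants), 2)
                if migrants
                else 0.0,
                shannon=shannon(counts) if s_all else float("nan"),
                pielou=pielou(counts) if s_all else float("nan"),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("habitat")


def richness_area_correlation(
    report: pd.DataFrame, habitat_meta: dict[str, HabitatInfo]
) -> dict[str, float]:
    """Pearson correlation between per-habitat richness and area (ha).

    Two-sided t-test on r with n - 2 degrees of freedom.  Requires at
    least 3 habitats and non-constant richness and area vectors.
    """
    habitats = list(report.index)
    if len(habitats) < 3:
        raise ValueError("need at least 3 habitats for a correlation test")
    rich = report["richness"].to_numpy(dtype=float)
    areas = np.array([habitat_meta[h].area_ha for h in habitats], dtype=float)
    if np.ptp(rich) == 0 or np.ptp(areas) == 0:
        raise ValueError("zero variance in richness or area")
    r, p = stats.pearsonr(rich, areas)
    return {"r": float(r), "p": float(p), "n": len(habitats)}
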