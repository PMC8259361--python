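import numpy as np
import pytest

from coralnet import (
    CommunityDataset,
    HabitatInfo,
    InteractionMatrix,
    SpeciesInfo,
    generate,
)


def make_matrix(counts, habitats=None, species=None) -> InteractionMatrix:
    counts = np.asarray(counts)
    habitats = habitats or tuple(f"h{i}" for i in range(counts.shape[0]))
    species = species or tuple(f"s{j}" for j in range(counts.shape[1]))
    return InteractionMatrix(tuple(habitats), tuple(species), counts)


def make_dataset(
    counts,
    habitats=None,
    species=None,
    residency=None,
    areas=None,
    exclude=(),
) -> CommunityDataset:
    """Small hand-built dataset; residency defaults to alternating classes."""
    matrix = make_matrix(counts, habitats, species)
    residency = residency or [
        "migrant" if j % 2 else "resident"
        for j in range(matrix.n_species)
    ]
    areas = areas or [float(i + 1) for i in range(matrix.n_habitats)]
    return CommunityDataset(
        matrix,
        {
            s: SpeciesInfo(s, r, exclude_flag=s in exclude)
            for s, r in zip(matrix.species_labels, residency)
        },
        {
            h: HabitatInfo(h, a)
            for h, a in zip(matrix.habitat_labels, areas)
        },
    )


@pytest.fixture(scope="session")
def surrogate():
    """Default-configuration synthetic island community (fixed seed)."""
    return generate(seed=0)


def random_matrix(rng, max_rows=6, max_cols=6, max_count=9, min_rows=2, min_cols=2):
    """Random count matrix without all-zero rows or columns."""
    while True:
        n_r = rng.integers(min_rows, max_rows + 1)
        n_c = rng.integers(min_cols, max_cols + 1)
        counts = rng.integers(0, max_count + 1, size=(n_r, n_c))
        counts[rng.random(counts.shape) < 0.4] = 0
        if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).all():
            return make_matrix(counts)
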