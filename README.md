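# coralnet

Bipartite bird–habitat network analysis and habitat-loss co-extinction
simulation for island bird communities.

Small oceanic islands hold few habitat types, and their bird communities —
largely migrants using the island as a stopover, plus a handful of resident
breeders — depend on those habitats very unevenly. A community survey can be
summarised as a weighted bipartite network: a *flux matrix* `A` whose entry
`A[i, j]` counts the individuals of bird species `j` recorded in habitat `i`.
`coralnet` takes that matrix (plus per-species residency classes and
per-habitat areas) and answers two questions that matter for conservation
planning: *which habitats structure the community*, and *what happens to the
bird community as habitats shrink or disappear*.

## What it computes

**Diversity per habitat** — richness `S`, Shannon–Wiener `H = −Σ pₖ ln pₖ`
(natural log), Pielou evenness `J = H / ln S`, split by residency class, and
the Pearson test of the richness–area relationship.

**Network structure** — connectance `C = L/(I·J)`; nestedness NODF
(Almeida-Neto overlap-and-decreasing-fill, on the presence–absence matrix);
and Barber's bipartite modularity

```
Q = (1/m) Σᵢⱼ (Aᵢⱼ − kᵢ dⱼ / m) δ(gᵢ, gⱼ)
```

maximised over joint habitat+species partitions by restarted simulated
annealing (counts as weights by default).

**Habitat roles** — habitat strength `sᵢ = Σⱼ Aᵢⱼ / Σᵢ′ Aᵢ′ⱼ` (species'
dependences sum to 1, so strengths sum to the species count); push–pull
interaction asymmetry in [−1, 1]; normalised nested rank; and a
Blüthgen-style standardised specialization `d′` in [0, 1].

**Similarity trees** — UPGMA dendrograms over Bray–Curtis (or Jaccard)
habitat distances, for the total, migrant-only and resident-only
communities, serialised as Newick.

**Habitat loss** — whole-habitat deletion with the binary secondary-
extinction rule (a species is lost exactly when every habitat it uses is
gone; birds cannot switch habitats), gradual random loss of one habitat with
metric trajectories, and attack sequences (random, most/least connected,
largest/smallest area) scored by survival curves and R50 — the fraction of
habitats that must be removed before no more than half the species survive —
compared across strategies by one-way ANOVA with Tukey compact letters.

A synthetic-community generator reproduces the statistical structure of a
five-habitat coral-island survey (57 species, ~65 % migrants, ~100 links,
wetland-centred migrants, forest-centred residents, one hyper-abundant
colonial seabird), so the whole pipeline is testable without field data.

## Worked example

```python
import coralnet as cn

ds = cn.generate(seed=42)          # synthetic island community
print(ds.summary())
rep = cn.network_report(ds.matrix, seed=0)
print(round(rep.connectance, 4), round(rep.nodf, 2), round(rep.modularity.q, 3))
```

prints

```
{'n_habitats': 5, 'n_species': 57, 'n_links': 87, 'total_individuals': 6219,
 'n_resident': 19, 'n_migrant': 38, 'empty_habitats': []}
0.3053 33.54 0.26
```

— 87 of 285 possible habitat–species links are realized (moderate
connectance), the network is substantially nested (NODF 33.5 of 100), and
only weakly modular (Q 0.26). Removing the wetland habitat and applying the
binary extinction rule:

```python
res = cn.remove_habitats(ds, ["wetlands"])
print(len(res.extinct_species), len(res.extinct_by_residency("migrant")))
# 23 20
```

23 species lose their last habitat, 20 of them migrants — the wetland is the
migrant hub. Attack sequences make the same point at the community scale:

```python
means = {s: cn.attack_sequence(ds, s, replicates=50, rng_seed=0).r50.mean()
         for s in cn.coextinction_sim.STRATEGIES}
# {'random': 0.73, 'most_connected': 0.4, 'least_connected': 1.0,
#  'largest_area': 1.0, 'smallest_area': 0.4}
```

Removing habitats smallest-first (the wetland is the smallest) or
best-connected-first halves the community after 40 % of habitats are gone,
while largest-first leaves half the species standing until the very last
removal.

The same analyses run from the shell:

```
coralnet synth --seed 42 --out data/
coralnet run --matrix data/matrix.csv --species data/species.tsv \
             --habitats data/habitats.tsv --seed 42 --out results/
```

which writes `table1.csv` (per-habitat diversity and role metrics),
`network.json`, three Newick trees, per-habitat removal and gradual-loss
tables, and the R50 robustness comparison, reproducibly from the one seed.

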