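# protstoich

Proteome resource allocation, nonparametric Bayesian local biclustering,
and elemental-stoichiometry variance partitioning for factorial chemostat
experiments on marine picocyanobacteria.

## The problem

How do nutrient supply and temperature shape the elemental composition
(C:N:P) of a phytoplankton cell? A factorial chemostat design — two
nutrient regimes (N:P input 1.7 vs 80) × three temperatures (20, 24,
28 °C) × five replicates — holds growth rate fixed so the two drivers can
be separated, with DIA-MS proteomics linking the chemical answer to the
underlying protein traits. `protstoich` implements the computational
chain for such a study, for researchers in microbial ecology and
ecological stoichiometry:

1. **Allocation** (`protstoich.abundance`): filter protein×sample peak
   areas (≥2 peptides; ≤2 missing of 30 samples), equalize per-sample
   totals, and compute the resource-allocation metric
   `%PA_Total = PA(protein or group) / PA_Total × 100` for trait groups
   (P-acquisition, ribosomal, heat shock, …).
2. **Biclustering** (`protstoich.biclust`): NoB-LoC — a Dirichlet-process
   mixture with a zero-enriched Pólya urn in which protein *g* is variant
   with probability π₀ and each protein set carries its own local
   partition of the samples (with inactive samples). Collapsed Gibbs
   sampling with conjugate Normal–Inverse-Gamma blocks; the point
   estimate ω^LS minimizes the summed pairwise co-clustering distance
   H(ω, ω′) = Σ_{g<g′} |I(ω_g=ω_{g′}) − I(ω′_g=ω′_{g′})| over visited
   partitions.
3. **Stoichiometry** (`protstoich.stoich`): cell quotas
   Q_X = X·10⁹/cells (fmol cell⁻¹), molar C:P/N:P/C:N, two-way ANOVA and
   two-way sequential PERMANOVA variance partitioning
   (nutrient / temperature / other), Benjamini–Hochberg pairwise tests.
4. **Synthetic data** (`protstoich.synth`): the 30-sample design with
   planted biclusters and known elemental effects, so every stage has a
   ground-truth test surface.
5. **Pipeline** (`protstoich.pipeline`, CLI `protstoich`): one-seed
   reproducible orchestration with a hashed run manifest.

Model details, defaults, and limitations: [docs/methods.md](docs/methods.md).

## Worked example

`examples/03_biclustering.py` plants three biclusters (15 proteins each,
block separation 2 log-SD, cell noise 0.5) plus 15 unstructured proteins
in a 60×30 matrix, runs the sampler, and compares the least-squares
partition with the truth:

```
$ python examples/03_biclustering.py
estimated: 3 biclusters (sizes [15, 15, 15]), 15 invariant proteins
planted:   3 biclusters (sizes [15, 15, 15]), 15 invariant proteins
adjusted Rand index vs truth: 1.000  (1.0 = perfect recovery)
posterior scaled-distance median: 0.0000 (near 0 = partition uncertainty is low)
```

The adjusted Rand index of 1.0 means every protein was assigned to its
planted set; the scaled posterior distance near zero means the chain's
partitions barely disagree with the point estimate, i.e. the clustering
is confidently determined. The other examples cover data generation
(`01`), allocation summaries (`02`), variance partitioning (`04`), and
the full pipeline with its manifest (`05`).

The same operations run from the shell:

```bash
protstoich simulate --proteins 200 --seed 1 --out run/
protstoich allocate --input run/abundance.tsv --groups run/groups.tsv --out run/
protstoich bicluster --input run/normalized.tsv --pi0 0.01 --iters 35000 --burnin 5000 --seed 1 --out run/
protstoich stats anova --response C:P --table run/elemental.tsv
protstoich run --paper-defaults --seed 1 --out run/   # full pipeline
```

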