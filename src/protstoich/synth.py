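"""Synthetic factorial-design data with planted, recoverable structure.

The generator emulates a 2 nutrient-regime × 3 temperature × 5 replicate
chemostat experiment (30 samples): a log-normal protein×sample peak-area
matrix containing planted biclusters — protein sets sharing a local
partition of the samples — plus unstructured ("invariant") proteins, and a
per-sample elemental table (POC/PON/POP, cell density, forward scatter)
with additive factor effects on the underlying cell quotas.

Ground truth is carried alongside the data so every downstream stage
(filtering, allocation, biclustering, variance partitioning) can be tested
against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix

NUTRIENT_REGIMES = ("N_stress", "P_stress")  # N:P input 1.7 and 80
TEMPERATURES = (20, 24, 28)  # °C
N_REPLICATES = 5

#: Input molar N:P supply ratio for each regime.
NP_INPUT = {"N_stress": 1.7, "P_stress": 80.0}


def make_design() -> pd.DataFrame:
    """Full factorial 2 regimes × 3 temperatures × 5 replicates (30 samples).

    Returns a DataFrame with columns ``sample_id``, ``nutrient_regime``,
    ``temperature``, ``replicate``; sample ids are unique by construction.
    """
    rows = []
    for regime in NUTRIENT_REGIMES:
        for temp in TEMPERATURES:
            for rep in range(1, N_REPLICATES + 1):
                rows.append(
                    {
                        "sample_id": f"{regime[0]}{temp}_r{rep}",
                        "nutrient_regime": regime,
                        "temperature": temp,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PlantedStructure:
    """Ground-truth biclustering used to build a synthetic proteome matrix.

    ``protein_membership[g] = k`` places protein ``g`` in bicluster ``k``
    (0 = invariant).  For each bicluster ``k``, ``sample_partitions[k][s]``
    gives sample ``s``'s subcluster (0 = inactive sample, drawn from the
    baseline), and ``block_means[k][j-1]`` the log-abundance mean of
    subcluster ``j``.  All means are natural-log peak-area units.
    """

    protein_membership: np.ndarray
    sample_partitions: dict[int, np.ndarray]
    block_means: dict[int, np.ndarray]
    noise_sd: float = 1.0
    baseline_mean: float = 14.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        self.protein_membership = np.asarray(self.protein_membership, dtype=int)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for k in self.biclusters:
            if (self.protein_membership == k).sum() < 2:
                raise ValueError(f"bicluster {k} has fewer than 2 proteins")
            part = np.asarray(self.sample_partitions[k], dtype=int)
            self.sample_partitions[k] = part
            n_sub = int(part.max()) if part.size else 0
            for j in range(1, n_sub + 1):
                if (part == j).sum() < 1:
                    raise ValueError(f"bicluster {k}, subcluster {j} is empty")
            means = np.asarray(self.block_means[k], dtype=float)
            if means.size != n_sub or not np.all(np.isfinite(means)):
                raise ValueError(f"bicluster {k}: block means invalid")
            self.block_means[k] = means

    @property
    def n_proteins(self) -> int:
        return self.protein_membership.size

    @property
    def biclusters(self) -> list[int]:
        return sorted(int(k) for k in np.unique(self.protein_membership) if k > 0)

    def truth_frame(self, protein_ids: list[str]) -> pd.DataFrame:
        """Two-column ground-truth table (protein_id, bicluster_id)."""
        member = np.zeros(len(protein_ids), dtype=int)
        member[: self.n_proteins] = self.protein_membership
        return pd.DataFrame({"protein_id": protein_ids, "bicluster_id": member})


def planted_structure(
    design: pd.DataFrame,
    G: int = 200,
    K: int = 4,
    proteins_per_bicluster: int = 15,
    separation: float = 2.0,
    noise_sd: float = 1.0,
    baseline_mean: float = 14.0,
    baseline_sd: float = 1.0,
) -> PlantedStructure:
    """Build a default planted structure tied to the factorial design.

    Bicluster sample partitions follow the design factors so planted
    patterns resemble real treatment responses, and are pairwise distinct
    (a bicluster is identified by its local sample partition):

    1. split by nutrient regime (2 subclusters);
    2. split by temperature (3 subclusters);
    3. 20 °C vs {24, 28} °C (2 subclusters);
    4. regime × temperature cells (6 subclusters).

    ``separation`` is the log-scale spread between adjacent block means; at
    the default ``noise_sd`` of 1.0 it is measured in noise SD units.
    """
    if not 1 <= K <= 4:
        raise ValueError("the default factory supports 1 <= K <= 4 biclusters")
    if G < K * proteins_per_bicluster:
        raise ValueError("G smaller than the planted structure")
    regime = design["nutrient_regime"].to_numpy()
    temp = design["temperature"].to_numpy()

    partitions: dict[int, np.ndarray] = {}
    means: dict[int, np.ndarray] = {}
    patterns = {
        1: pd.factorize(regime)[0] + 1,
        2: pd.factorize(temp)[0] + 1,
        3: np.where(temp == 20, 1, 2),
        4: pd.factorize(pd.Series(zip(regime, temp)))[0] + 1,
    }
    for k in range(1, K + 1):
        part = np.asarray(patterns[k], dtype=int)
        n_sub = int(part.max())
        offsets = separation * (np.arange(n_sub) - (n_sub - 1) / 2.0)
        partitions[k] = part
        means[k] = baseline_mean + offsets

    membership = np.zeros(G, dtype=int)
    for k in range(1, K + 1):
        lo = (k - 1) * proteins_per_bicluster
        membership[lo : lo + proteins_per_bicluster] = k
    return PlantedStructure(
        protein_membership=membership,
        sample_partitions=partitions,
        block_means=means,
        noise_sd=noise_sd,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
    )


def simulate_proteome(
    design: pd.DataFrame,
    G: int,
    structure: PlantedStructure,
    seed: int,
    missing_rate: float = 0.0,
    min_peptides: int = 2,
    mean_extra_peptides: float = 6.0,
) -> tuple[AbundanceMatrix, PlantedStructure]:
    """Simulate a G×S positive peak-area matrix with planted biclusters.

    Log peak areas of protein ``g`` in bicluster ``k`` and sample ``s`` in
    subcluster ``j`` are drawn Normal(block_mean[k][j], noise_sd²); invariant
    proteins and inactive samples are drawn Normal(baseline_mean,
    baseline_sd²).  Values are exponentiated to peak areas.  Missing cells
    (rate ``missing_rate``) are flagged, not imputed.  The same seed yields
    the same matrix.
    """
    if G < structure.n_proteins:
        raise ValueError(
            f"G={G} smaller than planted structure ({structure.n_proteins} proteins)"
        )
    if structure.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    S = len(design)
    logpa = rng.normal(structure.baseline_mean, structure.baseline_sd, size=(G, S))
    for k in structure.biclusters:
        part = structure.sample_partitions[k]
        rows = np.flatnonzero(
            np.pad(structure.protein_membership, (0, G - structure.n_proteins)) == k
        )
        for j in range(1, int(part.max()) + 1):
            cols = np.flatnonzero(part == j)
            logpa[np.ix_(rows, cols)] = rng.normal(
                structure.block_means[k][j - 1],
                structure.noise_sd,
                size=(rows.size, cols.size),
            )
    values = np.exp(logpa)
    missing = rng.random(size=(G, S)) < missing_rate
    values[missing] = 0.0
    peptide_counts = min_peptides + rng.poisson(mean_extra_peptides, size=G)
    matrix = AbundanceMatrix(
        protein_ids=[f"SYN{g:04d}" for g in range(G)],
        peptide_counts=peptide_counts,
        values=values,
        missing_mask=missing,
        sample_ids=list(design["sample_id"]),
    )
    return matrix, structure


@dataclass
class ElementalEffects:
    """Additive factor effects on per-cell quotas and the size proxy.

    Baselines are fmol cell⁻¹ (quotas) and instrument units (FSC_H);
    offsets are added for the named factor level.  Defaults emulate the
    study conditions: the P quota is ~3-fold higher under N- than P-stress,
    carbon density is slightly elevated under N-stress, cells are smallest
    at 24 °C and largest at 28 °C.
    """

    baselines: dict[str, float] = field(
        default_factory=lambda: {"Q_C": 20.0, "Q_N": 3.0, "Q_P": 0.2, "FSC_H": 1000.0}
    )
    nutrient: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Q_C": {"N_stress": 2.0},
            "Q_N": {"P_stress": 0.3},
            "Q_P": {"N_stress": 0.4},
            "FSC_H": {"P_stress": 100.0},
        }
    )
    temperature: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "Q_C": {28: 2.0},
            "FSC_H": {24: -100.0, 28: 150.0},
        }
    )

    def expected(self, variable: str, regime: str, temp: int) -> float:
        base = self.baselines[variable]
        base += self.nutrient.get(variable, {}).get(regime, 0.0)
        base += self.temperature.get(variable, {}).get(temp, 0.0)
        return base


def simulate_elemental(
    design: pd.DataFrame,
    effects: ElementalEffects | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    cell_density: float = 2.0e11,
) -> pd.DataFrame:
    """Simulate a 30-row elemental table consistent with the design.

    Per-cell quotas are drawn around additive factor effects with Gaussian
    noise (``noise_sd`` is a fraction of each variable's baseline, i.e. a
    CV), then converted to particulate concentrations::

        POC [μmol L⁻¹] = Q_C [fmol cell⁻¹] × cell_density [cells L⁻¹] / 10⁹

    so that quota computation downstream recovers the drawn quotas exactly.
    """
    effects = effects or ElementalEffects()
    if any(v <= 0 for v in effects.baselines.values()):
        raise ValueError("quota/FSC_H baselines must be positive")
    rng = np.random.default_rng(seed)
    out = design.copy()
    quotas = {}
    for var in ("Q_C", "Q_N", "Q_P", "FSC_H"):
        mu = np.array(
            [
                effects.expected(var, r, t)
                for r, t in zip(design["nutrient_regime"], design["temperature"])
            ]
        )
        sd = noise_sd * effects.baselines[var]
        quotas[var] = mu + rng.normal(0.0, sd, size=len(design)) if sd > 0 else mu
    density = cell_density * (
        1.0 + (rng.normal(0.0, noise_sd, size=len(design)) if noise_sd > 0 else 0.0)
    )
    out["POC"] = quotas["Q_C"] * density / 1e9
    out["PON"] = quotas["Q_N"] * density / 1e9
    out["POP"] = quotas["Q_P"] * density / 1e9
    out["cell_density"] = density
    out["FSC_H"] = quotas["FSC_H"]
    return out


TRAIT_VOCABULARY = (
    "P-acquisition",
    "N-acquisition",
    "metal transport",
    "ribosomal",
    "heat shock",
    "phycobilisome",
    "photic electron transport",
    "CO2 fixation",
    "cell structure",
    "oxidative stress",
    "cell motility",
    "biosynthesis",
)


def synthetic_trait_groups(structure: PlantedStructure, protein_ids: list[str]):
    """Assign planted biclusters to trait-group labels for allocation tests.

    Bicluster k gets the k-th vocabulary label; the first 30 invariant
    proteins are labelled "biosynthesis" and the rest stay ungrouped so
    the "other" bucket is exercised downstream.
    """
    from .abundance import TraitGroupMap

    membership = np.zeros(len(protein_ids), dtype=int)
    membership[: structure.n_proteins] = structure.protein_membership
    mapping: dict[str, str] = {}
    for k in structure.biclusters:
        for i in np.flatnonzero(membership == k):
            mapping[protein_ids[i]] = TRAIT_VOCABULARY[(k - 1) % len(TRAIT_VOCABULARY)]
    invariant = np.flatnonzero(membership == 0)[:30]
    for i in invariant:
        mapping[protein_ids[i]] = "biosynthesis"
    return TraitGroupMap(mapping, vocabulary=TRAIT_VOCABULARY)


def write_truth(structure: PlantedStructure, protein_ids: list[str], path: str | Path) -> None:
    """Write the ground-truth membership as a two-column TSV sidecar."""
    structure.truth_frame(protein_ids).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
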