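"""End-to-end orchestration: simulate → allocate → bicluster → stats.

A :class:`RunConfig` captures every tunable of a run (filter thresholds,
normalization, NoB-LoC priors and chain settings, permutation counts and
a single global seed from which all stage seeds are derived).  Configs
round-trip through YAML, every stage output is listed in a JSON manifest
with a content hash, and a run with the same config and seed reproduces
the same hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import biclust, reproduce, stoich, synth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "protstoich_run"
    # synthetic data
    n_proteins: int = 200
    n_biclusters: int = 4
    proteins_per_bicluster: int = 15
    separation: float = 2.0
    proteome_noise_sd: float = 0.5
    missing_rate: float = 0.0
    elemental_noise_sd: float = 0.05
    # preprocessing
    min_peptides: int = 2
    max_missing: int = 2
    normalize: str = "total_sum"
    pa_total_universe: str = "retained"
    # NoB-LoC: sparse variant prior; also guards against noise-absorbing
    # spurious biclusters on matrices with many unstructured proteins
    pi0: float = 0.01
    pi0_sample: float = 0.5
    alpha_protein: float = 1.0
    alpha_sample: float = 1.0
    n_iter: int = 400
    burn_in: int = 100
    thin: int = 1
    n_init_sets: int | None = None  # None = adaptive (max(20, G/5))
    # stats
    n_perm: int = 999
    top_n: int = 100

    def validate(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if not 0 < self.pi0 <= 1:
            raise ValueError("pi0 must lie in (0, 1]")
        if self.min_peptides < 1 or self.max_missing < 0 or self.n_perm < 1:
            raise ValueError("thresholds out of range")

    @classmethod
    def paper_defaults(cls, **overrides) -> "RunConfig":
        """The study's stated parameter set: 2-peptide filter, ≤2 missing,
        π₀ = 0.01, 35 000 iterations with 5 000 burn-in."""
        base = dict(min_peptides=2, max_missing=2, pi0=0.01, n_iter=35_000, burn_in=5_000)
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Derive independent per-stage seeds (< 2³¹) from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on synthetic data and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "stages": {},
        "results": {},
    }

    def record(stage: str, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in files.items()
        }

    try:
        # ---- simulate -----------------------------------------------------
        design = synth.make_design()
        structure = synth.planted_structure(
            design,
            G=config.n_proteins,
            K=config.n_biclusters,
            proteins_per_bicluster=config.proteins_per_bicluster,
            separation=config.separation,
            noise_sd=config.proteome_noise_sd,
        )
        matrix, _ = synth.simulate_proteome(
            design, config.n_proteins, structure, seed=seeds[0],
            missing_rate=config.missing_rate,
        )
        elemental = synth.simulate_elemental(
            design, noise_sd=config.elemental_noise_sd, seed=seeds[1]
        )
        groups = synth.synthetic_trait_groups(structure, matrix.protein_ids)
        paths = {
            "abundance": out / "abundance.tsv",
            "truth": out / "truth.tsv",
            "elemental": out / "elemental.tsv",
            "groups": out / "groups.tsv",
            "design": out / "design.tsv",
        }
        ab.write_abundance_table(matrix, paths["abundance"])
        synth.write_truth(structure, matrix.protein_ids, paths["truth"])
        elemental.to_csv(paths["elemental"], sep="\t", index=False)
        groups.write(paths["groups"])
        design.to_csv(paths["design"], sep="\t", index=False)
        record("simulate", paths)

        # ---- allocate -----------------------------------------------------
        loaded = ab.read_abundance_table(paths["abundance"])
        m1 = ab.filter_by_peptide_count(loaded, config.min_peptides)
        m2 = ab.filter_by_missingness(m1, config.max_missing)
        m3 = ab.normalize_samples(m2, method=config.normalize)
        treatments = [
            f"{r}_{t}" for r, t in zip(design["nutrient_regime"], design["temperature"])
        ]
        alloc = ab.group_allocations(m3, groups)
        top_mean, top_se = ab.top_n_share(
            m3, treatments, n=min(config.top_n, m3.n_proteins)
        )
        apaths = {
            "normalized": out / "normalized.tsv",
            "allocations": out / "allocations.tsv",
        }
        ab.write_abundance_table(m3, apaths["normalized"])
        alloc.to_csv(apaths["allocations"], sep="\t")
        record("allocate", apaths)
        manifest["results"]["allocate"] = {
            "n_detected": loaded.n_proteins,
            "n_retained": m2.n_proteins,
            "n_dropped_peptide_filter": loaded.n_proteins - m1.n_proteins,
            "n_dropped_missingness": m1.n_proteins - m2.n_proteins,
            "peptide_filter_loss_pct": m1.meta["peptide_filter_loss_pct"],
            "missingness_filter_loss_pct": m2.meta["missingness_filter_loss_pct"],
            "top_share_mean_pct": top_mean,
            "top_share_se_pct": top_se,
            "group_allocation_treatment_means": alloc.groupby(
                np.asarray(treatments)
            ).mean().round(6).to_dict(),
        }

        # ---- bicluster ----------------------------------------------------
        priors = biclust.PriorSettings(
            pi0=config.pi0,
            pi0_sample=config.pi0_sample,
            alpha_protein=config.alpha_protein,
            alpha_sample=config.alpha_sample,
        )
        trace = biclust.run_mcmc(
            m3,
            priors,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=seeds[2],
            n_init_sets=config.n_init_sets,
        )
        omega_ls, scaled_dist = biclust.least_squares_partition(trace)
        summary = biclust.summarize_partition(omega_ls)
        truth = synth.read_truth(paths["truth"])
        ari = biclust.recovery_ari(
            truth.set_index("protein_id").loc[m3.protein_ids, "bicluster_id"].to_numpy(),
            omega_ls.omega,
        )
        bpaths = {
            "omega": out / "omega_ls.tsv",
            "sample_partitions": out / "sample_partitions.tsv",
            "trace_summary": out / "trace_summary.json",
        }
        pd.DataFrame(
            {"protein_id": m3.protein_ids, "bicluster_id": omega_ls.omega}
        ).to_csv(bpaths["omega"], sep="\t", index=False)
        pd.DataFrame(
            {
                f"bicluster_{k}": omega_ls.sample_partitions[k]
                for k in range(1, omega_ls.n_biclusters + 1)
            },
            index=m3.sample_ids,
        ).rename_axis("sample_id").to_csv(bpaths["sample_partitions"], sep="\t")
        trace_summary = {
            "n_iter": trace.n_iter,
            "burn_in": trace.burn_in,
            "thin": trace.thin,
            "seed": trace.seed,
            "n_samples": len(trace.partitions),
            "scaled_distance_quantiles": {
                q: float(np.quantile(scaled_dist, float(q)))
                for q in ("0.05", "0.5", "0.95")
            },
            **summary,
            "bicluster_sizes": {str(k): v for k, v in summary["bicluster_sizes"].items()},
            "sample_subclusters": {str(k): v for k, v in summary["sample_subclusters"].items()},
            "recovery_ari": ari,
        }
        bpaths["trace_summary"].write_text(json.dumps(trace_summary, indent=2))
        record("bicluster", bpaths)
        manifest["results"]["bicluster"] = trace_summary

        # ---- stats --------------------------------------------------------
        elem_report = reproduce.elemental_report(elemental)
        X = reproduce.log_imputed(m3)
        perm = stoich.permanova_two_way(
            X,
            design["nutrient_regime"],
            design["temperature"],
            n_perm=config.n_perm,
            seed=seeds[3],
            response="proteome_proteins",
        )
        pair = stoich.pairwise_comparisons(
            stoich.element_ratios(stoich.cell_quotas(elemental))["C:P"],
            treatments,
        )
        spaths = {
            "variance_partition": out / "variance_partition.json",
            "pairwise": out / "pairwise_cp.tsv",
        }
        spaths["variance_partition"].write_text(
            json.dumps({"anova": elem_report["anova"], "permanova": perm.to_dict()}, indent=2)
        )
        pair.to_csv(spaths["pairwise"], sep="\t", index=False)
        record("stats", spaths)
        manifest["results"]["stats"] = {
            "nutrient_fraction_pct": elem_report["nutrient_fraction_pct"],
            "temperature_fraction_pct": elem_report["temperature_fraction_pct"],
            "proteome_permanova_fractions": perm.fractions,
        }
    except Exception as exc:
        stage = len(manifest["stages"])
        names = ["simulate", "allocate", "bicluster", "stats"]
        raise RuntimeError(
            f"pipeline failed in stage '{names[min(stage, 3)]}': {exc}"
        ) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def make_report(manifest: dict | str | Path) -> str:
    """Human-readable summary of a run manifest.

    Sections mirror the study's reporting: variance fractions per
    response, trait-group allocations by treatment, bicluster/invariant
    counts, and the top-N share.  Sections whose stage is absent from the
    manifest are omitted.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    results = manifest.get("results", {})
    lines = ["# protstoich run report", ""]
    stats = results.get("stats")
    if stats:
        lines.append("## Variance fractions (% of total SS, two-way ANOVA)")
        lines.append(f"{'response':<10} {'nutrient':>9} {'temperature':>12} {'other':>7}")
        for resp, nut in stats["nutrient_fraction_pct"].items():
            temp = stats["temperature_fraction_pct"][resp]
            lines.append(f"{resp:<10} {nut:>8.1f}% {temp:>11.1f}% {100 - nut - temp:>6.1f}%")
        pf = stats["proteome_permanova_fractions"]
        lines.append(
            "proteome (PERMANOVA): nutrient "
            f"{100 * pf['nutrient']:.1f}%, temperature {100 * pf['temperature']:.1f}%, "
            f"other {100 * pf['other']:.1f}%"
        )
        lines.append("")
    alloc = results.get("allocate")
    if alloc:
        lines.append("## Proteome allocation")
        lines.append(
            f"retained {alloc['n_retained']} of {alloc['n_detected']} proteins "
            f"(peptide filter loss {alloc['peptide_filter_loss_pct']:.2f}% PA, "
            f"missingness loss {alloc['missingness_filter_loss_pct']:.2f}% PA)"
        )
        lines.append(
            f"top-100 share: {alloc['top_share_mean_pct']:.1f} "
            f"± SE {alloc['top_share_se_pct']:.1f} %PA_Total"
        )
        lines.append("trait-group %PA_Total treatment means:")
        means = alloc["group_allocation_treatment_means"]
        for group, per_treat in means.items():
            rng = sorted(per_treat.values())
            lines.append(f"  {group}: {rng[0]:.1f}–{rng[-1]:.1f}%")
        lines.append("")
    bic = results.get("bicluster")
    if bic:
        lines.append("## NoB-LoC biclustering")
        lines.append(
            f"{bic['n_biclusters']} biclusters, {bic['n_invariant']} invariant proteins "
            f"(ARI vs planted truth: {bic['recovery_ari']:.3f})"
        )
        lines.append(
            "scaled posterior distance quantiles: "
            + ", ".join(f"q{q}={v:.4f}" for q, v in bic["scaled_distance_quantiles"].items())
        )
        lines.append("")
    return "\n".join(lines)
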