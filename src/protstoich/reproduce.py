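"""Headline summary statistics for a full study dataset.

These entry points chain the package's operations the way the original
chemostat study reports them: preprocessing losses and retained-protein
counts, trait-group allocation ranges, the top-100 protein share,
ANOVA variance fractions for elemental ratios, and the proteome
PERMANOVA.  They run on any conforming tables — the synthetic
generator's output or deposited supplementary data exported as
delimited text (see the README for the expected columns).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import stoich


def log_imputed(matrix: ab.AbundanceMatrix) -> np.ndarray:
    """Sample × protein log peak areas; missing cells take the protein's
    mean log abundance (neutral under Euclidean distances)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        X = np.log(np.where(matrix.values > 0, matrix.values, np.nan)).T
    return np.where(np.isfinite(X), X, np.nanmean(X, axis=0, keepdims=True))


def proteome_report(
    matrix: ab.AbundanceMatrix,
    groups: ab.TraitGroupMap,
    design: pd.DataFrame,
    min_peptides: int = 2,
    max_missing: int = 2,
    normalize: str = "total_sum",
    n_top: int = 100,
    n_perm: int = 999,
    seed: int = 0,
    permanova_on: str = "proteins",
) -> dict:
    """Preprocess a peak-area matrix and compute the study's headline
    proteome statistics.

    Returns a dict with the peptide-filter and missingness-filter %PA
    losses, the retained protein count, per-treatment allocation ranges
    for each trait group, the top-``n_top`` share (mean ± SE over
    treatments), and two-way PERMANOVA fractions for the proteome
    (``permanova_on`` selects all retained proteins or trait-group sums).
    """
    design = design.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    treatments = [
        f"{r}_{t}" for r, t in zip(design["nutrient_regime"], design["temperature"])
    ]
    m1 = ab.filter_by_peptide_count(matrix, min_peptides)
    m2 = ab.filter_by_missingness(m1, max_missing)
    m3 = ab.normalize_samples(m2, method=normalize)

    alloc = ab.group_allocations(m3, groups)
    per_treat = alloc.groupby(np.asarray(treatments)).mean()
    group_ranges = {
        g: {"min": float(per_treat[g].min()), "max": float(per_treat[g].max())}
        for g in alloc.columns
    }
    top_mean, top_se = ab.top_n_share(m3, treatments, n=min(n_top, m3.n_proteins))

    if permanova_on == "proteins":
        X = log_imputed(m3)
    elif permanova_on == "groups":
        X = alloc.to_numpy()
    else:
        raise ValueError("permanova_on must be 'proteins' or 'groups'")
    perm = stoich.permanova_two_way(
        X,
        design["nutrient_regime"],
        design["temperature"],
        n_perm=n_perm,
        seed=seed,
        response=f"proteome_{permanova_on}",
    )
    return {
        "n_detected": matrix.n_proteins,
        "n_peptide_filtered": m1.n_proteins,
        "n_retained": m2.n_proteins,
        "peptide_filter_loss_pct": m1.meta["peptide_filter_loss_pct"],
        "missingness_filter_loss_pct": m2.meta["missingness_filter_loss_pct"],
        "group_allocation_ranges_pct": group_ranges,
        "top_n": min(n_top, m3.n_proteins),
        "top_share_mean_pct": top_mean,
        "top_share_se_pct": top_se,
        "permanova": perm.to_dict(),
    }


def elemental_report(table: pd.DataFrame) -> dict:
    """Quotas, ratios, and two-way ANOVA variance fractions for an
    elemental table with design columns and POC/PON/POP/cell_density/FSC_H."""
    q = stoich.element_ratios(stoich.cell_quotas(table))
    responses = ["C:P", "N:P", "C:N", "Q_C", "Q_N", "Q_P", "FSC_H"]
    anova = {
        resp: stoich.two_way_anova(
            q[resp], q["nutrient_regime"], q["temperature"], response=resp
        ).to_dict()
        for resp in responses
    }
    return {
        "anova": anova,
        "nutrient_fraction_pct": {
            resp: 100.0 * anova[resp]["fractions"]["nutrient"] for resp in responses
        },
        "temperature_fraction_pct": {
            resp: 100.0 * anova[resp]["fractions"]["temperature"] for resp in responses
        },
        "treatment_ratios": stoich.treatment_ratio_summary(q).to_dict(orient="records"),
    }


def load_study_tables(
    abundance_path: str | Path, groups_path: str | Path, elemental_path: str | Path
) -> tuple[ab.AbundanceMatrix, ab.TraitGroupMap, pd.DataFrame]:
    """Load the three study inputs from delimited text files."""
    matrix = ab.read_abundance_table(abundance_path)
    groups = ab.TraitGroupMap.read(groups_path)
    elem = pd.read_csv(elemental_path, sep="\t")
    return matrix, groups, elem
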