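"""Peak-area tables: ingestion, filtering, normalization, %PA_Total.

A DIA-MS experiment yields, per sample, a summed peptide peak area (PA)
for every confidently identified protein.  The allocation metric used
throughout is

    %PA_Total = PA(protein or protein group) / PA_Total × 100,

where PA_Total is a sample's summed PA over the protein universe.  Summed
PA is interpreted as cellular resource allocation to a function, not copy
number.  Standard preprocessing: keep proteins with ≥2 representative
peptides, drop proteins missing in more than 2 of the 30 samples, and
equalize per-sample totals across the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SENTINELS = {"", "na", "nan", "n/a", "missing", "null"}


@dataclass
class AbundanceMatrix:
    """Protein × sample peak areas with missingness mask and peptide counts.

    ``values[g, s]`` is the (non-negative, finite) peak area of protein
    ``g`` in sample ``s``; cells flagged in ``missing_mask`` hold 0 and are
    treated as 0 in PA sums (no imputation).
    """

    protein_ids: list[str]
    peptide_counts: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.peptide_counts = np.asarray(self.peptide_counts, dtype=int)
        G, S = self.values.shape
        if len(self.protein_ids) != G or self.peptide_counts.size != G:
            raise ValueError("protein dimension mismatch")
        if len(self.sample_ids) != S or self.missing_mask.shape != (G, S):
            raise ValueError("sample dimension mismatch")
        if len(set(self.protein_ids)) != G:
            raise ValueError("duplicate protein ids")
        if len(set(self.sample_ids)) != S:
            raise ValueError("duplicate sample ids")
        observed = self.values[~self.missing_mask]
        if observed.size and (not np.all(np.isfinite(observed)) or observed.min() < 0):
            raise ValueError("observed peak areas must be finite and >= 0")
        self.values = self.values.copy()
        self.values[self.missing_mask] = 0.0

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def n_missing_per_protein(self) -> np.ndarray:
        return self.missing_mask.sum(axis=1)

    def total_pa(self) -> np.ndarray:
        """Per-sample PA_Total over this matrix's proteins (missing = 0)."""
        return self.values.sum(axis=0)

    def subset(self, row_idx: np.ndarray) -> "AbundanceMatrix":
        return AbundanceMatrix(
            protein_ids=[self.protein_ids[i] for i in row_idx],
            peptide_counts=self.peptide_counts[row_idx],
            values=self.values[row_idx],
            missing_mask=self.missing_mask[row_idx],
            sample_ids=list(self.sample_ids),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame (protein_id, peptide_count, samples); missing → NaN."""
        vals = np.where(self.missing_mask, np.nan, self.values)
        df = pd.DataFrame(vals, columns=self.sample_ids)
        df.insert(0, "peptide_count", self.peptide_counts)
        df.insert(0, "protein_id", self.protein_ids)
        return df


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write samples-as-columns delimited text; missing cells are blank."""
    matrix.to_frame().to_csv(path, sep=sep, index=False, na_rep="")


def read_abundance_table(path: str | Path, sep: str = "\t") -> AbundanceMatrix:
    """Read a protein×sample peak-area table.

    Expected layout: ``protein_id``, optional ``peptide_count`` (defaults
    to 2 when absent), then one numeric column per sample.  Blank or
    sentinel cells (NA/NaN/missing) become missing flags.  Duplicate
    accessions, ragged rows, and non-numeric non-sentinel cells raise.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, on_bad_lines="error")
    if "protein_id" not in df.columns:
        raise ValueError("header must contain a 'protein_id' column")
    ids = df["protein_id"].tolist()
    dupes = df["protein_id"][df["protein_id"].duplicated()].unique()
    if dupes.size:
        raise ValueError(f"duplicate protein accession(s): {', '.join(dupes)}")
    if "peptide_count" in df.columns:
        counts = df["peptide_count"].astype(int).to_numpy()
        sample_cols = [c for c in df.columns if c not in ("protein_id", "peptide_count")]
    else:
        counts = np.full(len(df), 2, dtype=int)
        sample_cols = [c for c in df.columns if c != "protein_id"]
    raw = df[sample_cols].to_numpy(dtype=str)
    missing = np.vectorize(lambda c: c.strip().lower() in _SENTINELS)(raw) if raw.size else np.zeros_like(raw, bool)
    values = np.zeros(raw.shape, dtype=float)
    obs = ~missing
    try:
        values[obs] = raw[obs].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric peak-area cell: {exc}") from exc
    return AbundanceMatrix(
        protein_ids=ids,
        peptide_counts=counts,
        values=values,
        missing_mask=missing,
        sample_ids=sample_cols,
    )


def summed_pa_loss(before: AbundanceMatrix, after: AbundanceMatrix) -> float:
    """Percent of total summed PA removed going from ``before`` to ``after``."""
    t0, t1 = before.values.sum(), after.values.sum()
    return 100.0 * (t0 - t1) / t0 if t0 > 0 else 0.0


def filter_by_peptide_count(matrix: AbundanceMatrix, min_peptides: int = 2) -> AbundanceMatrix:
    """Keep proteins identified by at least ``min_peptides`` peptides."""
    keep = np.flatnonzero(matrix.peptide_counts >= min_peptides)
    out = matrix.subset(keep)
    loss = summed_pa_loss(matrix, out)
    logger.info(
        "peptide-count filter (>=%d): kept %d/%d proteins, removed %.3f%% of summed PA",
        min_peptides, out.n_proteins, matrix.n_proteins, loss,
    )
    out.meta["peptide_filter_loss_pct"] = loss
    return out


def filter_by_missingness(matrix: AbundanceMatrix, max_missing: int = 2) -> AbundanceMatrix:
    """Drop proteins with more than ``max_missing`` missing cells."""
    keep = np.flatnonzero(matrix.n_missing_per_protein() <= max_missing)
    out = matrix.subset(keep)
    loss = summed_pa_loss(matrix, out)
    logger.info(
        "missingness filter (<=%d missing): kept %d/%d proteins, removed %.3f%% of summed PA",
        max_missing, out.n_proteins, matrix.n_proteins, loss,
    )
    out.meta["missingness_filter_loss_pct"] = loss
    return out


def normalize_samples(matrix: AbundanceMatrix, method: str = "total_sum") -> AbundanceMatrix:
    """Equalize samples for cross-sample comparison.

    ``total_sum`` rescales each sample so its summed PA over observed cells
    equals the grand mean of per-sample totals (within-sample proportions
    unchanged).  ``median_ratio`` divides each sample by the median ratio
    of its observed values to the per-protein geometric mean (size-factor
    normalization).  The method applied is recorded in ``meta``.
    """
    totals = matrix.total_pa()
    if np.any(totals <= 0):
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"sample(s) with non-positive total PA: {', '.join(bad)}")
    if method == "total_sum":
        scale = totals.mean() / totals
    elif method == "median_ratio":
        obs_all = ~matrix.missing_mask.any(axis=1)
        pos = obs_all & (matrix.values > 0).all(axis=1)
        if not pos.any():
            raise ValueError("median_ratio requires fully observed positive proteins")
        ref = np.exp(np.log(matrix.values[pos]).mean(axis=1, keepdims=True))
        scale = 1.0 / np.median(matrix.values[pos] / ref, axis=0)
    else:
        raise ValueError(f"unknown normalization method: {method}")
    out = matrix.subset(np.arange(matrix.n_proteins))
    out.values = out.values * scale
    out.meta["normalization"] = method
    return out


@dataclass
class TraitGroupMap:
    """Map protein accession → trait-group label (one group per protein)."""

    mapping: dict[str, str]
    vocabulary: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.vocabulary is not None:
            bad = set(self.mapping.values()) - set(self.vocabulary)
            if bad:
                raise ValueError(f"group labels outside vocabulary: {sorted(bad)}")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "TraitGroupMap":
        df = pd.read_csv(path, sep=sep)
        if df["protein_id"].duplicated().any():
            raise ValueError("protein mapped to more than one group")
        return cls(dict(zip(df["protein_id"], df["group"])))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(
            {"protein_id": list(self.mapping), "group": list(self.mapping.values())}
        ).to_csv(path, sep=sep, index=False)


def _pa_total(matrix: AbundanceMatrix, universe: str, identified: AbundanceMatrix | None) -> np.ndarray:
    if universe == "retained":
        return matrix.total_pa()
    if universe == "identified":
        if identified is None:
            raise ValueError("universe='identified' requires the identification matrix")
        if identified.sample_ids != matrix.sample_ids:
            raise ValueError("identification matrix sample ids do not match")
        return identified.total_pa()
    raise ValueError(f"unknown PA_Total universe: {universe}")


def percent_pa_total(
    matrix: AbundanceMatrix,
    protein_set: list[str],
    universe: str = "retained",
    identified: AbundanceMatrix | None = None,
) -> pd.Series:
    """Per-sample %PA_Total of a protein set: sum(PA in set)/PA_Total × 100.

    Missing cells contribute 0.  With the default ``retained`` universe the
    denominator is the summed PA of this matrix's proteins, so querying the
    whole set returns exactly 100.
    """
    index = {p: i for i, p in enumerate(matrix.protein_ids)}
    unknown = [p for p in protein_set if p not in index]
    if unknown:
        raise KeyError(f"unknown protein id(s): {', '.join(unknown[:5])}")
    rows = np.array([index[p] for p in protein_set], dtype=int)
    num = matrix.values[rows].sum(axis=0) if rows.size else np.zeros(matrix.n_samples)
    share = 100.0 * num / _pa_total(matrix, universe, identified)
    return pd.Series(share, index=matrix.sample_ids, name="percent_pa_total")


def group_allocations(
    matrix: AbundanceMatrix,
    groups: TraitGroupMap,
    universe: str = "retained",
    identified: AbundanceMatrix | None = None,
) -> pd.DataFrame:
    """Sample × trait-group table of %PA_Total; ungrouped proteins → "other"."""
    cols = {}
    grouped: set[str] = set()
    for label in groups.groups:
        members = [p for p in matrix.protein_ids if groups.mapping.get(p) == label]
        grouped.update(members)
        cols[label] = percent_pa_total(matrix, members, universe, identified)
    other = [p for p in matrix.protein_ids if p not in grouped]
    cols["other"] = percent_pa_total(matrix, other, universe, identified)
    return pd.DataFrame(cols)


def top_n_share(
    matrix: AbundanceMatrix,
    treatments: list | np.ndarray,
    n: int = 100,
) -> tuple[float, float]:
    """Mean ± SE (over treatments) of the %PA_Total of the ``n`` most
    abundant proteins, ranked by mean PA across all samples.

    ``treatments`` labels each sample with its treatment; the set share is
    averaged over each treatment's samples first, then across treatments.
    """
    if n > matrix.n_proteins:
        raise ValueError(f"n={n} exceeds the {matrix.n_proteins} retained proteins")
    mean_pa = matrix.values.mean(axis=1)
    top = [matrix.protein_ids[i] for i in np.argsort(mean_pa)[::-1][:n]]
    share = percent_pa_total(matrix, top)
    per_treatment = share.groupby(np.asarray(treatments)).mean()
    mean = float(per_treatment.mean())
    se = float(per_treatment.std(ddof=1) / np.sqrt(len(per_treatment))) if len(per_treatment) > 1 else 0.0
    return mean, se


def log_prop_diff(matrix: AbundanceMatrix) -> np.ndarray:
    """Proportional difference from the per-protein mean log PA.

    Entry (g, s) = (ln PA_gs − mean_s ln PA_g·) / mean_s ln PA_g·, the mean
    taken over observed samples; missing cells are NaN.  Requires strictly
    positive observed values.
    """
    obs = ~matrix.missing_mask
    if np.any(matrix.values[obs] <= 0):
        raise ValueError("log_prop_diff requires strictly positive observed peak areas")
    logv = np.where(obs, np.log(np.where(obs, matrix.values, 1.0)), np.nan)
    row_mean = np.nanmean(logv, axis=1, keepdims=True)
    if np.any(row_mean == 0):
        raise ValueError("a protein has mean log PA of exactly 0; proportional difference undefined")
    return (logv - row_mean) / row_mean
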