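"""Elemental stoichiometry and variance partitioning.

Cell quotas convert culture-level particulate element concentrations to
per-cell amounts::

    Q_X [fmol cell⁻¹] = X [μmol L⁻¹] × 10⁹ / cell density [cells L⁻¹]

and molar ratios (C:P, N:P, C:N) compare quotas against the Redfield
expectation of 106:16:1.  Variance in any response is split between the
nutrient regime, temperature, and "other" (interaction + residual) with a
two-way ANOVA for scalar responses and a two-way sequential PERMANOVA
(McArdle & Anderson trace identities on the Gower-centered distance
matrix) for the multivariate proteome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: fmol per μmol
FMOL_PER_UMOL = 1.0e9

ELEMENTS = {"C": "POC", "N": "PON", "P": "POP"}


def cell_quotas(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-cell quotas Q_C/Q_N/Q_P (fmol cell⁻¹) and their FSC_H-normalized
    counterparts to an elemental table.

    Requires columns POC/PON/POP (μmol L⁻¹), ``cell_density`` (cells L⁻¹)
    and, for the size-normalized quotas, ``FSC_H``.
    """
    out = table.copy()
    dens = out["cell_density"].to_numpy(dtype=float)
    if np.any(dens <= 0):
        raise ValueError("cell_density must be positive for quota computation")
    for elem, col in ELEMENTS.items():
        out[f"Q_{elem}"] = out[col].to_numpy(dtype=float) * FMOL_PER_UMOL / dens
        if "FSC_H" in out.columns:
            out[f"Q_{elem}:FSC_H"] = out[f"Q_{elem}"] / out["FSC_H"].to_numpy(dtype=float)
    return out


def element_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Add molar C:P, N:P, C:N columns (quota quotients) to a quota table."""
    out = table.copy()
    for num, den, name in (("Q_C", "Q_P", "C:P"), ("Q_N", "Q_P", "N:P"), ("Q_C", "Q_N", "C:N")):
        d = out[den].to_numpy(dtype=float)
        if np.any(d <= 0):
            raise ValueError(f"{den} must be positive to form {name}")
        out[name] = out[num].to_numpy(dtype=float) / d
    return out


def treatment_ratio_summary(table: pd.DataFrame, by=("nutrient_regime", "temperature")) -> pd.DataFrame:
    """Per-treatment elemental ratios, reported both ways the convention
    allows: mean of per-sample ratios and ratio of treatment-mean quotas."""
    rows = []
    for key, grp in table.groupby(list(by)):
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        for num, den, name in (("Q_C", "Q_P", "C:P"), ("Q_N", "Q_P", "N:P"), ("Q_C", "Q_N", "C:N")):
            rec[f"{name}_mean_of_ratios"] = float((grp[num] / grp[den]).mean())
            rec[f"{name}_ratio_of_means"] = float(grp[num].mean() / grp[den].mean())
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class VariancePartitionResult:
    """Per-factor variance decomposition of a response.

    ``fractions`` maps nutrient/temperature/other to shares of the total
    sum of squares (summing to 1); ``tests`` carries the per-term test
    statistic and p-value (classical F for ANOVA, pseudo-F with a
    permutation p for PERMANOVA).
    """

    response: str
    ss: dict[str, float]
    fractions: dict[str, float]
    tests: dict[str, dict[str, float]]
    method: str
    n_permutations: int | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tot = sum(self.fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"variance fractions sum to {tot}, not 1")
        if any(v < -1e-12 for v in self.ss.values()):
            raise ValueError("negative sum of squares")

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "method": self.method,
            "ss": self.ss,
            "fractions": self.fractions,
            "tests": self.tests,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            **({"meta": self.meta} if self.meta else {}),
        }


def two_way_anova(
    y, factor_a, factor_b, response: str = "y", names: tuple[str, str] = ("nutrient", "temperature")
) -> VariancePartitionResult:
    """Two-way ANOVA with interaction; variance split A / B / other.

    "Other" pools the interaction and residual sums of squares, so the
    three reported fractions partition the total SS exactly.  Sequential
    (Type I) SS with A entered first; for the balanced factorial design
    this equals the usual orthogonal decomposition.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response: total sum of squares is zero")
    df = pd.DataFrame({"y": y, "A": np.asarray(factor_a), "B": np.asarray(factor_b)})
    counts = df.groupby(["A", "B"]).size()
    if counts.size < df["A"].nunique() * df["B"].nunique():
        raise ValueError("missing cells in the two-way design")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    ss_a = float(tab.loc["C(A)", "sum_sq"])
    ss_b = float(tab.loc["C(B)", "sum_sq"])
    ss_ab = float(tab.loc["C(A):C(B)", "sum_sq"])
    ss_res = float(tab.loc["Residual", "sum_sq"])
    total = ss_a + ss_b + ss_ab + ss_res
    a, b = names
    return VariancePartitionResult(
        response=response,
        ss={a: ss_a, b: ss_b, "interaction": ss_ab, "residual": ss_res},
        fractions={a: ss_a / total, b: ss_b / total, "other": (ss_ab + ss_res) / total},
        tests={
            a: {"F": float(tab.loc["C(A)", "F"]), "p": float(tab.loc["C(A)", "PR(>F)"])},
            b: {"F": float(tab.loc["C(B)", "F"]), "p": float(tab.loc["C(B)", "PR(>F)"])},
            "interaction": {
                "F": float(tab.loc["C(A):C(B)", "F"]),
                "p": float(tab.loc["C(A):C(B)", "PR(>F)"]),
            },
        },
        method="two_way_anova",
    )


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _dummies(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels).astype("category"), drop_first=True).to_numpy(float)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    J = np.eye(D.shape[0]) - 1.0 / D.shape[0]
    return J @ A @ J


def permanova_two_way(
    X,
    factor_a,
    factor_b,
    distance: str = "euclidean",
    n_perm: int = 9999,
    seed: int = 0,
    names: tuple[str, str] = ("nutrient", "temperature"),
    response: str = "X",
) -> VariancePartitionResult:
    """Two-way sequential PERMANOVA on a sample × variable table.

    The distance matrix (Euclidean by default, or a precomputed square
    matrix) is Gower-centered; sums of squares for A, B (after A), A×B and
    residual follow the hat-matrix trace identities of McArdle & Anderson
    (2001).  R² per term is SS/SS_total; p-values come from ``n_perm``
    free permutations of the sample rows under a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    counts = pd.crosstab(fa, fb).to_numpy()
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per design cell")
    if distance == "euclidean":
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        D = np.sqrt(((Xv[:, None, :] - Xv[None, :, :]) ** 2).sum(axis=2))
    elif distance == "precomputed":
        D = np.asarray(X, dtype=float)
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
            raise ValueError("precomputed distance matrix must be symmetric with zero diagonal")
    else:
        raise ValueError(f"unknown distance: {distance}")
    n = D.shape[0]
    if n != fa.size or n != fb.size:
        raise ValueError("factor length does not match the number of samples")
    G = _gower_center(D)
    ss_total = float(np.trace(G))
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix: zero total sum of squares")

    ones = np.ones((n, 1))
    A = _dummies(fa)
    B = _dummies(fb)
    AB = np.column_stack([A[:, i : i + 1] * B[:, j : j + 1] for i in range(A.shape[1]) for j in range(B.shape[1])]) if A.size and B.size else np.empty((n, 0))
    H0 = _hat(ones)
    H1 = _hat(np.column_stack([ones, A]))
    H2 = _hat(np.column_stack([ones, A, B]))
    H3 = _hat(np.column_stack([ones, A, B, AB]))
    df_a = A.shape[1]
    df_b = B.shape[1]
    df_ab = AB.shape[1]
    df_res = n - 1 - df_a - df_b - df_ab

    def seq_ss(Gm: np.ndarray) -> tuple[float, float, float, float]:
        t0, t1, t2, t3 = (float(np.trace(H @ Gm)) for H in (H0, H1, H2, H3))
        tot = float(np.trace(Gm))
        return t1 - t0, t2 - t1, t3 - t2, tot - (t3 - t0)

    ss_a, ss_b, ss_ab, ss_res = seq_ss(G)
    f_a = (ss_a / df_a) / (ss_res / df_res)
    f_b = (ss_b / df_b) / (ss_res / df_res)
    f_ab = (ss_ab / df_ab) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    hits = np.zeros(3, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        pa, pb, pab, pres = seq_ss(Gp)
        hits[0] += (pa / df_a) / (pres / df_res) >= f_a
        hits[1] += (pb / df_b) / (pres / df_res) >= f_b
        hits[2] += (pab / df_ab) / (pres / df_res) >= f_ab
    pvals = (hits + 1) / (n_perm + 1)

    a, b = names
    return VariancePartitionResult(
        response=response,
        ss={a: ss_a, b: ss_b, "interaction": ss_ab, "residual": ss_res},
        fractions={
            a: ss_a / ss_total,
            b: ss_b / ss_total,
            "other": (ss_ab + ss_res) / ss_total,
        },
        tests={
            a: {"pseudo_F": f_a, "p": float(pvals[0]), "R2": ss_a / ss_total},
            b: {"pseudo_F": f_b, "p": float(pvals[1]), "R2": ss_b / ss_total},
            "interaction": {"pseudo_F": f_ab, "p": float(pvals[2]), "R2": ss_ab / ss_total},
        },
        method="permanova_two_way",
        n_permutations=n_perm,
        seed=seed,
        meta={"distance": distance, "order": list(names)},
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≥ raw)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pairwise_comparisons(y, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All unordered pairwise Welch t-tests with BH adjustment.

    Returns one row per group pair with the raw and adjusted p-value and
    a significance flag at ``alpha``.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 observations")
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        res = sps.ttest_ind(y[groups == g1], y[groups == g2], equal_var=False)
        rows.append({"group1": g1, "group2": g2, "t": float(res.statistic), "p_raw": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out
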