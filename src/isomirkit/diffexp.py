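"""Negative-binomial differential expression for count matrices.

Two-group contrasts (e.g. each post-hCG time point against the
proliferative baseline) are tested per feature with a Wald statistic on the
log2 fold change of median-of-ratios-normalized group means, under an NB
noise model with variance ``mu + dispersion * mu**2``.

Dispersion is estimated per feature by a bias-corrected method of moments
within each contrast group and squeezed toward the across-feature mean with
a fixed prior weight (see ``DEConfig.dispersion_prior_df``); the moderation
is what keeps the normal-reference Wald p-values calibrated at the small
per-group sample sizes typical of biopsy studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

DE_COLUMNS = ["base_mean", "log2fc", "se", "wald", "p", "padj", "filtered"]


class DiffExpError(ValueError):
    pass


@dataclass(frozen=True)
class Design:
    """Sample -> group labels plus a (test, reference) contrast."""

    groups: Mapping[str, str]
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        test, ref = self.contrast
        if test == ref:
            raise DiffExpError("contrast test and reference groups must differ")
        for g in (test, ref):
            if len(self.samples(g)) < 2:
                raise DiffExpError(f"contrast group {g!r} needs >= 2 samples")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


@dataclass(frozen=True)
class DEConfig:
    """Significance and filtering thresholds.

    ``lfc_min`` is 0 for miR/isomiR features and 1 for gene-level tests;
    ``alpha`` applies to raw p-values (an adjusted-p column is emitted but
    not used for calling).
    """

    alpha: float = 0.05
    lfc_min: float = 0.0
    min_total_count: int = 10
    dispersion_floor: float = 1e-8
    dispersion_prior_df: float = 16.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DiffExpError("alpha must be in (0, 1)")
        if self.lfc_min < 0:
            raise DiffExpError("lfc_min must be >= 0")


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The pseudo-reference is the per-feature geometric mean across samples,
    computed over features with all-positive counts.
    """
    values = matrix.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise DiffExpError(
            "no feature has nonzero counts in every sample; "
            "pre-filter the matrix before normalization"
        )
    logs = np.log(values[positive])
    log_ref = logs.mean(axis=1, keepdims=True)
    log_factors = np.median(logs - log_ref, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=matrix.columns, name="size_factor")


def _moment_dispersion(norm: np.ndarray) -> tuple[np.ndarray, int]:
    """Bias-corrected per-feature moment estimate of NB dispersion.

    Solves ``E[v] = mu + a*mu**2`` with the finite-sample correction
    ``E[m^2] ~= mu**2 + var/n``; undefined estimates (zero mean, negative
    denominator) come back NaN.
    """
    n = norm.shape[1]
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    den = m**2 - v / n
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where((m > 0) & (den > 0), (v - m) / den, np.nan)
    return a, n - 1


def nb_wald(
    matrix: pd.DataFrame, design: Design, config: DEConfig = DEConfig()
) -> pd.DataFrame:
    """Per-feature NB Wald test of the contrast in ``design``.

    Returns a table indexed by feature with base mean, log2 fold change
    (test over reference, 0.5 pseudo-count), delta-method standard error,
    Wald statistic, two-sided normal p, BH-adjusted p, and a ``filtered``
    flag for features below ``min_total_count`` (which are not tested).
    """
    test_s = design.samples(design.contrast[0])
    ref_s = design.samples(design.contrast[1])
    missing = [s for s in test_s + ref_s if s not in matrix.columns]
    if missing:
        raise DiffExpError(f"design samples missing from matrix: {missing}")
    sub = matrix[test_s + ref_s]

    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()
    t_idx = np.arange(len(test_s))
    r_idx = np.arange(len(test_s), len(test_s) + len(ref_s))
    nt, nr = len(test_s), len(ref_s)

    filtered = sub.sum(axis=1).to_numpy() < config.min_total_count
    if filtered.all():
        raise DiffExpError("all features filtered; nothing to test")

    m_t = norm[:, t_idx].mean(axis=1)
    m_r = norm[:, r_idx].mean(axis=1)
    if (m_t[~filtered] + m_r[~filtered] == 0).any():
        raise DiffExpError("a tested feature has zero counts in both contrast groups")

    a_t, df_t = _moment_dispersion(norm[:, t_idx])
    a_r, df_r = _moment_dispersion(norm[:, r_idx])
    weights = df_t * np.isfinite(a_t) + df_r * np.isfinite(a_r)
    pooled = np.nansum(np.vstack([df_t * a_t, df_r * a_r]), axis=0)
    disp = np.where(weights > 0, pooled / np.maximum(weights, 1), np.nan)

    # moderation: squeeze toward a robust across-feature mean
    finite = disp[np.isfinite(disp) & ~filtered]
    if finite.size:
        clipped = np.clip(finite, 0.0, np.quantile(finite, 0.99))
        center = float(clipped.mean())
    else:
        center = config.dispersion_floor
    disp = np.where(np.isfinite(disp), disp, center)
    prior = config.dispersion_prior_df
    disp = (weights * disp + prior * center) / (weights + prior)
    disp = np.maximum(disp, config.dispersion_floor)

    inv_sf = 1.0 / sf.to_numpy()
    s_t, s_r = inv_sf[t_idx].sum(), inv_sf[r_idx].sum()
    var_mt = (m_t * s_t) / nt**2 + disp * m_t**2 / nt
    var_mr = (m_r * s_r) / nr**2 + disp * m_r**2 / nr

    # 0.5 pseudo-count only where a group mean is zero: keeps fold changes
    # finite without breaking exact scale invariance for positive means
    pseudo = np.where((m_t == 0) | (m_r == 0), 0.5, 0.0)
    log2fc = np.log2((m_t + pseudo) / (m_r + pseudo))
    ln2 = np.log(2.0)
    se = np.sqrt(var_mt / (m_t + 0.5) ** 2 + var_mr / (m_r + 0.5) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))

    base_mean = norm.mean(axis=1)
    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "padj": np.nan,
            "filtered": filtered,
        },
        index=matrix.index.copy(),
    )
    result.loc[filtered, ["base_mean", "log2fc", "se", "wald", "p"]] = np.nan
    tested = result.index[~filtered]
    result.loc[tested, "padj"] = stats.false_discovery_control(
        result.loc[tested, "p"].to_numpy()
    )
    return result


def call_de(records: pd.DataFrame, config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Subset to DE features: raw p < alpha and |log2fc| >= lfc_min."""
    tested = records[~records["filtered"]]
    keep = tested[(tested["p"] < config.alpha) & (tested["log2fc"].abs() >= config.lfc_min)]
    keep = keep.copy()
    keep["direction"] = np.where(keep["log2fc"] > 0, "up", "down")
    return keep


def read_design(path: str | Path, contrast: tuple[str, str]) -> Design:
    """Read a sample/group TSV (columns ``sample``, ``group``) into a Design."""
    table = pd.read_csv(path, sep="\t")
    for col in ("sample", "group"):
        if col not in table.columns:
            raise DiffExpError(f"design table {path}: missing column {col!r}")
    if table["sample"].duplicated().any():
        raise DiffExpError(f"design table {path}: duplicate sample names")
    return Design(
        groups=dict(zip(table["sample"], table["group"])), contrast=contrast
    )


def write_de(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    out.index.name = "feature"
    out.sort_index(kind="mergesort").to_csv(path, sep="\t")


def read_de(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")
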