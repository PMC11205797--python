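"""Alpha/beta diversity, habitat heterogeneity and species-area regressions.

Alpha diversity (Shannon, observed richness, Chao1) is computed per sample and
regressed on log10 patch area at the sample level; beta diversity (mean
within-patch Bray-Curtis) and habitat heterogeneity (mean pairwise Euclidean
distance in soil-property space) are per-patch quantities regressed at the
patch level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress

from .dataset import AbundanceTable, SampleMetadata, ValidationError


@dataclass(frozen=True)
class SARFit:
    """Ordinary least-squares fit of a response on log10(area)."""

    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int
    predictor: str = "log10_area_m2"
    response: str = ""

    @property
    def direction(self) -> str:
        """Sign of the species-area relationship."""
        if self.slope > 0:
            return "positive"
        if self.slope < 0:
            return "negative"
        return "flat"


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts: np.ndarray | pd.Series, base: float | None = None) -> float:
    """Shannon-Wiener index H = -sum p_i log p_i over positive proportions.

    Natural log by default; pass ``base=2`` for bits.
    """
    x = np.asarray(counts, dtype=float)
    if x.sum() <= 0:
        raise ValidationError("shannon requires at least one positive count")
    p = x[x > 0] / x.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def richness(counts: np.ndarray | pd.Series) -> int:
    return int((np.asarray(counts) > 0).sum())


def chao1(counts: np.ndarray | pd.Series) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), bias-corrected when F2 = 0.

    F1 = number of singletons, F2 = number of doubletons. With no doubletons
    the bias-corrected form S_obs + F1(F1-1)/2 is used.
    """
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValidationError("chao1 requires integer counts")
        x = np.round(x).astype(np.int64)
    if (x < 0).any():
        raise ValidationError("chao1 requires non-negative counts")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 ** 2 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon, observed richness and Chao1."""
    rows = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        rows[sid] = {"shannon": shannon(col), "richness": richness(col),
                     "chao1": chao1(col)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# Beta diversity and heterogeneity
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity among samples, in [0, 1]."""
    if table.n_samples < 2:
        raise ValidationError("bray_curtis_matrix needs >= 2 samples")
    sums = table.sample_sums()
    if (sums == 0).any():
        empty = sums.index[sums == 0].tolist()
        raise ValidationError(f"samples with zero total: {empty}")
    X = table.counts.to_numpy(dtype=float).T
    mat = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


def within_patch_beta(table: AbundanceTable, metadata: SampleMetadata) -> pd.Series:
    """Mean within-patch Bray-Curtis per patch; NaN for patches with < 2 samples."""
    bc = bray_curtis_matrix(table)
    patch = metadata.patch_of().reindex(table.sample_ids)
    out = {}
    for pid in metadata.patch_ids:
        sids = patch.index[patch == pid].tolist()
        if len(sids) < 2:
            out[pid] = np.nan
            continue
        sub = bc.loc[sids, sids].to_numpy()
        iu = np.triu_indices(len(sids), k=1)
        out[pid] = float(sub[iu].mean())
    return pd.Series(out, name="beta_bray_curtis").rename_axis("patch_id")


def habitat_heterogeneity(metadata: SampleMetadata,
                          properties: list[str] | None = None,
                          standardize: bool = False) -> pd.Series:
    """Mean pairwise Euclidean distance among samples in soil-property space.

    Raw measurement units by default; ``standardize=True`` z-scores each
    property across all samples first (making the result unit-free).
    """
    props = properties or metadata.soil_property_names
    missing = [p for p in props if p not in metadata.df.columns]
    if missing:
        raise ValidationError(f"missing soil properties: {missing}")
    X = metadata.df[props].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValidationError(f"missing values in soil properties: {bad}")
    if standardize:
        sd = X.std(ddof=0).replace(0, 1.0)
        X = (X - X.mean()) / sd
    out = {}
    for pid in metadata.patch_ids:
        sub = X.loc[metadata.patch_of() == pid].to_numpy()
        if len(sub) < 2:
            out[pid] = np.nan
            continue
        out[pid] = float(pdist(sub, metric="euclidean").mean())
    return pd.Series(out, name="heterogeneity").rename_axis("patch_id")


# ---------------------------------------------------------------------------
# Species-area regression
# ---------------------------------------------------------------------------

def sar_regression(areas: pd.Series | np.ndarray,
                   response: pd.Series | np.ndarray,
                   response_name: str = "") -> SARFit:
    """OLS of a response on log10(area); NaN responses are dropped."""
    a = np.asarray(areas, dtype=float)
    y = np.asarray(response, dtype=float)
    keep = np.isfinite(a) & np.isfinite(y)
    a, y = a[keep], y[keep]
    if len(a) < 3:
        raise ValidationError("sar_regression needs >= 3 points")
    if (a <= 0).any():
        raise ValidationError("areas must be positive")
    x = np.log10(a)
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in log10(area)")
    if np.ptp(y) == 0:
        # constant response: slope 0 by construction, no association
        return SARFit(0.0, float(y[0]), 0.0, 1.0, len(a), response=response_name)
    fit = linregress(x, y)
    return SARFit(float(fit.slope), float(fit.intercept),
                  float(fit.rvalue ** 2), float(fit.pvalue),
                  len(a), response=response_name)


def diversity_sar_summary(table: AbundanceTable, metadata: SampleMetadata,
                          standardize_heterogeneity: bool = False
                          ) -> dict[str, SARFit]:
    """The standard regression set: alpha per sample, beta/heterogeneity per patch."""
    alpha = alpha_diversity_table(table)
    area_sample = metadata.df["area_m2"].reindex(table.sample_ids)
    area_patch = metadata.area_of_patch()
    beta = within_patch_beta(table, metadata)
    het = habitat_heterogeneity(metadata, standardize=standardize_heterogeneity)
    fits = {}
    for metric in ("shannon", "richness", "chao1"):
        fits[metric] = sar_regression(area_sample, alpha[metric], metric)
    fits["beta_bray_curtis"] = sar_regression(
        area_patch.reindex(beta.index), beta, "beta_bray_curtis")
    fits["heterogeneity"] = sar_regression(
        area_patch.reindex(het.index), het, "heterogeneity")
    return fits


def sar_table(fits: dict[str, SARFit]) -> pd.DataFrame:
    rows = {name: {"slope": f.slope, "intercept": f.intercept, "r2": f.r2,
                   "pvalue": f.pvalue, "n": f.n, "direction": f.direction}
            for name, f in fits.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "response"
    return out
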