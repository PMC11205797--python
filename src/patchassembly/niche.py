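"""Levins' niche breadth and generalist/specialist classification.

A taxon's niche breadth B = 1 / sum_h q_h^2, where q_h is habitat h's share of
the taxon's summed per-habitat mean relative abundance — the inverse Simpson
concentration of the taxon across habitats (1 = confined to one habitat,
n_habitats = perfectly even). Habitats are patches by default.

Observed B is compared against a permutation null; taxa above the upper null
quantile are habitat generalists (more evenly spread than chance), below the
lower quantile specialists. Two nulls are available:

* ``fixed_margins`` (default) — each replicate redraws the whole count table
  uniformly among tables with the observed taxon and sample totals (Patefield
  algorithm), then recomputes B with the real habitat labels. This mirrors the
  matrix-randomization null of the standard generalist/specialist pipelines
  and can flag a taxon that is identical in every sample (its breadth cannot
  be exceeded, while random reallocation of its counts is almost surely less
  even).
* ``labels`` — habitat labels are shuffled across samples, within-sample
  composition preserved. Exactly calibrated for exchangeable samples, but
  blind to taxa whose abundance carries no habitat association at all (a
  constant taxon is invariant under any relabelling, hence always "neither").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import random_table

from .dataset import AbundanceTable, SampleMetadata, ValidationError


@dataclass
class NicheBreadthResult:
    """Per-taxon observed breadth, null interval and category."""

    table: pd.DataFrame  # taxon_id index; B_obs, null_mean, null_lo, null_hi, category
    n_habitats: int
    n_perm: int
    alpha: float

    def taxa_in(self, category: str) -> list[str]:
        return self.table.index[self.table["category"] == category].tolist()

    def counts(self) -> dict[str, int]:
        return self.table["category"].value_counts().to_dict()


def levins_breadth(habitat_means: np.ndarray | pd.Series) -> float:
    """B = 1 / sum q_h^2 over habitat shares q of the taxon's habitat means.

    Invariant to rescaling all means by a constant; bounded by [1, n_habitats].
    """
    x = np.asarray(habitat_means, dtype=float)
    if (x < 0).any():
        raise ValidationError("habitat means must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValidationError("levins_breadth requires a positive habitat mean")
    q = x / total
    return float(1.0 / np.sum(q ** 2))


def _breadths_for(counts: np.ndarray, col_sums: np.ndarray,
                  group_matrix: np.ndarray) -> np.ndarray:
    """Levins B for every taxon of a count matrix.

    ``group_matrix`` is samples x habitats with column-normalized membership
    weights, so ``X @ group_matrix`` is the per-habitat mean of relative
    abundances.
    """
    X = counts / col_sums
    M = X @ group_matrix
    totals = M.sum(axis=1, keepdims=True)
    q = np.divide(M, totals, out=np.zeros_like(M), where=totals > 0)
    ss = (q ** 2).sum(axis=1)
    return np.divide(1.0, ss, out=np.full(len(M), np.nan), where=ss > 0)


def _group_matrix(labels: np.ndarray, habitats: list) -> np.ndarray:
    G = np.stack([(labels == h).astype(float) for h in habitats], axis=1)
    return G / G.sum(axis=0, keepdims=True)


def classify_taxa(table: AbundanceTable, metadata: SampleMetadata,
                  n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                  habitat: str = "patch",
                  null_model: str = "fixed_margins") -> NicheBreadthResult:
    """Permutation classification into generalist / specialist / neither.

    A taxon is a generalist when its observed B exceeds the null's upper
    1 - alpha/2 quantile, a specialist when below the lower alpha/2 quantile,
    otherwise neither. Taxa absent from every sample are dropped. With
    n_perm = 1 both quantiles collapse onto the single null value, so only
    taxa strictly outside it are flagged.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if habitat not in ("patch", "sample"):
        raise ValidationError("habitat must be 'patch' or 'sample'")
    if null_model not in ("fixed_margins", "labels"):
        raise ValidationError("null_model must be 'fixed_margins' or 'labels'")
    tab = table.drop_empty_taxa()
    counts = tab.counts.to_numpy(dtype=float)
    col_sums = counts.sum(axis=0, keepdims=True)
    if (col_sums == 0).any():
        raise ValidationError("samples with zero total count")
    if habitat == "patch":
        labels = metadata.patch_of().reindex(tab.sample_ids).to_numpy()
    else:
        labels = np.asarray(tab.sample_ids)
    habitats = sorted(pd.unique(labels))
    if len(habitats) < 2:
        raise ValidationError("classification needs >= 2 habitats")

    G = _group_matrix(labels, habitats)
    obs = _breadths_for(counts, col_sums, G)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(obs)))
    if null_model == "labels":
        for k in range(n_perm):
            Gp = _group_matrix(rng.permutation(labels), habitats)
            null[k] = _breadths_for(counts, col_sums, Gp)
    else:
        dist = random_table(counts.sum(axis=1).astype(np.int64),
                            counts.sum(axis=0).astype(np.int64))
        draws = dist.rvs(size=n_perm, random_state=rng)
        for k in range(n_perm):
            null[k] = _breadths_for(draws[k].astype(float), col_sums, G)

    lo = np.nanquantile(null, alpha / 2, axis=0)
    hi = np.nanquantile(null, 1 - alpha / 2, axis=0)
    category = np.where(obs > hi, "generalist",
                        np.where(obs < lo, "specialist", "neither"))
    out = pd.DataFrame({
        "B_obs": obs,
        "null_mean": np.nanmean(null, axis=0),
        "null_lo": lo,
        "null_hi": hi,
        "category": category,
    }, index=pd.Index(tab.taxon_ids, name="taxon_id"))
    return NicheBreadthResult(out, len(habitats), n_perm, alpha)


def subset_by_category(table: AbundanceTable, result: NicheBreadthResult,
                       subset: str) -> AbundanceTable:
    """Restrict a table to 'entire', 'generalist' or 'specialist' taxa.

    Samples left with zero total count in the subset are dropped alongside.
    """
    if subset == "entire":
        return table
    if subset not in ("generalist", "specialist"):
        raise ValidationError(f"unknown subset {subset!r}")
    taxa = [t for t in result.taxa_in(subset) if t in set(table.taxon_ids)]
    if not taxa:
        raise ValidationError(f"no taxa classified as {subset}")
    sub = table.subset_taxa(taxa).drop_empty_taxa()
    keep = sub.sample_sums() > 0
    return sub.subset_samples(keep.index[keep].tolist())
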