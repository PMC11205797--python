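"""Phylogenetic and taxonomic null models for assembly-process partitioning.

For every sample pair the module computes:

* betaMNTD — abundance-weighted mean distance from each taxon to its nearest
  neighbour in the paired community, averaged over both directions;
* betaNTI — the standardized effect size of betaMNTD against a null that
  shuffles taxon labels across the whole phylogeny (implemented as joint
  row/column permutation of the patristic distance matrix, which is the same
  operation);
* RC_bray — the rank of the observed Bray-Curtis dissimilarity within a null
  that reassembles each sample preserving its richness and total count,
  drawing species identity with probability proportional to metacommunity
  occupancy and individuals proportional to metacommunity relative abundance;
  rescaled to [-1, 1] with ties counted half.

Pairs are then classified into five mutually exclusive, exhaustive processes:
variable selection (betaNTI > 2), homogeneous selection (betaNTI < -2),
dispersal limitation (|betaNTI| <= 2 and RC_bray > 0.95), homogenizing
dispersal (|betaNTI| <= 2 and RC_bray < -0.95) and undominated/drift
(the remainder). Pairs landing exactly on |betaNTI| = 2 fall to the
stochastic branch; RC_bray exactly at +/-0.95 falls to undominated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd

from .dataset import AbundanceTable, Phylogeny, SampleMetadata, ValidationError
from .diversity import bray_curtis_matrix

PROCESSES = ("variable_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "undominated")

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def bmntd(abund_a: np.ndarray, abund_b: np.ndarray, dmat: np.ndarray,
          abundance_weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance.

    ``abund_a``/``abund_b`` are count (or abundance) vectors over the same
    taxon ordering as ``dmat``. Each community's taxa are matched to their
    nearest taxon in the other community; the two directed means (abundance
    weighted by default) are averaged.
    """
    a = np.asarray(abund_a, dtype=float)
    b = np.asarray(abund_b, dtype=float)
    ia = np.flatnonzero(a > 0)
    ib = np.flatnonzero(b > 0)
    if len(ia) == 0 or len(ib) == 0:
        raise ValidationError("bmntd requires two non-empty communities")
    sub = dmat[np.ix_(ia, ib)]
    min_a = sub.min(axis=1)  # nearest in B for each taxon of A
    min_b = sub.min(axis=0)  # nearest in A for each taxon of B
    if abundance_weighted:
        wa = a[ia] / a[ia].sum()
        wb = b[ib] / b[ib].sum()
    else:
        wa = np.full(len(ia), 1.0 / len(ia))
        wb = np.full(len(ib), 1.0 / len(ib))
    return float(0.5 * ((wa * min_a).sum() + (wb * min_b).sum()))


def bnti_matrix(table: AbundanceTable, phylogeny: Phylogeny,
                n_null: int = 999, seed: int = 0,
                abundance_weighted: bool = True) -> pd.DataFrame:
    """betaNTI for every sample pair.

    Null betaMNTD distributions come from ``n_null`` random permutations of
    taxon labels on the patristic distance matrix; each permutation is shared
    across all pairs within a replicate (one randomized tree per replicate).
    Pairs whose null standard deviation is zero get betaNTI = NaN and are
    flagged undefined rather than silently zeroed.

    Returns a long-format frame indexed by (sample_a, sample_b) with columns
    bmntd_obs, null_mean, null_sd, bnti, undefined.
    """
    if table.n_samples < 2:
        raise ValidationError("bnti_matrix needs >= 2 samples")
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    _, dmat = phylogeny.patristic_matrix(order=table.taxon_ids)
    X = table.counts.to_numpy(dtype=float)
    samples = table.sample_ids
    pairs = list(combinations(range(len(samples)), 2))

    cols = [X[:, j] for j in range(X.shape[1])]
    obs = np.array([bmntd(cols[i], cols[j], dmat, abundance_weighted)
                    for i, j in pairs])

    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, len(pairs)))
    n_taxa = dmat.shape[0]
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        dperm = dmat[np.ix_(perm, perm)]
        nulls[r] = [bmntd(cols[i], cols[j], dperm, abundance_weighted)
                    for i, j in pairs]

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1) if n_null > 1 else np.zeros(len(pairs))
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)

    out = pd.DataFrame({
        "sample_a": [samples[i] for i, _ in pairs],
        "sample_b": [samples[j] for _, j in pairs],
        "bmntd_obs": obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "bnti": bnti,
        "undefined": null_sd == 0,
    })
    return out.set_index(["sample_a", "sample_b"])


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def _null_assemblage(richness: int, total: int, occ_w: np.ndarray,
                     ab_w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One null sample: identities by occupancy, individuals by abundance."""
    n_taxa = len(occ_w)
    k = min(richness, n_taxa)
    chosen = rng.choice(n_taxa, size=k, replace=False, p=occ_w)
    w = ab_w[chosen]
    counts = np.zeros(n_taxa, dtype=np.int64)
    # every chosen species keeps at least one individual (preserves richness)
    counts[chosen] = 1
    remaining = total - k
    if remaining > 0:
        counts[chosen] += rng.multinomial(remaining, w / w.sum())
    return counts


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom) if denom > 0 else 0.0


def rc_bray_matrix(table: AbundanceTable, n_null: int = 999,
                   seed: int = 0) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick for every sample pair.

    RC_bray = 2 * [(#null < obs) + 0.5 * (#null = obs)] / n_null - 1, in
    [-1, 1]. One set of ``n_null`` null assemblages is drawn per sample and
    replicate r pairs the r-th nulls of the two samples, so the per-pair
    marginal null is unchanged while the draw count scales with samples, not
    pairs. Metacommunity occupancy and relative abundance are taken from the
    full table.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    if table.n_samples < 2:
        raise ValidationError("rc_bray_matrix needs >= 2 samples")
    X = table.counts.to_numpy(dtype=np.int64)
    samples = table.sample_ids
    occ = (X > 0).sum(axis=1).astype(float)
    ab = X.sum(axis=1).astype(float)
    occ_w = occ / occ.sum()
    ab_w = ab / ab.sum()

    rng = np.random.default_rng(seed)
    nulls = []  # per sample: (n_null, n_taxa)
    for j in range(X.shape[1]):
        richness = int((X[:, j] > 0).sum())
        total = int(X[:, j].sum())
        nulls.append(np.stack([
            _null_assemblage(richness, total, occ_w, ab_w, rng)
            for _ in range(n_null)]))

    bc_obs_mat = bray_curtis_matrix(table)
    rows = []
    for i, j in combinations(range(len(samples)), 2):
        obs = float(bc_obs_mat.iloc[i, j])
        null_bc = np.array([_bray_curtis(nulls[i][r], nulls[j][r])
                            for r in range(n_null)])
        ties = np.isclose(null_bc, obs, rtol=0.0, atol=1e-12)
        below = (null_bc < obs) & ~ties
        rc = 2.0 * (below.sum() + 0.5 * ties.sum()) / n_null - 1.0
        rows.append((samples[i], samples[j], obs, rc))
    out = pd.DataFrame(rows, columns=["sample_a", "sample_b", "bc_obs", "rc_bray"])
    return out.set_index(["sample_a", "sample_b"])


# ---------------------------------------------------------------------------
# Combined metrics and partition
# ---------------------------------------------------------------------------

def assembly_metrics(table: AbundanceTable, phylogeny: Phylogeny,
                     n_null: int = 999, seed: int = 0,
                     abundance_weighted: bool = True) -> pd.DataFrame:
    """betaNTI and RC_bray joined per sample pair."""
    bnti = bnti_matrix(table, phylogeny, n_null=n_null, seed=seed,
                       abundance_weighted=abundance_weighted)
    rc = rc_bray_matrix(table, n_null=n_null, seed=seed + 1)
    return bnti.join(rc)


def classify_pairs(metrics: pd.DataFrame) -> pd.Series:
    """Assign each pair to one of the five processes (NaN betaNTI -> NaN)."""
    bnti = metrics["bnti"]
    rc = metrics["rc_bray"]
    out = pd.Series(pd.NA, index=metrics.index, dtype="object")
    det_plus = bnti > BNTI_THRESHOLD
    det_minus = bnti < -BNTI_THRESHOLD
    stoch = bnti.abs() <= BNTI_THRESHOLD
    out[det_plus] = "variable_selection"
    out[det_minus] = "homogeneous_selection"
    out[stoch & (rc > RC_THRESHOLD)] = "dispersal_limitation"
    out[stoch & (rc < -RC_THRESHOLD)] = "homogenizing_dispersal"
    out[stoch & (rc.abs() <= RC_THRESHOLD)] = "undominated"
    out[bnti.isna()] = pd.NA
    return out


@dataclass
class AssemblyPartition:
    """Process fractions for one group of sample pairs.

    Fractions are exact rationals over classified pair counts, so the five
    always sum to exactly 1.
    """

    group: str
    counts: dict[str, int]
    n_pairs: int
    n_undefined: int = 0

    def fractions(self) -> dict[str, Fraction]:
        if self.n_pairs == 0:
            raise ValidationError(f"group {self.group!r} has no classified pairs")
        return {p: Fraction(self.counts.get(p, 0), self.n_pairs)
                for p in PROCESSES}

    def float_fractions(self) -> dict[str, float]:
        return {p: float(v) for p, v in self.fractions().items()}

    def rollup(self) -> dict[str, Fraction]:
        """Deterministic (|betaNTI| > 2) vs stochastic share."""
        f = self.fractions()
        det = f["variable_selection"] + f["homogeneous_selection"]
        return {"deterministic": det, "stochastic": 1 - det}


def partition_processes(metrics: pd.DataFrame,
                        metadata: SampleMetadata | None = None,
                        groups: dict[str, pd.Series] | None = None
                        ) -> list[AssemblyPartition]:
    """Partition pairs into the five processes, per group.

    With ``metadata`` the default groups are "all", one within-patch group per
    patch with >= 1 pair, and "between_patch". ``groups`` may instead supply
    explicit boolean masks over ``metrics``' pair index. Undefined-betaNTI
    pairs are excluded from denominators and counted separately.
    """
    processes = classify_pairs(metrics)

    if groups is None:
        groups = {"all": pd.Series(True, index=metrics.index)}
        if metadata is not None:
            patch = metadata.patch_of()
            pa = np.asarray(metrics.index.get_level_values("sample_a").map(patch))
            pb = np.asarray(metrics.index.get_level_values("sample_b").map(patch))
            same = pd.Series(pa == pb, index=metrics.index)
            for pid in metadata.patch_ids:
                mask = same & pd.Series(pa == pid, index=metrics.index)
                if mask.any():
                    groups[f"within:{pid}"] = mask
            if (~same).any():
                groups["between_patch"] = ~same

    out = []
    for name, mask in groups.items():
        sub = processes[mask.reindex(metrics.index, fill_value=False)]
        n_undef = int(sub.isna().sum())
        sub = sub.dropna()
        if len(sub) == 0 and n_undef == 0:
            raise ValidationError(f"group {name!r} contains no pairs")
        counts = sub.value_counts().to_dict()
        out.append(AssemblyPartition(group=name,
                                     counts={p: int(counts.get(p, 0)) for p in PROCESSES},
                                     n_pairs=int(len(sub)),
                                     n_undefined=n_undef))
    return out


def partition_table(partitions: list[AssemblyPartition]) -> pd.DataFrame:
    rows = {}
    for part in partitions:
        row = part.float_fractions()
        roll = part.rollup()
        row["deterministic"] = float(roll["deterministic"])
        row["stochastic"] = float(roll["stochastic"])
        row["n_pairs"] = part.n_pairs
        row["n_undefined"] = part.n_undefined
        rows[part.group] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
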