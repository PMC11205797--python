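"""Core data containers and I/O: abundance tables, phylogenies, sample metadata.

All downstream analyses operate on a consistent triple (AbundanceTable,
Phylogeny, SampleMetadata) whose identifiers have been cross-validated and
whose counts have been rarefied to a common per-sample depth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
import yaml


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ValidationError(ValueError):
    """Base class for dataset validation failures."""


class DuplicateIDError(ValidationError):
    """Duplicate taxon or sample identifiers."""


class TaxonTreeMismatchError(ValidationError):
    """Taxa in the count table are missing from the phylogeny."""


class NewickParseError(ValidationError):
    """The tree file could not be parsed as newick."""


class MissingMetadataError(ValidationError):
    """Samples in the count table lack metadata rows."""


class ShallowSampleError(ValidationError):
    """Samples whose total count is below the requested rarefaction depth."""


# ---------------------------------------------------------------------------
# Seed derivation
# ---------------------------------------------------------------------------

def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed (< 2**31) from one master seed.

    Uses CRC32 of the stage name so each pipeline stage gets an independent,
    platform-stable stream regardless of the order stages run in.
    """
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# AbundanceTable
# ---------------------------------------------------------------------------

class AbundanceTable:
    """Integer count matrix, taxa x samples — the currency of every stage.

    Parameters
    ----------
    counts
        DataFrame with taxa as the index and samples as columns; values must
        be non-negative integers.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate taxon ids: {dups}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self._df = counts.astype(np.int64)
        self._df.index = self._df.index.astype(str)
        self._df.columns = self._df.columns.astype(str)

    # -- basic accessors ----------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> pd.DataFrame:
        return self._df

    @property
    def n_taxa(self) -> int:
        return self._df.shape[0]

    @property
    def n_samples(self) -> int:
        return self._df.shape[1]

    def sample_sums(self) -> pd.Series:
        return self._df.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self._df.sum(axis=0)
        if (sums == 0).any():
            empty = sums.index[sums == 0].tolist()
            raise ValidationError(f"samples with zero total count: {empty}")
        return self._df / sums

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon occurs (count >= 1)."""
        return (self._df > 0).mean(axis=1)

    def drop_empty_taxa(self) -> "AbundanceTable":
        keep = self._df.sum(axis=1) > 0
        return AbundanceTable(self._df.loc[keep])

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self._df.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return AbundanceTable(self._df[list(sample_ids)])

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "AbundanceTable":
        missing = [t for t in taxon_ids if t not in self._df.index]
        if missing:
            raise ValidationError(f"unknown taxon ids: {missing}")
        return AbundanceTable(self._df.loc[list(taxon_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, AbundanceTable) and self._df.equals(other._df)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, samples_as_rows: bool = False) -> "AbundanceTable":
        """Read a tab-delimited count table.

        Default on-disk orientation: rows = taxa, first column = taxon id,
        header = sample ids (the common amplicon export layout); pass
        ``samples_as_rows=True`` for the transpose.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        if samples_as_rows:
            df = df.T
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        df = self._df.copy()
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_biom_json(cls, path: str | Path) -> "AbundanceTable":
        """Read a (sparse or dense) BIOM v1 JSON table."""
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:] = np.asarray(doc["data"])
        return cls(pd.DataFrame(mat, index=taxa, columns=samples))


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """Rooted tree with branch lengths; tips are taxa of the count table."""

    def __init__(self, tree: skbio.TreeNode):
        names = [t.name for t in tree.tips()]
        if any(n is None for n in names):
            raise ValidationError("tree has unlabelled tips")
        if len(names) != len(set(names)):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateIDError(f"duplicate tip labels: {dups}")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError(f"negative branch length at {node.name!r}")
        self._tree = tree

    @property
    def tree(self) -> skbio.TreeNode:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self._tree.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.tips())

    @classmethod
    def from_newick(cls, path: str | Path) -> "Phylogeny":
        try:
            tree = skbio.TreeNode.read(str(path), format="newick",
                                       convert_underscores=False)
        except Exception as exc:  # skbio raises several parser error types
            raise NewickParseError(f"could not parse newick file {path}: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick_string(cls, newick: str) -> "Phylogeny":
        try:
            tree = skbio.TreeNode.read([newick], format="newick",
                                       convert_underscores=False)
        except Exception as exc:
            raise NewickParseError(f"could not parse newick string: {exc}") from exc
        return cls(tree)

    def to_newick(self, path: str | Path) -> None:
        self._tree.write(str(path), format="newick")

    def prune_to(self, taxon_ids: Iterable[str]) -> "Phylogeny":
        """Return a copy pruned to the given tips (all must exist)."""
        wanted = set(taxon_ids)
        have = set(self.tip_names)
        missing = sorted(wanted - have)
        if missing:
            raise TaxonTreeMismatchError(
                f"taxa in table absent from tree: {missing}")
        pruned = self._tree.shear(wanted)
        pruned.prune()
        return Phylogeny(pruned)

    def patristic_matrix(self, order: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Pairwise tip-to-tip distances as (labels, dense symmetric matrix)."""
        dm = self._tree.tip_tip_distances()
        labels = list(dm.ids) if order is None else list(order)
        missing = [t for t in labels if t not in set(dm.ids)]
        if missing:
            raise TaxonTreeMismatchError(f"taxa absent from tree: {missing}")
        idx = [list(dm.ids).index(t) for t in labels]
        mat = dm.data[np.ix_(idx, idx)]
        return labels, mat


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

MANDATORY_METADATA = ("sample_id", "patch_id", "area_m2")


class SampleMetadata:
    """Per-sample patch membership, patch area and soil properties."""

    def __init__(self, df: pd.DataFrame):
        for col in ("patch_id", "area_m2"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing mandatory column {col!r}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate sample ids in metadata: {dups}")
        if (df["area_m2"] <= 0).any():
            bad = df.index[df["area_m2"] <= 0].tolist()
            raise ValidationError(f"non-positive areas for samples: {bad}")
        per_patch = df.groupby("patch_id")["area_m2"].nunique()
        if (per_patch > 1).any():
            bad = per_patch.index[per_patch > 1].tolist()
            raise ValidationError(f"area_m2 not constant within patch: {bad}")
        self._df = df.copy()
        self._df.index = self._df.index.astype(str)
        self._df["patch_id"] = self._df["patch_id"].astype(str)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def patch_ids(self) -> list[str]:
        return sorted(self._df["patch_id"].unique())

    @property
    def soil_property_names(self) -> list[str]:
        return [c for c in self._df.columns
                if c not in ("patch_id", "area_m2")
                and pd.api.types.is_numeric_dtype(self._df[c])]

    def patch_of(self) -> pd.Series:
        return self._df["patch_id"]

    def area_of_patch(self) -> pd.Series:
        """Patch id -> area (m^2)."""
        return self._df.groupby("patch_id")["area_m2"].first()

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self._df.loc[list(sample_ids)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t")
        if "sample_id" not in df.columns:
            raise ValidationError("metadata missing mandatory column 'sample_id'")
        df = df.set_index("sample_id")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self._df.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Pipeline configuration: all tunable constants in one place.

    Null/permutation counts default to the production values (999 tree
    randomizations for betaNTI/RC_bray, 1000 label permutations for niche
    breadth); desk-scale runs lower them via the config file.
    """

    seed: int = 42
    rarefaction_depth: int | None = None          # None -> min sample sum
    n_null: int = 999                             # betaNTI / RC_bray randomizations
    n_permutations: int = 1000                    # niche-breadth permutations
    alpha: float = 0.05                           # two-sided niche-breadth level
    network_profile: str = "bacteria-like"
    subset: str = "entire"                        # entire | generalist | specialist
    standardize_heterogeneity: bool = False
    absolute_rho: bool = False
    adjust_p: bool = False
    inputs: dict = field(default_factory=dict)    # counts/tree/metadata paths
    simulate: dict = field(default_factory=dict)  # generator parameters

    def __post_init__(self):
        if self.n_null < 1:
            raise ValidationError("n_null must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0,1)")
        if self.subset not in ("entire", "generalist", "specialist"):
            raise ValidationError(f"unknown subset {self.subset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Dataset assembly and rarefaction
# ---------------------------------------------------------------------------

def read_dataset(counts_path: str | Path,
                 tree_path: str | Path,
                 metadata_path: str | Path,
                 samples_as_rows: bool = False,
                 ) -> tuple[AbundanceTable, Phylogeny, SampleMetadata]:
    """Read and cross-validate the three input artifacts.

    The tree is pruned to the taxa present in the table; every table sample
    must have a metadata row (samples present only in metadata are dropped
    from metadata, keeping the table authoritative).
    """
    table = AbundanceTable.from_tsv(counts_path, samples_as_rows=samples_as_rows)
    phylo = Phylogeny.from_newick(tree_path)
    meta = SampleMetadata.from_tsv(metadata_path)

    missing_meta = [s for s in table.sample_ids if s not in set(meta.sample_ids)]
    if missing_meta:
        raise MissingMetadataError(f"samples without metadata: {missing_meta}")
    meta = meta.subset(table.sample_ids)
    phylo = phylo.prune_to(table.taxon_ids)
    return table, phylo, meta


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Draws are multivariate hypergeometric (classic rarefaction), seeded and
    reproducible. Taxa left with zero total count are dropped. Samples whose
    total equals ``depth`` are returned unchanged.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    sums = table.sample_sums()
    shallow = sums.index[sums < depth].tolist()
    if shallow:
        raise ShallowSampleError(
            f"samples shallower than depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j, sample in enumerate(table.sample_ids):
        col = table.counts.iloc[:, j].to_numpy()
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    rarefied = AbundanceTable(
        pd.DataFrame(out, index=table.taxon_ids, columns=table.sample_ids))
    return rarefied.drop_empty_taxa()
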