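"""Thresholded Spearman co-occurrence networks and per-sample subnetworks.

Edges connect taxa whose abundance profiles are strongly, significantly rank
correlated. Two built-in threshold profiles match common practice for the two
kingdoms: "bacteria-like" (prevalence >= 0.5, rho > 0.8, p < 0.01) and
"fungi-like" (prevalence >= 0.4, rho > 0.5, p < 0.05). Positive correlations
only by default; an absolute-rho mode and BH p-adjustment sit behind flags.

Per-sample subnetworks are the induced subgraphs on the taxa present in each
sample; their size (nodes), connectivity (edges) and modularity are the
topological responses regressed on patch area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .dataset import AbundanceTable, SampleMetadata, ValidationError
from .diversity import SARFit, sar_regression


@dataclass(frozen=True)
class ThresholdProfile:
    """Prevalence / correlation / significance cutoffs for network building."""

    name: str = "custom"
    min_prevalence: float = 0.5
    rho_cutoff: float = 0.8
    p_cutoff: float = 0.01
    absolute_rho: bool = False
    adjust_p: bool = False

    def __post_init__(self):
        if not (0 < self.min_prevalence <= 1):
            raise ValidationError("min_prevalence must be in (0, 1]")
        if not (0 < self.rho_cutoff < 1):
            raise ValidationError("rho_cutoff must be in (0, 1)")
        if not (0 < self.p_cutoff < 1):
            raise ValidationError("p_cutoff must be in (0, 1)")


BACTERIA_LIKE = ThresholdProfile("bacteria-like", 0.5, 0.8, 0.01)
FUNGI_LIKE = ThresholdProfile("fungi-like", 0.4, 0.5, 0.05)

PROFILES = {"bacteria-like": BACTERIA_LIKE, "fungi-like": FUNGI_LIKE}


def get_profile(name: str, absolute_rho: bool = False,
                adjust_p: bool = False) -> ThresholdProfile:
    if name not in PROFILES:
        raise ValidationError(f"unknown profile {name!r}; have {sorted(PROFILES)}")
    base = PROFILES[name]
    return ThresholdProfile(base.name, base.min_prevalence, base.rho_cutoff,
                            base.p_cutoff, absolute_rho, adjust_p)


@dataclass
class CooccurrenceNetwork:
    """Undirected graph of co-occurring taxa plus the profile that built it."""

    graph: nx.Graph
    profile: ThresholdProfile
    taxa_tested: list[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, d["rho"], d["p"])
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p"])


@dataclass
class SubnetworkStats:
    """Per-sample induced subgraph topology; modularity None when undefined."""

    sample_id: str
    n_nodes: int
    n_edges: int
    modularity: float | None
    n_modules: int | None


def prevalence_filter(table: AbundanceTable, min_prevalence: float) -> AbundanceTable:
    """Keep taxa occurring in at least ``min_prevalence`` of samples."""
    if not (0 < min_prevalence <= 1):
        raise ValidationError("min_prevalence must be in (0, 1]")
    keep = table.prevalence() >= min_prevalence
    if not keep.any():
        raise ValidationError(
            f"no taxa pass prevalence >= {min_prevalence}; lower the threshold")
    return table.subset_taxa(keep.index[keep].tolist())


def build_network(table: AbundanceTable,
                  profile: ThresholdProfile,
                  keep_isolated: bool = False) -> CooccurrenceNetwork:
    """All-pairs Spearman correlation, thresholded into an undirected graph.

    Constant-abundance taxa (undefined rank correlation) are excluded with a
    warning. Deterministic: same table and profile give the same edge list.
    """
    if table.n_samples < 4:
        raise ValidationError("build_network needs >= 4 samples")
    filtered = prevalence_filter(table, profile.min_prevalence)
    X = filtered.counts.to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    if constant.any():
        dropped = [t for t, c in zip(filtered.taxon_ids, constant) if c]
        warnings.warn(f"excluding constant-abundance taxa: {dropped}")
        filtered = filtered.subset_taxa(
            [t for t, c in zip(filtered.taxon_ids, constant) if not c])
        X = filtered.counts.to_numpy(dtype=float)
    taxa = filtered.taxon_ids
    if len(taxa) < 2:
        raise ValidationError("fewer than 2 variable taxa; nothing to correlate")

    rho, p = spearmanr(X, axis=1)
    if len(taxa) == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu = np.triu_indices(len(taxa), k=1)
    rho_u, p_u = rho[iu], p[iu]
    if profile.adjust_p:
        p_u = multipletests(p_u, method="fdr_bh")[1]
    strength = np.abs(rho_u) if profile.absolute_rho else rho_u
    keep = (strength > profile.rho_cutoff) & (p_u < profile.p_cutoff)

    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(taxa)
    for (i, j, r, pv) in zip(iu[0][keep], iu[1][keep], rho_u[keep], p_u[keep]):
        g.add_edge(taxa[i], taxa[j], rho=float(r), p=float(pv))
    return CooccurrenceNetwork(g, profile, taxa)


def extract_subnetwork(network: CooccurrenceNetwork,
                       sample_abundances: pd.Series,
                       sample_id: str = "") -> SubnetworkStats:
    """Induced subgraph on the network taxa present (count > 0) in a sample.

    Modularity uses deterministic greedy agglomeration (CNM) on the induced
    subgraph; it is reported missing for graphs with no edges.
    """
    present = set(sample_abundances.index[sample_abundances > 0])
    nodes = [n for n in network.graph.nodes if n in present]
    sub = network.graph.subgraph(nodes)
    n_nodes, n_edges = sub.number_of_nodes(), sub.number_of_edges()
    if n_edges == 0:
        return SubnetworkStats(sample_id, n_nodes, 0, None, None)
    comms = nx.community.greedy_modularity_communities(sub)
    q = nx.community.modularity(sub, comms)
    return SubnetworkStats(sample_id, n_nodes, n_edges, float(q), len(comms))


def subnetwork_table(network: CooccurrenceNetwork,
                     table: AbundanceTable) -> pd.DataFrame:
    """SubnetworkStats for every sample of the table."""
    rows = {}
    for sid in table.sample_ids:
        st = extract_subnetwork(network, table.counts[sid], sid)
        rows[sid] = {"n_nodes": st.n_nodes, "n_edges": st.n_edges,
                     "modularity": st.modularity, "n_modules": st.n_modules}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def topology_area_regression(stats: pd.DataFrame, metadata: SampleMetadata
                             ) -> dict[str, SARFit]:
    """OLS of node count, edge count and modularity on log10(area)."""
    area = metadata.df["area_m2"].reindex(stats.index)
    fits = {}
    for metric in ("n_nodes", "n_edges", "modularity"):
        y = pd.to_numeric(stats[metric], errors="coerce")
        if y.notna().sum() < 3:
            raise ValidationError(
                f"fewer than 3 samples with defined {metric}")
        fits[metric] = sar_regression(area, y, metric)
    return fits


def write_graphml(network: CooccurrenceNetwork, path: str) -> None:
    nx.write_graphml(network.graph, path)
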