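"""Co-regulatory, ceRNA and pathogenic-rescue network operations.

The co-regulatory network is the bipartite mRNA-lncRNA graph induced by
super-threshold adjusted correlations; the ceRNA network joins lncRNA
and mRNA miRNA-target tables on their shared miRNAs; the rescue step
recovers lncRNAs adjacent to known pathogenic mRNAs, feeding the final
multivariate survival model alongside the regression-screened set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .fusion import AdjustedCorrelation

__all__ = ["CoRegNetwork", "CeRNANetwork", "coreg_network", "cerna_network", "rescue_lncrnas"]


@dataclass
class CoRegNetwork:
    """Bipartite lncRNA-mRNA edge list with signed correlation weights."""

    edges: pd.DataFrame  # columns: mrna, lncrna, weight
    mrna_degree: pd.Series  # sorted descending
    lncrna_degree: pd.Series

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.edges["mrna"].unique(), bipartite="mRNA")
        g.add_nodes_from(self.edges["lncrna"].unique(), bipartite="lncRNA")
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.mrna, row.lncrna, weight=row.weight)
        return g


@dataclass
class CeRNANetwork:
    """Tripartite lncRNA-miRNA-mRNA edge lists restricted to shared miRNAs."""

    lnc_edges: pd.DataFrame  # columns: lncrna, mirna
    mrna_edges: pd.DataFrame  # columns: mrna, mirna
    shared_mirnas: set

    @property
    def n_nodes(self) -> tuple[int, int, int]:
        return (
            self.lnc_edges["lncrna"].nunique(),
            self.mrna_edges["mrna"].nunique(),
            len(self.shared_mirnas),
        )


def coreg_network(ac, edge_alpha: float) -> CoRegNetwork:
    """Edges for every adjusted-correlation entry with |AC| >= edge_alpha."""
    if not 0 <= edge_alpha:
        raise ValueError("edge_alpha must be non-negative")
    mat = ac.matrix if isinstance(ac, AdjustedCorrelation) else ac
    long = mat.stack().rename("weight").rename_axis(["mrna", "lncrna"]).reset_index()
    edges = long[long["weight"].abs() >= edge_alpha].reset_index(drop=True)
    return CoRegNetwork(
        edges=edges,
        mrna_degree=edges["mrna"].value_counts(),
        lncrna_degree=edges["lncrna"].value_counts(),
    )


def _check_table(t: pd.DataFrame, feature_col: str) -> pd.DataFrame:
    if feature_col not in t.columns or "mirna" not in t.columns:
        raise ValueError(f"table must have columns ({feature_col}, mirna)")
    return t[[feature_col, "mirna"]].drop_duplicates()


def cerna_network(
    lnc_mir: pd.DataFrame,
    mrna_mir: pd.DataFrame,
    lnc_set=None,
    mrna_set=None,
) -> CeRNANetwork:
    """Join target tables on miRNAs shared between the two feature sets.

    Tables need (feature, mirna) columns; the first column is taken as
    the feature id if not named.  ``lnc_set`` / ``mrna_set`` restrict to
    the differentially expressed features before the join.  Duplicated
    rows and row order do not affect the result (set semantics).
    """
    lnc = lnc_mir.rename(columns={lnc_mir.columns[0]: "lncrna"})
    mr = mrna_mir.rename(columns={mrna_mir.columns[0]: "mrna"})
    lnc = _check_table(lnc, "lncrna")
    mr = _check_table(mr, "mrna")
    if lnc_set is not None:
        lnc = lnc[lnc["lncrna"].isin(set(lnc_set))]
    if mrna_set is not None:
        mr = mr[mr["mrna"].isin(set(mrna_set))]
    shared = set(lnc["mirna"]) & set(mr["mirna"])
    lnc = lnc[lnc["mirna"].isin(shared)].sort_values(["lncrna", "mirna"]).reset_index(drop=True)
    mr = mr[mr["mirna"].isin(shared)].sort_values(["mrna", "mirna"]).reset_index(drop=True)
    return CeRNANetwork(lnc_edges=lnc, mrna_edges=mr, shared_mirnas=shared)


def rescue_lncrnas(coreg: CoRegNetwork, pathogenic) -> set:
    """lncRNAs adjacent (in the co-regulatory network) to pathogenic mRNAs."""
    pathogenic = set(pathogenic)
    hit = coreg.edges["mrna"].isin(pathogenic)
    return set(coreg.edges.loc[hit, "lncrna"])
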