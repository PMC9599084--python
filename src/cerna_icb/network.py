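"""ceRNA--miRNA--mRNA network assembly and correlation validation.

A competing-endogenous-RNA (ceRNA) edge links a differentially expressed
circRNA or lncRNA to a differentially expressed mRNA when the two share
at least one miRNA: the miRNA must be predicted to bind the ceRNA, and
the miRNA-mRNA interaction must be supported by at least ``min_tools``
of the prediction tools (default 5 of 7).  Only miRNAs interacting with
at least one DE ceRNA enter the network.  Because a ceRNA sponges the
shared miRNA, the model predicts a *positive* ceRNA-mRNA expression
correlation, so edges are validated by the Pearson correlation of
log2-normalized expression and, by default, only positively correlated
edges are kept.  miRNA expression is not modeled; miRNAs annotate edges.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "CeRnaNetworkBuilder",
    "consensus_mrna_mirna",
    "select_network_mirnas",
    "assemble_cerna_network",
    "correlate_edges",
]


def consensus_mrna_mirna(
    records: pd.DataFrame, min_tools: int = 5, n_tools: int = 7
) -> pd.DataFrame:
    """Keep miRNA-mRNA predictions supported by >= ``min_tools`` tools."""
    if min_tools > n_tools:
        raise ValueError(
            f"min_tools={min_tools} exceeds the configured {n_tools} tools"
        )
    if "support" not in records.columns:
        raise ValueError("mRNA-miRNA records must carry a 'support' column")
    if (records["support"] > n_tools).any():
        raise ValueError(
            f"support values exceed the configured {n_tools} tools"
        )
    return records.loc[records["support"] >= min_tools].reset_index(drop=True)


def select_network_mirnas(
    circ_mirna: pd.DataFrame,
    lnc_mirna: pd.DataFrame,
    de_cerna_ids,
) -> set[str]:
    """miRNAs predicted to bind any differentially expressed ceRNA."""
    de = set(de_cerna_ids)
    out: set[str] = set()
    for tab in (circ_mirna, lnc_mirna):
        if len(tab) == 0:
            continue
        hit = tab.loc[tab["source_id"].isin(de), "mirna_id"]
        out.update(hit.tolist())
    return out


def assemble_cerna_network(
    de_cerna_ids,
    de_mrna_ids,
    filtered_mrna_records: pd.DataFrame,
    cerna_records: pd.DataFrame,
    mirna_set,
) -> pd.DataFrame:
    """Pre-correlation edge set: (ceRNA, mRNA) pairs with shared miRNAs.

    An edge exists iff some miRNA in ``mirna_set`` binds the DE ceRNA and
    its interaction with the DE mRNA survived the tool-consensus filter;
    ``shared_mirnas`` lists every such miRNA.  ceRNAs without any miRNA
    interaction do not appear.
    """
    de_ce = set(de_cerna_ids)
    de_g = set(de_mrna_ids)
    mirnas = set(mirna_set)

    ce = cerna_records.loc[
        cerna_records["source_id"].isin(de_ce)
        & cerna_records["mirna_id"].isin(mirnas),
        ["source_id", "mirna_id"],
    ].drop_duplicates()
    gg = filtered_mrna_records.loc[
        filtered_mrna_records["source_id"].isin(de_g)
        & filtered_mrna_records["mirna_id"].isin(mirnas),
        ["source_id", "mirna_id"],
    ].drop_duplicates()
    merged = ce.merge(gg, on="mirna_id", suffixes=("_cerna", "_mrna"))
    if len(merged) == 0:
        return pd.DataFrame(columns=["cerna_id", "mrna_id", "shared_mirnas"])
    edges = (
        merged.groupby(["source_id_cerna", "source_id_mrna"], sort=True)[
            "mirna_id"
        ]
        .apply(lambda s: frozenset(s))
        .reset_index()
        .rename(
            columns={
                "source_id_cerna": "cerna_id",
                "source_id_mrna": "mrna_id",
                "mirna_id": "shared_mirnas",
            }
        )
    )
    return edges


def correlate_edges(
    edges: pd.DataFrame,
    cerna_expression: pd.DataFrame,
    mrna_expression: pd.DataFrame,
    keep: str = "positive",
    r_min: float = 0.0,
) -> pd.DataFrame:
    """Attach Pearson r/p to each edge and apply the retention rule.

    Expression inputs are normalized (log2(size-factor-scaled + 1))
    feature x sample matrices sharing one sample namespace; vectors need
    length >= 3.  Zero-variance endpoints drop the edge with a logged
    reason.  ``keep="positive"`` removes edges with r <= ``r_min``
    (ceRNA sponging predicts direct correlation); ``keep="all"`` retains
    everything.
    """
    if keep not in ("positive", "all"):
        raise ValueError("keep must be 'positive' or 'all'")
    if len(edges) == 0:
        out = edges.copy()
        out["pearson_r"] = pd.Series(dtype=float)
        out["pearson_p"] = pd.Series(dtype=float)
        return out
    common = [c for c in cerna_expression.columns
              if c in set(mrna_expression.columns)]
    if len(common) < 3:
        raise ValueError(
            "at least 3 shared samples are required for correlation"
        )
    rows = []
    n_dropped_var = 0
    for e in edges.itertuples(index=False):
        if e.cerna_id not in cerna_expression.index:
            raise ValueError(f"expression missing for ceRNA {e.cerna_id!r}")
        if e.mrna_id not in mrna_expression.index:
            raise ValueError(f"expression missing for mRNA {e.mrna_id!r}")
        x = cerna_expression.loc[e.cerna_id, common].to_numpy(dtype=float)
        y = mrna_expression.loc[e.mrna_id, common].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            n_dropped_var += 1
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((*tuple(e), float(r), float(p)))
    if n_dropped_var:
        logger.warning(
            "correlate_edges: dropped %d edge(s) with a zero-variance "
            "expression vector", n_dropped_var,
        )
    out = pd.DataFrame(
        rows, columns=list(edges.columns) + ["pearson_r", "pearson_p"]
    )
    if keep == "positive":
        out = out.loc[out["pearson_r"] > r_min].reset_index(drop=True)
    return out


def _edges_to_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for e in edges.itertuples(index=False):
        g.add_node(e.cerna_id, node_class="cerna")
        g.add_node(e.mrna_id, node_class="mrna")
        attrs = {"shared_mirnas": ";".join(sorted(e.shared_mirnas))}
        if hasattr(e, "pearson_r"):
            attrs["pearson_r"] = float(e.pearson_r)
            attrs["pearson_p"] = float(e.pearson_p)
        g.add_edge(e.cerna_id, e.mrna_id, **attrs)
    return g


class CeRnaNetworkBuilder(BaseEstimator):
    """Assemble and correlation-validate the ceRNA network.

    Parameters
    ----------
    min_tools, n_tools
        Tool-consensus filter on miRNA-mRNA predictions (default 5 of 7).
    keep, r_min
        Edge retention rule after Pearson correlation (default keeps
        edges with r > 0).

    Attributes
    ----------
    mirna_set_ : set
        miRNAs binding at least one DE ceRNA.
    filtered_mrna_records_ : pd.DataFrame
    edges_pre_ : pd.DataFrame
        Pre-correlation edges with shared miRNAs.
    edges_ : pd.DataFrame
        Final edges with ``pearson_r`` / ``pearson_p``.
    graph_ : networkx.Graph
    """

    def __init__(
        self,
        min_tools: int = 5,
        n_tools: int = 7,
        keep: str = "positive",
        r_min: float = 0.0,
    ):
        self.min_tools = min_tools
        self.n_tools = n_tools
        self.keep = keep
        self.r_min = r_min

    def fit(
        self,
        circ_mirna: pd.DataFrame,
        lnc_mirna: pd.DataFrame,
        mrna_mirna: pd.DataFrame,
        de_cerna_ids,
        de_mrna_ids,
        cerna_expression: pd.DataFrame | None = None,
        mrna_expression: pd.DataFrame | None = None,
    ):
        """Build the network from interaction tables and DE id sets.

        Expression matrices (normalized, features x samples) are needed
        for the correlation step; without them only ``edges_pre_`` is
        populated and ``edges_`` carries no correlation columns.
        """
        self.filtered_mrna_records_ = consensus_mrna_mirna(
            mrna_mirna, self.min_tools, self.n_tools
        )
        self.mirna_set_ = select_network_mirnas(
            circ_mirna, lnc_mirna, de_cerna_ids
        )
        cerna_records = pd.concat(
            [circ_mirna, lnc_mirna], ignore_index=True
        )
        self.edges_pre_ = assemble_cerna_network(
            de_cerna_ids,
            de_mrna_ids,
            self.filtered_mrna_records_,
            cerna_records,
            self.mirna_set_,
        )
        if cerna_expression is not None and mrna_expression is not None:
            self.edges_ = correlate_edges(
                self.edges_pre_, cerna_expression, mrna_expression,
                keep=self.keep, r_min=self.r_min,
            )
        else:
            self.edges_ = self.edges_pre_.copy()
        self.graph_ = _edges_to_graph(self.edges_)
        return self

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph_, path)

    def edge_table(self) -> pd.DataFrame:
        """Edge list with shared miRNAs flattened for TSV export."""
        out = self.edges_.copy()
        out["shared_mirnas"] = out["shared_mirnas"].map(
            lambda s: ";".join(sorted(s))
        )
        return out
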