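"""Gene-network construction, community decomposition and composite scoring.

The ranking machinery follows the decomposition-integration scheme: build
an undirected gene network from positive relation predictions, split it
into communities (sub-networks), then score

    CMI = CD * CB * (1/CC) + CE          (per-gene composite centrality)
    SW  = N + ZJW                        (sub-network weight)
    ZSW = (SW - MIN) / (MAX - MIN)       (min-max over sub-networks)
    GW  = CMI + ZSW                      (final gene weight)

where CD/CB/CC/CE are degree, betweenness, closeness and eigenvector (hub)
centralities, N the sub-network size and ZJW an expert-assigned relevance
score for the sub-network (nonnegative, default 0).

Normalization: each centrality is scaled by its maximum over the network so
the top gene scores exactly 1.0 in each index (closeness and eigenvector
are computed within connected components; eigenvector is scaled to max 1
per component since cross-component magnitudes are not comparable).  When
CB = 0 the product term is taken as 0 regardless of CC.  When all
sub-networks tie on SW, every ZSW is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ValidationError
from .io import GenePairKey
from .relations import RelationPrediction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CentralityProfile:
    """Per-gene centralities, each max-scaled into [0, 1]."""

    cd: float  # degree
    cb: float  # betweenness
    cc: float  # closeness
    ce: float  # eigenvector / hub


@dataclass
class SubnetInfo:
    """One community: members, size, expert score and derived weights."""

    subnet_id: int
    members: frozenset[str]
    zjw: float = 0.0
    sw: float | None = None
    zsw: float | None = None

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class SubnetPartition:
    """A disjoint, covering community decomposition of the network."""

    subnets: list[SubnetInfo]

    @property
    def sw_min(self) -> float:
        return min(s.sw for s in self.subnets)

    @property
    def sw_max(self) -> float:
        return max(s.sw for s in self.subnets)

    def subnet_of(self, symbol: str) -> SubnetInfo:
        for s in self.subnets:
            if symbol in s.members:
                return s
        raise KeyError(symbol)


def build_network(predictions: Sequence[RelationPrediction]) -> nx.Graph:
    """Network whose edges are the positively-labeled gene pairs.

    Duplicate pairs collapse to one edge; genes never appearing in a
    positive pair are excluded (no isolated nodes).  An input with no
    positive prediction yields an empty network with a logged warning.
    """
    graph = nx.Graph()
    for p in predictions:
        if p.label == 1:
            graph.add_edge(*p.pair)
    if graph.number_of_nodes() == 0:
        logger.warning("no positive relation predictions; network is empty")
    return graph


def compute_centralities(network: nx.Graph) -> dict[str, CentralityProfile]:
    """Max-scaled degree, betweenness, closeness and eigenvector centralities.

    Degenerate single-node contract: CD = CB = 0, CC = 0, CE = 1.
    """
    if network.number_of_nodes() == 0:
        raise ValidationError("cannot compute centralities of an empty network")
    nodes = list(network.nodes())
    if len(nodes) == 1:
        return {nodes[0]: CentralityProfile(cd=0.0, cb=0.0, cc=0.0, ce=1.0)}

    degree = dict(network.degree())
    max_deg = max(degree.values())
    cd = {v: (degree[v] / max_deg if max_deg else 0.0) for v in nodes}

    btw = nx.betweenness_centrality(network, normalized=True)
    max_btw = max(btw.values())
    cb = {v: (btw[v] / max_btw if max_btw > 0 else 0.0) for v in nodes}

    cc_raw: dict[str, float] = {}
    ce_raw: dict[str, float] = {}
    for comp in nx.connected_components(network):
        sub = network.subgraph(comp)
        if sub.number_of_nodes() == 1:
            v = next(iter(comp))
            cc_raw[v] = 0.0
            ce_raw[v] = 1.0
            continue
        clo = nx.closeness_centrality(sub)  # Freeman-normalized in-component
        cc_raw.update(clo)
        if sub.number_of_nodes() == 2:
            # the ARPACK path needs n >= 3; the 2-node answer is symmetric
            eig = {v: 1.0 for v in sub}
        else:
            eig = nx.eigenvector_centrality_numpy(sub)
        max_e = max(eig.values())
        for v, val in eig.items():
            ce_raw[v] = val / max_e  # per-component scaling: each hub gets 1
    max_cc = max(cc_raw.values())
    cc = {v: (cc_raw[v] / max_cc if max_cc > 0 else 0.0) for v in nodes}

    return {v: CentralityProfile(cd=cd[v], cb=cb[v], cc=cc[v], ce=ce_raw[v])
            for v in nodes}


def detect_communities(network: nx.Graph, seed: int = 0) -> SubnetPartition:
    """Louvain modularity communities with deterministic ordering.

    Sub-networks are sorted by descending size then smallest member symbol
    and numbered from 1; singleton components become singleton sub-networks.
    """
    if network.number_of_nodes() == 0:
        raise ValidationError("cannot decompose an empty network")
    communities = nx.community.louvain_communities(network, seed=seed)
    ordered = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    return SubnetPartition(subnets=[
        SubnetInfo(subnet_id=i + 1, members=frozenset(c))
        for i, c in enumerate(ordered)])


def compute_cmi(profile: CentralityProfile) -> float:
    """Composite centrality CMI = CD*CB*(1/CC) + CE.

    The product term is 0 whenever CB = 0 (so leaf or isolated genes fall
    back to their hub score); CC = 0 with CB > 0 is an arithmetic guard
    error — closeness is computed within components, so this cannot arise
    from the pipeline's own profiles.
    """
    if profile.cb == 0:
        return profile.ce
    if profile.cc == 0:
        raise InvalidParameterError("CC = 0 with CB > 0: undefined 1/CC term")
    return profile.cd * profile.cb / profile.cc + profile.ce


def score_subnets(partition: SubnetPartition,
                  zjw_map: Mapping[int, float] | None = None) -> SubnetPartition:
    """Fill SW = N + ZJW per sub-network (ZJW defaults to 0)."""
    zjw_map = zjw_map or {}
    for s in partition.subnets:
        zjw = float(zjw_map.get(s.subnet_id, 0.0))
        if zjw < 0:
            raise ValidationError(f"negative ZJW {zjw} for subnet {s.subnet_id}")
        s.zjw = zjw
        s.sw = s.n + zjw
    return partition


def normalize_subnet_weights(partition: SubnetPartition) -> SubnetPartition:
    """Min-max normalize SW into ZSW; all-equal SW means every ZSW = 1."""
    if any(s.sw is None for s in partition.subnets):
        raise ValidationError("score_subnets must run before normalization")
    lo, hi = partition.sw_min, partition.sw_max
    for s in partition.subnets:
        s.zsw = 1.0 if hi == lo else (s.sw - lo) / (hi - lo)
    return partition


def compute_gw(cmi: float, zsw: float) -> float:
    """Final gene weight GW = CMI + ZSW."""
    if not (np.isfinite(cmi) and np.isfinite(zsw)) or cmi < 0 or zsw < 0:
        raise InvalidParameterError("CMI and ZSW must be finite and nonnegative")
    return cmi + zsw


RANKING_COLUMNS = ["Id", "Gene", "Degree", "Closeness", "Betweenness", "Hub",
                   "CMI", "ZSW", "GW"]


def rank_genes(network: nx.Graph, partition: SubnetPartition | None = None,
               zjw_map: Mapping[int, float] | None = None,
               seed: int = 0) -> pd.DataFrame:
    """Full ranking table: one row per gene, sorted by GW descending.

    Runs centralities, community scoring and the composite formulas; ties
    on GW break by gene symbol.  Columns follow the standard report layout
    (Id, Gene, Degree, Closeness, Betweenness, Hub, CMI, ZSW, GW).
    """
    profiles = compute_centralities(network)
    if partition is None:
        partition = detect_communities(network, seed=seed)
    score_subnets(partition, zjw_map)
    normalize_subnet_weights(partition)
    rows = []
    for symbol, prof in profiles.items():
        cmi = compute_cmi(prof)
        zsw = partition.subnet_of(symbol).zsw
        rows.append({"Gene": symbol, "Degree": prof.cd, "Closeness": prof.cc,
                     "Betweenness": prof.cb, "Hub": prof.ce, "CMI": cmi,
                     "ZSW": zsw, "GW": compute_gw(cmi, zsw)})
    table = pd.DataFrame(rows).sort_values(
        ["GW", "Gene"], ascending=[False, True], kind="mergesort")
    table.insert(0, "Id", range(1, len(table) + 1))
    return table.reset_index(drop=True)[RANKING_COLUMNS]
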