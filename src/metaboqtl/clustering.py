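"""Deconvolution of redundant LC-MS features.

Electrospray ionization produces several ions per molecule — adducts
([M+Na]+, [M+K]+ ...), in-source fragments and multimers — so one
metabolite yields several feature columns that co-elute and are strongly
intensity-correlated. Features are grouped into clusters by retention-time
proximity and Spearman correlation, the protonated ion (or the most
abundant member) is chosen as the cluster's primary feature, and known
identities are propagated to co-clustered unknowns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable

__all__ = ["AdductTable", "FeatureCluster", "cluster_features", "assign_primary", "propagate_identity"]

logger = logging.getLogger(__name__)

PROTON_MASS = 1.00728  # Da


@dataclass
class AdductTable:
    """Positive-mode adduct mass offsets relative to [M+H]+.

    ``multimer`` enables [2M+H]+ detection, which requires solving for the
    neutral mass M from the candidate primary.
    """

    offsets: dict[str, float] = field(
        default_factory=lambda: {
            "[M+H]+": 0.0,
            "[M+Na]+": 21.98194,
            "[M+K]+": 37.95588,
            "[M+H-H2O]+": -18.01056,
        }
    )
    multimer: bool = True

    def satellite_offsets(self) -> dict[str, float]:
        return {k: v for k, v in self.offsets.items() if v != 0.0}


@dataclass
class FeatureCluster:
    """A group of redundant features representing one molecule."""

    members: list[str]
    primary: str | None = None
    roles: dict[str, str] = field(default_factory=dict)
    identity: str = ""
    conflict: bool = False


def _spearman(x: np.ndarray, y: np.ndarray, min_overlap: int) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_overlap:
        return np.nan
    rho = stats.spearmanr(x[ok], y[ok]).statistic
    return float(rho)


def cluster_features(
    table: FeatureTable,
    rt_tol: float = 0.25,
    rho_min: float = 0.80,
    min_overlap: int = 20,
) -> list[FeatureCluster]:
    """Group features by co-elution and intensity correlation.

    An edge joins features i and j iff |RT_i - RT_j| <= rt_tol AND the
    pairwise-complete Spearman correlation of their study-sample
    intensities exceeds rho_min over at least ``min_overlap`` samples.
    Clusters are the connected components of this graph (singletons
    allowed). Order of input features does not affect the partition, and
    the criterion is invariant to monotone intensity transforms.
    """
    bio = table.biological()
    feats = list(table.features.index)
    rt = table.features["rt"].to_numpy(float)
    order = np.argsort(rt, kind="stable")

    g = nx.Graph()
    g.add_nodes_from(feats)
    vals = {f: bio[f].to_numpy(float) for f in feats}
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1 :]:
            if rt[j] - rt[i] > rt_tol:
                break
            rho = _spearman(vals[feats[i]], vals[feats[j]], min_overlap)
            if np.isnan(rho):
                logger.info(
                    "pair (%s, %s): overlap below %d samples, no edge",
                    feats[i], feats[j], min_overlap,
                )
                continue
            if rho > rho_min:
                g.add_edge(feats[i], feats[j])

    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=feats.index)
        clusters.append(FeatureCluster(members=members))
    clusters.sort(key=lambda c: feats.index(c.members[0]))
    return clusters


def assign_primary(
    cluster: FeatureCluster,
    table: FeatureTable,
    adducts: AdductTable | None = None,
    mz_tol_ppm: float = 10.0,
) -> FeatureCluster:
    """Choose the cluster's primary ion and label adduct satellites.

    If some member's m/z plus a tabulated offset (or the [2M+H]+ relation)
    matches another member within ``mz_tol_ppm``, the inferred [M+H]+
    member becomes primary and matched members get adduct labels. When
    several interpretations are possible, the one explaining the most
    members wins. Otherwise the member with highest mean intensity is
    primary; remaining members are labeled unassigned satellites.
    """
    adducts = adducts or AdductTable()
    mz = table.features["mz"]
    bio = table.biological()

    if len(cluster.members) == 1:
        only = cluster.members[0]
        cluster.primary = only
        cluster.roles = {only: "primary"}
        return cluster

    mean_int = {f: float(np.nanmean(bio[f].to_numpy(float))) for f in cluster.members}

    best: tuple[int, float, str, dict[str, str]] | None = None
    for cand in cluster.members:
        p = float(mz[cand])
        labels: dict[str, str] = {}
        for other in cluster.members:
            if other == cand:
                continue
            o = float(mz[other])
            for name, off in adducts.satellite_offsets().items():
                if abs(o - (p + off)) / p * 1e6 <= mz_tol_ppm:
                    labels[other] = f"adduct:{name}"
                    break
            else:
                if adducts.multimer:
                    multimer_mz = 2.0 * p - PROTON_MASS  # 2M+H from M+H
                    if abs(o - multimer_mz) / multimer_mz * 1e6 <= mz_tol_ppm:
                        labels[other] = "adduct:[2M+H]+"
        if labels and (best is None or (len(labels), mean_int[cand]) > (best[0], best[1])):
            best = (len(labels), mean_int[cand], cand, labels)

    if best is not None:
        n_explained, _, primary, labels = best
        if n_explained < len(cluster.members) - 1:
            logger.info(
                "cluster %s: adduct interpretation explains %d of %d satellites",
                primary, n_explained, len(cluster.members) - 1,
            )
        cluster.primary = primary
        cluster.roles = {primary: "primary"}
        for m in cluster.members:
            if m != primary:
                cluster.roles[m] = labels.get(m, "unassigned-satellite")
    else:
        primary = max(cluster.members, key=lambda f: (mean_int[f], f))
        cluster.primary = primary
        cluster.roles = {m: ("primary" if m == primary else "unassigned-satellite") for m in cluster.members}
    return cluster


def propagate_identity(
    clusters: list[FeatureCluster], table: FeatureTable
) -> list[FeatureCluster]:
    """Assign the identity of a co-clustered known metabolite to unknowns.

    A cluster containing exactly one distinct known identity donates it to
    every unknown member (annotation Category 2 evidence); clusters with
    conflicting known identities are flagged and left unassigned.
    """
    identity = table.features["identity"].fillna("")
    for cluster in clusters:
        known = {identity[m] for m in cluster.members if identity[m]}
        if len(known) == 1:
            cluster.identity = known.pop()
        elif len(known) > 1:
            cluster.conflict = True
            logger.warning(
                "cluster with primary %s has conflicting identities %s",
                cluster.primary, sorted(known),
            )
    return clusters


def cluster_report(clusters: list[FeatureCluster]) -> pd.DataFrame:
    """Flat per-feature report (feature, cluster id, role, identity)."""
    rows = []
    for cid, cluster in enumerate(clusters):
        for m in cluster.members:
            rows.append(
                {
                    "feature": m,
                    "cluster": cid,
                    "role": cluster.roles.get(m, ""),
                    "identity": cluster.identity,
                    "conflict": cluster.conflict,
                }
            )
    return pd.DataFrame(rows)
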