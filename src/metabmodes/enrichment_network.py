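"""Cross-dataset mode-overlap enrichment, network assembly, metaclusters.

Each dataset's k-medoids partition assigns every feature to one mode.  For
every pair of modes from two different datasets we ask whether they share
more features than random assignment would give: the null is generated by
uniformly permuting one partition's label vector over the common feature
universe (mode sizes preserved) and recounting all shared-member counts,
with p = (1 + #{draws with shared >= observed}) / (1 + n_perm).

Modes with at least ``min_mode_size`` members become network nodes; every
cross-dataset pair with p < alpha becomes an edge.  A *metacluster* is a
connected component rooted in a culture-dataset mode; a compound belongs
to the metacluster when it sits in the root mode and in at least two of
the component's environmental modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .feature_tables import ValidationError
from .pattern_analysis import ModePartition

__all__ = ["EnrichmentResult", "Metacluster", "observed_shared",
           "permutation_enrichment", "build_network", "assign_metaclusters",
           "network_to_edge_table"]


def _common_universe(pa: ModePartition, pb: ModePartition) -> pd.Index:
    ia, ib = pa.labels.index, pb.labels.index
    sym = ia.symmetric_difference(ib)
    if len(sym):
        raise ValidationError(
            f"partitions cover different feature universes; symmetric "
            f"difference: {sym.tolist()[:20]}{'...' if len(sym) > 20 else ''}")
    return ia


def observed_shared(pa: ModePartition, pb: ModePartition) -> pd.DataFrame:
    """Count matrix of shared features over mode pairs (modes_a × modes_b).

    Entries sum to the universe size; row sums are the mode sizes of
    ``pa`` and column sums those of ``pb``.
    """
    universe = _common_universe(pa, pb)
    return pd.crosstab(pa.labels.loc[universe], pb.labels.loc[universe])


@dataclass
class EnrichmentResult:
    """Observed shared counts and permutation p-values for one dataset pair."""

    dataset_a: str
    dataset_b: str
    observed: pd.DataFrame            # modes_a x modes_b
    p_values: pd.DataFrame            # same shape
    n_perm: int
    seed: int | None

    def to_edges(self) -> pd.DataFrame:
        rows = []
        for ma in self.observed.index:
            for mb in self.observed.columns:
                rows.append({
                    "dataset_a": self.dataset_a, "mode_a": ma,
                    "dataset_b": self.dataset_b, "mode_b": mb,
                    "shared": int(self.observed.loc[ma, mb]),
                    "p_value": float(self.p_values.loc[ma, mb]),
                })
        return pd.DataFrame(rows)


def permutation_enrichment(pa: ModePartition, pb: ModePartition,
                           n_perm: int = 1000, seed: int | None = 0,
                           exclude_labels: tuple[str, ...] = (),
                           ) -> EnrichmentResult:
    """Monte Carlo enrichment of shared members for every mode pair.

    The second partition's label vector is permuted uniformly over the
    universe each draw (the null distribution of pairwise overlap is the
    same whichever side is permuted).  ``exclude_labels`` drops features
    carrying those labels in either partition from the universe (used to
    leave the ``not_observed`` pseudo-mode out of the test).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    universe = _common_universe(pa, pb)
    la = pa.labels.loc[universe]
    lb = pb.labels.loc[universe]
    if exclude_labels:
        keep = ~(la.isin(exclude_labels) | lb.isin(exclude_labels))
        la, lb = la[keep], lb[keep]
    ca, mode_a = pd.factorize(la, sort=True)
    cb, mode_b = pd.factorize(lb, sort=True)
    A, B = len(mode_a), len(mode_b)
    obs = np.bincount(ca * B + cb, minlength=A * B)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(A * B, dtype=np.int64)
    cb_work = cb.copy()
    for _ in range(n_perm):
        rng.shuffle(cb_work)
        counts = np.bincount(ca * B + cb_work, minlength=A * B)
        exceed += counts >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return EnrichmentResult(
        dataset_a=pa.dataset_id, dataset_b=pb.dataset_id,
        observed=pd.DataFrame(obs.reshape(A, B), index=mode_a, columns=mode_b),
        p_values=pd.DataFrame(p.reshape(A, B), index=mode_a, columns=mode_b),
        n_perm=n_perm, seed=seed)


def build_network(partitions: list[ModePartition], alpha: float = 0.05,
                  min_mode_size: int = 10, n_perm: int = 1000,
                  seed: int | None = 0,
                  include_not_observed: bool = True) -> nx.Graph:
    """Enrichment network over all pairwise dataset combinations.

    Nodes are (dataset_id, mode) tuples for modes of at least
    ``min_mode_size`` members (pseudo-modes included); edges join
    cross-dataset mode pairs with p < alpha.  Edge attributes carry the
    shared count and p-value; node attributes the dataset, mode and size.
    """
    if len(partitions) < 2:
        raise ValidationError("need at least two partitions")
    ids = [p.dataset_id for p in partitions]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate dataset ids: {ids}")
    exclude = () if include_not_observed else ("not_observed",)

    g = nx.Graph()
    for part in partitions:
        for mode, size in part.mode_sizes().items():
            if size >= min_mode_size and mode not in exclude:
                g.add_node((part.dataset_id, mode), dataset=part.dataset_id,
                           mode=mode, size=int(size))
    rng = np.random.default_rng(seed)
    for i in range(len(partitions)):
        for j in range(i + 1, len(partitions)):
            res = permutation_enrichment(
                partitions[i], partitions[j], n_perm=n_perm,
                seed=int(rng.integers(2 ** 31)), exclude_labels=exclude)
            for ma in res.observed.index:
                for mb in res.observed.columns:
                    na, nb = (ids[i], ma), (ids[j], mb)
                    if na in g and nb in g and res.p_values.loc[ma, mb] < alpha:
                        g.add_edge(na, nb,
                                   shared=int(res.observed.loc[ma, mb]),
                                   p_value=float(res.p_values.loc[ma, mb]))
    return g


@dataclass
class Metacluster:
    """A rooted connected component of the enrichment network."""

    name: str
    root: tuple[str, str]             # (culture dataset, mode)
    modes: list[tuple[str, str]]      # all member modes of the component
    compounds: list[str]


def assign_metaclusters(network: nx.Graph, partitions: list[ModePartition],
                        culture_dataset_id: str,
                        ) -> tuple[list[Metacluster], list[list[tuple[str, str]]]]:
    """Metaclusters from rooted connected components.

    A component with at least one culture-dataset mode yields one
    metacluster per culture mode (its root).  A compound is a member iff
    it belongs to the root mode *and* to at least two environmental (non-
    culture) modes of the component.  Components without a culture mode
    come back separately as unrooted.
    """
    by_id = {p.dataset_id: p for p in partitions}
    if culture_dataset_id not in by_id:
        raise ValidationError(f"unknown culture dataset {culture_dataset_id!r}")
    culture = by_id[culture_dataset_id]
    metaclusters: list[Metacluster] = []
    unrooted: list[list[tuple[str, str]]] = []
    for comp in nx.connected_components(network):
        comp = sorted(comp)
        roots = [n for n in comp if n[0] == culture_dataset_id]
        env_modes = [n for n in comp if n[0] != culture_dataset_id]
        if not roots:
            unrooted.append(comp)
            continue
        for root in roots:
            members = []
            root_members = set(culture.members(root[1]))
            for fid in sorted(root_members):
                hits = sum(1 for (ds, mode) in env_modes
                           if by_id[ds].labels.get(fid) == mode)
                if hits >= 2:
                    members.append(fid)
            metaclusters.append(Metacluster(
                name=f"{root[0]}:{root[1]}", root=root, modes=comp,
                compounds=members))
    return metaclusters, unrooted


def network_to_edge_table(network: nx.Graph) -> pd.DataFrame:
    """Flatten the network to an edge-list table for export."""
    rows = [{"dataset_a": a[0], "mode_a": a[1], "dataset_b": b[0],
             "mode_b": b[1], "shared": d.get("shared"),
             "p_value": d.get("p_value")}
            for a, b, d in network.edges(data=True)]
    return pd.DataFrame(rows, columns=["dataset_a", "mode_a", "dataset_b",
                                       "mode_b", "shared", "p_value"])
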