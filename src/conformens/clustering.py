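"""Trajectory subsampling and greedy RMSD-based conformational clustering.

The clustering is the neighbour-counting algorithm of Daura et al.:
repeatedly take the conformer with the most neighbours within an RMSD
cutoff as a cluster centre, assign centre plus neighbours to a cluster,
remove them, and iterate until no frames remain.  Neighbour counts include
the frame itself, so an isolated frame forms a singleton cluster and every
frame ends in exactly one cluster.  Ties on neighbour count are broken by
lowest frame index, which makes runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import pairwise_rmsd, rama_segments, classify_rama, \
    backbone_torsions
from .hbonds import hbond_populations, PopulationTable
from .model import Ensemble, StructureError

__all__ = [
    "Cluster",
    "ClusterSet",
    "subsample",
    "daura_cluster",
    "daura_partition",
    "cluster_report",
]


def subsample(ensemble: Ensemble, spacing_ps: float) -> Ensemble:
    """Keep frames at times k*spacing (k = 1, 2, ...); t = 0 is excluded.

    ``spacing_ps`` must be a positive multiple of the trajectory's saving
    interval, otherwise the requested grid would fall between saved frames
    and an error is raised.
    """
    if spacing_ps <= 0:
        raise ValueError("spacing must be positive")
    times = ensemble.times
    if len(times) > 1:
        dt = float(np.min(np.diff(times)))
        ratio = spacing_ps / dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"spacing {spacing_ps} ps is not a positive multiple of the "
                f"saving interval {dt} ps")
    k = times / spacing_ps
    keep = np.nonzero((times > 0) & (np.abs(k - np.round(k)) < 1e-9))[0]
    if keep.size == 0:
        raise ValueError("subsampling removed every frame")
    return ensemble.subset_frames(keep.tolist())


@dataclass
class Cluster:
    centre: int                  # frame index of the cluster centre
    members: np.ndarray          # sorted frame indices, centre included
    fraction: float              # members / total frames
    source_histogram: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return int(self.members.size)


@dataclass
class ClusterSet:
    """Partition of an ensemble into clusters, largest first."""

    clusters: list[Cluster]
    n_frames: int

    def labels(self) -> np.ndarray:
        """Per-frame cluster index (0-based, by decreasing cluster size)."""
        lab = np.full(self.n_frames, -1, dtype=int)
        for ci, cl in enumerate(self.clusters):
            lab[cl.members] = ci
        return lab

    def validate(self) -> None:
        seen = np.concatenate([c.members for c in self.clusters]) \
            if self.clusters else np.array([], dtype=int)
        if seen.size != self.n_frames or \
                np.unique(seen).size != self.n_frames:
            raise StructureError("cluster memberships do not partition "
                                 "the frame set")
        sizes = [c.size for c in self.clusters]
        if sizes != sorted(sizes, reverse=True):
            raise StructureError("clusters are not ordered by size")
        for c in self.clusters:
            if c.centre not in c.members:
                raise StructureError("cluster centre not among members")


def daura_partition(rmsd_matrix: np.ndarray, cutoff: float
                    ) -> list[tuple[int, np.ndarray]]:
    """Core greedy loop on a precomputed RMSD matrix.

    Returns (centre, members) in discovery order.  Neighbourhoods use
    ``rmsd <= cutoff`` and include the frame itself.
    """
    n = rmsd_matrix.shape[0]
    adjacency = rmsd_matrix <= cutoff
    np.fill_diagonal(adjacency, True)
    unassigned = np.ones(n, dtype=bool)
    out: list[tuple[int, np.ndarray]] = []
    while unassigned.any():
        counts = (adjacency & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest tied index
        members = np.nonzero(adjacency[centre] & unassigned)[0]
        out.append((centre, members))
        unassigned[members] = False
    return out


def daura_cluster(
    ensemble: Ensemble,
    selection: str,
    cutoff: float,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterSet:
    """Daura clustering of an ensemble on a fitted-atom selection.

    ``selection`` names the atoms used both for superposition and for the
    RMSD (e.g. ``"resseq 40-48 and name N,CA,C"``); ``cutoff`` is the RMSD
    threshold in nm.  A precomputed symmetric RMSD matrix may be passed to
    avoid recomputation.  Clusters are numbered by decreasing size.
    """
    if ensemble.n_frames == 0:
        raise StructureError("empty ensemble")
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd(ensemble, selection)
    if rmsd_matrix.shape != (ensemble.n_frames, ensemble.n_frames):
        raise ValueError("rmsd_matrix shape does not match ensemble")
    raw = daura_partition(rmsd_matrix, cutoff)
    n = ensemble.n_frames
    clusters = []
    for centre, members in raw:
        hist: dict[str, float] = {}
        for i in members:
            lbl = ensemble.frame_labels[int(i)]
            hist[lbl] = hist.get(lbl, 0) + 1
        hist = {k: v / members.size for k, v in sorted(hist.items())}
        clusters.append(Cluster(centre=centre, members=np.sort(members),
                                fraction=members.size / n,
                                source_histogram=hist))
    # stable sort: by decreasing size, discovery order breaks ties
    clusters.sort(key=lambda c: -c.size)
    cs = ClusterSet(clusters, n_frames=n)
    cs.validate()
    return cs


def cluster_report(
    cs: ClusterSet,
    ensemble: Ensemble,
    chain_id: str | None = None,
    with_hbonds: bool = True,
    top_n_bonds: int = 10,
) -> dict:
    """Per-cluster summary: size, fraction, provenance, H bonds, basins.

    For each cluster: member count and fraction, centre frame index,
    source-trajectory histogram, the highest-population hydrogen bonds
    within the cluster, and the Ramachandran basin segments of the centre
    conformer (runs of >= 2 residues in the same basin).
    """
    if chain_id is None:
        chain_id = ensemble.frames[0].chain_ids[0]
    report: dict = {"n_frames": cs.n_frames, "n_clusters": len(cs.clusters),
                    "clusters": []}
    for ci, cl in enumerate(cs.clusters, start=1):
        entry: dict = {
            "cluster": ci,
            "size": cl.size,
            "fraction": cl.fraction,
            "centre_frame": int(cl.centre),
            "source_histogram": cl.source_histogram,
        }
        centre_model = ensemble.frames[cl.centre]
        tors = backbone_torsions(centre_model, chain_id)
        labels = classify_rama(tors)
        entry["centre_rama_segments"] = [
            {"basin": lab,
             "res_start": int(tors.res_seqs[i0]),
             "res_end": int(tors.res_seqs[i1])}
            for lab, i0, i1 in rama_segments(labels)
        ]
        if with_hbonds:
            pops = hbond_populations(ensemble, frame_indices=cl.members)
            entry["hbond_populations_percent"] = dict(
                (k, round(100.0 * v, 1))
                for k, v in pops.sorted_items()[:top_n_bonds])
        report["clusters"].append(entry)
    return report
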