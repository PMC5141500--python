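"""gromos (Daura) RMSD clustering and representative-structure selection.

Frames are compared by least-squares-fitted RMSD over a caller-supplied
atom selection (canonically: main-chain atoms of the TM helices, to keep
flexible loops from dominating).  Clustering follows the Daura
algorithm: repeatedly take the frame with the most neighbours within the
cutoff as a cluster centre, assign it and its neighbours to a cluster,
remove them, and continue until no frames remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .geometry import kabsch
from .structures import BWMap, Ensemble, Selection, select


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame cluster id, 1 = most populated
    centers: list[int]  # per-cluster Daura centre frame index (cluster order)
    representative: int | None  # frame index for cluster 1 (see below)
    cutoff: float
    atom_spec: Selection | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def populations(self) -> np.ndarray:
        return np.array(
            [int(np.sum(self.labels == c + 1)) for c in range(self.n_clusters)]
        )


def pairwise_rmsd_matrix(
    ensemble: Ensemble,
    atom_spec: Selection | None = None,
    bwmap: BWMap | None = None,
) -> np.ndarray:
    """Symmetric matrix of pairwise fitted RMSDs over the selection.

    Each pair of frames is superposed independently (pairwise fitting,
    matching the behaviour of trajectory-clustering tools), so entry
    (i, j) is the minimum attainable RMSD between the two frames.
    """
    if atom_spec is None:
        atom_spec = Selection(atom_names="main_chain")
    idx = select(ensemble.topology, atom_spec, bwmap)
    if idx.size < 3:
        raise ValidationError("selection resolves to fewer than 3 atoms")
    n = ensemble.n_frames
    X = ensemble.frames[:, idx, :].copy()
    X -= X.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", X, X)  # per-frame sum of squares
    m = idx.size
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # Kabsch RMSD from the covariance SVD (both sets pre-centred)
            C = X[i].T @ X[j]
            s = np.linalg.svd(C, compute_uv=False)
            if np.linalg.det(C) < 0:
                s[-1] = -s[-1]
            msd = max((sq[i] + sq[j] - 2.0 * s.sum()) / m, 0.0)
            out[i, j] = out[j, i] = np.sqrt(msd)
    return out


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Daura clustering of a pairwise-RMSD matrix at a fixed cutoff.

    Cluster ids are 1-based and ordered by descending population (ties:
    lower centre frame index).  Neighbour counts are recomputed over the
    remaining frames each round; ties on the count go to the lowest
    frame index.  The ``representative`` field is left unset here; use
    :func:`representative_structure`.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValidationError("matrix must be symmetric")
    if np.any(matrix < 0):
        raise ValidationError("matrix entries must be non-negative")
    n = matrix.shape[0]
    within = matrix <= cutoff
    remaining = np.ones(n, dtype=bool)
    clusters: list[tuple[int, np.ndarray]] = []  # (centre, member indices)
    while remaining.any():
        rem_idx = np.flatnonzero(remaining)
        counts = within[np.ix_(rem_idx, rem_idx)].sum(axis=1)
        centre = rem_idx[int(np.argmax(counts))]  # argmax takes lowest on ties
        members = rem_idx[within[centre, rem_idx]]
        clusters.append((int(centre), members))
        remaining[members] = False
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    labels = np.zeros(n, dtype=int)
    centers = []
    for cid, (centre, members) in enumerate(clusters, start=1):
        labels[members] = cid
        centers.append(centre)
    return ClusterResult(labels=labels, centers=centers, representative=None,
                         cutoff=float(cutoff))


def representative_structure(
    ensemble: Ensemble,
    result: ClusterResult,
    atom_spec: Selection | None = None,
    bwmap: BWMap | None = None,
) -> int:
    """Frame of the top cluster closest to the cluster's mean structure.

    All cluster-1 members are superposed onto the Daura centre frame
    over the selection; the mean of the superposed coordinates defines
    the cluster's average structure, and the member with the smallest
    RMSD to that average (tie: lowest frame index) is returned.
    """
    if atom_spec is None:
        atom_spec = result.atom_spec or Selection(atom_names="main_chain")
    members = result.members(1)
    if members.size == 0:
        raise ValidationError("cluster 1 is empty")
    idx = select(ensemble.topology, atom_spec, bwmap)
    centre = result.centers[0]
    ref = ensemble.frames[centre, idx, :]
    fitted = np.empty((members.size, idx.size, 3))
    for k, fi in enumerate(members):
        if fi == centre:
            fitted[k] = ref
        else:
            sup = kabsch(ensemble.frames[fi, idx, :], ref)
            fitted[k] = sup.apply(ensemble.frames[fi, idx, :])
    mean = fitted.mean(axis=0)
    rmsds = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=1))
    # lowest frame index wins ties (within numerical noise of the fit)
    best = int(members[int(np.flatnonzero(rmsds <= rmsds.min() + 1e-9)[0])])
    result.representative = best
    return best


def cluster_report_tsv(
    result: ClusterResult, matrix: np.ndarray, path
) -> None:
    """Per-frame cluster assignment with RMSD to the cluster's Daura centre."""
    lines = [f"# cutoff_A: {result.cutoff}", "frame_index\tcluster_id\trmsd_to_center"]
    for fi, cid in enumerate(result.labels):
        centre = result.centers[cid - 1]
        lines.append(f"{fi}\t{cid}\t{matrix[fi, centre]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
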