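"""Distance-distribution prediction from conformer ensembles.

Given an ensemble of conformers of a structural model with designated
spin-labeled residues, the predicted inter-label distance distribution is
obtained by (1) clustering the ensemble on backbone (C-alpha) RMSD with the
greedy gromos algorithm, (2) keeping clusters above a population threshold,
(3) broadening each kept cluster center's inter-site distance with an
isotropic Gaussian pseudo-label model that emulates the conformational
spread of the nitroxide tether, and (4) averaging the per-cluster
distributions with cluster-size weights, reporting a +/- weighted-standard-
deviation band clipped below at zero.

All coordinates are handled in nm; PDB files (angstrom) are converted on
ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .distributions import DistanceDistribution, DistanceGrid

__all__ = [
    "ConformerEnsemble",
    "ClusterSet",
    "kabsch_rmsd",
    "pairwise_rmsd",
    "gromos_cluster",
    "site_distance_samples",
    "samples_to_distribution",
    "cluster_weighted_average",
    "predict_distance_distribution",
    "read_ensemble_pdb",
    "write_ensemble_pdb",
]

#: Paper-style population filter: clusters must exceed this fraction of all
#: frames (50 of 1000) to contribute to the averaged prediction.
MIN_CLUSTER_FRACTION = 0.05

#: Default per-site, per-axis Gaussian spread of the effective label
#: position (nm), standing in for the rotamer cloud of the nitroxide tether.
DEFAULT_LABEL_SIGMA = 0.25


@dataclass
class ConformerEnsemble:
    """Per-frame backbone and labeled-site coordinates (nm).

    ``backbone``: (n_frames, n_atoms, 3) reference atoms (C-alpha) used for
    RMSD; ``sites``: mapping site label -> (n_frames, 3) effective label
    attachment coordinates (C-beta, falling back to C-alpha).
    """

    backbone: np.ndarray
    sites: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        bb = np.asarray(self.backbone, dtype=float)
        if bb.ndim != 3 or bb.shape[2] != 3 or bb.shape[0] < 1:
            raise ValueError("backbone must have shape (n_frames, n_atoms, 3)")
        self.backbone = bb
        self.sites = {
            k: np.asarray(v, dtype=float).reshape(bb.shape[0], 3)
            for k, v in self.sites.items()
        }

    @property
    def n_frames(self) -> int:
        return self.backbone.shape[0]

    @property
    def site_labels(self) -> list[str]:
        return list(self.sites)

    def subset(self, frame_indices) -> "ConformerEnsemble":
        idx = np.asarray(frame_indices, dtype=int)
        return ConformerEnsemble(
            self.backbone[idx], {k: v[idx] for k, v in self.sites.items()}
        )


@dataclass
class ClusterSet:
    """Result of gromos clustering: frame assignments, sizes, centers."""

    assignments: np.ndarray  # frame -> cluster id (0 = largest)
    sizes: np.ndarray        # members per cluster id
    centers: np.ndarray      # frame index of each cluster center
    kept: np.ndarray         # cluster ids passing the population filter

    @property
    def n_clusters(self) -> int:
        return self.sizes.size

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.assignments == cluster_id)[0]


def kabsch_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray, selection=None
) -> float:
    """Minimum RMSD between two conformations after optimal superposition.

    Uses the SVD form of the Kabsch algorithm with the determinant correction
    that restricts the alignment to proper rotations (no reflections).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if selection is not None:
        sel = np.asarray(selection)
        a, b = a[sel], b[sel]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n_atoms, 3)")
    if a.shape[0] < 3:
        raise ValueError("need >= 3 atoms for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if np.linalg.matrix_rank(ac, tol=1e-10) < 2 and np.linalg.matrix_rank(bc, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    H = ac.T @ bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # residual-based RMSD avoids the cancellation of the singular-value form
    diff = ac @ R.T - bc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def pairwise_rmsd(ensemble: ConformerEnsemble) -> np.ndarray:
    n = ensemble.n_frames
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kabsch_rmsd(ensemble.backbone[i], ensemble.backbone[j])
    return D


def gromos_cluster(
    ensemble: ConformerEnsemble,
    cutoff: float = 0.15,
    min_fraction: float = MIN_CLUSTER_FRACTION,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterSet:
    """Greedy gromos clustering on backbone RMSD.

    Repeatedly the frame with the most neighbors within ``cutoff`` (ties
    broken toward the lowest frame index) becomes a cluster center; it and
    its neighbors form a cluster and are removed.  Clusters whose size
    exceeds ``min_fraction`` of the frame count are marked as kept.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    D = pairwise_rmsd(ensemble) if rmsd_matrix is None else rmsd_matrix
    n = ensemble.n_frames
    neighbor = D <= cutoff  # includes self
    active = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    sizes, centers = [], []
    cid = 0
    while active.any():
        counts = (neighbor & active[None, :]).sum(axis=1)
        counts[~active] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbor[center] & active)[0]
        assignments[members] = cid
        sizes.append(members.size)
        centers.append(center)
        active[members] = False
        cid += 1
    sizes = np.asarray(sizes)
    centers = np.asarray(centers)
    kept = np.nonzero(sizes > min_fraction * n)[0]
    return ClusterSet(assignments, sizes, centers, kept)


def site_distance_samples(
    ensemble: ConformerEnsemble,
    site_i: str,
    site_j: str,
    label_sigma: float = DEFAULT_LABEL_SIGMA,
    n_draws: int = 200,
    seed: int | None = None,
) -> np.ndarray:
    """Inter-label distance samples with pseudo-label broadening.

    For every frame the reference inter-site distance (C-beta to C-beta) is
    broadened by drawing ``n_draws`` pairs of effective label positions with
    independent Gaussian displacement (sigma per site per axis); with
    ``label_sigma=0`` the frame distances are returned unchanged.
    """
    for s in (site_i, site_j):
        if s not in ensemble.sites:
            raise KeyError(f"site {s!r} not in ensemble (has {ensemble.site_labels})")
    if label_sigma < 0:
        raise ValueError("label_sigma must be >= 0")
    xi = ensemble.sites[site_i]
    xj = ensemble.sites[site_j]
    if label_sigma == 0:
        return np.linalg.norm(xi - xj, axis=1)
    rng = np.random.default_rng(seed)
    pi = xi[:, None, :] + rng.normal(0.0, label_sigma, size=(xi.shape[0], n_draws, 3))
    pj = xj[:, None, :] + rng.normal(0.0, label_sigma, size=(xj.shape[0], n_draws, 3))
    return np.linalg.norm(pi - pj, axis=2).ravel()


def _silverman_bandwidth(samples: np.ndarray) -> float:
    n = samples.size
    sd = np.std(samples)
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale == 0:
        scale = 0.05  # degenerate point cloud: fall back to a narrow kernel
    return 0.9 * scale * n ** (-0.2)


def samples_to_distribution(
    samples: np.ndarray,
    grid: DistanceGrid,
    bandwidth: float | None = None,
) -> DistanceDistribution:
    """Gaussian kernel density estimate of distance samples on a grid.

    ``bandwidth=None`` applies Silverman's rule to the pooled samples.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 1:
        raise ValueError("need at least one sample")
    if bandwidth is None:
        bandwidth = _silverman_bandwidth(samples)
    if np.all((samples < grid.r[0] - 3 * bandwidth) | (samples > grid.r[-1] + 3 * bandwidth)):
        raise ValueError("all samples lie outside the distance grid")
    z = (grid.r[:, None] - samples[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1)
    return DistanceDistribution(grid, density)


def cluster_weighted_average(
    per_cluster: list[DistanceDistribution],
    sizes,
) -> tuple[DistanceDistribution, tuple[np.ndarray, np.ndarray]]:
    """Cluster-size-weighted mean distribution and +/- weighted-std band.

    mean = sum_i w_i P_i with w_i = size_i / sum size; the band is
    mean +/- sqrt(sum_i w_i (P_i - mean)^2) pointwise, with the lower
    boundary clipped at 0.
    """
    if len(per_cluster) < 1:
        raise ValueError(
            "no cluster passed the population filter; lower the threshold "
            "(min_fraction) or supply a larger ensemble"
        )
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size != len(per_cluster) or np.any(sizes <= 0):
        raise ValueError("sizes must be positive and match per_cluster")
    grid = per_cluster[0].grid
    stack = np.asarray([p.density for p in per_cluster])
    w = sizes / sizes.sum()
    mean = w @ stack
    std = np.sqrt(w @ (stack - mean) ** 2)
    low = np.clip(mean - std, 0.0, None)
    high = mean + std
    return DistanceDistribution(grid, mean), (low, high)


def predict_distance_distribution(
    ensemble: ConformerEnsemble,
    site_i: str,
    site_j: str,
    grid: DistanceGrid,
    cutoff: float = 0.15,
    label_sigma: float = DEFAULT_LABEL_SIGMA,
    n_draws: int = 200,
    seed: int | None = None,
    min_fraction: float = MIN_CLUSTER_FRACTION,
) -> tuple[DistanceDistribution, tuple[np.ndarray, np.ndarray], ClusterSet]:
    """Full prediction chain: cluster, per-center broadening, weighted mean."""
    clusters = gromos_cluster(ensemble, cutoff, min_fraction)
    if clusters.kept.size == 0:
        raise ValueError(
            f"no cluster exceeds {min_fraction:.0%} of {ensemble.n_frames} frames; "
            "lower min_fraction"
        )
    dists, sizes = [], []
    for cid in clusters.kept:
        center = ensemble.subset([clusters.centers[cid]])
        samples = site_distance_samples(
            center, site_i, site_j, label_sigma, n_draws, seed,
        )
        dists.append(samples_to_distribution(samples, grid))
        sizes.append(clusters.sizes[cid])
    mean, band = cluster_weighted_average(dists, sizes)
    return mean, band, clusters


# --------------------------------------------------------------------------
# Multi-model PDB I/O (coordinates converted angstrom <-> nm).

def read_ensemble_pdb(path, site_residues: list[int]) -> ConformerEnsemble:
    """Read a multi-model PDB into an ensemble.

    Backbone reference atoms are all C-alpha; for each residue number in
    ``site_residues`` the C-beta coordinate is taken as the label attachment
    point (falling back to C-alpha for glycine or incomplete residues).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ensemble", str(path))
    backbone_frames: list[np.ndarray] = []
    site_frames: dict[str, list[np.ndarray]] = {str(r): [] for r in site_residues}
    for model in structure:
        cas, site_coords = [], {}
        for chain in model:
            for res in chain:
                atoms = {a.get_name(): a.get_coord() for a in res}
                if "CA" not in atoms:
                    continue
                cas.append(atoms["CA"])
                resnum = res.get_id()[1]
                if resnum in site_residues:
                    site_coords[str(resnum)] = atoms.get("CB", atoms["CA"])
        missing = [s for s in site_frames if s not in site_coords]
        if missing:
            raise ValueError(f"model missing labeled residues {missing}")
        backbone_frames.append(np.asarray(cas))
        for s in site_frames:
            site_frames[s].append(site_coords[s])
    if not backbone_frames:
        raise ValueError(f"no models found in {path}")
    backbone = np.asarray(backbone_frames) * 0.1  # A -> nm
    sites = {s: np.asarray(v) * 0.1 for s, v in site_frames.items()}
    return ConformerEnsemble(backbone, sites)


def write_ensemble_pdb(path, ensemble: ConformerEnsemble) -> None:
    """Write backbone C-alpha traces as a poly-alanine multi-model PDB."""
    lines = []
    for m in range(ensemble.n_frames):
        lines.append(f"MODEL     {m + 1:4d}")
        serial = 1
        for i, (x, y, z) in enumerate(ensemble.backbone[m] * 10.0):  # nm -> A
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        for label, coords in ensemble.sites.items():
            x, y, z = coords[m] * 10.0
            resnum = int(label) if label.isdigit() else serial
            lines.append(
                f"ATOM  {serial:5d}  CB  ALA A{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
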