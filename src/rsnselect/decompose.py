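"""Spatial ICA decomposition, cross-subject component clustering, and ROI
derivation from an average network map.

Spatial ICA treats voxels as samples and time points as mixture channels:
after PCA reduction, a fixed-point (FastICA, logcosh) rotation maximizes the
spatial non-Gaussianity of the component maps.  Each component is a z-scored
spatial map paired with a time course; their signs are jointly indeterminate,
which all downstream selection logic must (and does) tolerate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import BoldRun

DEFAULT_N_COMPONENTS = 30
ICA_MAX_ITER = 200
ICA_TOL = 1e-4


@dataclass
class IcaDecomposition:
    """Per-subject spatial ICA result: z-scored maps and paired courses."""

    maps: np.ndarray          # (n_components, x, y, z)
    courses: np.ndarray       # (t, n_components), column mean 0
    mask: np.ndarray
    tr_seconds: float
    n_components: int
    subject_id: str = ""
    seed: int = 0
    converged: bool = True

    def map_vectors(self) -> np.ndarray:
        """(n_components, n_in_mask) matrix of flattened in-mask maps."""
        return self.maps[:, self.mask]


def spatial_ica(run: BoldRun, n_components=DEFAULT_N_COMPONENTS, seed=0,
                max_iter=ICA_MAX_ITER, tol=ICA_TOL) -> IcaDecomposition:
    """Decompose a run into spatially independent components.

    Dimensionality is reduced to ``n_components`` principal components and a
    fixed-point logcosh rotation applied; maps are z-scored in-mask with the
    scale folded into the paired course, so map x course products are
    preserved.  Non-convergence within the iteration cap is reported through
    the ``converged`` flag on the (still usable) partial result.
    """
    X = run.in_mask()                                   # (t, v)
    if n_components >= run.n_volumes:
        raise ValueError("n_components must be < n_volumes")
    X = X - X.mean(axis=0)
    ica = FastICA(n_components=n_components, fun="logcosh", max_iter=max_iter,
                  tol=tol, whiten="unit-variance", random_state=seed)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            S = ica.fit_transform(X.T)                  # (v, n_components)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(n_components=n_components, fun="logcosh",
                              max_iter=max_iter, tol=tol,
                              whiten="unit-variance", random_state=seed)
                S = ica.fit_transform(X.T)
    A = ica.mixing_                                     # (t, n_components)

    mu = S.mean(axis=0)
    sd = S.std(axis=0)
    if (sd == 0).any():
        raise ValueError("degenerate (constant) component map")
    S_z = (S - mu) / sd
    courses = A * sd
    courses = courses - courses.mean(axis=0)

    maps = np.zeros((n_components,) + run.grid_shape)
    maps[:, run.mask] = S_z.T
    return IcaDecomposition(maps=maps, courses=courses, mask=run.mask,
                            tr_seconds=run.tr_seconds,
                            n_components=n_components, seed=seed,
                            converged=converged)


@dataclass
class ComponentCluster:
    """A cross-subject cluster of spatially similar components."""

    members: list                # [(subject_id, component_index), ...]
    mean_map: np.ndarray         # voxelwise average of sign-aligned maps
    member_signs: list = field(default_factory=list)
    label: str = ""


def cluster_components(decomps, n_clusters=None):
    """Group components across subjects into clusters of spatially similar
    maps (average linkage on |spatial correlation|), at most one component
    per subject per cluster.

    Greedy agglomeration merges the cluster pair with the highest average
    |r| whose subject sets are disjoint, until ``n_clusters`` clusters remain
    or no admissible merge exists.
    """
    if len(decomps) < 2:
        raise ValueError("need decompositions from at least 2 subjects")
    n_comp = decomps[0].n_components
    if n_clusters is None:
        n_clusters = n_comp
    if n_clusters > n_comp:
        raise ValueError("n_clusters cannot exceed components per subject")

    items = []
    for si, d in enumerate(decomps):
        V = d.map_vectors()
        V = (V - V.mean(axis=1, keepdims=True))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        for c in range(d.n_components):
            items.append((si, c, V[c]))
    n = len(items)
    M = np.stack([it[2] for it in items])
    C = M @ M.T                                   # signed correlations
    sim = np.abs(C)
    np.fill_diagonal(sim, 0.0)

    subj_bits = np.array([np.uint64(1) << np.uint64(it[0]) for it in items])
    active = np.ones(n, dtype=bool)
    sums = sim.copy()                             # sum of pairwise sims
    sizes = np.ones(n, dtype=int)
    members = [[i] for i in range(n)]
    n_active = n
    while n_active > n_clusters:
        avg = sums / np.outer(sizes, sizes)
        ok = active[:, None] & active[None, :]
        ok &= (subj_bits[:, None] & subj_bits[None, :]) == 0
        avg = np.where(ok, avg, -np.inf)
        iu = np.triu_indices(n, 1)
        flat = avg[iu]
        best = np.argmax(flat)
        if not np.isfinite(flat[best]):
            break
        a, b = iu[0][best], iu[1][best]
        members[a] += members[b]
        sums[a] += sums[b]
        sums[:, a] += sums[:, b]
        sums[a, a] = 0.0
        sizes[a] += sizes[b]
        subj_bits[a] |= subj_bits[b]
        active[b] = False
        n_active -= 1

    clusters = []
    for ci in np.flatnonzero(active):
        idx = members[ci]
        # seed = member with the largest total similarity to the others
        sub = sim[np.ix_(idx, idx)]
        seed_pos = int(np.argmax(sub.sum(axis=1))) if len(idx) > 1 else 0
        seed_item = idx[seed_pos]
        signs = [1.0 if C[seed_item, j] >= 0 else -1.0 for j in idx]
        stacked = np.stack([
            s * decomps[items[j][0]].maps[items[j][1]]
            for j, s in zip(idx, signs)
        ])
        mem = sorted(
            zip((decomps[items[j][0]].subject_id or str(items[j][0])
                 for j in idx),
                (items[j][1] for j in idx), signs))
        clusters.append(ComponentCluster(
            members=[(s, c) for s, c, _ in mem],
            member_signs=[g for _, _, g in mem],
            mean_map=stacked.mean(axis=0)))
    clusters.sort(key=lambda cl: (-len(cl.members), cl.members))
    return clusters


def match_cluster_to_map(clusters, reference_map, mask):
    """Index of the cluster whose mean map best matches a reference map
    (by |spatial correlation|); used to identify the network cluster on
    phantoms, replacing visual inspection."""
    ref = reference_map[mask].astype(float)
    ref = ref - ref.mean()
    ref /= np.linalg.norm(ref)
    best, best_r = -1, -1.0
    for i, cl in enumerate(clusters):
        v = cl.mean_map[mask]
        v = v - v.mean()
        nrm = np.linalg.norm(v)
        if nrm == 0:
            continue
        r = abs(float(ref @ (v / nrm)))
        if r > best_r:
            best, best_r = i, r
    return best, best_r


def best_match(decomp: IcaDecomposition, reference_map: np.ndarray):
    """(component index, |r|) of the component map best matching a
    reference 3D map."""
    ref = reference_map[decomp.mask].astype(float)
    ref = ref - ref.mean()
    ref /= np.linalg.norm(ref)
    V = decomp.map_vectors()
    V = V - V.mean(axis=1, keepdims=True)
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    r = V @ ref
    idx = int(np.argmax(np.abs(r)))
    return idx, float(abs(r[idx]))


@dataclass
class RoiSet:
    """Named target and anti-correlated voxel sets on one grid."""

    targets: dict               # name -> (k, 3) int voxel indices
    anti: dict                  # name -> (k, 3)
    source_map_id: str = ""
    voxel_mm: tuple = (3.0, 3.0, 3.0)

    def __post_init__(self):
        seen = set()
        for name, vox in {**self.targets, **self.anti}.items():
            vox = np.atleast_2d(np.asarray(vox, dtype=int))
            if vox.size == 0:
                raise ValueError(f"ROI {name!r} is empty")
            for ijk in map(tuple, vox):
                if ijk in seen:
                    raise ValueError(f"ROI {name!r} overlaps another ROI")
                seen.add(ijk)

    @property
    def names(self):
        return list(self.targets) + list(self.anti)

    def to_json(self, path=None) -> str:
        recs = []
        for polarity, group in (("target", self.targets),
                                ("anti", self.anti)):
            for name, vox in group.items():
                vox = np.atleast_2d(vox)
                center = vox.mean(axis=0) * np.asarray(self.voxel_mm)
                recs.append({"name": name, "polarity": polarity,
                             "center_mm": [round(float(c), 3) for c in center],
                             "voxel_ijk": vox.tolist()})
        text = json.dumps({"source_map_id": self.source_map_id,
                           "voxel_mm": list(self.voxel_mm),
                           "rois": recs}, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path):
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        obj = json.loads(text)
        targets, anti = {}, {}
        for rec in obj["rois"]:
            dest = targets if rec["polarity"] == "target" else anti
            dest[rec["name"]] = np.array(rec["voxel_ijk"], dtype=int)
        return cls(targets=targets, anti=anti,
                   source_map_id=obj.get("source_map_id", ""),
                   voxel_mm=tuple(obj.get("voxel_mm", (3.0, 3.0, 3.0))))


def derive_rois(mean_map, target_centers_mm, anti_centers_mm, cube_mm=10.0,
                map_threshold=1.0, voxel_mm=(3.0, 3.0, 3.0),
                mask=None) -> RoiSet:
    """Carve ROIs out of an average network map.

    Each ROI is the set of voxels whose centers fall inside the axis-aligned
    cube of side ``cube_mm`` around the given mm coordinate (half-open on the
    positive side) AND whose map value passes ``map_threshold`` (>= for
    targets, <= -threshold for anti ROIs).
    """
    target_centers_mm = np.atleast_2d(target_centers_mm)
    anti_centers_mm = np.atleast_2d(anti_centers_mm)
    if len(target_centers_mm) != 14 or len(anti_centers_mm) != 6:
        raise ValueError("need 14 target and 6 anti centers")
    if cube_mm <= max(voxel_mm):
        raise ValueError("cube_mm must exceed the voxel size")
    if mask is None:
        mask = np.ones(mean_map.shape, dtype=bool)

    def carve(center_mm, comparator):
        half = cube_mm / 2.0
        ranges = []
        for ax in range(3):
            vm = voxel_mm[ax]
            lo = int(np.ceil((center_mm[ax] - half) / vm))
            hi = int(np.ceil((center_mm[ax] + half) / vm))  # exclusive
            lo = max(lo, 0)
            hi = min(hi, mean_map.shape[ax])
            ranges.append(range(lo, hi))
        vox = [ijk for ijk in np.array(
            np.meshgrid(*ranges, indexing="ij")).reshape(3, -1).T
            if mask[tuple(ijk)] and comparator(mean_map[tuple(ijk)])]
        return np.array(vox, dtype=int)

    targets, anti, empty = {}, {}, []
    for i, c in enumerate(target_centers_mm):
        name = f"T{i + 1:02d}"
        vox = carve(c, lambda v: v >= map_threshold)
        if vox.size == 0:
            empty.append(name)
        else:
            targets[name] = vox
    for i, c in enumerate(anti_centers_mm):
        name = f"A{i + 1:02d}"
        vox = carve(c, lambda v: v <= -map_threshold)
        if vox.size == 0:
            empty.append(name)
        else:
            anti[name] = vox
    if empty:
        raise ValueError(
            "empty ROI(s) — center/threshold mismatch for: " + ", ".join(empty))
    return RoiSet(targets=targets, anti=anti, voxel_mm=tuple(voxel_mm))
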