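"""Ground-truth BOLD phantom generator.

Each phantom run is a linear mixture of six latent sources — a low-frequency
(0.01-0.05 Hz) "neuronal" network with bilateral blob topography and designated
anti-correlated regions (negative-weight blobs of the same source, so they are
genuinely anti-correlated with the network course), a second independent
low-frequency source on its own distinct blobs, a global source positive
everywhere, and three artifact classes (slow scanner drift, a motion-like
spike, a high-frequency physiological oscillation) — plus i.i.d. Gaussian
voxel noise.  Two cohort
conditions are supported: "patient" runs additionally couple the network time
course into designated extra regions, mimicking pathologically increased
connectivity outside the core network.

Everything is deterministic given the seed, and the latent structure is
retained in a :class:`GroundTruth` record so downstream stages can be tested
against known truth.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BoldRun, save_run

SOURCE_LABELS = ("network", "anti_network", "global", "drift", "spike", "physio")

#: Mixture amplitude per source, relative to unit-variance time courses and
#: unit-peak spatial maps.
AMPLITUDES = {
    "network": 1.0,
    "anti_network": 0.6,
    "global": 0.7,
    "drift": 1.5,
    "spike": 1.2,
    "physio": 0.8,
}

NETWORK_BAND_HZ = (0.01, 0.05)
GLOBAL_BAND_HZ = (0.005, 0.05)
PHYSIO_FREQ_HZ = 0.2
ANTI_WEIGHT_IN_NETWORK_MAP = 0.7
BLOB_RADIUS_VOX = 2.0
N_TARGET_BLOBS = 14  # bilateral: 7 mirrored pairs
N_ANTI_BLOBS = 6     # bilateral: 3 mirrored pairs
SITE_MARGIN = 4
SITE_SPACING = 5


@dataclass
class ComponentBank:
    """Latent spatial maps and temporal model descriptors for one phantom."""

    grid_shape: tuple
    spatial_maps: dict            # label -> 3D float array
    time_specs: dict              # label -> descriptor dict
    labels: tuple = SOURCE_LABELS
    target_centers: np.ndarray = None       # (14, 3) int voxel centers
    anti_centers: np.ndarray = None         # (6, 3) negative network blobs
    anti_source_centers: np.ndarray = None  # (6, 3) anti_network source blobs
    extra_centers: np.ndarray = None        # (n_extra, 3)
    voxel_mm: tuple = (3.0, 3.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if sorted(self.spatial_maps) != sorted(self.labels):
            raise ValueError("spatial_maps labels mismatch")
        if sum(l == "network" for l in self.labels) != 1:
            raise ValueError("exactly one network source required")
        if sum(l == "global" for l in self.labels) != 1:
            raise ValueError("exactly one global source required")
        if not (self.spatial_maps["global"] > 0).all():
            raise ValueError("global map must be strictly positive in-mask")

    @property
    def mask(self) -> np.ndarray:
        return np.ones(self.grid_shape, dtype=bool)

    def blob_mask(self, centers: np.ndarray) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        for c in np.atleast_2d(centers):
            m |= _sphere(self.grid_shape, c, BLOB_RADIUS_VOX)
        return m

    @property
    def network_mask(self) -> np.ndarray:
        return self.blob_mask(self.target_centers)

    @property
    def anti_mask(self) -> np.ndarray:
        return self.blob_mask(self.anti_centers)

    @property
    def extra_mask(self) -> np.ndarray:
        if self.extra_centers is None or len(self.extra_centers) == 0:
            return np.zeros(self.grid_shape, dtype=bool)
        return self.blob_mask(self.extra_centers)

    def extra_masks(self) -> list:
        """One boolean mask per extra region."""
        return [self.blob_mask(c) for c in self.extra_centers]


@dataclass
class GroundTruth:
    """Complete latent record of one simulated run."""

    mixing: np.ndarray            # (t, n_sources), amplitude-scaled courses
    bank: ComponentBank
    condition: str
    seed: int
    coupling_gain: float = 0.0
    tr_seconds: float = 2.0

    @property
    def source_index(self) -> dict:
        return {l: i for i, l in enumerate(self.bank.labels)}

    def course(self, label: str) -> np.ndarray:
        """Unit-amplitude-scaled mixing column for one source."""
        return self.mixing[:, self.source_index[label]]

    @property
    def network_map(self) -> np.ndarray:
        return self.bank.spatial_maps["network"]


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - float(c)) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def _candidate_pairs(grid_shape):
    """Mirrored (left, right) site pairs on a coarse lattice, spaced so that
    radius-2 spheres at distinct sites are always disjoint."""
    gx, gy, gz = grid_shape
    xs_left = list(range(SITE_MARGIN, gx // 2 - 2, SITE_SPACING))
    ys = list(range(SITE_MARGIN, gy - SITE_MARGIN + 1, SITE_SPACING))
    zs = list(range(SITE_MARGIN, gz - SITE_MARGIN + 1, SITE_SPACING))
    pairs = []
    for x, y, z in itertools.product(xs_left, ys, zs):
        pairs.append(((x, y, z), (gx - 1 - x, y, z)))
    return pairs


def band_limited_noise(rng, n, tr_seconds, f_lo, f_hi) -> np.ndarray:
    """Unit-variance Gaussian noise with spectral support limited to
    [f_lo, f_hi] Hz (by zeroing out-of-band Fourier coefficients)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("band too narrow for this run length")
    return x / sd


def make_component_bank(grid_shape=(24, 24, 24), n_extra_regions=2,
                        seed=0) -> ComponentBank:
    """Place the latent spatial sources on a grid.

    The network source consists of 7 mirrored pairs of positive spherical
    blobs (the 14 target regions) plus 3 mirrored pairs of negative-weight
    blobs (the 6 anti-correlated regions — sharing the network time course
    with opposite sign, as anti-correlation demands).  The independent
    ``anti_network`` source occupies a further 3 disjoint pairs.  All blobs
    (including the patient-condition extra regions) are pairwise disjoint by
    construction.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g < 16 for g in grid_shape):
        raise ValueError("each grid dimension must be >= 16")
    rng = np.random.default_rng(seed)
    pairs = _candidate_pairs(grid_shape)
    n_pairs_needed = (N_TARGET_BLOBS // 2 + 2 * (N_ANTI_BLOBS // 2)
                      + n_extra_regions)
    if len(pairs) < n_pairs_needed:
        raise ValueError(
            f"grid {grid_shape} too small to place {n_pairs_needed} disjoint "
            f"blob pairs (only {len(pairs)} sites)"
        )
    order = rng.permutation(len(pairs))
    it = iter(order)
    take_pair = lambda: pairs[next(it)]

    target_centers = []
    for _ in range(N_TARGET_BLOBS // 2):
        l, r = take_pair()
        target_centers += [l, r]
    anti_centers = []
    for _ in range(N_ANTI_BLOBS // 2):
        l, r = take_pair()
        anti_centers += [l, r]
    anti_source_centers = []
    for _ in range(N_ANTI_BLOBS // 2):
        l, r = take_pair()
        anti_source_centers += [l, r]
    extra_centers = []
    for k in range(n_extra_regions):
        l, r = take_pair()
        extra_centers.append(l if k % 2 == 0 else r)  # unilateral extras

    target_centers = np.array(target_centers, dtype=int)
    anti_centers = np.array(anti_centers, dtype=int)
    anti_source_centers = np.array(anti_source_centers, dtype=int)
    extra_centers = np.array(extra_centers, dtype=int).reshape(-1, 3)

    maps = _build_maps(grid_shape, target_centers, anti_centers,
                       anti_source_centers, rng)
    time_specs = {
        "network": {"kind": "bandlimited", "band_hz": NETWORK_BAND_HZ},
        "anti_network": {"kind": "bandlimited", "band_hz": NETWORK_BAND_HZ},
        "global": {"kind": "bandlimited", "band_hz": GLOBAL_BAND_HZ},
        "drift": {"kind": "poly", "order": 1},
        "spike": {"kind": "spike", "onset_frac": float(rng.uniform(0.3, 0.7)),
                  "width": 3},
        "physio": {"kind": "sinusoid", "freq_hz": PHYSIO_FREQ_HZ,
                   "phase": float(rng.uniform(0, 2 * np.pi))},
    }
    return ComponentBank(grid_shape=grid_shape, spatial_maps=maps,
                         time_specs=time_specs,
                         target_centers=target_centers,
                         anti_centers=anti_centers,
                         anti_source_centers=anti_source_centers,
                         extra_centers=extra_centers, seed=seed)


def _build_maps(grid_shape, target_centers, anti_centers,
                anti_source_centers, rng):
    def blob_field(centers, weight):
        f = np.zeros(grid_shape)
        for c in centers:
            f[_sphere(grid_shape, c, BLOB_RADIUS_VOX)] = weight
        return f

    network = blob_field(target_centers, 1.0) + blob_field(
        anti_centers, -ANTI_WEIGHT_IN_NETWORK_MAP)
    anti = blob_field(anti_source_centers, 1.0)

    g = ndimage.gaussian_filter(rng.standard_normal(grid_shape), 2.0)
    g /= np.abs(g).max()
    global_map = 1.0 + 0.3 * g                       # strictly positive

    gz = grid_shape[2]
    drift = np.broadcast_to(
        0.3 + 0.7 * np.arange(gz) / (gz - 1), grid_shape).copy()

    rim = np.zeros(grid_shape, dtype=bool)
    for ax, size in enumerate(grid_shape):
        idx = [slice(None)] * 3
        idx[ax] = slice(0, 2)
        rim[tuple(idx)] = True
        idx[ax] = slice(size - 2, size)
        rim[tuple(idx)] = True
    spike = rim.astype(float)

    physio = np.zeros(grid_shape)
    physio[:, :, : max(4, grid_shape[2] // 4)] = 1.0

    return {"network": network, "anti_network": anti, "global": global_map,
            "drift": drift, "spike": spike, "physio": physio}


def _make_course(spec, rng, n, tr_seconds):
    kind = spec["kind"]
    if kind == "bandlimited":
        return band_limited_noise(rng, n, tr_seconds, *spec["band_hz"])
    if kind == "poly":
        ramp = np.linspace(-1.0, 1.0, n)   # monotone by construction
        return ramp / ramp.std()
    if kind == "spike":
        c = np.zeros(n)
        onset = int(spec["onset_frac"] * n)
        c[onset: onset + spec["width"]] = 1.0
        c -= c.mean()
        return c / c.std()
    if kind == "sinusoid":
        t = np.arange(n) * tr_seconds
        c = np.sin(2 * np.pi * spec["freq_hz"] * t + spec["phase"])
        c -= c.mean()
        return c / c.std()
    raise ValueError(f"unknown time spec kind {kind!r}")


def simulate_subject(bank: ComponentBank, condition="control", n_volumes=300,
                     tr_seconds=2.0, snr=2.0, seed=0,
                     coupling_gain=0.6):
    """Simulate one subject's run from a component bank.

    data = mixing @ maps + N(0, 1/snr); under ``condition="patient"`` the
    network course is additionally injected into the extra-region voxels with
    gain ``coupling_gain`` (relative to the unit network blob amplitude).
    """
    if condition not in ("control", "patient"):
        raise ValueError(f"unknown condition {condition!r}")
    if n_volumes < 60:
        raise ValueError("n_volumes must be >= 60")
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    courses = np.column_stack([
        _make_course(bank.time_specs[l], rng, n_volumes, tr_seconds)
        for l in bank.labels
    ])
    mixing = courses * np.array([AMPLITUDES[l] for l in bank.labels])

    v = int(np.prod(bank.grid_shape))
    S = np.stack([bank.spatial_maps[l].ravel() for l in bank.labels])
    data = mixing @ S                                     # (t, v)
    sigma = 0.0 if np.isinf(snr) else 1.0 / snr
    if sigma > 0:
        data = data + sigma * rng.standard_normal(data.shape)
    if condition == "patient" and len(bank.extra_centers):
        extra = bank.extra_mask.ravel()
        net = mixing[:, list(bank.labels).index("network")]
        data[:, extra] += coupling_gain * net[:, None]

    run = BoldRun(data=data.T.reshape(bank.grid_shape + (n_volumes,)),
                  tr_seconds=tr_seconds, mask=bank.mask,
                  voxel_mm=bank.voxel_mm)
    truth = GroundTruth(mixing=mixing, bank=bank, condition=condition,
                        seed=seed, tr_seconds=tr_seconds,
                        coupling_gain=coupling_gain if condition == "patient"
                        else 0.0)
    return run, truth


@dataclass
class CohortParams:
    """Study conditions for a simulated cohort (defaults mirror the target
    acquisition: 300 volumes at TR 2 s on a 24-cube 3 mm grid)."""

    grid_shape: tuple = (24, 24, 24)
    n_extra_regions: int = 2
    n_volumes: int = 300
    tr_seconds: float = 2.0
    snr: float = 2.0
    coupling_gain: float = 0.6
    jitter_vox: int = 1


def _translate_bank(bank: ComponentBank, shift, rng) -> ComponentBank:
    """Shift all blob centers by one shared integer translation (<= 2 voxels
    per axis), rebuilding the blob-borne maps; non-blob maps are untouched."""
    shift = np.asarray(shift, dtype=int)
    lo = np.array([2, 2, 2])
    hi = np.array(bank.grid_shape) - 3
    tc = np.clip(bank.target_centers + shift, lo, hi)
    ac = np.clip(bank.anti_centers + shift, lo, hi)
    sc = np.clip(bank.anti_source_centers + shift, lo, hi)
    ec = np.clip(bank.extra_centers + shift, lo, hi) \
        if len(bank.extra_centers) else bank.extra_centers

    def blob_field(centers, weight):
        f = np.zeros(bank.grid_shape)
        for c in centers:
            f[_sphere(bank.grid_shape, c, BLOB_RADIUS_VOX)] = weight
        return f

    maps = dict(bank.spatial_maps)
    maps["network"] = blob_field(tc, 1.0) + blob_field(
        ac, -ANTI_WEIGHT_IN_NETWORK_MAP)
    maps["anti_network"] = blob_field(sc, 1.0)
    return replace(bank, spatial_maps=maps, target_centers=tc,
                   anti_centers=ac, anti_source_centers=sc,
                   extra_centers=ec)


def make_cohort(n_controls=15, n_patients=13, params: CohortParams = None,
                seed=42, bank: ComponentBank = None):
    """Simulate a two-group cohort; per-subject seeds and blob jitter are
    derived deterministically from the master seed.

    A shared base ``bank`` may be supplied so that several cohorts (e.g. a
    reference group and a study group) share the same latent anatomy, as
    spatial normalization to a common space would provide; otherwise one is
    generated from the master seed.

    Returns a list of (BoldRun, GroundTruth), controls first.
    """
    if n_controls < 1 and n_patients < 1:
        raise ValueError("need at least one subject")
    params = params or CohortParams()
    n = n_controls + n_patients
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(n + 1)
    if bank is None:
        bank_seed = int(state[0] % (2 ** 31))
        bank = make_component_bank(params.grid_shape, params.n_extra_regions,
                                   seed=bank_seed)
    out = []
    conditions = ["control"] * n_controls + ["patient"] * n_patients
    for i, cond in enumerate(conditions):
        subj_seed = int(state[i + 1] % (2 ** 31))
        rng = np.random.default_rng(subj_seed)
        shift = rng.integers(-params.jitter_vox, params.jitter_vox + 1, size=3)
        bank_i = _translate_bank(bank, shift, rng)
        run, truth = simulate_subject(
            bank_i, condition=cond, n_volumes=params.n_volumes,
            tr_seconds=params.tr_seconds, snr=params.snr,
            seed=subj_seed, coupling_gain=params.coupling_gain)
        out.append((run, truth))
    return out


def write_cohort(cohort, outdir, seed=None) -> Path:
    """Write each run as NIfTI + JSON sidecar and a TSV manifest; returns
    the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (run, truth) in enumerate(cohort):
        subject_id = f"sub-{i + 1:03d}"
        path = outdir / f"{subject_id}.nii"
        save_run(run, path, sidecar={"seed": truth.seed,
                                     "condition": truth.condition})
        rows.append({"subject_id": subject_id, "group": truth.condition,
                     "nifti_path": path.name, "seed": truth.seed})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if seed is not None:
        (outdir / "cohort.json").write_text(json.dumps({"seed": seed}))
    return manifest
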