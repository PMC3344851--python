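"""Component fingerprints: spatial/temporal/spectral feature vectors used to
weigh how "neuronal-like" an ICA component is.

The feature set (11 features, versioned below) characterizes a component's
spatial map (moments, histogram entropy, clusteredness of suprathreshold
voxels) and its time course (one-lag autocorrelation, histogram entropy,
periodogram band-power fractions).  A component's neuronal-likeness weight
w_F = exp(-d/k) decays with the standardized distance d of its fingerprint
from a reference fingerprint averaged over known network components, with
k the number of features; it approaches 1 for network-like components and 0
for artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

FEATURE_SET_VERSION = "rsnselect-fp-1"

BAND_EDGES_HZ = (0.0, 0.008, 0.02, 0.05, 0.1)   # last band runs to Nyquist

FEATURE_NAMES = (
    "skewness", "kurtosis", "spatial_entropy", "clusterness",
    "one_lag_autocorr", "temporal_entropy",
    "bp_0.000_0.008", "bp_0.008_0.020", "bp_0.020_0.050",
    "bp_0.050_0.100", "bp_0.100_nyq",
)

N_HIST_BINS = 64
CLUSTER_Z = 2.0
CLUSTER_MIN_SIZE = 10
_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class Fingerprint:
    features: dict

    def __post_init__(self):
        if tuple(self.features) != FEATURE_NAMES:
            raise ValueError("unexpected feature set")
        vals = np.array(list(self.features.values()), dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite fingerprint feature")

    def vector(self) -> np.ndarray:
        return np.array([self.features[f] for f in FEATURE_NAMES])


@dataclass
class ReferenceFingerprint:
    """Per-feature mean and robust spread of network-component fingerprints."""

    mean: np.ndarray
    scale: np.ndarray
    n_sources: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if (self.scale <= 0).any():
            raise ValueError("scale must be strictly positive")

    def to_json(self, path=None) -> str:
        import json
        from pathlib import Path
        text = json.dumps({"feature_set_version": FEATURE_SET_VERSION,
                           "feature_names": list(FEATURE_NAMES),
                           "mean": self.mean.tolist(),
                           "scale": self.scale.tolist(),
                           "n_sources": self.n_sources}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path):
        import json
        from pathlib import Path
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        obj = json.loads(text)
        if obj.get("feature_set_version") != FEATURE_SET_VERSION:
            raise ValueError("fingerprint feature-set version mismatch")
        return cls(mean=np.array(obj["mean"]), scale=np.array(obj["scale"]),
                   n_sources=int(obj["n_sources"]))


def _hist_entropy(values) -> float:
    counts, _ = np.histogram(values, bins=N_HIST_BINS)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _band_power_fractions(course, tr_seconds) -> np.ndarray:
    freqs, psd = signal.periodogram(course, fs=1.0 / tr_seconds)
    total = psd.sum()
    if total == 0:
        raise ValueError("degenerate (constant) course")
    nyq = 0.5 / tr_seconds
    edges = list(BAND_EDGES_HZ) + [np.inf]
    fracs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (freqs >= lo) & (freqs < hi)
        fracs.append(psd[sel].sum() / total)
    return np.array(fracs)


def fingerprint(map3d, course, tr_seconds, mask=None) -> Fingerprint:
    """Compute the 11-feature fingerprint of one (map, course) component."""
    course = np.asarray(course, dtype=float)
    if course.size < 64:
        raise ValueError("course must have length >= 64")
    if mask is None:
        mask = np.ones(map3d.shape, dtype=bool)
    vals = np.asarray(map3d, dtype=float)[mask]
    sd = vals.std()
    if sd == 0 or course.std() == 0:
        raise ValueError("degenerate (constant) map or course")

    z3d = np.where(mask, (map3d - vals.mean()) / sd, 0.0)
    supra = np.abs(z3d) > CLUSTER_Z
    supra &= mask
    n_supra = int(supra.sum())
    if n_supra:
        lab, nlab = ndimage.label(supra, structure=_CONN26)
        sizes = np.bincount(lab.ravel())[1:]
        big = np.isin(lab, 1 + np.flatnonzero(sizes >= CLUSTER_MIN_SIZE))
        clusterness = float(big.sum() / n_supra)
    else:
        clusterness = 0.0

    c = course - course.mean()
    ac1 = float(np.corrcoef(c[:-1], c[1:])[0, 1])
    feats = dict(zip(FEATURE_NAMES, np.concatenate([
        [stats.skew(vals), stats.kurtosis(vals), _hist_entropy(vals),
         clusterness, ac1, _hist_entropy(c)],
        _band_power_fractions(c, tr_seconds),
    ])))
    return Fingerprint(features=feats)


def reference_fingerprint(fps, scale_floor=1e-6) -> ReferenceFingerprint:
    """Per-feature mean and robust spread (scaled MAD, floored) over a set of
    network-component fingerprints."""
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints")
    V = np.stack([fp.vector() for fp in fps])
    mean = V.mean(axis=0)
    mad = np.median(np.abs(V - np.median(V, axis=0)), axis=0)
    scale = np.maximum(1.4826 * mad, scale_floor)
    return ReferenceFingerprint(mean=mean, scale=scale, n_sources=len(fps))


_SKEW_IDX = FEATURE_NAMES.index("skewness")


def fingerprint_weight(fp: Fingerprint, ref: ReferenceFingerprint) -> float:
    """Neuronal-likeness weight w_F = exp(-d/k) in (0, 1], where d is the
    Euclidean distance of scale-standardized features from the reference
    mean and k the number of features.  Skewness enters in absolute value so
    the weight is invariant to the ICA sign indeterminacy."""
    v = fp.vector()
    m = ref.mean.copy()
    if len(v) != len(m):
        raise ValueError("feature sets do not match")
    v = v.copy()
    v[_SKEW_IDX] = abs(v[_SKEW_IDX])
    m[_SKEW_IDX] = abs(m[_SKEW_IDX])
    d = float(np.linalg.norm((v - m) / ref.scale))
    return float(np.exp(-d / len(FEATURE_NAMES)))


def fingerprints_frame(fps, index=None) -> pd.DataFrame:
    """Tabulate fingerprints, one row per component, named feature columns."""
    df = pd.DataFrame([fp.features for fp in fps], index=index)
    df.attrs["feature_set_version"] = FEATURE_SET_VERSION
    return df
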