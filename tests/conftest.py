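"""Shared phantom fixtures.

Session-scoped fixtures amortize the expensive pieces (spatial ICA) across
test modules; everything is seeded and deterministic.
"""

import warnings

import numpy as np
import pytest
from scipy import ndimage

import rsnselect as rs
from rsnselect.preprocess import FWHM_TO_SIGMA

warnings.filterwarnings("ignore", message=".*did not converge.*")

GRID = (24, 24, 24)
VOX = (3.0, 3.0, 3.0)


def smoothed(map3d, fwhm_mm=8.0, voxel_mm=3.0):
    """Ground-truth map as observable after the acquisition smoothing."""
    return ndimage.gaussian_filter(map3d,
                                   sigma=fwhm_mm * FWHM_TO_SIGMA / voxel_mm)


def ground_truth_rois(bank):
    """ROI set carved from the exact ground-truth blob masks."""
    guide = np.where(bank.network_mask, 2.0,
                     np.where(bank.anti_mask, -2.0, 0.0))
    vm = np.array(bank.voxel_mm)
    return rs.derive_rois(guide, bank.target_centers * vm,
                          bank.anti_centers * vm, voxel_mm=bank.voxel_mm)


def ica_reference_fingerprint(bank, n_subjects=3, n_volumes=120,
                              n_components=12, seed0=900):
    """Reference fingerprint from ICA-recovered network components of a few
    phantom subjects (the way the reference stage produces it)."""
    hint = smoothed(bank.spatial_maps["network"])
    fps = []
    for s in range(n_subjects):
        run, _ = rs.simulate_subject(bank, "control", n_volumes=n_volumes,
                                     seed=seed0 + s, snr=2.0)
        pre = rs.preprocess(run)
        d = rs.spatial_ica(pre, n_components, seed=s)
        idx, _ = rs.best_match(d, hint)
        sgn = np.sign(np.corrcoef(d.maps[idx][d.mask], hint[d.mask])[0, 1])
        fps.append(rs.fingerprint(d.maps[idx] * sgn,
                                  d.courses[:, idx] * sgn,
                                  run.tr_seconds))
    return rs.reference_fingerprint(fps)


@pytest.fixture(scope="session")
def bank():
    return rs.make_component_bank(GRID, n_extra_regions=2, seed=7)


@pytest.fixture(scope="session")
def phantom(bank):
    """One control subject at the study conditions (300 vols, TR 2, snr 2)."""
    run, truth = rs.simulate_subject(bank, "control", seed=3, snr=2.0)
    return run, truth


@pytest.fixture(scope="session")
def full_decomp(phantom):
    """Preprocessed run + 30-component decomposition of the phantom."""
    run, truth = phantom
    pre = rs.preprocess(run)
    d = rs.spatial_ica(pre, 30, seed=0)
    return pre, d, truth


@pytest.fixture(scope="session")
def fast_phantom(bank):
    """Cheap phantom: 120 volumes, 12 components."""
    run, truth = rs.simulate_subject(bank, "control", n_volumes=120,
                                     seed=5, snr=2.0)
    pre = rs.preprocess(run)
    d = rs.spatial_ica(pre, 12, seed=1)
    return pre, d, truth


@pytest.fixture(scope="session")
def reference_fp(bank):
    return ica_reference_fingerprint(bank)


@pytest.fixture(scope="session")
def gt_rois(bank):
    return ground_truth_rois(bank)
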