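"""End-to-end two-group workflow.

Stage 1 (``run_reference``): a reference cohort of healthy runs is
preprocessed and decomposed; components are clustered across subjects; the
network cluster's average map yields the 14 target + 6 anti ROIs and the
reference fingerprint.

Stage 2 (``run_study``): every study run is preprocessed, decomposed, and its
network component selected by the anticorrelation-corrected score; the
sign-corrected component course gives a residualized beta map per subject;
beta maps enter the random-effects group analysis with FDR and Monte-Carlo
cluster-extent thresholding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BoldRun, load_run
from .decompose import (RoiSet, cluster_components, derive_rois,
                        match_cluster_to_map, spatial_ica)
from .fingerprints import (ReferenceFingerprint, fingerprint,
                           reference_fingerprint)
from .group import (BetaMap, GroupContrast, component_beta_map,
                    residualize, residualize_course)
from .preprocess import PreprocParams, preprocess
from .selection import ComponentSelection

log = logging.getLogger("rsnselect")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters plus the master seed."""

    preproc_highpass_hz: float = 0.005
    preproc_fwhm_mm: float = 8.0
    ica_n_components: int = 30
    ica_max_iter: int = 200
    selection_alpha: float = 0.05
    roi_cube_mm: float = 10.0
    roi_map_threshold: float = 1.0
    group_q_fdr: float = 0.05
    group_voxel_p: float = 0.01
    group_n_iterations: int = 1000
    group_alpha_cluster: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config": self.to_dict(), "config_hash": self.hash(),
                "seed": self.seed}

    def preproc_params(self) -> PreprocParams:
        return PreprocParams(highpass_hz=self.preproc_highpass_hz,
                             fwhm_mm=self.preproc_fwhm_mm)


@dataclass
class ReferenceResult:
    rois: RoiSet
    reference: ReferenceFingerprint
    mean_map: np.ndarray
    cluster_index: int
    match_r: float


def _load_manifest(manifest_path):
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    runs, groups, ids = [], [], []
    for _, row in df.iterrows():
        runs.append(load_run(manifest_path.parent / row["nifti_path"]))
        groups.append(str(row.get("group", "control")))
        ids.append(str(row["subject_id"]))
    return runs, groups, ids


def run_reference(runs, target_centers_mm, anti_centers_mm,
                  config: PipelineConfig = None,
                  network_hint_map: np.ndarray = None,
                  network_cluster_index: int = None) -> ReferenceResult:
    """Derive the ROI set and reference fingerprint from a healthy cohort.

    The network cluster is identified either by best spatial match with
    ``network_hint_map`` (phantoms: the ground-truth network map) or by an
    explicit ``network_cluster_index``; one of the two must be given (this
    replaces selection by visual inspection).
    """
    config = config or PipelineConfig()
    if len(runs) < 2:
        raise ValueError("reference stage needs at least 2 subjects")
    if network_hint_map is None and network_cluster_index is None:
        raise ValueError("give network_hint_map or network_cluster_index")
    decomps = []
    for i, run in enumerate(runs):
        pre = preprocess(run, config.preproc_params())
        d = spatial_ica(pre, n_components=config.ica_n_components,
                        seed=config.seed + i, max_iter=config.ica_max_iter)
        d.subject_id = f"ref-{i:03d}"
        decomps.append(d)
        log.info("reference subject %d decomposed (converged=%s)", i,
                 d.converged)
    clusters = cluster_components(decomps, config.ica_n_components)
    if network_cluster_index is not None:
        ci, r = network_cluster_index, np.nan
    else:
        ci, r = match_cluster_to_map(clusters, network_hint_map,
                                     runs[0].mask)
    cl = clusters[ci]
    cl.label = "network"
    mean_map = cl.mean_map
    # orient the cluster: its global sign is ICA-arbitrary, but ROI carving
    # needs targets positive.  Align with the hint map when given, else make
    # the map's heavy tail positive.
    mm = mean_map[runs[0].mask]
    if network_hint_map is not None:
        flip = float(np.corrcoef(mm, network_hint_map[runs[0].mask])[0, 1])
    else:
        from scipy.stats import skew
        flip = float(skew(mm))
    if flip < 0:
        mean_map = -mean_map
        cl.mean_map = mean_map
        cl.member_signs = [-s for s in cl.member_signs]
    rois = derive_rois(mean_map, target_centers_mm, anti_centers_mm,
                       cube_mm=config.roi_cube_mm,
                       map_threshold=config.roi_map_threshold,
                       voxel_mm=runs[0].voxel_mm, mask=runs[0].mask)
    rois.source_map_id = f"reference-cluster-{ci}"
    id_map = {d.subject_id: d for d in decomps}
    fps = [fingerprint(id_map[sid].maps[c] * sgn,
                       id_map[sid].courses[:, c] * sgn,
                       runs[0].tr_seconds, mask=runs[0].mask)
           for (sid, c), sgn in zip(cl.members, cl.member_signs)]
    ref = reference_fingerprint(fps)
    log.info("reference: cluster %d (|r|=%.3f), %d member fingerprints",
             ci, r, len(fps))
    return ReferenceResult(rois=rois, reference=ref, mean_map=mean_map,
                           cluster_index=ci, match_r=float(r))


@dataclass
class SubjectOutcome:
    subject_id: str
    group: str
    selection: object            # SelectionResults
    beta_map: BetaMap = None
    error: str = ""


@dataclass
class StudyResult:
    subjects: list
    group_results: object        # GroupResults or None
    summary_tables: dict = field(default_factory=dict)

    def report(self) -> str:
        parts = []
        for s in self.subjects:
            if s.error:
                parts.append(f"{s.subject_id} ({s.group}): FAILED: {s.error}")
            else:
                sel = s.selection.result
                parts.append(
                    f"{s.subject_id} ({s.group}): component "
                    f"{sel.selected_component} via graph {sel.selected}")
        if self.group_results is not None:
            parts.append(self.group_results.summary())
        return "\n".join(parts)


def run_study(runs, groups, rois: RoiSet, reference: ReferenceFingerprint,
              config: PipelineConfig = None, subject_ids=None,
              skip_failures=False) -> StudyResult:
    """Select the network component per subject and run the group analysis.

    Subjects whose selection finds no network component abort the run unless
    ``skip_failures`` is set, in which case they are reported and excluded.
    """
    config = config or PipelineConfig()
    subject_ids = subject_ids or [f"sub-{i + 1:03d}" for i in range(len(runs))]
    outcomes = []
    for sid, grp, run in zip(subject_ids, groups, runs):
        pre = preprocess(run, config.preproc_params())
        decomp = spatial_ica(pre, n_components=config.ica_n_components,
                             seed=config.seed, max_iter=config.ica_max_iter)
        decomp.subject_id = sid
        model = ComponentSelection(pre, decomp, rois, reference,
                                   alpha=config.selection_alpha)
        sel = model.fit()
        if sel.no_network:
            msg = "no network component found (all scores zero)"
            if not skip_failures:
                raise RuntimeError(f"subject {sid}: {msg}")
            outcomes.append(SubjectOutcome(sid, grp, sel, error=msg))
            continue
        resid = residualize(pre, decomp.courses, sel.selected_component)
        course = residualize_course(sel.selected_course(),
                                    decomp.courses, sel.selected_component)
        course /= course.std()      # per-unit-SD betas, comparable across
        beta = component_beta_map(resid, course, subject_id=sid,
                                  selected_component=sel.selected_component)
        outcomes.append(SubjectOutcome(sid, grp, sel, beta_map=beta))
        log.info("%s (%s): selected component %d", sid, grp,
                 sel.selected_component)

    controls = [o.beta_map for o in outcomes
                if o.group == "control" and o.beta_map is not None]
    patients = [o.beta_map for o in outcomes
                if o.group == "patient" and o.beta_map is not None]
    group_results = None
    if len(controls) >= 3:
        model = GroupContrast(controls, patients, voxel_mm=runs[0].voxel_mm)
        group_results = model.fit(q_fdr=config.group_q_fdr,
                                  voxel_p=config.group_voxel_p,
                                  n_iterations=config.group_n_iterations,
                                  alpha_cluster=config.group_alpha_cluster,
                                  seed=config.seed)
    tables = {"selection": pd.concat(
        [o.selection.frame().assign(subject_id=o.subject_id)
         for o in outcomes if not o.error], ignore_index=True)}
    return StudyResult(subjects=outcomes, group_results=group_results,
                       summary_tables=tables)


def run_reference_from_manifest(manifest_path, target_centers_mm,
                                anti_centers_mm, config=None, **kw):
    runs, _, _ = _load_manifest(manifest_path)
    return run_reference(runs, target_centers_mm, anti_centers_mm, config,
                         **kw)


def run_study_from_manifest(manifest_path, rois, reference, config=None,
                            **kw):
    runs, groups, ids = _load_manifest(manifest_path)
    return run_study(runs, groups, rois, reference, config,
                     subject_ids=ids, **kw)
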