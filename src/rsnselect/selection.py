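"""Automatic network-component selection by the anticorrelation-corrected
score.

For each ICA component, the mean time course of every ROI is regressed on all
component courses, yielding per-ROI t-values.  A connectivity graph is built
for each component and each sign (positive graphs 1..n, negative graphs
n+1..2n): the nodes are the target ROIs whose t-value passes the
Bonferroni-corrected threshold T_th with the graph's sign, and every pair of
suprathreshold targets is joined (clique rule), giving an edge count E.  The
score of a graph is

    score = E * w * w_F

where w in [0, 1] is the fraction of anti-correlated ROIs expressed with the
opposite sign (w ~ 0 for the global component, whose ROIs are all positively
expressed) and w_F in (0, 1] is the component's neuronal-likeness fingerprint
weight.  The graph with the highest score identifies the network component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BoldRun
from .decompose import IcaDecomposition, RoiSet
from .fingerprints import (Fingerprint, ReferenceFingerprint, fingerprint,
                           fingerprint_weight)

DEFAULT_ALPHA = 0.05


@dataclass
class RoiRegression:
    betas: np.ndarray          # (n_rois, n_components)
    tvalues: np.ndarray        # (n_rois, n_components)
    dof: int
    roi_order: list            # target names then anti names
    n_targets: int

    def __post_init__(self):
        if self.dof <= 0:
            raise ValueError("non-positive degrees of freedom")
        if not np.isfinite(self.tvalues).all():
            raise ValueError("non-finite t-values")


@dataclass
class ConnectivityGraph:
    """Clique graph over suprathreshold target ROIs for one component/sign."""

    nodes: list
    edges: set               # unordered name pairs, stored sorted
    sign: str                # "positive" | "negative"
    component_index: int     # 1..n positive, n+1..2n negative

    @property
    def E(self) -> int:
        return len(self.edges)


@dataclass
class SelectionScore:
    component_index: int     # graph index, 1..2n
    component: int           # physical component, 0-based
    sign: str
    E: int
    w: float
    w_F: float

    @property
    def score(self) -> float:
        return self.E * self.w * self.w_F


@dataclass
class SelectionResult:
    scores: list                  # 2n SelectionScore entries
    selected: int | None          # graph index with maximal score, or None
    threshold: float
    no_network: bool = False

    @property
    def selected_component(self) -> int | None:
        """0-based physical component index of the winning graph."""
        if self.selected is None:
            return None
        n = len(self.scores) // 2
        return (self.selected - 1) % n

    @property
    def selected_sign(self) -> str | None:
        if self.selected is None:
            return None
        n = len(self.scores) // 2
        return "positive" if self.selected <= n else "negative"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"graph": s.component_index, "component": s.component + 1,
              "sign": s.sign, "E": s.E, "w": s.w, "w_F": s.w_F,
              "score": s.score,
              "selected": s.component_index == self.selected}
             for s in self.scores])


def roi_timecourses(run: BoldRun, rois: RoiSet) -> np.ndarray:
    """(t, n_rois) matrix of unweighted voxel-mean ROI courses, targets
    first then anti ROIs."""
    cols = []
    for name in rois.names:
        vox = np.atleast_2d((rois.targets | rois.anti)[name])
        if not all(run.mask[tuple(ijk)] for ijk in vox):
            raise ValueError(f"ROI {name!r} has out-of-mask voxels")
        cols.append(run.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0))
    return np.column_stack(cols)


def regress_components(roi_tc: np.ndarray, courses: np.ndarray,
                       n_targets=14, roi_names=None) -> RoiRegression:
    """OLS of each ROI course on [intercept + all component courses];
    t-statistics per component coefficient, dof = t - n_components - 1."""
    t, n_comp = courses.shape
    dof = t - n_comp - 1
    if dof <= 0:
        raise ValueError("need more volumes than components + 1")
    X = np.column_stack([np.ones(t), courses])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-8 * np.abs(R).max())
        raise ValueError(f"rank-deficient design; collinear columns {bad}")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ roi_tc                      # (n_comp+1, n_rois)
    resid = roi_tc - X @ B
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        tv = np.where(se > 0, B / se, 0.0)
    names = roi_names if roi_names is not None else [
        str(i) for i in range(roi_tc.shape[1])]
    return RoiRegression(betas=B[1:].T, tvalues=tv[1:].T, dof=dof,
                         roi_order=list(names), n_targets=n_targets)


def n_possible_edges(n: int) -> int:
    """Number of unordered node pairs, n(n-1)/2."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return n * (n - 1) // 2


def edge_threshold(alpha=DEFAULT_ALPHA, n_nodes=14, dof=269) -> float:
    """Bonferroni-corrected edge threshold: the upper-tail t quantile at
    1 - alpha / (n(n-1)/2) with the given dof."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if dof <= 0:
        raise ValueError("dof must be positive")
    return float(stats.t.ppf(1.0 - alpha / n_possible_edges(n_nodes), dof))


def build_graphs(reg: RoiRegression, T_th: float):
    """Two clique graphs per component: nodes are the target ROIs with
    t > T_th (positive graphs, indices 1..n) or t < -T_th (negative graphs,
    indices n+1..2n); edges join every suprathreshold pair."""
    if T_th <= 0:
        raise ValueError("T_th must be positive")
    n_comp = reg.tvalues.shape[1]
    target_names = reg.roi_order[:reg.n_targets]
    tv = reg.tvalues[:reg.n_targets]
    graphs = []
    for sign, cmp_fn, offset in (("positive", lambda t: t > T_th, 0),
                                 ("negative", lambda t: t < -T_th, n_comp)):
        for c in range(n_comp):
            nodes = [target_names[i] for i in np.flatnonzero(cmp_fn(tv[:, c]))]
            edges = {tuple(sorted(p))
                     for i, a in enumerate(nodes) for b in nodes[i + 1:]
                     for p in [(a, b)]}
            graphs.append(ConnectivityGraph(
                nodes=nodes, edges=edges, sign=sign,
                component_index=offset + c + 1))
    return graphs


def anticorrelation_weight(reg: RoiRegression, component: int,
                           sign="positive") -> float:
    """Fraction of anti ROIs whose t-value for this component has the sign
    opposite to the graph's condition; ~0 for the global component."""
    if not 0 <= component < reg.tvalues.shape[1]:
        raise ValueError("component out of range")
    anti_t = reg.tvalues[reg.n_targets:, component]
    if anti_t.size == 0:
        return 1.0
    opposite = (anti_t < 0) if sign == "positive" else (anti_t > 0)
    return float(opposite.sum() / anti_t.size)


def score_and_select(reg: RoiRegression, graphs, fps,
                     ref: ReferenceFingerprint,
                     threshold=None) -> SelectionResult:
    """Score every graph (E * w * w_F) and select the arg-max; ties broken
    by higher E, then lower graph index.  If every score is zero the result
    is flagged ``no_network`` instead of picking arbitrarily."""
    n_comp = reg.tvalues.shape[1]
    if len(graphs) != 2 * n_comp or len(fps) != n_comp:
        raise ValueError("graphs/fingerprints not aligned with regression")
    wf = [fingerprint_weight(fp, ref) for fp in fps]
    scores = []
    for g in graphs:
        comp = (g.component_index - 1) % n_comp
        w = anticorrelation_weight(reg, comp, g.sign)
        scores.append(SelectionScore(
            component_index=g.component_index, component=comp, sign=g.sign,
            E=g.E, w=w, w_F=wf[comp]))
    best = max(scores, key=lambda s: (s.score, s.E, -s.component_index))
    if best.score <= 0:
        return SelectionResult(scores=scores, selected=None,
                               threshold=threshold if threshold is not None
                               else np.nan, no_network=True)
    return SelectionResult(scores=scores, selected=best.component_index,
                           threshold=threshold if threshold is not None
                           else np.nan)


class ComponentSelection:
    """Model object tying one subject's decomposition, an ROI set and a
    reference fingerprint into the automatic selection procedure.

    Parameters
    ----------
    run : BoldRun
        The (preprocessed) run the decomposition came from.
    decomp : IcaDecomposition
    rois : RoiSet
    reference : ReferenceFingerprint
    alpha : float
        Family-wise error level for the Bonferroni edge threshold.
    """

    def __init__(self, run, decomp, rois, reference, alpha=DEFAULT_ALPHA):
        self.run = run
        self.decomp = decomp
        self.rois = rois
        self.reference = reference
        self.alpha = alpha

    def fit(self) -> "SelectionResults":
        roi_tc = roi_timecourses(self.run, self.rois)
        reg = regress_components(roi_tc, self.decomp.courses,
                                 n_targets=len(self.rois.targets),
                                 roi_names=self.rois.names)
        T_th = edge_threshold(self.alpha, n_nodes=len(self.rois.targets),
                              dof=reg.dof)
        graphs = build_graphs(reg, T_th)
        fps = [fingerprint(self.decomp.maps[c], self.decomp.courses[:, c],
                           self.run.tr_seconds, mask=self.run.mask)
               for c in range(self.decomp.n_components)]
        result = score_and_select(reg, graphs, fps, self.reference,
                                  threshold=T_th)
        return SelectionResults(self, reg, graphs, fps, result, T_th)


class SelectionResults:
    """Fitted selection: scores for all graphs, the winning component, and
    the sign-corrected course/map ready for group analysis."""

    def __init__(self, model, regression, graphs, fingerprints, result, T_th):
        self.model = model
        self.regression = regression
        self.graphs = graphs
        self.fingerprints = fingerprints
        self.result = result
        self.threshold = T_th

    @property
    def selected_component(self):
        return self.result.selected_component

    @property
    def no_network(self):
        return self.result.no_network

    def selected_course(self, normalize=False) -> np.ndarray:
        """Course of the winning component, sign-flipped if the negative
        graph won, so the target ROIs are always positively expressed.

        With ``normalize`` the course is scaled to unit variance, putting
        beta maps computed against it in per-unit-course-SD units that are
        comparable across subjects (the ICA course scale is arbitrary and
        varies between subjects)."""
        c = self.result.selected_component
        if c is None:
            raise ValueError("no network component was found")
        sgn = 1.0 if self.result.selected_sign == "positive" else -1.0
        course = sgn * self.model.decomp.courses[:, c]
        if normalize:
            course = course / course.std()
        return course

    def selected_map(self) -> np.ndarray:
        c = self.result.selected_component
        if c is None:
            raise ValueError("no network component was found")
        sgn = 1.0 if self.result.selected_sign == "positive" else -1.0
        return sgn * self.model.decomp.maps[c]

    def frame(self) -> pd.DataFrame:
        return self.result.frame()

    def summary(self) -> str:
        df = self.frame()
        lines = ["Anticorrelation-corrected component selection",
                 "=" * 46,
                 f"components: {self.model.decomp.n_components}"
                 f"   edge threshold T_th = {self.threshold:.3f}"
                 f" (alpha={self.model.alpha}, dof={self.regression.dof})"]
        if self.result.no_network:
            lines.append("result: NO network component found "
                         "(all scores zero)")
        else:
            s = df[df.selected].iloc[0]
            lines.append(
                f"selected: component {int(s.component)} ({s.sign} graph"
                f" {int(s.graph)}): E={int(s.E)}, w={s.w:.3f},"
                f" w_F={s.w_F:.3f}, score={s.score:.2f}")
        top = df.sort_values("score", ascending=False).head(5)
        lines.append("top graphs:")
        lines.append(top.to_string(
            index=False, float_format=lambda x: f"{x:.3f}"))
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Score vs. graph index, the winning graph highlighted."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        df = self.frame()
        ax.bar(df.graph, df.score, color="steelblue")
        if self.result.selected is not None:
            sel = df[df.selected]
            ax.bar(sel.graph, sel.score, color="crimson")
        ax.set_xlabel("connectivity graph (1..n positive, n+1..2n negative)")
        ax.set_ylabel("anticorrelation-corrected score")
        return ax
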