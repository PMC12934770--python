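"""Control ensembles: canonical correlation between CBGT activity and DDM
parameters.

Across a family of network instances, per-network activity summaries (18
elements: channel sums L+R and channel differences L-R of the eight
channelized cell types, plus the shared CxI and FSI rates) are related to
the four static drift-diffusion parameters (boundary height a, drift rate
v, onset time tr, starting bias z) by canonical correlation analysis.  The
first three components are labelled by their loading signature:

- choice          dominated by L-R differences, tied to drift rate v;
- responsiveness  overall activity of the corticothalamic and direct
                  pathways, tied to onset time and boundary height;
- pliancy         overall activity of the indirect and pallidostriatal
                  pathways, tied to onset time and boundary height with
                  the opposite sign of effect on a.

Within-trial engagement is obtained by projecting the change in the
activity summary relative to cue onset through the activity loadings U
(W_k = dF_k' U) and onward into DDM-parameter space through the parameter
loadings V (P_k = W_k V').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.multivariate.cancorr import CanCorr

from .errors import MissingDataError, ParameterError
from .synth import CHANNELIZED_TYPES, TrialRecord, stream_index

__all__ = [
    "ACTIVITY_ELEMENTS",
    "DDM_PARAMS",
    "Loadings",
    "EnsembleTimeCourse",
    "ControlEnsembleCCA",
    "summarize_activity",
    "fit_cca",
    "project_timecourse",
    "average_aligned",
    "boundary_contributions",
]

#: Order of the 18 activity elements.
ACTIVITY_ELEMENTS: tuple[str, ...] = tuple(
    [f"{ct}_sum" for ct in CHANNELIZED_TYPES]
    + [f"{ct}_diff" for ct in CHANNELIZED_TYPES]
    + ["CxI", "FSI"]
)

DDM_PARAMS: tuple[str, ...] = ("a", "v", "tr", "z")

_SUM_IDX = np.arange(0, 8)
_DIFF_IDX = np.arange(8, 16)
_DIRECT_SUMS = [ACTIVITY_ELEMENTS.index(f"{t}_sum") for t in ("Cx", "dSPN", "Th")]
_INDIRECT_SUMS = [
    ACTIVITY_ELEMENTS.index(f"{t}_sum") for t in ("iSPN", "GPeP", "GPeA")
]

COMPONENT_LABELS = ("choice", "responsiveness", "pliancy")


def summarize_activity(
    rates: np.ndarray, window: tuple[int, int] | None = None
) -> np.ndarray:
    """18-element activity summary of a [time x 18 streams] rate segment.

    Each element is the time mean over ``window`` (sample indices, defaults
    to the whole segment); channel pairs enter as sums (L+R) and
    differences (L-R).
    """
    if rates.ndim != 2 or rates.shape[1] != 18:
        raise MissingDataError(
            f"expected a [time x 18] rate matrix, got shape {rates.shape}"
        )
    if window is not None:
        lo, hi = window
        if not 0 <= lo < hi <= rates.shape[0]:
            raise ParameterError(f"window {window} outside segment of "
                                 f"length {rates.shape[0]}")
        rates = rates[lo:hi]
    mean = rates.mean(axis=0)
    out = np.empty(18)
    for i, ct in enumerate(CHANNELIZED_TYPES):
        l = mean[stream_index(f"{ct}-L")]
        r = mean[stream_index(f"{ct}-R")]
        out[i] = l + r
        out[8 + i] = l - r
    out[16] = mean[stream_index("CxI")]
    out[17] = mean[stream_index("FSI")]
    return out


@dataclass
class Loadings:
    """Canonical loadings of the three control ensembles.

    ``U`` ([18 x 3]) and ``V`` ([4 x 3]) hold structure correlations —
    correlations between each original (standardised) variable and the
    canonical variate of its own set — with columns ordered
    (choice, responsiveness, pliancy).
    """

    U: np.ndarray
    V: np.ndarray
    correlations: np.ndarray  # 3 canonical correlations
    labels: tuple[str, ...] = COMPONENT_LABELS
    element_names: tuple[str, ...] = ACTIVITY_ELEMENTS
    param_names: tuple[str, ...] = DDM_PARAMS


@dataclass
class EnsembleTimeCourse:
    """Within-trial ensemble engagement and projected parameter changes."""

    W: np.ndarray  # [bins x 3] engagement (percent scale)
    P: np.ndarray  # [bins x 4] projected DDM-parameter changes
    bin_width_ms: float
    alignment: str = "cue_onset"
    labels: tuple[str, ...] = COMPONENT_LABELS
    param_names: tuple[str, ...] = DDM_PARAMS


class ControlEnsembleCCA:
    """Canonical-correlation estimator of the CBGT control ensembles.

    Parameters
    ----------
    n_components : number of canonical components kept (default 3).
    label_override : optional tuple naming the components in fitted column
        order, bypassing the signature-based labelling.

    Attributes (after :meth:`fit`)
    ------------------------------
    loadings_ : the :class:`Loadings` (structure correlations, labelled and
        sign-fixed).
    correlations_ : canonical correlations of the kept components.
    x_mean_, x_std_, y_mean_, y_std_ : standardisation of the two blocks.
    score_std_ : cross-network SD of the structure-projected activity
        scores; the reference scale that expresses engagement in percent.
    """

    def __init__(self, n_components: int = 3,
                 label_override: tuple[str, ...] | None = None):
        self.n_components = n_components
        self.label_override = label_override

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "label_override": self.label_override,
        }

    def set_params(self, **params) -> "ControlEnsembleCCA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ParameterError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, activity: np.ndarray, ddm: np.ndarray) -> "ControlEnsembleCCA":
        X = np.asarray(activity, dtype=float)
        Y = np.asarray(ddm, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(ACTIVITY_ELEMENTS):
            raise ParameterError("activity must be [networks x 18]")
        if Y.ndim != 2 or Y.shape[1] != len(DDM_PARAMS):
            raise ParameterError("ddm must be [networks x 4]")
        if X.shape[0] != Y.shape[0]:
            raise ParameterError("activity and ddm row counts differ")
        n = X.shape[0]
        if n < self.n_components + 1:
            raise ParameterError(
                f"{n} networks cannot support {self.n_components} canonical "
                "components"
            )
        if n < 30:
            warnings.warn(f"only {n} networks; canonical loadings will be "
                          "noisy", stacklevel=2)

        self.x_mean_, self.x_std_ = X.mean(axis=0), X.std(axis=0, ddof=1)
        self.y_mean_, self.y_std_ = Y.mean(axis=0), Y.std(axis=0, ddof=1)
        if np.any(self.x_std_ == 0) or np.any(self.y_std_ == 0):
            raise ParameterError("constant column in activity or ddm block")
        Xs = (X - self.x_mean_) / self.x_std_
        Ys = (Y - self.y_mean_) / self.y_std_

        # rank-deficient blocks (fewer networks than variables) are solved
        # in their principal-component subspace; structure correlations are
        # computed against the original variables either way
        Xw, Yw = Xs, Ys
        Px = Py = None
        if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
            warnings.warn("activity block is rank-deficient; solving the "
                          "canonical system in PCA space", stacklevel=2)
            Px = _pca_basis(Xs)
            Xw = Xs @ Px
        if np.linalg.matrix_rank(Ys) < Ys.shape[1]:
            warnings.warn("ddm block is rank-deficient; solving the "
                          "canonical system in PCA space", stacklevel=2)
            Py = _pca_basis(Ys)
            Yw = Ys @ Py

        cc = CanCorr(Yw, Xw)
        k = self.n_components
        # canonical weights -> variates -> structure correlations
        x_scores = Xw @ cc.x_cancoef[:, :k]
        y_scores = Yw @ cc.y_cancoef[:, :k]
        U = _corr_block(Xs, x_scores)
        V = _corr_block(Ys, y_scores)
        corr = np.asarray(cc.cancorr[:k], dtype=float)

        order, signs = self._label_components(U, V)
        U, V = U[:, order] * signs, V[:, order] * signs
        x_scores = x_scores[:, order] * signs
        self.loadings_ = Loadings(U=U, V=V, correlations=corr[order])
        self.correlations_ = self.loadings_.correlations
        # percent-engagement reference: SD of structure-projected scores
        self.score_std_ = (Xs @ U).std(axis=0, ddof=1)
        return self

    def _label_components(self, U, V):
        k = U.shape[1]
        v_idx = DDM_PARAMS.index("v")
        a_idx = DDM_PARAMS.index("a")
        if self.label_override is not None:
            order = [list(self.label_override).index(lbl)
                     for lbl in COMPONENT_LABELS]
        else:
            diff_score = (np.abs(U[_DIFF_IDX, :]).mean(axis=0)
                          - np.abs(U[_SUM_IDX, :]).mean(axis=0))
            choice = int(np.argmax(diff_score))
            rest = [c for c in range(k) if c != choice]
            direct_score = [
                np.abs(U[_DIRECT_SUMS, c]).mean()
                - np.abs(U[_INDIRECT_SUMS, c]).mean()
                for c in rest
            ]
            resp = rest[int(np.argmax(direct_score))]
            pli = [c for c in rest if c != resp][0]
            order = [choice, resp, pli]
        # sign conventions: choice correlates positively with leftward v;
        # responsiveness/pliancy point along their defining pathway sums
        signs = np.ones(3)
        if V[v_idx, order[0]] < 0:
            signs[0] = -1
        if U[_DIRECT_SUMS, order[1]].mean() < 0:
            signs[1] = -1
        if U[_INDIRECT_SUMS, order[2]].mean() < 0:
            signs[2] = -1
        a_resp = V[a_idx, order[1]] * signs[1]
        a_pli = V[a_idx, order[2]] * signs[2]
        if a_resp * a_pli > 0:
            warnings.warn(
                "responsiveness and pliancy do not show opposite-signed "
                "boundary-height loadings; check the component signature",
                stacklevel=3,
            )
        return order, signs

    # -- application --------------------------------------------------------

    def transform(
        self,
        trial: TrialRecord,
        bin_width_ms: float = 10.0,
    ) -> EnsembleTimeCourse:
        """Project one trial's decision-period rates into ensemble space.

        dF_k is the change of the standardised activity summary at bin k
        relative to the cue-onset bin (dF_0 = 0 by construction); engagement
        is reported in percent of the cross-network score scale.
        """
        from .claw import bin_rates  # local import avoids a cycle

        binned = bin_rates(trial.decision_rates, bin_width_ms, trial.dt_ms)
        if binned.shape[0] == 0:
            raise ParameterError("trial shorter than one bin")
        summaries = np.stack(
            [summarize_activity(binned[k][None, :]) for k in range(binned.shape[0])]
        )
        dF = (summaries - summaries[0]) / self.x_std_
        W = dF @ self.loadings_.U
        P = W @ self.loadings_.V.T
        W_pct = 100.0 * W / self.score_std_
        return EnsembleTimeCourse(
            W=W_pct, P=P, bin_width_ms=bin_width_ms, alignment="cue_onset"
        )

    def fit_transform(self, activity, ddm, trial, **kw):
        return self.fit(activity, ddm).transform(trial, **kw)


def _pca_basis(Z: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the row space of a standardised block."""
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    keep = s > tol * s[0]
    return vt[keep].T


def _corr_block(Z: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Correlation of each column of Z with each score column."""
    Zc = Z - Z.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    num = Zc.T @ Sc
    den = np.outer(
        np.sqrt((Zc ** 2).sum(axis=0)), np.sqrt((Sc ** 2).sum(axis=0))
    )
    return num / den


# ---------------------------------------------------------------------------
# module-level wrappers


def fit_cca(activity: np.ndarray, ddm: np.ndarray, **kw) -> ControlEnsembleCCA:
    """Fit the control-ensemble CCA (see :class:`ControlEnsembleCCA`)."""
    return ControlEnsembleCCA(**kw).fit(activity, ddm)


def project_timecourse(
    trial: TrialRecord, model: ControlEnsembleCCA, bin_width_ms: float = 10.0
) -> EnsembleTimeCourse:
    """Within-trial ensemble engagement of one trial."""
    return model.transform(trial, bin_width_ms)


def average_aligned(
    timecourses: list[EnsembleTimeCourse],
    alignment: str = "cue_onset",
    window_ms: float = 50.0,
) -> dict[str, np.ndarray]:
    """Trial-average engagement under cue-onset or decision alignment.

    Cue alignment keeps the first ``window_ms`` of each trial (the
    launching phase); decision alignment keeps the final ``window_ms``
    before the decision (the committed phase).  Trials shorter than the
    window are excluded with a notice.  Returns mean, the 95% CI
    half-width, and n per bin.
    """
    if alignment not in ("cue_onset", "decision"):
        raise ParameterError(f"unknown alignment {alignment!r}")
    if not timecourses:
        raise MissingDataError("no timecourses to average")
    n_bins = int(round(window_ms / timecourses[0].bin_width_ms))
    kept = []
    for tc in timecourses:
        if tc.W.shape[0] < n_bins:
            continue
        kept.append(tc.W[:n_bins] if alignment == "cue_onset" else tc.W[-n_bins:])
    dropped = len(timecourses) - len(kept)
    if dropped:
        warnings.warn(
            f"excluded {dropped} trial(s) shorter than the {window_ms} ms "
            f"window", stacklevel=2,
        )
    if not kept:
        raise MissingDataError("every trial is shorter than the window")
    stack = np.stack(kept)  # [trials x bins x 3]
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0]) if stack.shape[0] > 1 \
        else np.zeros_like(mean)
    return {"mean": mean, "ci95": 1.96 * se, "n": stack.shape[0]}


def boundary_contributions(
    W: np.ndarray, loadings: Loadings
) -> np.ndarray:
    """Fraction of the boundary-height drive attributable to responsiveness.

    Per bin: c_resp = |W_resp * V[a, resp]|, c_pli = |W_pli * V[a, pli]|;
    returns c_resp / (c_resp + c_pli) with NaN where both vanish.  The
    complementary fraction is the pliancy share.
    """
    a_idx = loadings.param_names.index("a")
    resp = loadings.labels.index("responsiveness")
    pli = loadings.labels.index("pliancy")
    c_resp = np.abs(W[:, resp] * loadings.V[a_idx, resp])
    c_pli = np.abs(W[:, pli] * loadings.V[a_idx, pli])
    total = c_resp + c_pli
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, c_resp / np.where(total > 0, total, 1.0), np.nan)
    return frac
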