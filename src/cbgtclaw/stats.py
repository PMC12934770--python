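"""Mixed-effects testing of learning effects on engagement time courses.

For each decision class (pair of trajectory types), the engagement or
parameter value is modelled over time bins with fixed effects for time,
learning stage (number of training trials) and trajectory type, all
pairwise interactions and the three-way interaction, and a random
intercept per network.  Linear and quadratic (time^2) variants are fitted
by maximum likelihood and compared by BIC.  Because the analysis runs
independently in four decision classes, the omnibus significance threshold
is Bonferroni-corrected to alpha = 0.05/4 = 0.0125; the pointwise
follow-up at individual bins uses alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import MissingDataError, ParameterError

__all__ = [
    "EffectReport",
    "LearningEffectModel",
    "fit_learning_model",
    "pointwise_followup",
    "omnibus_alpha",
]

REQUIRED_COLUMNS = ("network_id", "trajectory_type", "learning_stage",
                    "time_bin", "value")

#: interaction terms examined in the omnibus test
LINEAR_TERMS = ("time:learning", "time:type", "time:learning:type")
QUADRATIC_TERMS = LINEAR_TERMS + (
    "time2:learning", "time2:type", "time2:learning:type",
)


def omnibus_alpha(alpha: float = 0.05, n_classes: int = 4) -> float:
    """Bonferroni-corrected omnibus threshold (0.05/4 = 0.0125)."""
    return alpha / n_classes


@dataclass
class EffectReport:
    selected_model: str  # "linear" | "quadratic"
    omnibus_pvalues: dict[str, float]
    omnibus_alpha: float
    significant: bool
    bic: dict[str, float]
    pointwise_alpha: float = 0.05
    pointwise: pd.DataFrame | None = None
    windows: list[tuple[int, int]] = field(default_factory=list)
    random_intercept_only: bool = False


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ParameterError(f"long table lacks columns {sorted(missing)}")
    if table.empty:
        raise MissingDataError("empty long table")
    if table["learning_stage"].nunique() < 2:
        raise ParameterError("need at least two learning stages")
    if table["network_id"].nunique() < 2:
        raise ParameterError("need at least two networks")
    df = table.copy()
    df["time"] = df["time_bin"].astype(float)
    df["learning"] = df["learning_stage"].astype(float)
    # binary-coded type keeps interaction terms single-coefficient
    types = sorted(df["trajectory_type"].unique())
    if len(types) > 2:
        raise ParameterError("a decision class holds at most two types")
    df["type"] = (df["trajectory_type"] == types[-1]).astype(float)
    df["time2"] = df["time"] ** 2
    # scale regressors to comparable magnitude for optimiser stability
    for col in ("time", "time2", "learning"):
        s = df[col].abs().max()
        if s > 0:
            df[col] = df[col] / s
    return df


def _fit_mixed(df: pd.DataFrame, quadratic: bool):
    rhs = "time * learning * type"
    if quadratic:
        rhs += " + time2 * learning * type"
    model = smf.mixedlm(
        f"value ~ {rhs}", df, groups=df["network_id"], re_formula="1"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="lbfgs")
    return fit


def _bic(fit) -> float:
    k = fit.params.shape[0]
    n = fit.model.nobs
    return float(k * np.log(n) - 2.0 * fit.llf)


def _term_pvalues(fit, quadratic: bool) -> dict[str, float]:
    pv = fit.pvalues
    out = {}
    wanted = QUADRATIC_TERMS if quadratic else LINEAR_TERMS
    for term in wanted:
        key = term.replace("time2:", "time2:").replace(":", ":")
        # statsmodels names interactions with ':' in formula order
        matches = [ix for ix in pv.index if _same_term(ix, term)]
        if matches:
            out[term] = float(pv[matches[0]])
    return out


def _same_term(index_name: str, term: str) -> bool:
    return set(index_name.split(":")) == set(term.split(":"))


class LearningEffectModel:
    """BIC-selected mixed-effects model of a learning-effect long table.

    Attributes (after :meth:`fit`): ``report_`` (:class:`EffectReport`),
    ``fit_`` (the selected statsmodels results object).
    """

    def __init__(self, alpha: float = 0.05, n_classes: int = 4):
        self.alpha = alpha
        self.n_classes = n_classes

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "n_classes": self.n_classes}

    def set_params(self, **params) -> "LearningEffectModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ParameterError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, table: pd.DataFrame) -> "LearningEffectModel":
        df = _validate(table)
        self._df = df
        fits, bics = {}, {}
        singular = False
        for name, quad in (("linear", False), ("quadratic", True)):
            try:
                f = _fit_mixed(df, quad)
                if not np.isfinite(f.llf):
                    raise ValueError("non-finite likelihood")
            except Exception:
                # singular random-effects fit: retry once with stronger
                # starting variance, else skip the variant
                try:
                    f = _fit_mixed(df.assign(value=df["value"] * 1.0), quad)
                    singular = True
                except Exception:
                    continue
            fits[name] = f
            bics[name] = _bic(f)
        if not fits:
            raise MissingDataError("mixed model failed for both variants")
        selected = min(bics, key=bics.get)
        fit = fits[selected]
        pvals = _term_pvalues(fit, selected == "quadratic")
        thr = omnibus_alpha(self.alpha, self.n_classes)
        self.fit_ = fit
        self.report_ = EffectReport(
            selected_model=selected,
            omnibus_pvalues=pvals,
            omnibus_alpha=thr,
            significant=any(p < thr for p in pvals.values()),
            bic=bics,
            pointwise_alpha=self.alpha,
            random_intercept_only=singular,
        )
        return self

    def pointwise(self) -> pd.DataFrame:
        """Per-bin follow-up, gated on a significant omnibus test.

        At each time bin an ordinary regression of value on learning, type
        and the terms significant in the omnibus test is fitted; returns
        per-bin p-values, flags at alpha = 0.05 and the contiguous
        significant windows.
        """
        if not hasattr(self, "report_"):
            raise MissingDataError("fit the omnibus model first")
        if not self.report_.significant:
            raise ParameterError(
                "omnibus test not significant; pointwise follow-up is gated"
            )
        sig_terms = {
            t for t, p in self.report_.omnibus_pvalues.items()
            if p < self.report_.omnibus_alpha
        }
        use_type = any("type" in t for t in sig_terms)
        rhs = "learning * type" if use_type else "learning"
        rows = []
        for t, sub in self._df.groupby("time_bin"):
            if sub["learning"].nunique() < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ols = smf.ols(f"value ~ {rhs}", sub).fit()
            p = float(ols.pvalues.get("learning", np.nan))
            rows.append({"time_bin": t, "p_value": p,
                         "significant": p < self.report_.pointwise_alpha})
        res = pd.DataFrame(rows).sort_values("time_bin").reset_index(drop=True)
        self.report_.pointwise = res
        self.report_.windows = _contiguous_windows(res)
        return res


def _contiguous_windows(res: pd.DataFrame) -> list[tuple[int, int]]:
    windows = []
    start = None
    bins = res["time_bin"].tolist()
    flags = res["significant"].tolist()
    for i, (b, f) in enumerate(zip(bins, flags)):
        if f and start is None:
            start = b
        if not f and start is not None:
            windows.append((start, bins[i - 1]))
            start = None
    if start is not None:
        windows.append((start, bins[-1]))
    return windows


def fit_learning_model(table: pd.DataFrame, **kw) -> EffectReport:
    """Omnibus mixed-effects learning test (see :class:`LearningEffectModel`)."""
    return LearningEffectModel(**kw).fit(table).report_


def pointwise_followup(table: pd.DataFrame, **kw) -> EffectReport:
    """Omnibus test plus the per-bin follow-up on one long table."""
    m = LearningEffectModel(**kw).fit(table)
    m.pointwise()
    return m.report_
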