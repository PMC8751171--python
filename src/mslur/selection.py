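"""Variable screening: distance-decay buffer choice and stepwise selection.

Each buffered predictor family (e.g. residential fraction at 50–2000 m) is
first reduced to the single radius whose values correlate most strongly
(in absolute Pearson r) with the response; ties go to the smallest radius.
The surviving per-family columns plus all temporal covariates then enter a
bidirectional stepwise screen on ordinary least squares with two hard
rules: every non-forced term must keep p < 0.05, and every variance
inflation factor must stay below the stage's collinearity bound (3 at
city scale, 4 for the neighborhood model).  AOD is forced into the
city-scale model throughout.

Entry order is by largest |t| among admissible candidates, which makes the
procedure deterministic and independent of column order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "distance_decay_select",
    "stepwise_select",
    "vif",
    "StepwiseResult",
]

log = logging.getLogger(__name__)

P_ENTER = 0.05
VIF_MAX = 3.0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def distance_decay_select(response, table: pd.DataFrame,
                          family_columns: list[str]) -> tuple[str, pd.Series]:
    """Pick the family column with the highest |Pearson r| to the response.

    *family_columns* are the per-radius columns of one variable family,
    ordered by increasing radius.  Returns (chosen column, r-vs-radius
    curve).  Raises ``ValueError`` when the family is constant at every
    radius (caller drops it).
    """
    y = np.asarray(response, dtype=float)
    curve = pd.Series(
        {col: _pearson(y, table[col].to_numpy(dtype=float))
         for col in family_columns})
    if curve.isna().all():
        raise ValueError("variable family is constant at all radii")
    best = curve.abs().fillna(-1.0)
    # first index at the maximum -> smallest radius on ties
    chosen = best.index[int(np.argmax(best.to_numpy()))]
    return chosen, curve


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors of each column given the others
    (intercept excluded from the reported set but included in the fits)."""
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        if others.shape[1] == 0:
            out[col] = 1.0
            continue
        r2 = sm.OLS(X[col], sm.add_constant(others)).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


class StepwiseResult:
    """Selected predictor subset with the fitted screening model and a
    step-by-step trace."""

    def __init__(self, selected, model, trace, pvalues, vifs):
        self.selected = list(selected)
        self.model = model
        self.trace = trace
        self.pvalues = pvalues
        self.vifs = vifs

    def report(self) -> dict:
        return {
            "selected": self.selected,
            "trace": self.trace,
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "vif": {k: float(v) for k, v in self.vifs.items()},
            "adj_r2": float(self.model.rsquared_adj),
        }


def _fit(y: pd.Series, X: pd.DataFrame):
    yv = np.asarray(y, dtype=float)
    if X.shape[1] == 0:  # intercept-only
        design = pd.DataFrame({"const": np.ones(len(yv))}, index=X.index)
        return sm.OLS(yv, design).fit()
    return sm.OLS(yv, sm.add_constant(X.astype(float),
                                      has_constant="add")).fit()


def stepwise_select(table: pd.DataFrame, response,
                    forced: tuple[str, ...] = ("AOD",),
                    candidates: list[str] | None = None,
                    vif_max: float = VIF_MAX) -> StepwiseResult:
    """Bidirectional stepwise OLS screen with forced terms.

    A candidate enters only if, after entry, its own p-value is < 0.05 and
    every VIF (intercept excluded) stays below *vif_max* (default 3, the
    city-scale bound; the neighborhood stage uses 4); any non-forced term
    whose p-value rises to >= 0.05 is removed.  Among admissible
    candidates the one with the largest |t| on entry is taken first.
    """
    y = pd.Series(np.asarray(response, dtype=float), index=table.index)
    for f in forced:
        if f not in table.columns:
            raise ValueError(f"forced variable {f!r} missing from table")
    if candidates is None:
        candidates = [c for c in table.columns if c not in forced]
    # drop constant / non-finite candidates up front
    usable = []
    for c in candidates:
        vals = table[c].to_numpy(dtype=float)
        if np.all(np.isfinite(vals)) and np.std(vals) > 0:
            usable.append(c)
        else:
            log.info("dropping constant or non-finite candidate %s", c)
    selected = list(forced)
    trace: list[dict] = []
    for _ in range(100):  # hard cap against entry/removal oscillation
        changed = False
        # --- entry: score remaining candidates by |t| ---------------------
        scores = []
        for c in usable:
            if c in selected:
                continue
            fit = _fit(y, table[selected + [c]])
            tval = abs(fit.tvalues.get(c, 0.0))
            scores.append((tval, c, fit))
        for tval, c, fit in sorted(scores, reverse=True, key=lambda s: s[0]):
            if not (fit.pvalues[c] < P_ENTER):  # NaN p fails entry too
                continue
            vifs = vif(table[selected + [c]])
            if (vifs >= vif_max).any():
                trace.append({"step": "reject", "variable": c,
                              "reason": "vif"})
                continue
            selected.append(c)
            trace.append({"step": "enter", "variable": c,
                          "p": float(fit.pvalues[c])})
            changed = True
            break
        # --- removal: worst offending non-forced term ---------------------
        fit = _fit(y, table[selected])
        removable = [c for c in selected if c not in forced]
        if removable:
            pv = fit.pvalues[removable].fillna(1.0)  # NaN p -> remove
            worst = pv.idxmax()
            if pv.max() >= P_ENTER:
                selected.remove(worst)
                trace.append({"step": "remove", "variable": worst,
                              "p": float(pv.max())})
                changed = True
            else:
                vifs = vif(table[selected])
                bad = vifs[removable][vifs[removable] >= vif_max]
                if len(bad):
                    worst = bad.idxmax()
                    selected.remove(worst)
                    trace.append({"step": "remove", "variable": worst,
                                  "reason": "vif",
                                  "vif": float(bad.max())})
                    changed = True
        if not changed:
            break
    fit = _fit(y, table[selected])
    vifs = vif(table[selected]) if len(selected) > 1 else pd.Series(
        {c: 1.0 for c in selected})
    return StepwiseResult(selected, fit, trace, fit.pvalues[selected], vifs)
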