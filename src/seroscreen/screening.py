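"""Per-marker screening statistics and Up/Down/Unchanged classification.

For each protein and isotype the screen computes, on normalized SNRs:

* an optimal cutoff constrained to at least 90% specificity against the
  control group for that direction, maximizing discriminant ability
  (Youden's J = sensitivity + specificity - 1 by default);
* positive ratios (fraction of samples strictly above the cutoff) in the
  renal-cancer (RC) and healthy-control (HC) groups;
* fold change FC = mean(RC)/mean(HC) and a two-sided Welch t-test p-value;
* a label: Up (RC ratio > 30%, HC ratio < 10%, FC >= 1.5, p < 0.05),
  Down (the mirrored criteria with FC < 2/3), otherwise Unchanged —
  flagged when the ratio pattern matched Up or Down but FC or p did not.

Because a cutoff at >= 90% specificity w.r.t. HC caps the HC positive
ratio at 10%, the Down criteria are evaluated at a cutoff chosen with RC
as the specificity reference; each reported marker carries the cutoff of
the direction it was evaluated under.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .io import ISOTYPES, SampleManifest, SNRMatrix, ValidationError

LABELS = ("Up", "Down", "Unchanged", "Negative")


@dataclass
class ScreenCriteria:
    """Thresholds defining the Up/Down/Unchanged classes.

    Comparison operators follow the printed criteria exactly: positive-ratio
    bounds are strict, the Up fold-change bound is inclusive (>= 1.5), the
    Down bound strict (< 2/3), and p is strict (< alpha).
    """

    up_rc_pos_min: float = 0.30
    up_hc_pos_max: float = 0.10
    up_fc_min: float = 1.5
    down_hc_pos_min: float = 0.30
    down_rc_pos_max: float = 0.10
    down_fc_max: float = 2.0 / 3.0
    alpha: float = 0.05
    min_specificity: float = 0.90
    cutoff_objective: Literal["youden", "accuracy"] = "youden"
    t_test: Literal["welch", "student"] = "welch"

    def __post_init__(self) -> None:
        fracs = (
            self.up_rc_pos_min,
            self.up_hc_pos_max,
            self.down_hc_pos_min,
            self.down_rc_pos_max,
            self.min_specificity,
        )
        if not all(0 <= f <= 1 for f in fracs):
            raise ValidationError("ratio thresholds must lie in [0, 1]")
        if not (self.up_fc_min > 1 > self.down_fc_max > 0):
            raise ValidationError("need up_fc_min > 1 > down_fc_max > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


class DegenerateMarkerError(ValueError):
    """Fold change undefined (control-group mean is zero)."""


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name}: empty group")
    return arr


def candidate_cutoffs(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct pooled values, plus one above the max."""
    pooled = np.unique(np.concatenate([case, control]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    return np.append(mids, pooled[-1] + 1.0)


def sens_spec_at(case, control, cutoff: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule "positive iff value > cutoff"."""
    case = _as_1d(case, "case")
    control = _as_1d(control, "control")
    sens = float(np.mean(case > cutoff))
    spec = float(np.mean(control <= cutoff))
    return sens, spec


def optimal_cutoff(
    case,
    control,
    min_specificity: float = 0.90,
    objective: Literal["youden", "accuracy"] = "youden",
) -> float:
    """Best cutoff subject to a minimum-specificity constraint.

    A sample is called positive when its value is strictly above the
    cutoff; specificity is the fraction of controls at or below it. Among
    candidate cutoffs reaching ``min_specificity``, the one maximizing the
    discriminant objective is returned; ties are broken toward the higher
    (more specific) cutoff. A cutoff above the pooled maximum always
    satisfies the constraint, so a value is always returned.
    """
    case = _as_1d(case, "case")
    control = _as_1d(control, "control")
    best_cut = None
    best_score = -np.inf
    for cut in candidate_cutoffs(case, control):
        sens = np.mean(case > cut)
        spec = np.mean(control <= cut)
        if spec < min_specificity:
            continue
        if objective == "youden":
            score = sens + spec - 1.0
        elif objective == "accuracy":
            score = (sens * case.size + spec * control.size) / (
                case.size + control.size
            )
        else:
            raise ValidationError(f"unknown cutoff objective {objective!r}")
        if score >= best_score:  # >= keeps the highest cutoff among ties
            best_score = score
            best_cut = cut
    return float(best_cut)


def positive_ratio(values, cutoff: float) -> float:
    """Fraction of samples strictly above the cutoff."""
    arr = _as_1d(values, "values")
    return float(np.mean(arr > cutoff))


def fold_change(rc_values, hc_values) -> float:
    """mean(RC) / mean(HC)."""
    rc = _as_1d(rc_values, "RC")
    hc = _as_1d(hc_values, "HC")
    denom = hc.mean()
    if denom <= 0:
        raise DegenerateMarkerError("HC mean is not positive; fold change undefined")
    return float(rc.mean() / denom)


def t_test_pvalue(
    rc_values, hc_values, flavor: Literal["welch", "student"] = "welch"
) -> float:
    """Two-sided two-sample t-test p-value (Welch by default).

    With zero variance in both groups the statistic is undefined; equal
    means then give p = 1 by convention, distinct means p = 0.
    """
    rc = _as_1d(rc_values, "RC")
    hc = _as_1d(hc_values, "HC")
    if rc.size < 2 or hc.size < 2:
        raise ValidationError("t-test needs at least 2 values per group")
    if rc.var(ddof=1) == 0 and hc.var(ddof=1) == 0:
        return 1.0 if rc.mean() == hc.mean() else 0.0
    res = stats.ttest_ind(rc, hc, equal_var=(flavor == "student"))
    return float(res.pvalue)


def classify_marker(
    rc_pos: float,
    hc_pos: float,
    fc: float | None,
    p: float,
    criteria: ScreenCriteria | None = None,
) -> tuple[str, str]:
    """Apply the Up/Down/Unchanged criteria to one marker's statistics.

    Returns ``(label, subflag)``; the subflag marks Unchanged markers whose
    positive-ratio pattern matched Up or Down while fold change or p-value
    failed. An undefined fold change (``fc=None``) yields Unchanged/other.
    """
    c = criteria or ScreenCriteria()
    up_ratios = rc_pos > c.up_rc_pos_min and hc_pos < c.up_hc_pos_max
    down_ratios = hc_pos > c.down_hc_pos_min and rc_pos < c.down_rc_pos_max
    if fc is None:
        return "Unchanged", "other"
    sig = p < c.alpha
    if up_ratios and fc >= c.up_fc_min and sig:
        return "Up", "n/a"
    if down_ratios and fc < c.down_fc_max and sig:
        return "Down", "n/a"
    if up_ratios or down_ratios:
        return "Unchanged", "ratio_consistent_fc_or_p_fail"
    return "Unchanged", "other"


def _screen_one(
    rc: np.ndarray, hc: np.ndarray, criteria: ScreenCriteria
) -> dict:
    """All screening statistics for one protein x isotype."""
    try:
        fc = fold_change(rc, hc)
    except DegenerateMarkerError:
        fc = None
    p = t_test_pvalue(rc, hc, criteria.t_test)

    cut_up = optimal_cutoff(rc, hc, criteria.min_specificity, criteria.cutoff_objective)
    rc_pos_up = positive_ratio(rc, cut_up)
    hc_pos_up = positive_ratio(hc, cut_up)
    label, subflag = classify_marker(rc_pos_up, hc_pos_up, fc, p, criteria)
    if label == "Up":
        return dict(cutoff=cut_up, rc_pos=rc_pos_up, hc_pos=hc_pos_up,
                    fc=fc, p=p, label=label, subflag=subflag)

    # Down direction: RC is the specificity reference group.
    cut_dn = optimal_cutoff(hc, rc, criteria.min_specificity, criteria.cutoff_objective)
    rc_pos_dn = positive_ratio(rc, cut_dn)
    hc_pos_dn = positive_ratio(hc, cut_dn)
    label_dn, subflag_dn = classify_marker(rc_pos_dn, hc_pos_dn, fc, p, criteria)
    if label_dn == "Down":
        return dict(cutoff=cut_dn, rc_pos=rc_pos_dn, hc_pos=hc_pos_dn,
                    fc=fc, p=p, label=label_dn, subflag=subflag_dn)

    if subflag_dn == "ratio_consistent_fc_or_p_fail":
        return dict(cutoff=cut_dn, rc_pos=rc_pos_dn, hc_pos=hc_pos_dn,
                    fc=fc, p=p, label="Unchanged", subflag=subflag_dn)
    return dict(cutoff=cut_up, rc_pos=rc_pos_up, hc_pos=hc_pos_up,
                fc=fc, p=p, label="Unchanged", subflag=subflag)


class MarkerScreener(BaseEstimator):
    """Seroreactivity marker screen as a scikit-learn style selector.

    ``fit(X, y)`` takes a samples x proteins matrix of normalized SNRs and
    binary group labels (``"RC"``/``"HC"``); fitted attributes are
    ``results_`` (one row of statistics and a label per protein) and
    ``support_`` (boolean mask of Up markers). ``transform(X)`` selects the
    Up-marker columns, so the screener composes with downstream estimators
    such as the random-forest ranker.
    """

    def __init__(
        self,
        criteria: ScreenCriteria | None = None,
        excluded: Sequence[str] | None = None,
    ):
        self.criteria = criteria
        self.excluded = excluded

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if X.shape[0] != y.size:
            raise ValidationError("X rows and y length differ")
        groups = set(np.unique(y))
        if groups != {"RC", "HC"}:
            raise ValidationError(f"labels must be RC/HC, got {sorted(groups)}")
        criteria = self.criteria or ScreenCriteria()
        excluded = set(self.excluded or ())
        rc_mask = y == "RC"
        rows = []
        for protein in X.columns:
            col = X[protein].to_numpy(dtype=float)
            if protein in excluded:
                rows.append(
                    dict(protein_id=protein, cutoff=np.nan, rc_pos=np.nan,
                         hc_pos=np.nan, fc=np.nan, p=np.nan,
                         label="Negative", subflag="n/a")
                )
                continue
            res = _screen_one(col[rc_mask], col[~rc_mask], criteria)
            res["fc"] = np.nan if res["fc"] is None else res["fc"]
            rows.append(dict(protein_id=protein, **res))
        results = pd.DataFrame(rows)
        retained = results["label"] != "Negative"
        results["bh_q"] = np.nan
        if retained.any():
            results.loc[retained, "bh_q"] = multipletests(
                results.loc[retained, "p"], method="fdr_bh"
            )[1]
        self.results_ = results
        self.support_ = (results["label"] == "Up").to_numpy()
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]


def screen_all(
    igg: SNRMatrix,
    igm: SNRMatrix,
    manifest: SampleManifest,
    criteria: ScreenCriteria | None = None,
    excluded: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Screen every retained protein in both isotypes.

    Returns one row per protein x isotype with columns protein_id, isotype,
    cutoff, rc_pos, hc_pos, fc, p, bh_q, label, subflag. Proteins in the
    exclusion set for an isotype are labeled Negative with no statistics.
    """
    manifest.validate()
    excluded = excluded or {}
    frames = []
    for matrix in (igg, igm):
        matrix.validate()
        sample_ids = list(matrix.values.columns)
        missing = set(sample_ids) - set(manifest.table.index)
        if missing:
            raise ValidationError(f"arrays not in manifest: {sorted(missing)}")
        y = manifest.groups.loc[sample_ids].to_numpy()
        screener = MarkerScreener(
            criteria=criteria, excluded=excluded.get(matrix.isotype)
        ).fit(matrix.values.T, y)
        res = screener.results_
        res.insert(1, "isotype", matrix.isotype)
        frames.append(res)
    cols = ["protein_id", "isotype", "cutoff", "rc_pos", "hc_pos",
            "fc", "p", "bh_q", "label", "subflag"]
    return pd.concat(frames, ignore_index=True)[cols]


def summarize_counts(results: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Counts per isotype and label (labels always all present)."""
    out: dict[str, dict[str, int]] = {}
    for iso in sorted(results["isotype"].unique()):
        sub = results[results["isotype"] == iso]
        counts = sub["label"].value_counts()
        out[iso] = {label: int(counts.get(label, 0)) for label in LABELS}
    return out


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change and -log10 p per marker, for volcano plotting.

    Pure transform of the stored statistics; Negative rows (no statistics)
    are omitted.
    """
    sub = results[results["label"] != "Negative"].copy()
    sub = sub[np.isfinite(sub["fc"]) & np.isfinite(sub["p"])]
    with np.errstate(divide="ignore"):
        log2fc = np.log2(sub["fc"].to_numpy(dtype=float))
        neglogp = -np.log10(sub["p"].to_numpy(dtype=float))
    out = sub[["protein_id"]].copy()
    if "isotype" in sub.columns:
        out["isotype"] = sub["isotype"]
    out["log2_fc"] = log2fc
    out["neg_log10_p"] = neglogp
    out["label"] = sub["label"].to_numpy()
    return out.reset_index(drop=True)
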