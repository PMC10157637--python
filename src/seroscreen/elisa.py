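"""ELISA validation statistics: plate QC, relative OD scores, ROC/AUC,
specificity-constrained cutoffs, and marker panels.

Each microtiter plate carries human-IgG positive-control and BSA
negative-control wells. The plate-level signal-to-noise ratio is
(mean positive OD - mean negative OD) / mean negative OD; per-sample
scores use the same control-relative normalization,
score = (OD - mean negative OD) / mean negative OD, which removes the
plate offset and makes scores comparable across plates that pass QC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import ValidationError
from .screening import optimal_cutoff, sens_spec_at

logger = logging.getLogger(__name__)

WELL_ROLES = ("sample", "positive_control", "negative_control", "blank")


class PlateQCError(ValueError):
    """Plate controls make the relative score undefined or unreliable."""


@dataclass
class ELISAPlate:
    """One microtiter plate: well ODs (450 nm), roles and sample mapping."""

    plate_id: str
    wells: pd.DataFrame  # columns: well_id, role, sample_id, od450

    def validate(self) -> "ELISAPlate":
        need = {"well_id", "role", "od450"}
        missing = need - set(self.wells.columns)
        if missing:
            raise ValidationError(f"plate {self.plate_id!r}: missing {sorted(missing)}")
        bad = set(self.wells["role"]) - set(WELL_ROLES)
        if bad:
            raise ValidationError(f"plate {self.plate_id!r}: unknown roles {bad}")
        od = self.wells["od450"].to_numpy(dtype=float)
        if not np.all(np.isfinite(od)):
            raise ValidationError(f"plate {self.plate_id!r}: non-finite OD")
        for role in ("positive_control", "negative_control"):
            if not (self.wells["role"] == role).any():
                raise ValidationError(f"plate {self.plate_id!r}: no {role} well")
        return self

    def _control_mean(self, role: str) -> float:
        mask = self.wells["role"] == role
        return float(self.wells.loc[mask, "od450"].mean())


def read_plates(path: str | Path) -> list[ELISAPlate]:
    """Read ELISA plates from a CSV with columns plate_id, well_id, role, sample_id, od450."""
    df = pd.read_csv(path)
    need = {"plate_id", "well_id", "role", "od450"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"plate table missing columns {sorted(missing)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = None
    return [
        ELISAPlate(str(pid), sub.drop(columns="plate_id").reset_index(drop=True)).validate()
        for pid, sub in df.groupby("plate_id", sort=True)
    ]


def write_plates(plates: Sequence[ELISAPlate], path: str | Path) -> None:
    frames = []
    for p in plates:
        sub = p.wells.copy()
        sub.insert(0, "plate_id", p.plate_id)
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def plate_snr(plate: ELISAPlate) -> float:
    """(mean positive-control OD - mean negative-control OD) / mean negative-control OD."""
    plate.validate()
    neg = plate._control_mean("negative_control")
    pos = plate._control_mean("positive_control")
    if neg <= 0:
        raise PlateQCError(f"plate {plate.plate_id!r}: mean negative-control OD <= 0")
    return (pos - neg) / neg


def sample_relative_od(plate: ELISAPlate, *, raw: bool = False) -> pd.Series:
    """Per-sample control-relative score, indexed by sample_id.

    score = (OD - mean negative OD) / mean negative OD; ``raw=True`` returns
    the unadjusted ODs instead.
    """
    plate.validate()
    mask = plate.wells["role"] == "sample"
    od = plate.wells.loc[mask, "od450"].to_numpy(dtype=float)
    ids = plate.wells.loc[mask, "sample_id"]
    if raw:
        return pd.Series(od, index=ids, name=plate.plate_id)
    neg = plate._control_mean("negative_control")
    if neg <= 0:
        raise PlateQCError(f"plate {plate.plate_id!r}: mean negative-control OD <= 0")
    return pd.Series((od - neg) / neg, index=ids, name=plate.plate_id)


def score_cohort(
    plates: Sequence[ELISAPlate],
    *,
    min_plate_snr: float = 1.0,
    raw: bool = False,
) -> pd.Series:
    """Scores for all samples across plates, with plate QC.

    Plates with plate SNR below ``min_plate_snr`` are rejected; their
    samples are reported missing (absent), with a warning.
    """
    parts = []
    for plate in plates:
        if plate_snr(plate) < min_plate_snr:
            logger.warning(
                "plate %s rejected (SNR < %.3g); its samples marked missing",
                plate.plate_id,
                min_plate_snr,
            )
            continue
        parts.append(sample_relative_od(plate, raw=raw))
    if not parts:
        raise PlateQCError("all plates failed QC")
    return pd.concat(parts)


def roc_auc(scores_case, scores_control) -> float:
    """Area under the empirical ROC curve.

    Equals the concordant-pair probability: (#{case > control} + 0.5 *
    #{ties}) / (n_case * n_control), computed via midranks.
    """
    case = np.asarray(scores_case, dtype=float).ravel()
    control = np.asarray(scores_control, dtype=float).ravel()
    if case.size == 0 or control.size == 0:
        raise ValidationError("roc_auc: empty group")
    ranks = stats.rankdata(np.concatenate([case, control]))
    r_case = ranks[: case.size].sum()
    u = r_case - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def choose_cutoff(scores_case, scores_control, min_specificity: float = 0.90) -> float:
    """Specificity-constrained optimal cutoff (same rule as the microarray screen)."""
    return optimal_cutoff(scores_case, scores_control, min_specificity)


@dataclass
class ROCResult:
    """ROC summary for one marker or panel at its chosen cutoff."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_rc: int
    n_hc: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_rc": self.n_rc,
            "n_hc": self.n_hc,
        }


def evaluate_marker(
    scores_rc, scores_hc, min_specificity: float = 0.90
) -> ROCResult:
    """AUC plus sensitivity/specificity at the specificity-constrained cutoff."""
    rc = np.asarray(scores_rc, dtype=float).ravel()
    hc = np.asarray(scores_hc, dtype=float).ravel()
    cutoff = choose_cutoff(rc, hc, min_specificity)
    sens, spec = sens_spec_at(rc, hc, cutoff)
    return ROCResult(
        auc=roc_auc(rc, hc),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_rc=rc.size,
        n_hc=hc.size,
    )


class PanelModel(BaseEstimator):
    """Combine several markers' scores into one panel score.

    method="logistic" (default) fits a logistic regression on the marker
    scores and uses the linear predictor as the panel score; the fit is
    in-sample, so the resulting AUC is optimistic. When the fit fails
    (perfect separation), the model falls back to method="or_rule":
    a sample is panel-positive iff any marker exceeds its own
    specificity-constrained cutoff (the panel score is then 0/1).

    A single-marker panel passes the marker's score through unchanged, so
    it reproduces that marker's ranking exactly.
    """

    def __init__(
        self,
        method: Literal["logistic", "or_rule"] = "logistic",
        min_specificity: float = 0.90,
    ):
        self.method = method
        self.min_specificity = min_specificity

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if X.shape[1] < 1:
            raise ValidationError("panel needs at least one marker")
        pos = y == "RC"
        if pos.sum() == 0 or (~pos).sum() == 0:
            raise ValidationError("panel fit needs both groups")
        self.marker_names_ = list(X.columns)
        self.method_used_ = self.method
        if X.shape[1] == 1:
            self.method_used_ = "identity"
        elif self.method == "logistic":
            self._fit_logistic(X.to_numpy(dtype=float), pos.astype(float))
        if self.method_used_ == "or_rule":
            self.cutoffs_ = {
                m: choose_cutoff(X.loc[pos, m], X.loc[~pos, m], self.min_specificity)
                for m in self.marker_names_
            }
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_logistic(self, X: np.ndarray, y: np.ndarray) -> None:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                model = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
            self.coef_ = model.params[1:]
            self.intercept_ = model.params[0]
        except Exception:  # separation / convergence failure
            warnings.warn(
                "logistic panel fit failed (separation?); falling back to or_rule",
                stacklevel=2,
            )
            self.method_used_ = "or_rule"

    def decision_function(self, X):
        check_is_fitted(self, "method_used_")
        X = pd.DataFrame(X)[self.marker_names_]
        if self.method_used_ == "identity":
            return X.iloc[:, 0].to_numpy(dtype=float)
        if self.method_used_ == "logistic":
            return (
                X.to_numpy(dtype=float) @ self.coef_ + self.intercept_
            )
        positive = np.zeros(len(X), dtype=bool)
        for m, cut in self.cutoffs_.items():
            positive |= X[m].to_numpy(dtype=float) > cut
        return positive.astype(float)

    def fit_transform_scores(self, X, y) -> np.ndarray:
        return self.fit(X, y).decision_function(X)


def panel_score(
    score_table: pd.DataFrame,
    labels,
    method: Literal["logistic", "or_rule"] = "logistic",
    min_specificity: float = 0.90,
) -> np.ndarray:
    """Combined per-sample panel score (thin wrapper over :class:`PanelModel`)."""
    model = PanelModel(method=method, min_specificity=min_specificity)
    return model.fit_transform_scores(score_table, np.asarray(labels))


def evaluate_panel(
    score_table: pd.DataFrame,
    labels,
    method: Literal["logistic", "or_rule"] = "logistic",
    min_specificity: float = 0.90,
) -> ROCResult:
    """ROC summary of a marker panel (in-sample combination; optimistic)."""
    labels = np.asarray(labels)
    scores = panel_score(score_table, labels, method, min_specificity)
    return evaluate_marker(scores[labels == "RC"], scores[labels == "HC"], min_specificity)
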