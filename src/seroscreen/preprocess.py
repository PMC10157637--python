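"""Spot tables -> per-isotype SNR matrices.

Pipeline order: per-spot SNR = foreground/background, arithmetic mean over
duplicate spots, then multiplicative median scaling across arrays, with
negative proteins (never reactive in any sample) flagged for exclusion.

The negativity thresholds act on the raw SNR scale (IgG <= 4, IgM <= 5 in
every sample), so flagging is done before normalization by default; the
screening statistics downstream use normalized values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ISOTYPES, SNRMatrix, SpotTable, ValidationError

logger = logging.getLogger(__name__)


class DegenerateSpotError(ValueError):
    """A spot whose background makes the SNR undefined (B <= 0)."""


class NormalizationError(ValueError):
    """Median scaling is impossible (a sample column with median <= 0)."""


@dataclass
class NegativityThresholds:
    """Raw-SNR ceilings below which a protein counts as never reactive.

    A protein is negative for an isotype when its SNR is at or below the
    ceiling in *every* sample of both groups (inclusive comparison).
    """

    igg_max: float = 4.0
    igm_max: float = 5.0

    def __post_init__(self) -> None:
        if self.igg_max <= 0 or self.igm_max <= 0:
            raise ValidationError("negativity thresholds must be positive")

    def for_isotype(self, isotype: str) -> float:
        return {"IgG": self.igg_max, "IgM": self.igm_max}[isotype]


def spot_snr(foreground, background):
    """Per-spot signal-to-noise ratio F/B.

    Accepts scalars or arrays; raises :class:`DegenerateSpotError` if any
    background is non-positive (such spots are dropped at pipeline level
    instead, see :func:`collapse_duplicates`).
    """
    f = np.asarray(foreground, dtype=float)
    b = np.asarray(background, dtype=float)
    if (b <= 0).any():
        raise DegenerateSpotError("background <= 0: SNR undefined")
    out = f / b
    return float(out) if out.ndim == 0 else out


def collapse_duplicates(table: SpotTable) -> dict[str, pd.Series]:
    """Average duplicate-spot SNRs into one value per protein and isotype.

    Spots with background <= 0 are dropped individually (with a warning);
    a protein with no usable replicate in a channel is reported missing
    (absent from the returned Series) rather than raising.
    """
    data = table.data
    usable = data["background"] > 0
    n_bad = int((~usable).sum())
    if n_bad:
        logger.warning(
            "array %s: dropping %d spot(s) with background <= 0", table.array_id, n_bad
        )
    data = data[usable]
    out: dict[str, pd.Series] = {}
    for isotype in ISOTYPES:
        sub = data[data["channel"] == isotype]
        if sub.empty:
            continue
        snr = sub["foreground"].to_numpy() / sub["background"].to_numpy()
        out[isotype] = (
            pd.Series(snr, index=sub["protein_id"].to_numpy())
            .groupby(level=0)
            .mean()
            .rename(table.array_id)
        )
    return out


def build_snr_matrices(
    tables: Iterable[SpotTable],
    *,
    include_controls: bool = False,
) -> dict[str, SNRMatrix]:
    """Collapse a cohort of spot tables into per-isotype SNR matrices.

    Control spots are excluded from the matrices by default (they carry no
    screening information); proteins missing from any array are dropped so
    the matrices have no holes, with a warning listing how many.
    """
    tables = list(tables)
    if not tables:
        raise ValidationError("no spot tables given")
    control_ids: set[str] = set()
    if not include_controls:
        for t in tables:
            mask = t.data["control_class"] != "none"
            control_ids.update(t.data.loc[mask, "protein_id"])
    per_iso: dict[str, list[pd.Series]] = {iso: [] for iso in ISOTYPES}
    for t in tables:
        for iso, series in collapse_duplicates(t).items():
            per_iso[iso].append(series.drop(labels=control_ids, errors="ignore"))
    matrices: dict[str, SNRMatrix] = {}
    for iso, columns in per_iso.items():
        if not columns:
            continue
        grid = pd.concat(columns, axis=1)
        n_missing = int(grid.isna().any(axis=1).sum())
        if n_missing:
            logger.warning(
                "%s: dropping %d protein(s) missing from at least one array",
                iso,
                n_missing,
            )
            grid = grid.dropna(axis=0)
        matrices[iso] = SNRMatrix(isotype=iso, values=grid, normalized=False).validate()
    return matrices


class MedianScaler(TransformerMixin, BaseEstimator):
    """Multiplicative per-sample median scaling (scikit-learn transformer).

    Operates on samples x features arrays (sklearn orientation). ``fit``
    records the grand median of all cells; ``transform`` rescales each
    sample (row) so its median equals that target. Rank order and ratios
    within a sample are preserved, and the operation is idempotent.
    """

    def __init__(self, target: float | None = None):
        self.target = target

    def fit(self, X, y=None):
        X = self._check(X)
        self.target_ = (
            float(np.median(X)) if self.target is None else float(self.target)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "target_")
        is_frame = isinstance(X, pd.DataFrame)
        arr = self._check(X)
        medians = np.median(arr, axis=1)
        if (medians <= 0).any():
            raise NormalizationError("sample with non-positive median")
        scaled = arr * (self.target_ / medians)[:, None]
        if is_frame:
            return pd.DataFrame(scaled, index=X.index, columns=X.columns)
        return scaled

    @staticmethod
    def _check(X):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError("expected a non-empty 2D array")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite values in SNR matrix")
        return arr


def median_normalize(matrix: SNRMatrix) -> SNRMatrix:
    """Scale each array so its median SNR equals the grand median.

    Thin wrapper over :class:`MedianScaler`; the matrix is proteins x
    samples, the scaler works sample-wise, hence the transpose.
    """
    matrix.validate()
    scaled = MedianScaler().fit_transform(matrix.values.T).T
    return SNRMatrix(isotype=matrix.isotype, values=scaled, normalized=True)


def flag_negative_proteins(
    igg: SNRMatrix,
    igm: SNRMatrix,
    thresholds: NegativityThresholds | None = None,
    *,
    mode: Literal["per_isotype", "joint"] = "per_isotype",
) -> dict[str, set[str]]:
    """Identify never-reactive proteins to exclude from screening.

    per_isotype (default): a protein is excluded from the IgG analysis iff
    its IgG SNR <= igg_max in all samples, and independently for IgM.
    joint: excluded from both analyses only when both conditions hold.
    """
    thresholds = thresholds or NegativityThresholds()
    if set(igg.values.index) != set(igm.values.index):
        raise ValidationError("IgG and IgM matrices must share the protein set")
    below = {}
    for m in (igg, igm):
        limit = thresholds.for_isotype(m.isotype)
        below[m.isotype] = set(
            m.values.index[(m.values <= limit).all(axis=1)]
        )
    if mode == "joint":
        joint = below["IgG"] & below["IgM"]
        return {"IgG": joint, "IgM": joint}
    if mode != "per_isotype":
        raise ValidationError(f"unknown negativity mode {mode!r}")
    return below


def preprocess_cohort(
    tables: Iterable[SpotTable],
    *,
    thresholds: NegativityThresholds | None = None,
    negativity_on: Literal["raw", "normalized"] = "raw",
    negativity_mode: Literal["per_isotype", "joint"] = "per_isotype",
) -> tuple[dict[str, SNRMatrix], dict[str, set[str]]]:
    """Full preprocessing: collapse, flag negatives, median-normalize.

    Returns the normalized per-isotype matrices and the per-isotype
    exclusion sets. Negativity is judged on raw SNRs by default because the
    thresholds are stated on that scale; ``negativity_on="normalized"``
    applies them after scaling instead.
    """
    raw = build_snr_matrices(tables)
    if set(raw) != set(ISOTYPES):
        raise ValidationError("cohort must contain both IgG and IgM channels")
    normalized = {iso: median_normalize(m) for iso, m in raw.items()}
    basis = raw if negativity_on == "raw" else normalized
    if negativity_on not in ("raw", "normalized"):
        raise ValidationError(f"unknown negativity_on {negativity_on!r}")
    excluded = flag_negative_proteins(
        basis["IgG"], basis["IgM"], thresholds, mode=negativity_mode
    )
    return normalized, excluded
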