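"""Readers and writers for the pipeline's file formats.

The array side of the pipeline speaks a GPR dialect: tab-separated spot
tables with a one-line header, one file per array, two fluorescence
channels (each channel has its own foreground/background column pair named
after the scanner wavelength, e.g. ``F532 Median`` / ``B532 Median``).
Which wavelength carries which immunoglobulin isotype is scanner
configuration, so it is always passed explicitly as ``channel_map``.

Matrices are serialized as TSV with ``#key=value`` header lines carrying
isotype and normalization state, protein IDs as row keys and array IDs as
column keys, at full float precision so that read(write(m)) == m exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

ISOTYPES = ("IgG", "IgM")
GROUPS = ("RC", "HC")

SPOT_COLUMNS = [
    "protein_id",
    "block",
    "row",
    "col",
    "replicate_index",
    "channel",
    "foreground",
    "background",
    "control_class",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class IntegrityError(ValueError):
    """A file violates a uniqueness/consistency invariant."""


class ValidationError(ValueError):
    """An in-memory object violates its contract."""


@dataclass
class ControlPatterns:
    """Regexes classifying control spots by protein name.

    Defaults follow the array layout convention: histones H3/H4 are printed
    as positive controls, BSA and biotinylated BSA as negative controls.
    """

    positive: str = r"\bH3\b|\bH4\b|HISTONE"
    negative: str = r"BSA"

    def classify(self, name: str) -> str:
        if re.search(self.positive, name, flags=re.IGNORECASE):
            return "positive"
        if re.search(self.negative, name, flags=re.IGNORECASE):
            return "negative"
        return "none"


@dataclass
class SpotTable:
    """Per-spot foreground/background intensities for one array.

    ``data`` has one row per (protein, replicate, channel) with columns
    ``SPOT_COLUMNS``; ``channel`` is the isotype the scanner channel was
    mapped to, ``control_class`` one of none/positive/negative.
    """

    array_id: str
    data: pd.DataFrame

    def validate(self) -> "SpotTable":
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"spot table missing columns: {missing}")
        if self.data.empty:
            raise ValidationError(f"array {self.array_id!r}: empty spot table")
        key = ["protein_id", "replicate_index", "channel"]
        dup = self.data.duplicated(subset=key)
        if dup.any():
            first = self.data.loc[dup, key].iloc[0].tolist()
            raise IntegrityError(
                f"array {self.array_id!r}: duplicate spot key {tuple(first)}"
            )
        for col in ("foreground", "background"):
            vals = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"array {self.array_id!r}: non-finite {col}")
            if (vals < 0).any():
                raise ValidationError(f"array {self.array_id!r}: negative {col}")
        bad = set(self.data["channel"]) - set(ISOTYPES)
        if bad:
            raise ValidationError(f"array {self.array_id!r}: unknown channels {bad}")
        return self


@dataclass
class SampleManifest:
    """Assignment of array IDs to study groups (RC = renal cancer, HC = healthy control)."""

    table: pd.DataFrame  # index: array_id; columns: group [, sex, age]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def group_counts(self) -> dict[str, int]:
        counts = self.groups.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def arrays(self, group: str) -> list[str]:
        return list(self.table.index[self.groups == group])

    def validate(self, require_both_groups: bool = True) -> "SampleManifest":
        if self.table.empty:
            raise ValidationError("manifest is empty")
        if "group" not in self.table.columns:
            raise FormatError("manifest missing 'group' column")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise IntegrityError(f"array {dup!r} listed twice in manifest")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValidationError(
                f"manifest group labels outside {GROUPS}: {sorted(bad)}"
            )
        if require_both_groups:
            counts = self.group_counts()
            empty = [g for g, n in counts.items() if n == 0]
            if empty:
                raise ValidationError(f"manifest has empty group(s): {empty}")
        return self


@dataclass
class SNRMatrix:
    """Proteins x samples grid of signal-to-noise ratios for one isotype.

    SNR is the per-spot foreground/background ratio averaged over duplicate
    spots, so every cell is finite and strictly positive.
    """

    isotype: str
    values: pd.DataFrame  # index: protein_id, columns: array_id
    normalized: bool = False

    def validate(self) -> "SNRMatrix":
        if self.isotype not in ISOTYPES:
            raise ValidationError(f"unknown isotype {self.isotype!r}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValidationError("SNR matrix has an empty axis")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("SNR matrix contains non-finite values")
        if (arr <= 0).any():
            raise ValidationError("SNR matrix contains non-positive values")
        return self


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_gpr(
    path: str | Path,
    channel_map: Mapping[str, str],
    *,
    array_id: str | None = None,
    f_template: str = "F{} Median",
    b_template: str = "B{} Median",
    name_column: str = "Name",
    control_patterns: ControlPatterns | None = None,
) -> SpotTable:
    """Parse one GPR-dialect spot table into a :class:`SpotTable`.

    Parameters
    ----------
    channel_map
        Maps scanner wavelength (as it appears in the column names, e.g.
        ``"532"``) to isotype (``"IgG"``/``"IgM"``). Must cover both isotypes
        if both channel column pairs are to be read.
    array_id
        Defaults to the file stem.
    """
    path = Path(path)
    control_patterns = control_patterns or ControlPatterns()
    df = pd.read_csv(path, sep="\t")
    if name_column not in df.columns:
        raise FormatError(f"{path.name}: missing required column {name_column!r}")

    rows = []
    has_replicate = "Replicate" in df.columns
    for wavelength, isotype in channel_map.items():
        fcol = f_template.format(wavelength)
        bcol = b_template.format(wavelength)
        for col in (fcol, bcol):
            if col not in df.columns:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        sub = pd.DataFrame(
            {
                "protein_id": df[name_column].astype(str),
                "block": df["Block"] if "Block" in df else 1,
                "row": df["Row"] if "Row" in df else np.arange(1, len(df) + 1),
                "col": df["Column"] if "Column" in df else 1,
                "channel": isotype,
                "foreground": df[fcol].astype(float),
                "background": df[bcol].astype(float),
            }
        )
        if has_replicate:
            sub["replicate_index"] = df["Replicate"].astype(int)
        else:
            sub["replicate_index"] = sub.groupby("protein_id").cumcount() + 1
        rows.append(sub)

    data = pd.concat(rows, ignore_index=True)
    data["control_class"] = [
        control_patterns.classify(n) for n in data["protein_id"]
    ]
    data = data[SPOT_COLUMNS]
    return SpotTable(array_id or path.stem, data).validate()


def write_gpr(
    table: SpotTable,
    path: str | Path,
    *,
    channel_map: Mapping[str, str],
    f_template: str = "F{} Median",
    b_template: str = "B{} Median",
) -> None:
    """Serialize a :class:`SpotTable` back to the GPR dialect.

    ``channel_map`` is wavelength -> isotype as for :func:`read_gpr`; the two
    channels are joined back into one row per spot position. Deterministic
    byte output for identical inputs.
    """
    inverse = {iso: wl for wl, iso in channel_map.items()}
    frames = {}
    for iso, sub in table.data.groupby("channel"):
        wl = inverse[iso]
        sub = sub.set_index(["protein_id", "replicate_index"])
        frames[wl] = sub[["block", "row", "col", "foreground", "background"]]
    wavelengths = sorted(frames)
    base = frames[wavelengths[0]]
    out = pd.DataFrame(
        {
            "Block": base["block"],
            "Row": base["row"],
            "Column": base["col"],
        }
    )
    for wl in wavelengths:
        out[f_template.format(wl)] = frames[wl]["foreground"].round(4)
        out[b_template.format(wl)] = frames[wl]["background"].round(4)
    out = out.reset_index().rename(
        columns={"protein_id": "Name", "replicate_index": "Replicate"}
    )
    out = out.sort_values(["Name", "Replicate"], kind="mergesort")
    cols = ["Block", "Row", "Column", "Name", "Replicate"] + [
        t.format(wl) for wl in wavelengths for t in (f_template, b_template)
    ]
    out[cols].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest (CSV or TSV with ``array_id`` and ``group`` columns)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path.name}: manifest is empty") from None
    if "array_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path.name}: manifest needs 'array_id' and 'group' columns")
    df["array_id"] = df["array_id"].astype(str)
    df["group"] = df["group"].astype(str).str.strip()
    return SampleManifest(df.set_index("array_id")).validate()


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    path = Path(path)
    manifest.table.reset_index().to_csv(path, sep=_sep_for(path), index=False)


def write_snr_matrix(matrix: SNRMatrix, path: str | Path) -> None:
    """Write an :class:`SNRMatrix` as annotated TSV (full float precision)."""
    matrix.validate()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#isotype={matrix.isotype}\n")
        fh.write(f"#normalized={int(matrix.normalized)}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="protein_id")


def read_snr_matrix(path: str | Path) -> SNRMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col="protein_id")
    df.index.name = None
    if "isotype" not in meta:
        raise FormatError(f"{path.name}: missing #isotype header")
    return SNRMatrix(
        isotype=meta["isotype"],
        values=df,
        normalized=bool(int(meta.get("normalized", "0"))),
    ).validate()


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a screening results table (TSV)."""
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
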