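"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical regime of a dual-channel (IgG/IgM)
proteome-microarray case/control study: 16 renal-cancer (RC) and 16
healthy-control (HC) arrays, ~19,500 proteins spotted in duplicate,
log-normal background signal-to-noise ratios, per-array multiplicative
scale factors, histone H3/H4 positive and BSA negative control spots, and
a minority of planted markers in which a fraction of one group (the
responders) carries elevated reactivity. The ELISA arm emulates a 72 RC /
66 HC validation cohort on control-equipped microtiter plates.

Seroreactivity is modelled as a responder mixture: not every patient
mounts an antibody response, which is exactly the structure the positive-
ratio screening criteria assume. Planted markers sit on a reactive
baseline (antigens eliciting any measurable response are detectable above
the array noise floor); for a Down marker the responders are in the HC
group, so the RC group is the relatively depressed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import (
    ISOTYPES,
    SampleManifest,
    SpotTable,
    SPOT_COLUMNS,
    ValidationError,
)
from .elisa import ELISAPlate


@dataclass(frozen=True)
class PlantedMarker:
    """One planted differential autoantibody."""

    protein_id: str
    isotype: str  # IgG / IgM
    direction: str  # Up / Down
    effect_size: float  # shift in log-SNR, units of the within-protein SD
    prevalence: float  # fraction of the reactive group that responds

    def __post_init__(self) -> None:
        if not 0 < self.prevalence <= 1:
            raise ValidationError("prevalence must lie in (0, 1]")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be positive")
        if self.isotype not in ISOTYPES or self.direction not in ("Up", "Down"):
            raise ValidationError("bad isotype/direction on planted marker")


@dataclass(frozen=True)
class ElisaMarker:
    """One antigen assayed by ELISA, with its planted effect."""

    name: str
    effect_od: float = 0.4  # OD shift carried by RC responders
    prevalence: float = 0.5


@dataclass
class SimConfig:
    """Cohort-generator settings (defaults mirror the study regime)."""

    n_proteins: int = 19500
    n_rc: int = 16
    n_hc: int = 16
    n_duplicates: int = 2
    log_snr_mean: float = 0.3  # background log-SNR location
    protein_sd: float = 0.4  # between-protein spread of baselines
    sample_sd: float = 0.3  # within-protein, between-sample SD (log scale)
    dup_sd: float = 0.1  # duplicate-spot noise (log scale)
    array_scale_sd: float = 0.15  # per-array multiplicative factor, log-SD
    background_level: float = 200.0  # mean background intensity (a.u.)
    background_sd: float = 0.2  # log-SD of background intensity
    reactive_baseline: float = 1.1  # log-SNR baseline given to planted markers
    planted: tuple[PlantedMarker, ...] = ()
    # ELISA arm
    elisa_n_rc: int = 72
    elisa_n_hc: int = 66
    elisa_markers: tuple[ElisaMarker, ...] = (ElisaMarker("MARKER_1"),)
    elisa_baseline_od: float = 0.2
    elisa_noise_sd: float = 0.05
    elisa_pos_control_od: float = 2.0
    elisa_neg_control_od: float = 0.2
    elisa_control_wells: int = 3
    elisa_wells_per_plate: int = 96

    def __post_init__(self) -> None:
        counts = (
            self.n_proteins, self.n_rc, self.n_hc, self.n_duplicates,
            self.elisa_n_rc, self.elisa_n_hc, self.elisa_control_wells,
            self.elisa_wells_per_plate,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all cohort counts must be positive")
        sds = (self.protein_sd, self.sample_sd, self.dup_sd,
               self.array_scale_sd, self.background_sd, self.elisa_noise_sd)
        if any(s < 0 for s in sds):
            raise ValidationError("standard deviations must be >= 0")
        self.planted = tuple(self.planted)
        self.elisa_markers = tuple(self.elisa_markers)
        ids = {m.protein_id for m in self.planted}
        known = set(protein_ids(self.n_proteins))
        if not ids <= known:
            raise ValidationError("planted markers reference unknown proteins")


@dataclass
class SyntheticTruth:
    """Ledger of what was planted, for recovery scoring."""

    markers: list[PlantedMarker]
    responders: dict[tuple[str, str], list[str]]  # (protein, isotype) -> sample ids
    n_rc: int
    n_hc: int
    seed: int
    array_scale: dict[str, float] = field(default_factory=dict)
    elisa_markers: list[ElisaMarker] = field(default_factory=list)
    elisa_responders: dict[str, list[str]] = field(default_factory=dict)


def protein_ids(n: int) -> list[str]:
    return [f"PROT_{i:05d}" for i in range(1, n + 1)]


def plant_markers(
    n: int,
    isotype: str,
    direction: str,
    effect_size: float = 3.0,
    prevalence: float = 0.6,
    start: int = 1,
) -> tuple[PlantedMarker, ...]:
    """Convenience: plant ``n`` markers on consecutive protein IDs."""
    return tuple(
        PlantedMarker(f"PROT_{i:05d}", isotype, direction, effect_size, prevalence)
        for i in range(start, start + n)
    )


_CONTROLS = (  # name, control class, log-SNR location, log-SNR spread
    ("H3", "positive", np.log(30.0), 0.2),
    ("H4", "positive", np.log(30.0), 0.2),
    ("BSA", "negative", 0.0, 0.1),
    ("BSA-biotin", "negative", 0.0, 0.1),
)


def generate_array_cohort(
    config: SimConfig, seed: int
) -> tuple[list[SpotTable], SampleManifest, SyntheticTruth]:
    """Simulate one microarray cohort.

    Per protein p and isotype: baseline log-SNR mu_p ~ Normal(location,
    between-protein SD); planted markers instead sit at the reactive
    baseline. Each sample draws log-SNR ~ Normal(mu_p, sample_sd), plus
    effect_size * sample_sd for responders, plus the array's log scale
    factor. Duplicate spots multiply in LogNormal(0, dup_sd) noise; each
    spot is emitted as an (F, B) pair with B ~ LogNormal(background) and
    F = SNR * B. Identical seeds yield identical cohorts.
    """
    rng = np.random.default_rng(seed)
    n = config.n_proteins
    prots = protein_ids(n)
    prot_index = {p: i for i, p in enumerate(prots)}
    iso_index = {iso: k for k, iso in enumerate(ISOTYPES)}

    rc_ids = [f"RC_{i:02d}" for i in range(1, config.n_rc + 1)]
    hc_ids = [f"HC_{i:02d}" for i in range(1, config.n_hc + 1)]
    array_ids = rc_ids + hc_ids
    n_arrays = len(array_ids)

    mu = rng.normal(config.log_snr_mean, config.protein_sd, size=(n, 2))
    for m in config.planted:
        mu[prot_index[m.protein_id], iso_index[m.isotype]] = config.reactive_baseline

    scale_log = rng.normal(0.0, config.array_scale_sd, size=n_arrays)

    # Responder assignment and the planted log-SNR shifts.
    delta = np.zeros((n, 2, n_arrays))
    responders: dict[tuple[str, str], list[str]] = {}
    for m in config.planted:
        group_ids = rc_ids if m.direction == "Up" else hc_ids
        offset = 0 if m.direction == "Up" else config.n_rc
        mask = rng.random(len(group_ids)) < m.prevalence
        chosen = [sid for sid, hit in zip(group_ids, mask) if hit]
        responders[(m.protein_id, m.isotype)] = chosen
        cols = [offset + group_ids.index(sid) for sid in chosen]
        delta[prot_index[m.protein_id], iso_index[m.isotype], cols] = (
            m.effect_size * config.sample_sd
        )

    ctrl_names = [c[0] for c in _CONTROLS]
    n_spots = (n + len(_CONTROLS)) * config.n_duplicates
    n_cols_grid = 64
    spot_idx = np.arange(n_spots)
    grid = {
        "block": spot_idx // (n_cols_grid * n_cols_grid) + 1,
        "row": (spot_idx // n_cols_grid) % n_cols_grid + 1,
        "col": spot_idx % n_cols_grid + 1,
    }

    tables: list[SpotTable] = []
    for a, array_id in enumerate(array_ids):
        z = rng.standard_normal((n, 2))
        log_snr = mu + config.sample_sd * z + delta[:, :, a] + scale_log[a]
        ctrl_log = np.column_stack(
            [rng.normal(c[2], c[3], size=2) + scale_log[a] for c in _CONTROLS]
        ).T  # controls x isotypes
        full_log = np.vstack([log_snr, ctrl_log])
        dup = rng.normal(
            0.0, config.dup_sd, size=(full_log.shape[0], 2, config.n_duplicates)
        )
        bg = config.background_level * np.exp(
            rng.normal(0.0, config.background_sd, size=dup.shape)
        )
        snr = np.exp(full_log[:, :, None] + dup)
        fg = snr * bg

        names = prots + ctrl_names
        classes = ["none"] * n + [c[1] for c in _CONTROLS]
        frames = []
        for k, iso in enumerate(ISOTYPES):
            for r in range(config.n_duplicates):
                frames.append(
                    pd.DataFrame(
                        {
                            "protein_id": names,
                            "replicate_index": r + 1,
                            "channel": iso,
                            "foreground": fg[:, k, r],
                            "background": bg[:, k, r],
                            "control_class": classes,
                        }
                    )
                )
        data = pd.concat(frames, ignore_index=True)
        data = data.sort_values(
            ["protein_id", "replicate_index", "channel"], kind="mergesort"
        ).reset_index(drop=True)
        for key, vals in grid.items():
            # two channels share a physical spot: repeat each position twice
            data[key] = np.repeat(vals, 2)[: len(data)]
        tables.append(SpotTable(array_id, data[SPOT_COLUMNS]).validate())

    manifest = SampleManifest(
        pd.DataFrame(
            {"array_id": array_ids, "group": ["RC"] * config.n_rc + ["HC"] * config.n_hc}
        ).set_index("array_id")
    ).validate()
    truth = SyntheticTruth(
        markers=list(config.planted),
        responders=responders,
        n_rc=config.n_rc,
        n_hc=config.n_hc,
        seed=seed,
        array_scale={aid: float(np.exp(s)) for aid, s in zip(array_ids, scale_log)},
    )
    return tables, manifest, truth


def generate_elisa_cohort(
    config: SimConfig, seed: int
) -> tuple[list[ELISAPlate], pd.Series, SyntheticTruth]:
    """Simulate the ELISA validation arm.

    One plate series per marker (a plate is coated with a single antigen);
    sample OD = baseline + effect_od for RC responders + Normal noise,
    controls at their configured ODs with the same read noise. Returns the
    plates, a sample_id -> group Series, and the truth ledger.
    """
    rng = np.random.default_rng(seed)
    rc = [f"SER_RC_{i:03d}" for i in range(1, config.elisa_n_rc + 1)]
    hc = [f"SER_HC_{i:03d}" for i in range(1, config.elisa_n_hc + 1)]
    # interleave the groups so no plate is group-confounded (plates carry
    # their own control offsets; a designed run balances groups per plate)
    samples = [
        s
        for pair in zip(rc, hc)
        for s in pair
    ]
    samples += rc[len(hc):] + hc[len(rc):]
    groups = pd.Series(
        ["RC" if s in set(rc) else "HC" for s in samples], index=samples, name="group"
    )

    plates: list[ELISAPlate] = []
    elisa_responders: dict[str, list[str]] = {}
    n_sample_wells = config.elisa_wells_per_plate - 2 * config.elisa_control_wells
    if n_sample_wells <= 0:
        raise ValidationError("no sample wells left on the plate")
    for marker in config.elisa_markers:
        resp_mask = rng.random(len(rc)) < marker.prevalence
        chosen = [sid for sid, hit in zip(rc, resp_mask) if hit]
        elisa_responders[marker.name] = chosen
        effects = {sid: marker.effect_od for sid in chosen}
        for start in range(0, len(samples), n_sample_wells):
            chunk = samples[start : start + n_sample_wells]
            plate_id = f"{marker.name}_P{start // n_sample_wells + 1:02d}"
            rows = []
            for w, sid in enumerate(chunk):
                od = (
                    config.elisa_baseline_od
                    + effects.get(sid, 0.0)
                    + rng.normal(0.0, config.elisa_noise_sd)
                )
                rows.append((f"W{w + 1:03d}", "sample", sid, max(od, 0.001)))
            w0 = len(chunk)
            for j in range(config.elisa_control_wells):
                od = config.elisa_pos_control_od + rng.normal(0, config.elisa_noise_sd)
                rows.append((f"W{w0 + j + 1:03d}", "positive_control", None, max(od, 0.001)))
            for j in range(config.elisa_control_wells):
                od = config.elisa_neg_control_od + rng.normal(0, config.elisa_noise_sd)
                rows.append(
                    (
                        f"W{w0 + config.elisa_control_wells + j + 1:03d}",
                        "negative_control",
                        None,
                        max(od, 0.001),
                    )
                )
            wells = pd.DataFrame(
                rows, columns=["well_id", "role", "sample_id", "od450"]
            )
            plates.append(ELISAPlate(plate_id, wells).validate())

    truth = SyntheticTruth(
        markers=[],
        responders={},
        n_rc=config.elisa_n_rc,
        n_hc=config.elisa_n_hc,
        seed=seed,
        elisa_markers=list(config.elisa_markers),
        elisa_responders=elisa_responders,
    )
    return plates, groups, truth


def recovery_report(truth: SyntheticTruth, screen_results: pd.DataFrame) -> dict:
    """Score a screen against the planted ledger.

    recovery_sensitivity: planted markers recovered with the planted
    direction / planted markers. recovery_fdr: non-planted among all
    Up/Down-labeled markers / labeled (0 when nothing was labeled).
    """
    planted = {(m.protein_id, m.isotype): m.direction for m in truth.markers}
    universe = set(screen_results["protein_id"])
    missing = {p for p, _ in planted} - universe
    if missing:
        raise ValidationError(
            f"planted proteins absent from screen results: {sorted(missing)[:5]}"
        )
    labeled = screen_results[screen_results["label"].isin(["Up", "Down"])]
    labeled_keys = {
        (r.protein_id, r.isotype): r.label for r in labeled.itertuples()
    }
    hits = [
        (key, direction)
        for key, direction in planted.items()
        if labeled_keys.get(key) == direction
    ]
    n_labeled = len(labeled_keys)
    false = [k for k in labeled_keys if k not in planted]
    table = pd.DataFrame(
        [
            {
                "protein_id": key[0],
                "isotype": key[1],
                "planted_direction": direction,
                "called": labeled_keys.get(key, "none"),
            }
            for key, direction in sorted(planted.items())
        ]
    )
    return {
        "recovery_sensitivity": len(hits) / len(planted) if planted else float("nan"),
        "recovery_fdr": len(false) / n_labeled if n_labeled else 0.0,
        "n_planted": len(planted),
        "n_labeled": n_labeled,
        "hits": table,
    }


def generate_marker_stats_table(
    counts: dict[tuple[str, str], int],
    n_unchanged: int = 100,
    seed: int = 0,
    group_size: int = 16,
) -> pd.DataFrame:
    """SYNTHETIC stand-in for a published per-marker statistics table.

    Builds a table with columns protein_id, isotype, cutoff, rc_pos,
    hc_pos, fc, p whose rows are drawn inside the stated class regions:
    ``counts`` maps (isotype, direction) to the number of markers of that
    class, and ``n_unchanged`` near-boundary and null rows are added per
    isotype. Used to exercise the count-check path when the original
    table is not available; this is generated data, not study data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    n = group_size

    def ratio_above(min_frac: float) -> float:
        lo = int(np.floor(min_frac * n)) + 1
        return rng.integers(lo, n + 1) / n

    def ratio_below(max_frac: float) -> float:
        hi = int(np.ceil(max_frac * n)) - 1
        return rng.integers(0, hi + 1) / n

    for (isotype, direction), count in sorted(counts.items()):
        for _ in range(count):
            k += 1
            if direction == "Up":
                rows.append(
                    dict(
                        protein_id=f"SYN_{k:05d}",
                        isotype=isotype,
                        cutoff=round(rng.uniform(2, 20), 3),
                        rc_pos=ratio_above(0.30),
                        hc_pos=ratio_below(0.10),
                        fc=round(1.5 + rng.exponential(1.0), 4),
                        p=float(10 ** rng.uniform(-6, np.log10(0.049))),
                    )
                )
            else:
                rows.append(
                    dict(
                        protein_id=f"SYN_{k:05d}",
                        isotype=isotype,
                        cutoff=round(rng.uniform(2, 20), 3),
                        rc_pos=ratio_below(0.10),
                        hc_pos=ratio_above(0.30),
                        fc=round(rng.uniform(0.1, 0.66), 4),
                        p=float(10 ** rng.uniform(-6, np.log10(0.049))),
                    )
                )
    for isotype in ISOTYPES:
        for _ in range(n_unchanged // 2):
            k += 1
            style = rng.integers(0, 3)
            if style == 0:  # ratio pattern matches Up, fc or p fails
                rows.append(
                    dict(
                        protein_id=f"SYN_{k:05d}", isotype=isotype,
                        cutoff=round(rng.uniform(2, 20), 3),
                        rc_pos=ratio_above(0.30), hc_pos=ratio_below(0.10),
                        fc=round(rng.uniform(1.0, 1.49), 4),
                        p=float(rng.uniform(0.05, 0.9)),
                    )
                )
            elif style == 1:  # ratio pattern matches Down, fc fails
                rows.append(
                    dict(
                        protein_id=f"SYN_{k:05d}", isotype=isotype,
                        cutoff=round(rng.uniform(2, 20), 3),
                        rc_pos=ratio_below(0.10), hc_pos=ratio_above(0.30),
                        fc=round(rng.uniform(0.67, 1.0), 4),
                        p=float(rng.uniform(0.05, 0.9)),
                    )
                )
            else:  # unreactive everywhere
                rows.append(
                    dict(
                        protein_id=f"SYN_{k:05d}", isotype=isotype,
                        cutoff=round(rng.uniform(2, 20), 3),
                        rc_pos=ratio_below(0.10), hc_pos=ratio_below(0.10),
                        fc=round(rng.uniform(0.8, 1.2), 4),
                        p=float(rng.uniform(0.05, 1.0)),
                    )
                )
    return pd.DataFrame(rows)
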