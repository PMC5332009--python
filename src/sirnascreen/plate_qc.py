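"""Plate-level quality control for dual-luciferase siRNA screens.

Every screening plate carries its own controls, and four gates decide
whether a plate enters the analysis:

1. *Fold induction*: the LPS-stimulated NTC wells must show at least a
   5-fold higher reporter ratio than the unstimulated NTC wells.
2. *Transfection efficiency*: siRNA against the renilla reporter must
   knock the renilla channel down by at least 85% relative to unstimulated
   NTC wells.
3. *Pathway positive control*: siRNA against TLR4 must reduce the
   LPS-induced reporter ratio by at least 85% relative to stimulated NTC.
4. *No saturation*: the renilla channel must stay below the instrument
   saturation limit in every well.

This module also implements screen-wide technical-validation metrics:
replicate coefficient of variation (primary tier), pairwise replicate
correlation (secondary tier), and the plate-uniformity / edge-effect test
run on dedicated H/M/L dose plates before the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .screen_io import (EMPTY, NTC, SAMPLE, SIRENILLA, SITLR4, ScreenDataset,
                        ScreenError, parse_well)
from .scoring import log_transform, plate_median_normalize, reporter_ratio


class QCError(ScreenError):
    """A QC statistic cannot be computed (missing controls, ...)."""


DEFAULT_SATURATION_LIMIT = 2 ** 21 - 1  # counts; instrument-dependent


@dataclass(frozen=True)
class QCThresholds:
    min_fold_induction: float = 5.0
    min_renilla_kd: float = 0.85
    min_positive_control_reduction: float = 0.85
    saturation_limit: float = DEFAULT_SATURATION_LIMIT


@dataclass
class QCResult:
    plate_id: str
    fold_induction: float
    renilla_kd: float
    positive_control_reduction: float
    saturated: bool
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)


@dataclass
class UniformityReport:
    """Per-dose positional-uniformity result for one plate.

    ``variation`` is the maximal pairwise difference between the four
    group means divided by the mean of the four group means, in percent;
    a dose passes when variation < 20% (no edge effect).
    """

    plate_id: str
    group_means: dict[str, np.ndarray]
    variation: dict[str, float]
    passed: dict[str, bool]

    @property
    def all_pass(self) -> bool:
        return all(self.passed.values())


def _plate_frame(dataset: ScreenDataset | pd.DataFrame,
                 plate_id: str | None = None) -> pd.DataFrame:
    if isinstance(dataset, ScreenDataset):
        if plate_id is None:
            plates = dataset.plates()
            if len(plates) != 1:
                raise QCError("plate_id required for multi-plate dataset")
            plate_id = plates[0]
        return dataset.plate(plate_id)
    return dataset


def _control_stat(values: np.ndarray, stat: str) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise QCError("no finite control values")
    return float(np.median(values)) if stat == "median" else float(
        np.mean(values))


def _ratios(frame: pd.DataFrame, anno: str, stimulated: bool) -> np.ndarray:
    sel = frame[(frame["well_anno"] == anno)
                & (frame["stimulated"].astype(bool) == stimulated)]
    if sel.empty:
        raise QCError(
            f"no {'stimulated' if stimulated else 'unstimulated'} "
            f"{anno} wells on plate")
    return reporter_ratio(sel["r1"].to_numpy(float),
                          sel["r2"].to_numpy(float))


# --------------------------------------------------------------------------
# the four per-plate gates
# --------------------------------------------------------------------------


def fold_induction(dataset, plate_id: str | None = None,
                   stat: str = "mean") -> float:
    """Mean stimulated-NTC ratio over mean unstimulated-NTC ratio."""
    frame = _plate_frame(dataset, plate_id)
    stim = _control_stat(_ratios(frame, NTC, True), stat)
    unstim = _control_stat(_ratios(frame, NTC, False), stat)
    if unstim == 0:
        raise QCError("unstimulated NTC ratio mean is zero")
    return stim / unstim


def knockdown_efficiency(dataset, plate_id: str | None = None,
                         stat: str = "mean") -> float:
    """1 - mean(R2 of unstimulated siRenilla wells) / mean(R2 of
    unstimulated NTC wells): the transfection-efficiency readout."""
    frame = _plate_frame(dataset, plate_id)
    ren = frame[(frame["well_anno"] == SIRENILLA)
                & (~frame["stimulated"].astype(bool))]
    ntc = frame[(frame["well_anno"] == NTC)
                & (~frame["stimulated"].astype(bool))]
    if ren.empty or ntc.empty:
        raise QCError("need unstimulated siRenilla and NTC wells")
    ntc_mean = _control_stat(ntc["r2"].to_numpy(float), stat)
    if ntc_mean == 0:
        raise QCError("unstimulated NTC renilla mean is zero")
    return 1.0 - _control_stat(ren["r2"].to_numpy(float), stat) / ntc_mean


def positive_control_reduction(dataset, plate_id: str | None = None,
                               control: str = SITLR4,
                               stat: str = "mean") -> float:
    """1 - mean(ratio of stimulated ``control`` wells) / mean(ratio of
    stimulated NTC wells)."""
    frame = _plate_frame(dataset, plate_id)
    ctl = _control_stat(_ratios(frame, control, True), stat)
    ntc = _control_stat(_ratios(frame, NTC, True), stat)
    if ntc == 0:
        raise QCError("stimulated NTC ratio mean is zero")
    return 1.0 - ctl / ntc


def plate_acceptance(dataset, plate_id: str | None = None,
                     thresholds: QCThresholds = QCThresholds(),
                     control: str = SITLR4, stat: str = "mean") -> QCResult:
    """Evaluate the four acceptance gates for one plate.

    A missing control class does not raise; it becomes a failed criterion
    with the reason recorded.
    """
    frame = _plate_frame(dataset, plate_id)
    pid = str(frame["plate_id"].iat[0])
    failed: list[str] = []

    def _try(fn, label):
        try:
            return fn()
        except QCError as exc:
            failed.append(f"{label}: not computable ({exc})")
            return float("nan")

    fold = _try(lambda: fold_induction(frame, stat=stat), "fold_induction")
    kd = _try(lambda: knockdown_efficiency(frame, stat=stat), "renilla_kd")
    pcr = _try(lambda: positive_control_reduction(frame, control=control,
                                                  stat=stat),
               "positive_control_reduction")

    if np.isfinite(fold) and fold < thresholds.min_fold_induction:
        failed.append(
            f"fold_induction {fold:.3g} < {thresholds.min_fold_induction}")
    if np.isfinite(kd) and kd < thresholds.min_renilla_kd:
        failed.append(f"renilla_kd {kd:.3g} < {thresholds.min_renilla_kd}")
    if np.isfinite(pcr) and pcr < thresholds.min_positive_control_reduction:
        failed.append(
            f"positive_control_reduction {pcr:.3g} < "
            f"{thresholds.min_positive_control_reduction}")
    r2 = frame.loc[frame["well_anno"] != EMPTY, "r2"].to_numpy(float)
    saturated = bool(np.any(r2[np.isfinite(r2)] >= thresholds.saturation_limit))
    if saturated:
        failed.append("saturation: the renilla luciferase reading reached "
                      "the saturation limit")
    return QCResult(plate_id=pid, fold_induction=fold, renilla_kd=kd,
                    positive_control_reduction=pcr, saturated=saturated,
                    passed=not failed, failed_criteria=failed)


def qc_screen(dataset: ScreenDataset,
              thresholds: QCThresholds = QCThresholds(),
              control: str = SITLR4) -> list[QCResult]:
    """Per-plate acceptance over a whole dataset.

    For the secondary tier each (plate, week-replicate) copy is gated
    independently, since each physical plate run must meet the criteria.
    """
    results = []
    keys = ["plate_id"]
    if dataset.tier == "secondary":
        keys.append("replicate")
    for key, frame in dataset.frame.groupby(keys, sort=False):
        res = plate_acceptance(frame, thresholds=thresholds, control=control)
        if dataset.tier == "secondary":
            res.plate_id = f"{key[0]}/rep{key[1]}"
        results.append(res)
    return results


def qc_report_frame(results: list[QCResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "PlateID": r.plate_id,
        "FoldInduction": r.fold_induction,
        "RenillaKD": r.renilla_kd,
        "PositiveControlReduction": r.positive_control_reduction,
        "Saturated": r.saturated,
        "Passed": r.passed,
        "FailedCriteria": "; ".join(r.failed_criteria),
    } for r in results])


def write_qc_report(results: list[QCResult], csv_path: str | Path,
                    text_path: str | Path | None = None) -> None:
    frame = qc_report_frame(results)
    frame.to_csv(csv_path, index=False, lineterminator="\n")
    if text_path is not None:
        lines = []
        for r in results:
            status = "PASS" if r.passed else "FAIL"
            lines.append(
                f"{r.plate_id}: {status}  fold={r.fold_induction:.3g} "
                f"kd={r.renilla_kd:.3g} tlr4_red="
                f"{r.positive_control_reduction:.3g}"
                + (f"  [{'; '.join(r.failed_criteria)}]"
                   if r.failed_criteria else ""))
        Path(text_path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# plate uniformity (edge-effect) test
# --------------------------------------------------------------------------


def _uniformity_groups(wells: pd.DataFrame,
                       grouping: str) -> list[np.ndarray]:
    """Partition one dose's wells into 4 groups of readout values."""
    rows = wells["well"].map(lambda w: parse_well(w)[0])
    cols = wells["well"].map(lambda w: parse_well(w)[1])
    values = reporter_ratio(wells["r1"].to_numpy(float),
                            wells["r2"].to_numpy(float))
    if grouping == "column_blocks":
        # contiguous column blocks in plate order: with the repeating
        # 2-column H/M/L pattern these are exactly the 4 pattern repeats.
        uniq = np.sort(pd.unique(cols))
        if len(uniq) < 4:
            raise QCError(f"dose spans {len(uniq)} columns; need >= 4 for "
                          "column-block grouping")
        blocks = np.array_split(uniq, 4)
        return [values[np.isin(cols, b)] for b in blocks]
    if grouping == "quadrant":
        row_half = rows.map(lambda r: r in "ABCDEFGH").to_numpy()
        col_half = (cols <= 12).to_numpy()
        return [values[row_half & col_half], values[row_half & ~col_half],
                values[~row_half & col_half], values[~row_half & ~col_half]]
    raise ValueError(f"unknown grouping: {grouping!r}")


def uniformity_test(dataset: ScreenDataset,
                    dose_maps: dict[str, pd.Series],
                    grouping: str = "column_blocks",
                    max_variation: float = 20.0) -> list[UniformityReport]:
    """Edge-effect test on dedicated uniformity plates.

    ``dose_maps`` maps each plate id to a Series well -> dose label
    (H/M/L).  Per dose, the wells are split into four positional groups
    (default: contiguous column blocks, matching the staggered 2-column
    dose pattern; ``grouping="quadrant"`` is available); the variation
    statistic is max pairwise |difference of group means| / mean of the
    four group means x 100, and a dose passes when it is below
    ``max_variation`` percent.
    """
    reports = []
    for pid in dataset.plates():
        frame = dataset.plate(pid)
        dose_map = dose_maps[pid]
        means: dict[str, np.ndarray] = {}
        variation: dict[str, float] = {}
        passed: dict[str, bool] = {}
        doses = sorted(pd.unique(dose_map.to_numpy()))
        for dose in doses:
            dose_wells = set(dose_map.index[dose_map == dose])
            wells = frame[frame["well"].isin(dose_wells)]
            if len(wells) < 4:
                raise QCError(f"dose {dose} on plate {pid} has "
                              f"{len(wells)} wells; need >= 4")
            groups = _uniformity_groups(wells, grouping)
            gm = np.array([float(np.nanmean(g)) for g in groups])
            var = uniformity_variation(gm)
            means[dose] = gm
            variation[dose] = var
            passed[dose] = var < max_variation
        reports.append(UniformityReport(plate_id=pid, group_means=means,
                                        variation=variation, passed=passed))
    return reports


def uniformity_variation(group_means) -> float:
    """Max pairwise |difference of group means| / mean of group means,
    in percent."""
    gm = np.asarray(group_means, dtype=float)
    if gm.size != 4:
        raise QCError(f"expected 4 group means, got {gm.size}")
    spread = float(gm.max() - gm.min())
    center = float(gm.mean())
    if center == 0:
        raise QCError("mean of group means is zero")
    return spread / center * 100.0


def read_dose_map(path: str | Path) -> pd.Series:
    """CSV with columns Well,Dose -> Series indexed by canonical well."""
    df = pd.read_csv(path, dtype=str)
    if not {"Well", "Dose"} <= set(df.columns):
        raise QCError("dose map needs Well and Dose columns")
    wells = [  # canonicalize labels
        f"{r}{c:02d}" for r, c in (parse_well(w) for w in df["Well"])]
    return pd.Series(df["Dose"].str.strip().to_numpy(), index=wells)


# --------------------------------------------------------------------------
# replicate reproducibility
# --------------------------------------------------------------------------


def replicate_cv(dataset: ScreenDataset) -> tuple[pd.Series, float, list[str]]:
    """Coefficient of variation of the four raw replicate-well ratios of
    each SMARTpool, and the unweighted screen mean.

    Returns ``(per_pool_cv, screen_mean_cv, excluded_pools)``; pools with a
    zero or non-finite mean ratio are excluded and reported.
    """
    samples = dataset.samples()
    cvs, excluded = {}, []
    for sid, grp in samples.groupby("sirna_id", sort=False):
        ratio = reporter_ratio(grp["r1"].to_numpy(float),
                               grp["r2"].to_numpy(float))
        ratio = ratio[np.isfinite(ratio)]
        if ratio.size < 2 or ratio.mean() == 0:
            excluded.append(sid)
            continue
        cvs[sid] = float(np.std(ratio, ddof=1) / ratio.mean())
    series = pd.Series(cvs, dtype=float)
    mean_cv = float(series.mean()) if len(series) else float("nan")
    return series, mean_cv, excluded


def replicate_correlation(dataset_or_vectors, log: bool = True,
                          normalize: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlation between screen replicates.

    For a secondary :class:`ScreenDataset`, sample wells are aligned on
    (plate, well) across the week replicates; values are per-plate
    sample-median normalized and log2 transformed by default (``log=False``
    / ``normalize=False`` give raw-ratio correlations).  Alternatively a
    list of aligned value vectors may be passed directly.
    """
    if isinstance(dataset_or_vectors, ScreenDataset):
        ds = dataset_or_vectors
        samples = ds.frame[ds.frame["well_anno"] == SAMPLE].copy()
        samples["value"] = reporter_ratio(samples["r1"].to_numpy(float),
                                          samples["r2"].to_numpy(float))
        if normalize:
            parts = []
            for _, chunk in samples.groupby(["plate_id", "replicate"],
                                            sort=False):
                chunk = chunk.copy()
                chunk["value"] = plate_median_normalize(
                    chunk["value"].to_numpy(float))
                parts.append(chunk)
            samples = pd.concat(parts, ignore_index=True)
        if log:
            samples["value"] = log_transform(samples["value"].to_numpy(float))
        pivot = samples.pivot_table(index=["plate_id", "well"],
                                    columns="replicate", values="value")
        vectors = [pivot[c].to_numpy(float) for c in pivot.columns]
        labels = [f"rep{c}" for c in pivot.columns]
    else:
        vectors = [np.asarray(v, dtype=float) for v in dataset_or_vectors]
        labels = [f"rep{i + 1}" for i in range(len(vectors))]
    n = len(vectors)
    if n < 2:
        raise QCError("need at least two replicate vectors")
    length = len(vectors[0])
    if length < 3 or any(len(v) != length for v in vectors):
        raise QCError("replicate vectors must be aligned with length >= 3")
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(vectors[i]) & np.isfinite(vectors[j])
            xi, xj = vectors[i][mask], vectors[j][mask]
            if xi.size < 3 or np.std(xi) == 0 or np.std(xj) == 0:
                raise QCError(
                    f"correlation undefined between {labels[i]} and "
                    f"{labels[j]} (zero variance or too few points)")
            mat[i, j] = mat[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    return pd.DataFrame(mat, index=labels, columns=labels)
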