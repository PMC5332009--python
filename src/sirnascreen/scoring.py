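"""Normalization and robust z-scoring of dual-luciferase screen data.

The scoring chain mirrors standard high-throughput-screening practice:

1. reporter ratio R1/R2 per well (firefly over renilla; the renilla channel
   absorbs cell-number and viability variation),
2. per-plate normalization of the ratio to the intra-plate median of the
   *sample* wells (controls are divided by the same sample median),
3. for the secondary tier only, a log transform (screen ratios are closer
   to log-normal; replicate distributions are more nearly Gaussian on the
   log scale),
4. the robust z-score, (x - median) / (1.4826 * MAD), with center and
   scale estimated on the sample wells of each plate replicate and applied
   to control wells as well,
5. tier-specific aggregation: the primary tier averages the four
   within-plate replicate wells of each siRNA SMARTpool into a single gene
   score; the secondary tier averages each individual siRNA over its three
   across-week plate replicates and then takes the median over the six
   independent siRNAs per gene.  The median over six sequences is the
   screen's defence against seed-driven off-target effects: a phenotype
   carried by a single siRNA cannot move the gene score far.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_io import SAMPLE, ScreenDataset, ScreenError

MAD_CONSTANT = 1.4826  # normal-consistency factor for the MAD


class ScoringError(ScreenError):
    """Scoring cannot proceed (degenerate plate, too few wells...)."""


class FlaggedWellError(ScreenError):
    """A single well's readout is unusable (e.g. renilla channel zero)."""


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------


def reporter_ratio(r1, r2):
    """Firefly/renilla ratio R1/R2, the viability-corrected TNF readout.

    Scalars with ``r2 == 0`` raise :class:`FlaggedWellError`; for array
    input the offending wells become NaN (to be excluded and reported by
    the caller).
    """
    if np.isscalar(r1) and np.isscalar(r2):
        if r2 == 0 or not np.isfinite(r2):
            raise FlaggedWellError(f"renilla readout unusable: r2={r2!r}")
        return float(r1) / float(r2)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = r1 / r2
    ratio[~np.isfinite(ratio)] = np.nan
    return ratio


def plate_median_normalize(values, sample_mask=None):
    """Divide every value by the median of the sample wells.

    ``sample_mask`` selects the wells defining the median (default: all
    finite values).  The median must be positive.
    """
    values = np.asarray(values, dtype=float)
    if sample_mask is None:
        sample_mask = np.ones(len(values), dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    sample = values[sample_mask & np.isfinite(values)]
    if sample.size == 0:
        raise ScoringError("no finite sample-well values to normalize to")
    med = float(np.median(sample))
    if med <= 0:
        raise ScoringError(f"plate sample median must be > 0, got {med}")
    return values / med


def log_transform(values, base: float = 2.0):
    """Elementwise logarithm of normalized ratios (default base 2)."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if np.any(values[finite] <= 0):
        raise FlaggedWellError("log transform requires positive values")
    out = np.full(values.shape, np.nan)
    out[finite] = np.log(values[finite]) / np.log(base)
    return out


def robust_center_scale(values) -> tuple[float, float, bool]:
    """Median and scaled-MAD of the finite entries of ``values``.

    Returns ``(center, scale, used_fallback)``.  If the MAD is zero but the
    values still vary, the sample standard deviation is used instead (with
    a warning).  A perfectly constant vector gets scale 0, which callers
    treat as "all z-scores are zero".
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ScoringError(f"need >= 2 finite values, got {x.size}")
    center = float(np.median(x))
    mad = float(np.median(np.abs(x - center)))
    if mad > 0:
        return center, MAD_CONSTANT * mad, False
    sd = float(np.std(x, ddof=1))
    if sd > 0:
        warnings.warn("MAD is zero; falling back to sample standard "
                      "deviation", RuntimeWarning, stacklevel=2)
        return center, sd, True
    warnings.warn("all values identical; z-scores defined as 0",
                  RuntimeWarning, stacklevel=2)
    return center, 0.0, True


def robust_z(values, estimation_values=None):
    """Robust z-score: (x - median) / (1.4826 * MAD).

    ``estimation_values`` optionally supplies the set on which center and
    scale are estimated (e.g. sample wells only) while the transform is
    applied to all of ``values``.
    """
    values = np.asarray(values, dtype=float)
    est = values if estimation_values is None else np.asarray(
        estimation_values, dtype=float)
    center, scale, _ = robust_center_scale(est)
    if scale == 0.0:
        return np.where(np.isfinite(values), 0.0, np.nan)
    return (values - center) / scale


def aggregate_primary(z_by_well, min_wells: int = 2) -> float:
    """Mean of the (up to four) replicate-well robust z-scores of one
    SMARTpool; NaN if fewer than ``min_wells`` usable wells remain."""
    z = np.asarray(z_by_well, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < min_wells:
        return float("nan")
    return float(np.mean(z))


def aggregate_secondary(z_by_replicate_by_sirna,
                        min_replicates: int = 2) -> tuple[np.ndarray, float]:
    """Per-siRNA mean over replicates, then gene score as the median of the
    six per-siRNA values.

    ``z_by_replicate_by_sirna`` is a (6, n_replicates) array-like; rows are
    siRNAs.  Returns ``(per_sirna_z, gene_median_z)``.
    """
    z = np.asarray(z_by_replicate_by_sirna, dtype=float)
    if z.ndim != 2 or z.shape[0] != 6:
        raise ScoringError(
            f"expected exactly 6 siRNAs per gene, got shape {z.shape}")
    per_sirna = np.full(6, np.nan)
    for i in range(6):
        row = z[i][np.isfinite(z[i])]
        if row.size >= min_replicates:
            per_sirna[i] = row.mean()
    if np.isnan(per_sirna).any():
        return per_sirna, float("nan")
    return per_sirna, float(np.median(per_sirna))


# --------------------------------------------------------------------------
# dataset-level scoring
# --------------------------------------------------------------------------


@dataclass
class ScoreResult:
    """Scored screen: per-well and aggregated tables plus exclusion flags.

    ``well_frame`` extends the dataset frame with ``ratio``, ``normalized``
    (and ``log2`` for the secondary tier) and ``zscore`` columns.
    ``gene_frame`` holds one row per gene with the tier's aggregate score.
    """

    tier: str
    well_frame: pd.DataFrame
    gene_frame: pd.DataFrame
    sirna_frame: pd.DataFrame | None = None
    flagged_wells: list[str] = field(default_factory=list)
    unscorable: list[str] = field(default_factory=list)

    def gene_scores(self) -> pd.Series:
        return self.gene_frame.set_index("gene_symbol")["score"]

    def export_gene_table(self, path) -> None:
        """CSV with the deposit's score column names for diff-ability."""
        out = self.gene_frame.rename(columns={
            "score": "Zscore" if self.tier == "primary"
            else "ZscoreGeneMedian",
            "gene_symbol": "GeneSymbol",
        })
        out.to_csv(path, index=False, lineterminator="\n")


def _score_plate_wells(frame: pd.DataFrame, log2: bool,
                       min_sample_wells: int) -> pd.DataFrame:
    """Ratio -> sample-median normalization -> (log) -> robust z for the
    wells of one plate replicate.  Center/scale come from sample wells only
    and are applied to controls too."""
    out = frame.copy()
    ratio = reporter_ratio(out["r1"].to_numpy(float), out["r2"].to_numpy(float))
    out["ratio"] = ratio
    is_sample = (out["well_anno"] == SAMPLE).to_numpy()
    n_sample = int(np.sum(is_sample & np.isfinite(ratio)))
    if n_sample < min_sample_wells:
        raise ScoringError(
            f"plate {out['plate_id'].iat[0]}: {n_sample} usable sample wells "
            f"< required {min_sample_wells}")
    norm = plate_median_normalize(ratio, sample_mask=is_sample)
    out["normalized"] = norm
    values = norm
    if log2:
        values = log_transform(norm)
        out["log2"] = values
    out["zscore"] = robust_z(values, estimation_values=values[is_sample])
    return out


def score_primary(dataset: ScreenDataset, min_wells: int = 2,
                  min_sample_wells: int = 8) -> ScoreResult:
    """Score a primary (SMARTpool) screen.

    Robust z per plate on unlogged median-normalized ratios; gene score =
    mean z of the four within-plate replicate wells (minimum ``min_wells``
    usable wells, else the gene is reported unscorable).
    """
    if dataset.tier != "primary":
        raise ScoringError(f"expected primary dataset, got {dataset.tier!r}")
    scored = [
        _score_plate_wells(plate, log2=False,
                           min_sample_wells=min_sample_wells)
        for _, plate in dataset.frame.groupby("plate_id", sort=False)
    ]
    well_frame = pd.concat(scored, ignore_index=True)
    flagged = well_frame.loc[
        well_frame["ratio"].isna() & (well_frame["well_anno"] != "empty"),
        ["plate_id", "well"]]
    flagged_wells = [f"{p}:{w}" for p, w in flagged.itertuples(index=False)]

    samples = well_frame[well_frame["well_anno"] == SAMPLE]
    rows, unscorable = [], []
    for (sid, gene, entrez), grp in samples.groupby(
            ["sirna_id", "gene_symbol", "entrez_id"], sort=False,
            dropna=False):
        score = aggregate_primary(grp["zscore"].to_numpy(float),
                                  min_wells=min_wells)
        n_rep = int(np.isfinite(grp["zscore"].to_numpy(float)).sum())
        if np.isnan(score):
            unscorable.append(gene)
        rows.append({"gene_symbol": gene, "entrez_id": entrez,
                     "sirna_id": sid, "score": score, "n_replicates": n_rep})
    gene_frame = pd.DataFrame(rows)
    return ScoreResult(tier="primary", well_frame=well_frame,
                       gene_frame=gene_frame, flagged_wells=flagged_wells,
                       unscorable=unscorable)


def score_secondary(dataset: ScreenDataset, min_replicates: int = 2,
                    min_sample_wells: int = 8) -> ScoreResult:
    """Score a secondary (six-siRNAs-per-gene) screen.

    Robust z per plate replicate on log2 median-normalized ratios;
    per-siRNA z = mean over the three week replicates; gene score = median
    of the six per-siRNA z values.
    """
    if dataset.tier != "secondary":
        raise ScoringError(f"expected secondary dataset, got {dataset.tier!r}")
    scored = [
        _score_plate_wells(chunk, log2=True,
                           min_sample_wells=min_sample_wells)
        for _, chunk in dataset.frame.groupby(["plate_id", "replicate"],
                                              sort=False)
    ]
    well_frame = pd.concat(scored, ignore_index=True)
    samples = well_frame[well_frame["well_anno"] == SAMPLE]

    sirna_rows = []
    for (sid, gene), grp in samples.groupby(["sirna_id", "gene_symbol"],
                                            sort=False):
        z = grp["zscore"].to_numpy(float)
        z = z[np.isfinite(z)]
        sirna_rows.append({
            "sirna_id": sid, "gene_symbol": gene,
            "score": float(z.mean()) if z.size >= min_replicates
            else float("nan"),
            "n_replicates": int(z.size),
        })
    sirna_frame = pd.DataFrame(sirna_rows)

    gene_rows, unscorable = [], []
    for gene, grp in sirna_frame.groupby("gene_symbol", sort=False):
        if len(grp) != 6:
            raise ScoringError(
                f"gene {gene}: {len(grp)} siRNAs, expected exactly 6")
        per_sirna = grp["score"].to_numpy(float)
        if np.isnan(per_sirna).any():
            unscorable.append(gene)
            score = float("nan")
        else:
            score = float(np.median(per_sirna))
        gene_rows.append({"gene_symbol": gene, "score": score,
                          "n_sirnas": int(np.isfinite(per_sirna).sum())})
    gene_frame = pd.DataFrame(gene_rows)
    return ScoreResult(tier="secondary", well_frame=well_frame,
                       gene_frame=gene_frame, sirna_frame=sirna_frame,
                       unscorable=unscorable)
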