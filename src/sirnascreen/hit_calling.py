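"""Tiered hit selection for the LPS/TNF reporter screen.

Knocking down a *positive* regulator of the pathway lowers the LPS-induced
reporter ratio (negative z-score); knocking down a *negative* regulator
raises it.  The primary tier calls hits by fixed thresholds on the
per-gene mean robust z-score (<= -1.5 positive regulators, >= +2.8
negative regulators — thresholds chosen from the scores of known pathway
components such as TLR4 at -2.3).  Canonical-pathway genes are flagged
rather than carried forward, since the screen's goal is novel regulators.

Downstream filters:

* *expression filter* — a hit must be detectably expressed in the assay
  cells (microarray detection p < 0.1 in at least one of the +/-LPS
  conditions), otherwise it is re-flagged ``not_expressed``;
* *secondary candidate selection* — rank-based: the n lowest and n highest
  gene-median z-scores after removing the proteasome-component exclusion
  list (proteasome knockdown blocks NF-kB signalling nonspecifically);
* *tertiary multi-ligand confirmation* — the fractional effect
  F = readout / NTC readout per stimulus; a positive-regulator candidate
  is confirmed by a >30% reduction (F < 0.70), a negative-regulator
  candidate by a >25% increase (F > 1.25), with at least one stimulus
  other than LPS.

Activity scores reproduce the public-deposit binning: 0/25/50/75/100 by
strictly exceeding per-tier z cutpoints, outcome 2 ("active") for scores
of at least 50, and controls fixed at score 0 / outcome 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .screen_io import ExpressionTable, ScreenError

THETA_POS = -1.5
THETA_NEG = 2.8

# Canonical TLR4-pathway genes named as controls/known hits; shipped as a
# convenience default — the full exclusion list is user-supplied.
DEFAULT_CANONICAL_EXCLUSIONS = (
    "TLR4", "LY96", "CD14", "MYD88", "TIRAP", "IRAK1", "IKBKG", "MAP3K7",
)

TERTIARY_STIMULI = ("LPS", "P3C", "PGN", "R848", "P2C", "FLG", "BCG_extract")


class HitCallingError(ScreenError):
    pass


# --------------------------------------------------------------------------
# activity-score binning (deposit schema)
# --------------------------------------------------------------------------

# (negative cutpoints, positive cutpoints) per tier; bin k (score 25*k)
# is earned by strictly exceeding cutpoint k-1 in either tail.
_ACTIVITY_CUTS = {
    "primary": ((-1.0, -1.5, -2.0, -2.5), (1.0, 2.8, 4.0, 5.0)),
    "secondary": ((-0.75, -1.0, -1.5, -2.0), (1.0, 1.5, 2.0, 2.5)),
}


def activity_score(z: float, tier: str = "primary",
                   is_control: bool = False) -> tuple[int, int]:
    """Deposit activity score (0/25/50/75/100) and outcome (1/2/4).

    The score is the highest bin whose strict inequality holds (z strictly
    below the negative cutpoint or strictly above the positive one);
    outcome is 2 ("active") iff score >= 50, else 1, and control wells are
    fixed at (0, 4).
    """
    if is_control:
        return 0, 4
    neg, pos = _ACTIVITY_CUTS[tier]
    if not np.isfinite(z):
        raise HitCallingError(f"activity score needs a finite z, got {z!r}")
    score = 0
    for k in range(4):
        if z < neg[k] or z > pos[k]:
            score = 25 * (k + 1)
    return score, (2 if score >= 50 else 1)


def activity_scores(z: Iterable[float], tier: str = "primary",
                    is_control=None) -> pd.DataFrame:
    """Vectorized :func:`activity_score`."""
    z = np.asarray(list(z), dtype=float)
    if is_control is None:
        is_control = np.zeros(len(z), dtype=bool)
    rows = [activity_score(v, tier=tier, is_control=bool(c))
            for v, c in zip(z, is_control)]
    return pd.DataFrame(rows, columns=["activity_score", "outcome"])


# --------------------------------------------------------------------------
# primary hit calling
# --------------------------------------------------------------------------


def call_primary_hits(scores: pd.Series | Mapping[str, float],
                      theta_pos: float = THETA_POS,
                      theta_neg: float = THETA_NEG,
                      exclusions: Iterable[str] = (),
                      strict_boundaries: bool = False) -> pd.DataFrame:
    """Threshold the per-gene primary scores into regulator calls.

    Inclusive thresholds by default (score <= theta_pos is a positive
    regulator, score >= theta_neg a negative regulator), matching the
    stated ">=2.8" selection rule; ``strict_boundaries=True`` switches to
    the strict inequalities of the deposit's activity bins.  Genes on the
    exclusion list are flagged ``canonical_pathway`` and not called.

    Returns a hit table with columns ``score``, ``call``,
    ``excluded_reason``, ``activity_score`` and ``outcome``, indexed by
    gene symbol.
    """
    scores = pd.Series(dict(scores) if not isinstance(scores, pd.Series)
                       else scores, dtype=float)
    if scores.isna().any():
        bad = scores.index[scores.isna()][0]
        raise HitCallingError(f"non-finite score for gene {bad!r}")
    exclusions = {str(g) for g in exclusions}
    if strict_boundaries:
        pos = scores < theta_pos
        neg = scores > theta_neg
    else:
        pos = scores <= theta_pos
        neg = scores >= theta_neg
    call = np.where(pos, "positive_regulator",
                    np.where(neg, "negative_regulator", "none"))
    excluded = scores.index.isin(exclusions)
    table = pd.DataFrame({
        "score": scores,
        "call": np.where(excluded, "none", call),
        "excluded_reason": np.where(excluded, "canonical_pathway", "none"),
    }, index=scores.index)
    acts = activity_scores(scores.to_numpy(), tier="primary")
    table["activity_score"] = acts["activity_score"].to_numpy()
    table["outcome"] = acts["outcome"].to_numpy()
    table.index.name = "gene_symbol"
    return table


def hit_counts(table: pd.DataFrame) -> dict[str, int]:
    return {
        "positive_regulator": int((table["call"] == "positive_regulator").sum()),
        "negative_regulator": int((table["call"] == "negative_regulator").sum()),
        "none": int((table["call"] == "none").sum()),
        "excluded": int((table["excluded_reason"] != "none").sum()),
    }


def expression_filter(hits: pd.DataFrame, expr: ExpressionTable,
                      p_cut: float = 0.1) -> pd.DataFrame:
    """Re-flag called hits that are not expressed in the assay cells.

    A gene is expressed iff its detection p-value is strictly below
    ``p_cut`` in at least one of the two conditions; p >= p_cut in both
    means ``not_expressed`` and the call is withdrawn.  Genes absent from
    the expression table pass through with ``unmeasured_expression=True``.
    """
    out = hits.copy()
    out["unmeasured_expression"] = False
    for gene in out.index:
        if out.at[gene, "call"] == "none":
            continue
        expressed = expr.is_expressed(gene, p_cut=p_cut)
        if expressed is None:
            out.at[gene, "unmeasured_expression"] = True
        elif not expressed:
            out.at[gene, "call"] = "none"
            out.at[gene, "excluded_reason"] = "not_expressed"
    return out


# --------------------------------------------------------------------------
# secondary candidate selection
# --------------------------------------------------------------------------


def _support_counts(sirna_scores: pd.DataFrame | None, genes: pd.Index,
                    threshold: float, side: str) -> pd.Series:
    """Number of individual siRNAs per gene beyond the threshold (used as
    the first tie-break)."""
    if sirna_scores is None:
        return pd.Series(0, index=genes)
    s = sirna_scores
    beyond = s["score"] <= threshold if side == "pos" else s["score"] >= threshold
    counts = s[beyond].groupby("gene_symbol").size()
    return counts.reindex(genes, fill_value=0)


def select_secondary_candidates(gene_median_z: pd.Series | Mapping[str, float],
                                n_pos: int = 26, n_neg: int = 13,
                                exclusions: Iterable[str] = (),
                                sirna_scores: pd.DataFrame | None = None,
                                support_thresholds: tuple[float, float] =
                                (THETA_POS, THETA_NEG),
                                ) -> tuple[list[str], list[str]]:
    """Rank-based selection of secondary-screen candidates.

    After removing excluded genes (e.g. proteasome components), returns
    the ``n_pos`` genes with the lowest gene-median z-scores and the
    ``n_neg`` genes with the highest.  Ties at the cut are broken by (a)
    more individual siRNAs beyond the tier threshold, then (b)
    lexicographic gene symbol — fully deterministic.
    """
    scores = pd.Series(dict(gene_median_z)
                       if not isinstance(gene_median_z, pd.Series)
                       else gene_median_z, dtype=float)
    scores = scores.drop(index=[g for g in exclusions if g in scores.index])
    if n_pos + n_neg > len(scores):
        raise HitCallingError(
            f"requested {n_pos}+{n_neg} candidates from {len(scores)} genes")
    sup_pos = _support_counts(sirna_scores, scores.index,
                              support_thresholds[0], "pos")
    sup_neg = _support_counts(sirna_scores, scores.index,
                              support_thresholds[1], "neg")
    pos_order = sorted(scores.index,
                       key=lambda g: (scores[g], -sup_pos[g], g))
    neg_order = sorted(scores.index,
                       key=lambda g: (-scores[g], -sup_neg[g], g))
    return pos_order[:n_pos], neg_order[:n_neg]


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


# --------------------------------------------------------------------------
# tertiary multi-ligand confirmation
# --------------------------------------------------------------------------


@dataclass
class TertiaryResult:
    gene: str
    fractional_effect: dict[str, float]
    confirmed_positive: bool
    confirmed_negative: bool
    supporting_stimuli: list[str] = field(default_factory=list)
    dropped_stimuli: list[str] = field(default_factory=list)


def tertiary_classify(readouts: pd.DataFrame,
                      ntc_readouts: pd.Series | Mapping[str, float],
                      reduce_cut: float = 0.30,
                      increase_cut: float = 0.25) -> list[TertiaryResult]:
    """Classify tertiary candidates by their fractional effect per stimulus.

    ``readouts`` has one row per gene and one column per stimulus (mean
    reporter readout of the siRNA-transfected wells); ``ntc_readouts``
    gives the matched NTC5 readout per stimulus.  F = readout / NTC.
    A candidate is confirmed as a positive regulator when F < 1 -
    ``reduce_cut`` (>30% reduction) for at least one stimulus other than
    LPS, and as a negative regulator when F > 1 + ``increase_cut`` (>25%
    increase).  Stimuli with a missing or non-positive NTC readout are
    dropped with a warning entry in the result.
    """
    ntc = pd.Series(dict(ntc_readouts)
                    if not isinstance(ntc_readouts, pd.Series)
                    else ntc_readouts, dtype=float)
    usable, dropped = [], []
    for stim in readouts.columns:
        if stim in ntc.index and np.isfinite(ntc[stim]) and ntc[stim] > 0:
            usable.append(stim)
        else:
            dropped.append(stim)
    non_lps = [s for s in usable if s != "LPS"]
    if not non_lps:
        raise HitCallingError(
            "tertiary panel needs LPS plus at least one other stimulus "
            "with a usable NTC readout")
    results = []
    for gene, row in readouts.iterrows():
        F = {s: float(row[s] / ntc[s]) for s in usable}
        support_pos = [s for s in non_lps if F[s] < 1.0 - reduce_cut]
        support_neg = [s for s in non_lps if F[s] > 1.0 + increase_cut]
        results.append(TertiaryResult(
            gene=str(gene), fractional_effect=F,
            confirmed_positive=bool(support_pos),
            confirmed_negative=bool(support_neg),
            supporting_stimuli=sorted(set(support_pos) | set(support_neg)),
            dropped_stimuli=list(dropped)))
    return results


def tertiary_frame(results: list[TertiaryResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"GeneSymbol": r.gene}
        row.update({f"F_{s}": v for s, v in r.fractional_effect.items()})
        row["ConfirmedPositive"] = r.confirmed_positive
        row["ConfirmedNegative"] = r.confirmed_negative
        row["SupportingStimuli"] = ";".join(r.supporting_stimuli)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------


def write_hit_table(table: pd.DataFrame, path: str | Path) -> Path:
    out = table.reset_index().rename(columns={
        "gene_symbol": "GeneSymbol", "score": "Zscore", "call": "Call",
        "excluded_reason": "ExcludedReason",
        "activity_score": "ActivityScore", "outcome": "Outcome"})
    path = Path(path)
    out.to_csv(path, index=False, lineterminator="\n")
    return path
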