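"""Synthetic dual-luciferase screens with planted ground truth.

The generator emits 384-well screen datasets with the exact layouts,
control classes and replicate geometries of the real screens — primary
plates with four within-plate replicate wells per siRNA SMARTpool and
controls in columns 10/11/24, secondary plates with six independent siRNAs
per gene, an empty outer frame, controls in columns 11-13/22 and three
across-week plate replicates — so every analysis stage can be verified
without downloading anything.

Signal model (multiplicative throughout):

* renilla channel ``R2 = baseline * viability * plate_factor * edge``,
  where viability is a shared per-well lognormal (cell number); an
  siRenilla well additionally multiplies R2 by the knockdown residual;
* firefly channel ``R1 = R2 * basal_ratio * induction^stimulated *
  effect * noise * edge``, so the reporter ratio R1/R2 cancels viability
  and plate factors exactly — the design rationale of the dual-reporter
  assay — while gene effects, measurement noise and one power of any edge
  gradient survive in the ratio.

Planted regulator effects act multiplicatively on the induced ratio:
knocking down a positive regulator scales it below 1 (e.g. the TLR4
positive control leaves ~12% residual induction), a negative regulator
above 1.  Secondary-tier siRNAs draw individual on-target efficacies and
may additionally acquire a single-siRNA off-target effect, the failure
mode the gene-median aggregation is designed to absorb.

Generation is a pure function of (config, seed): identical inputs give
byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .screen_io import (EMPTY, LIPID_ONLY, NTC, PLATE_ROWS, SAMPLE,
                        SIIKBKG, SIIRAK1, SIMAP3K7, SIRENILLA, SITLR4,
                        ControlScheme, ExpressionTable, ScreenDataset,
                        ScreenError, format_well, write_screen_table)


class LayoutError(ScreenError):
    """Requested simulation does not fit the plate layout."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic screen.

    Defaults are calibrated to the study conditions the analysis assumes:
    ~10-fold LPS induction (comfortably above the 5-fold acceptance gate),
    replicate noise CV 0.15 (the primary screen's observed scale), 95%
    renilla knockdown in siRenilla wells and 88% residual-induction
    reduction in siTLR4 wells (both clearing their 85% gates).
    """

    n_genes: int = 320
    baseline_r2: float = 2.0e5          # counts, renilla channel
    basal_ratio: float = 0.05           # unstimulated R1/R2
    induction_fold: float = 10.0        # LPS induction of the ratio
    noise_cv: float = 0.15              # per-well ratio noise (lognormal CV)
    viability_cv: float = 0.10          # shared cell-number noise on R1 & R2
    plate_factor_sd: float = 0.10       # lognormal sigma of plate/week factor
    edge_gradient: float = 0.0          # column-wise multiplicative span
    frac_pos: float = 0.02              # fraction of genes: positive regs
    frac_neg: float = 0.013             # fraction of genes: negative regs
    pos_effect: tuple[float, float] = (0.1, 0.6)   # U-range, ratio multiplier
    neg_effect: tuple[float, float] = (1.8, 4.0)
    renilla_kd_effect: float = 0.05     # residual R2 in siRenilla wells
    tlr4_effect: float = 0.12           # residual induction, siTLR4 wells
    ikbkg_effect: float = 0.20
    irak1_effect: float = 0.35
    map3k7_effect: float = 0.30
    efficacy_range: tuple[float, float] = (0.6, 1.0)  # secondary per-siRNA
    ote_rate: float = 0.05              # P(single siRNA gains spurious effect)
    expressed_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_pos", "frac_neg", "ote_rate", "expressed_fraction",
                     "renilla_kd_effect", "tlr4_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("baseline_r2", "basal_ratio", "induction_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.induction_fold < 1:
            raise ValueError("induction_fold must be >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["pos_effect"] = list(d["pos_effect"])
        d["neg_effect"] = list(d["neg_effect"])
        d["efficacy_range"] = list(d["efficacy_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("pos_effect", "neg_effect", "efficacy_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth backing a simulated screen."""

    genes: pd.DataFrame    # gene_symbol, entrez_id, klass, effect
    sirnas: pd.DataFrame   # sirna_id, gene_symbol, efficacy, ote, net_effect
    plates: pd.DataFrame   # plate_id, replicate, plate_factor
    config: SimConfig

    def effect_of(self, gene: str) -> float:
        return float(self.genes.set_index("gene_symbol").at[gene, "effect"])

    def genes_of_class(self, klass: str) -> list[str]:
        g = self.genes
        return list(g.loc[g["klass"] == klass, "gene_symbol"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.genes.to_csv(path, index=False, lineterminator="\n")
        return path


# --------------------------------------------------------------------------
# low-level helpers
# --------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


def _edge_factor(col: int, gradient: float) -> float:
    """Linear column-wise multiplicative trend spanning ``gradient``
    (factor 1 - g/2 at column 1 up to 1 + g/2 at column 24)."""
    if gradient == 0:
        return 1.0
    return 1.0 + gradient * ((col - 1) / (24 - 1) - 0.5)


def _control_ratio_effect(anno: str, cfg: SimConfig) -> float:
    return {
        NTC: 1.0, LIPID_ONLY: 1.0,
        SITLR4: cfg.tlr4_effect, SIIKBKG: cfg.ikbkg_effect,
        SIIRAK1: cfg.irak1_effect, SIMAP3K7: cfg.map3k7_effect,
        SIRENILLA: 1.0,
    }[anno]


# Primary-plate control layout: columns 10, 11 and 24, each control class
# with at least three wells.
_PRIMARY_CONTROL_MAP: list[tuple[str, int, str, bool]] = (
    [(r, 10, NTC, True) for r in "ABCDEF"]
    + [(r, 10, NTC, False) for r in "GHI"]
    + [(r, 10, SIRENILLA, False) for r in "JKL"]
    + [(r, 10, SITLR4, True) for r in "MNOP"]
    + [(r, 11, SIIKBKG, True) for r in "ABCD"]
    + [(r, 11, SIIRAK1, True) for r in "EFGH"]
    + [(r, 11, SIMAP3K7, True) for r in "IJKL"]
    + [(r, 11, LIPID_ONLY, True) for r in "MNOP"]
    + [(r, 24, NTC, True) for r in PLATE_ROWS]
)

# Secondary-plate control layout: columns 11, 12, 13 and 22 of the used
# region (rows C-N).
_SECONDARY_CONTROL_MAP: list[tuple[str, int, str, bool]] = (
    [(r, 11, NTC, True) for r in "CDEFGH"]
    + [(r, 11, NTC, False) for r in "IJK"]
    + [(r, 11, SIRENILLA, False) for r in "LMN"]
    + [(r, 12, SITLR4, True) for r in "CDEF"]
    + [(r, 12, SIIKBKG, True) for r in "GHIJ"]
    + [(r, 12, SIIRAK1, True) for r in "KLMN"]
    + [(r, 13, SIMAP3K7, True) for r in "CDEFGH"]
    + [(r, 13, LIPID_ONLY, True) for r in "IJKLMN"]
    + [(r, 22, NTC, True) for r in "CDEFGHIJKLMN"]
)

_CONTROL_SIRNA_IDS = {
    NTC: "D-001210-05", SIRENILLA: "siRenilla-custom",
    SITLR4: "M-008088-01", SIIRAK1: "M-004760-03",
    SIIKBKG: "M-003767-02", SIMAP3K7: "S100300741", LIPID_ONLY: "",
}

PRIMARY_GENES_PER_PLATE = 80   # 320 sample wells / 4 replicate wells
SECONDARY_GENES_PER_PLATE = 32  # 192 sample wells / 6 siRNAs


def _gene_names(n: int) -> tuple[list[str], list[int]]:
    return ([f"GENE{i + 1:05d}" for i in range(n)],
            [100001 + i for i in range(n)])


def _assign_classes(rng: np.random.Generator, cfg: SimConfig,
                    genes: list[str], entrez: list[int]) -> pd.DataFrame:
    n = len(genes)
    n_pos = int(round(cfg.frac_pos * n))
    n_neg = int(round(cfg.frac_neg * n))
    klass = np.array(["null"] * n, dtype=object)
    effect = np.ones(n)
    chosen = rng.choice(n, size=n_pos + n_neg, replace=False)
    pos_idx, neg_idx = chosen[:n_pos], chosen[n_pos:]
    klass[pos_idx] = "positive"
    klass[neg_idx] = "negative"
    effect[pos_idx] = rng.uniform(*cfg.pos_effect, size=n_pos)
    effect[neg_idx] = rng.uniform(*cfg.neg_effect, size=n_neg)
    return pd.DataFrame({"gene_symbol": genes, "entrez_id": entrez,
                         "klass": klass, "effect": effect})


# --------------------------------------------------------------------------
# primary screen
# --------------------------------------------------------------------------


def generate_primary_screen(config: SimConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[ScreenDataset, SyntheticTruth]:
    """Simulate a primary SMARTpool screen with planted regulators.

    Each plate holds 80 SMARTpools in four consecutive replicate wells
    (columns 2-9 and 12-23), the standard control block in columns 10, 11
    and 24, and an unused (empty) column 1.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    genes, entrez = _gene_names(cfg.n_genes)
    gene_truth = _assign_classes(rng, cfg, genes, entrez)
    effects = dict(zip(gene_truth["gene_symbol"], gene_truth["effect"]))

    scheme = ControlScheme.primary_default()
    sample_cols = sorted(scheme.sample_columns)
    n_plates = int(np.ceil(cfg.n_genes / PRIMARY_GENES_PER_PLATE))

    records, plate_rows, sirna_rows = [], [], []
    gene_iter = iter(range(cfg.n_genes))
    for p in range(n_plates):
        pid = f"SIM-P{p + 1:03d}"
        plate_factor = float(rng.lognormal(0.0, cfg.plate_factor_sd)) \
            if cfg.plate_factor_sd else 1.0
        plate_rows.append({"plate_id": pid, "replicate": 1,
                           "plate_factor": plate_factor})

        def emit(row, col, anno, stim, gene="", eid=None, sid="", rep=1,
                 ratio_effect=1.0, r2_effect=1.0):
            edge = _edge_factor(col, cfg.edge_gradient)
            viability = float(_lognormal(rng, cfg.viability_cv, 1)[0])
            noise = float(_lognormal(rng, cfg.noise_cv, 1)[0])
            r2 = (cfg.baseline_r2 * viability * plate_factor * edge
                  * r2_effect)
            ratio = (cfg.basal_ratio
                     * (cfg.induction_fold if stim else 1.0)
                     * (ratio_effect if stim else 1.0) * noise * edge)
            records.append({
                "plate_id": pid, "well": format_well(row, col),
                "gene_symbol": gene, "entrez_id": eid, "sirna_id": sid,
                "well_anno": anno, "stimulated": stim,
                "stimulus": "LPS" if stim else "none",
                "r1": ratio * r2, "r2": r2, "replicate": rep,
            })

        # samples: 5 genes per row, 4 consecutive sample columns each
        for r_idx, row in enumerate(PLATE_ROWS):
            for block in range(5):
                try:
                    g = next(gene_iter)
                except StopIteration:
                    g = None
                cols = sample_cols[block * 4:(block + 1) * 4]
                if g is None:
                    for c in cols:
                        records.append({
                            "plate_id": pid, "well": format_well(row, c),
                            "gene_symbol": "", "entrez_id": None,
                            "sirna_id": "", "well_anno": EMPTY,
                            "stimulated": False, "stimulus": "none",
                            "r1": np.nan, "r2": np.nan, "replicate": 1})
                    continue
                gene, eid = genes[g], entrez[g]
                sid = f"M-{g + 1:06d}-01"
                sirna_rows.append({"sirna_id": sid, "gene_symbol": gene,
                                   "efficacy": 1.0, "ote_effect": 1.0,
                                   "net_effect": effects[gene]})
                for rep, c in enumerate(cols, start=1):
                    emit(row, c, SAMPLE, True, gene=gene, eid=eid, sid=sid,
                         rep=rep, ratio_effect=effects[gene])
        # controls
        for row, col, anno, stim in _PRIMARY_CONTROL_MAP:
            emit(row, col, anno, stim,
                 sid=_CONTROL_SIRNA_IDS[anno],
                 ratio_effect=_control_ratio_effect(anno, cfg),
                 r2_effect=cfg.renilla_kd_effect
                 if anno == SIRENILLA else 1.0)
        # unused column 1
        for row in PLATE_ROWS:
            records.append({
                "plate_id": pid, "well": format_well(row, 1),
                "gene_symbol": "", "entrez_id": None, "sirna_id": "",
                "well_anno": EMPTY, "stimulated": False, "stimulus": "none",
                "r1": np.nan, "r2": np.nan, "replicate": 1})

    frame = pd.DataFrame.from_records(records)
    frame["entrez_id"] = frame["entrez_id"].astype("Int64")
    dataset = ScreenDataset(tier="primary", frame=frame, scheme=scheme,
                            provenance=f"synthetic primary seed={cfg.seed}")
    truth = SyntheticTruth(genes=gene_truth,
                           sirnas=pd.DataFrame(sirna_rows),
                           plates=pd.DataFrame(plate_rows), config=cfg)
    return dataset, truth


# --------------------------------------------------------------------------
# secondary screen
# --------------------------------------------------------------------------


def generate_secondary_screen(config: SimConfig, truth: SyntheticTruth,
                              genes: list[str],
                              rng: np.random.Generator | None = None,
                              ote_sirnas_per_gene: int | None = None,
                              ) -> tuple[ScreenDataset, SyntheticTruth]:
    """Simulate the six-siRNAs-per-gene validation screen for ``genes``.

    Each of the six siRNAs draws its own on-target efficacy; off-target
    effects attach to individual siRNAs, either at random (``ote_rate``
    per siRNA) or exactly ``ote_sirnas_per_gene`` per gene when given.
    Three replicate plate copies are emitted with independent week factors.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    known = set(truth.genes["gene_symbol"])
    missing = [g for g in genes if g not in known]
    if missing:
        raise LayoutError(f"candidate genes not in truth: {missing[:5]}")
    gene_truth = truth.genes.set_index("gene_symbol")

    scheme = ControlScheme.secondary_default()
    sample_cols = sorted(scheme.sample_columns)
    region_rows = "CDEFGHIJKLMN"
    region_wells = [(r, c) for r in region_rows for c in sample_cols]

    n_plates = max(1, int(np.ceil(len(genes) / SECONDARY_GENES_PER_PLATE)))
    if not genes:
        n_plates = 0

    # per-siRNA truth drawn once, shared by the three replicate copies
    sirna_rows = []
    vendors = ("AMB", "AMB", "AMB", "QIA", "QIA", "QIA")
    for gi, gene in enumerate(genes):
        effect = float(gene_truth.at[gene, "effect"])
        if ote_sirnas_per_gene is not None:
            ote_mask = np.zeros(6, dtype=bool)
            ote_mask[rng.choice(6, size=ote_sirnas_per_gene,
                                replace=False)] = True
        else:
            ote_mask = rng.random(6) < cfg.ote_rate
        for s in range(6):
            efficacy = float(rng.uniform(*cfg.efficacy_range))
            on_target = 1.0 + (effect - 1.0) * efficacy
            ote_effect = 1.0
            if ote_mask[s]:
                if rng.random() < 0.5:
                    ote_effect = float(rng.uniform(*cfg.pos_effect))
                else:
                    ote_effect = float(rng.uniform(*cfg.neg_effect))
            sirna_rows.append({
                "sirna_id": f"{vendors[s]}-{gene}-s{s + 1}",
                "gene_symbol": gene, "sirna_number": s + 1,
                "efficacy": efficacy, "ote_effect": ote_effect,
                "net_effect": on_target * ote_effect,
            })
    sirna_truth = pd.DataFrame(
        sirna_rows, columns=["sirna_id", "gene_symbol", "sirna_number",
                             "efficacy", "ote_effect", "net_effect"])

    records, plate_rows = [], []
    for p in range(n_plates):
        pid = f"SIM-S{p + 1:03d}"
        plate_genes = genes[p * SECONDARY_GENES_PER_PLATE:
                            (p + 1) * SECONDARY_GENES_PER_PLATE]
        for rep in (1, 2, 3):
            week_factor = float(
                rng.lognormal(0.0, cfg.plate_factor_sd)
            ) if cfg.plate_factor_sd else 1.0
            plate_rows.append({"plate_id": pid, "replicate": rep,
                               "plate_factor": week_factor})

            def emit(row, col, anno, stim, gene="", eid=None, sid="",
                     ratio_effect=1.0, r2_effect=1.0):
                edge = _edge_factor(col, cfg.edge_gradient)
                viability = float(_lognormal(rng, cfg.viability_cv, 1)[0])
                noise = float(_lognormal(rng, cfg.noise_cv, 1)[0])
                r2 = (cfg.baseline_r2 * viability * week_factor * edge
                      * r2_effect)
                ratio = (cfg.basal_ratio
                         * (cfg.induction_fold if stim else 1.0)
                         * (ratio_effect if stim else 1.0) * noise * edge)
                records.append({
                    "plate_id": pid, "well": format_well(row, col),
                    "gene_symbol": gene, "entrez_id": eid, "sirna_id": sid,
                    "well_anno": anno, "stimulated": stim,
                    "stimulus": "LPS" if stim else "none",
                    "r1": ratio * r2, "r2": r2, "replicate": rep,
                })

            # samples: siRNA s of gene g at region well s*32 + g
            for s in range(6):
                for gi, gene in enumerate(plate_genes):
                    row, col = region_wells[s * SECONDARY_GENES_PER_PLATE
                                            + gi]
                    srow = sirna_truth[
                        (sirna_truth["gene_symbol"] == gene)
                        & (sirna_truth["sirna_number"] == s + 1)].iloc[0]
                    emit(row, col, SAMPLE, True, gene=gene,
                         eid=int(gene_truth.at[gene, "entrez_id"]),
                         sid=srow["sirna_id"],
                         ratio_effect=float(srow["net_effect"]))
            # unused sample region wells (when the plate is not full)
            n_used = len(plate_genes)
            for s in range(6):
                for gi in range(n_used, SECONDARY_GENES_PER_PLATE):
                    row, col = region_wells[s * SECONDARY_GENES_PER_PLATE
                                            + gi]
                    records.append({
                        "plate_id": pid, "well": format_well(row, col),
                        "gene_symbol": "", "entrez_id": None, "sirna_id": "",
                        "well_anno": EMPTY, "stimulated": False,
                        "stimulus": "none", "r1": np.nan, "r2": np.nan,
                        "replicate": rep})
            # controls
            for row, col, anno, stim in _SECONDARY_CONTROL_MAP:
                emit(row, col, anno, stim,
                     sid=_CONTROL_SIRNA_IDS[anno],
                     ratio_effect=_control_ratio_effect(anno, cfg),
                     r2_effect=cfg.renilla_kd_effect
                     if anno == SIRENILLA else 1.0)
            # empty outer frame
            for well in sorted(scheme.excluded_wells):
                records.append({
                    "plate_id": pid, "well": well, "gene_symbol": "",
                    "entrez_id": None, "sirna_id": "", "well_anno": EMPTY,
                    "stimulated": False, "stimulus": "none",
                    "r1": np.nan, "r2": np.nan, "replicate": rep})

    frame = pd.DataFrame.from_records(
        records, columns=["plate_id", "well", "gene_symbol", "entrez_id",
                          "sirna_id", "well_anno", "stimulated", "stimulus",
                          "r1", "r2", "replicate"])
    frame["entrez_id"] = frame["entrez_id"].astype("Int64")
    dataset = ScreenDataset(tier="secondary", frame=frame, scheme=scheme,
                            provenance=f"synthetic secondary seed={cfg.seed}")
    sel = truth.genes[truth.genes["gene_symbol"].isin(genes)]
    out_truth = SyntheticTruth(genes=sel.reset_index(drop=True),
                               sirnas=sirna_truth,
                               plates=pd.DataFrame(
                                   plate_rows,
                                   columns=["plate_id", "replicate",
                                            "plate_factor"]),
                               config=cfg)
    return dataset, out_truth


# --------------------------------------------------------------------------
# uniformity plates
# --------------------------------------------------------------------------

DOSE_INDUCTION_FRACTION = {"H": 1.0, "M": 0.4, "L": 0.0}


def generate_uniformity_plates(config: SimConfig,
                               rng: np.random.Generator | None = None,
                               ) -> tuple[ScreenDataset,
                                          dict[str, pd.Series]]:
    """Three full-plate NTC uniformity plates with the staggered H/M/L
    dose pattern: repeating 2-column blocks of High/Medium/Low LPS dose,
    with plate 1 starting H,M,L, plate 2 starting M,L,H and plate 3
    starting L,H,M.  Low dose is no LPS.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    scheme = ControlScheme.full_plate()
    rotations = (("H", "M", "L"), ("M", "L", "H"), ("L", "H", "M"))
    records, dose_maps = [], {}
    for p, rotation in enumerate(rotations):
        pid = f"SIM-U{p + 1}"
        plate_factor = float(rng.lognormal(0.0, cfg.plate_factor_sd)) \
            if cfg.plate_factor_sd else 1.0
        doses = {}
        for col in range(1, 25):
            dose = rotation[((col - 1) // 2) % 3]
            frac = DOSE_INDUCTION_FRACTION[dose]
            induction = 1.0 + (cfg.induction_fold - 1.0) * frac
            stim = frac > 0
            for row in PLATE_ROWS:
                edge = _edge_factor(col, cfg.edge_gradient)
                viability = float(_lognormal(rng, cfg.viability_cv, 1)[0])
                noise = float(_lognormal(rng, cfg.noise_cv, 1)[0])
                r2 = cfg.baseline_r2 * viability * plate_factor * edge
                ratio = cfg.basal_ratio * induction * noise * edge
                well = format_well(row, col)
                doses[well] = dose
                records.append({
                    "plate_id": pid, "well": well, "gene_symbol": "",
                    "entrez_id": None, "sirna_id": _CONTROL_SIRNA_IDS[NTC],
                    "well_anno": NTC, "stimulated": stim,
                    "stimulus": "LPS" if stim else "none",
                    "r1": ratio * r2, "r2": r2, "replicate": 1})
        dose_maps[pid] = pd.Series(doses)
    frame = pd.DataFrame.from_records(records)
    frame["entrez_id"] = frame["entrez_id"].astype("Int64")
    dataset = ScreenDataset(tier="primary", frame=frame, scheme=scheme,
                            provenance=f"synthetic uniformity seed={cfg.seed}")
    return dataset, dose_maps


def write_dose_maps(dose_maps: dict[str, pd.Series], directory: str | Path,
                    ) -> list[Path]:
    paths = []
    for pid, series in dose_maps.items():
        path = Path(directory) / f"dose_map_{pid}.csv"
        pd.DataFrame({"Well": series.index, "Dose": series.to_numpy()}
                     ).to_csv(path, index=False, lineterminator="\n")
        paths.append(path)
    return paths


# --------------------------------------------------------------------------
# expression table
# --------------------------------------------------------------------------


def generate_expression_table(genes: list[str], config: SimConfig,
                              rng: np.random.Generator | None = None,
                              ) -> ExpressionTable:
    """Gene-level detection p-values and log2 signals for both screen
    conditions.  A fraction ``expressed_fraction`` of genes gets a
    detection p below 0.1 in at least one randomly chosen condition."""
    cfg = config
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    n = len(genes)
    expressed = rng.random(n) < cfg.expressed_fraction
    in_lps = rng.random(n) < 0.5  # which condition carries the present call
    p_no = rng.uniform(0.1, 1.0, size=n)
    p_lps = rng.uniform(0.1, 1.0, size=n)
    strong = rng.uniform(0.0, 0.1, size=n)
    p_no = np.where(expressed & ~in_lps, strong, p_no)
    p_lps = np.where(expressed & in_lps, strong, p_lps)
    log2_base = rng.normal(5.0, 0.5, size=n)
    log2_hi = rng.normal(9.0, 2.0, size=n)
    frame = pd.DataFrame({
        "p_noLPS": p_no, "p_LPS": p_lps,
        "log2_noLPS": np.where(expressed & ~in_lps, log2_hi, log2_base),
        "log2_LPS": np.where(expressed & in_lps, log2_hi, log2_base),
    }, index=pd.Index(genes, name="gene_symbol"))
    return ExpressionTable(frame=frame)


def export_screen(dataset: ScreenDataset, truth: SyntheticTruth,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated screen plus its truth table as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_path = out_dir / f"{dataset.tier}_screen.csv"
    truth_path = out_dir / f"{dataset.tier}_truth.csv"
    write_screen_table(dataset, data_path)
    truth.to_csv(truth_path)
    return {"data": data_path, "truth": truth_path}
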