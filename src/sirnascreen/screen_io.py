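"""Data model and I/O for dual-luciferase siRNA screen tables.

The screens this package analyses are run in 384-well format (rows A-P,
columns 1-24).  Every well carries two luminescence readouts: firefly
luciferase (R1) driven by the *TNF* promoter, reporting inflammatory
pathway activation, and renilla luciferase (R2) driven by the constitutive
*UBC* promoter, reporting cell number and viability.  Wells are either
gene-targeting samples (an siRNA SMARTpool or an individual siRNA) or one
of a small vocabulary of controls: non-targeting siRNA (NTC), siRNA against
the renilla reporter itself (transfection-efficiency control), siRNAs
against known pathway components (TLR4, IRAK1, IKBKG, MAP3K7), transfection
lipid alone, or deliberately empty positions.

Tables are exchanged in a comma-separated "deposit schema" with the minimal
fields PlateID, Well, GeneSymbol, EntrezID, siRNAID and WellAnno plus raw
readout columns; this mirrors the layout of public screening-data deposits
so that exported tables are directly diffable against them.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------


class ScreenError(Exception):
    """Base class for all screen-analysis errors."""


class SchemaError(ScreenError):
    """A required column is missing or the header cannot be interpreted."""


class RecordError(ScreenError):
    """A single row is malformed (bad well coordinate, bad annotation...)."""


class IntegrityError(ScreenError):
    """Dataset-level consistency violation (duplicate wells, ...)."""


class ValidationError(ScreenError):
    """Value fails a domain constraint (e.g. detection p outside [0, 1])."""


# --------------------------------------------------------------------------
# controlled vocabularies
# --------------------------------------------------------------------------

SAMPLE = "sample"
NTC = "NTC"
SIRENILLA = "siRenilla"
SITLR4 = "siTLR4"
SIIRAK1 = "siIRAK1"
SIIKBKG = "siIKBKG"
SIMAP3K7 = "siMAP3K7"
LIPID_ONLY = "lipid_only"
EMPTY = "empty"

WELL_ANNOS = (
    SAMPLE, NTC, SIRENILLA, SITLR4, SIIRAK1, SIIKBKG, SIMAP3K7, LIPID_ONLY,
    EMPTY,
)
CONTROL_ANNOS = frozenset(WELL_ANNOS) - {SAMPLE, EMPTY}

# Case-insensitive synonyms seen in screen exports.  Keys must be unique
# after lower-casing (checked at import time) so normalization cannot
# silently collide.
_ANNO_SYNONYMS: dict[str, str] = {}


def _register_anno(canonical: str, *synonyms: str) -> None:
    for name in (canonical, *synonyms):
        key = name.lower()
        if key in _ANNO_SYNONYMS and _ANNO_SYNONYMS[key] != canonical:
            raise RuntimeError(f"annotation synonym collision: {name!r}")
        _ANNO_SYNONYMS[key] = canonical


_register_anno(SAMPLE, "sm", "s", "experimental")
_register_anno(NTC, "ntc3", "ntc5", "non-targeting", "nontargeting",
               "negative control")
_register_anno(SIRENILLA, "renilla", "si_renilla", "si-renilla")
_register_anno(SITLR4, "tlr4", "si_tlr4")
_register_anno(SIIRAK1, "irak1", "si_irak1")
_register_anno(SIIKBKG, "ikbkg", "si_ikbkg", "nemo")
_register_anno(SIMAP3K7, "map3k7", "si_map3k7", "tak1")
_register_anno(LIPID_ONLY, "lipid", "lipidonly", "mock", "lipid only")
_register_anno(EMPTY, "", "blank", "unused", "none")

STIMULI = ("LPS", "P3C", "PGN", "R848", "P2C", "FLG", "BCG_extract", "none")
_STIMULUS_LOOKUP = {s.lower(): s for s in STIMULI}

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24

_WELL_RE = re.compile(r"^([A-Pa-p])0?([1-9]|1\d|2[0-4])$")


def parse_well(well: str) -> tuple[str, int]:
    """Split a well label like ``"A1"`` or ``"A01"`` into (row, column).

    Raises :class:`RecordError` for anything outside the 384-well grid.
    """
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise RecordError(f"invalid 384-well coordinate: {well!r}")
    return m.group(1).upper(), int(m.group(2))


def format_well(row: str, col: int) -> str:
    """Canonical zero-padded well label, e.g. ``("A", 1) -> "A01"``."""
    if row not in PLATE_ROWS or not 1 <= col <= N_COLS:
        raise RecordError(f"invalid 384-well coordinate: {(row, col)!r}")
    return f"{row}{col:02d}"


def normalize_anno(value: str) -> str:
    key = str(value).strip().lower()
    try:
        return _ANNO_SYNONYMS[key]
    except KeyError:
        raise RecordError(f"unknown well annotation: {value!r}") from None


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WellRecord:
    """One well's identity, annotation and raw luminescence readouts."""

    plate_id: str
    well: str
    gene_symbol: str = ""
    entrez_id: int | None = None
    sirna_id: str = ""
    well_anno: str = SAMPLE
    stimulated: bool = True
    stimulus: str = "LPS"
    r1: float = float("nan")
    r2: float = float("nan")
    replicate: int = 1

    def __post_init__(self) -> None:
        parse_well(self.well)
        if self.well_anno not in WELL_ANNOS:
            raise RecordError(f"unknown well annotation: {self.well_anno!r}")
        if self.stimulus not in STIMULI:
            raise RecordError(f"unknown stimulus: {self.stimulus!r}")
        if self.well_anno != EMPTY:
            for name, v in (("r1", self.r1), ("r2", self.r2)):
                if not np.isfinite(v) or v < 0:
                    raise RecordError(
                        f"{name} must be finite and >= 0, got {v!r} "
                        f"({self.plate_id}:{self.well})")
        if self.well_anno == SAMPLE and not self.sirna_id:
            raise RecordError(
                f"sample well {self.plate_id}:{self.well} has no siRNA id")
        if self.replicate < 1:
            raise RecordError("replicate index must be >= 1")


FRAME_COLUMNS = [
    "plate_id", "well", "gene_symbol", "entrez_id", "sirna_id", "well_anno",
    "stimulated", "stimulus", "r1", "r2", "replicate",
]
SCORE_COLUMNS = ["zscore", "activity_score", "outcome"]


@dataclass(frozen=True)
class ControlScheme:
    """Which columns hold samples vs controls for one screen tier."""

    tier: str
    sample_columns: frozenset[int]
    control_columns: frozenset[int]
    excluded_wells: frozenset[str] = frozenset()
    min_control_wells: int = 3

    def __post_init__(self) -> None:
        if self.sample_columns & self.control_columns:
            raise ValidationError("sample and control columns overlap")

    @classmethod
    def primary_default(cls) -> "ControlScheme":
        """Primary tier: samples in columns 2-9 and 12-23, controls in
        columns 10, 11 and 24; column 1 unused."""
        return cls(
            tier="primary",
            sample_columns=frozenset(range(2, 10)) | frozenset(range(12, 24)),
            control_columns=frozenset({10, 11, 24}),
            excluded_wells=frozenset(
                format_well(r, 1) for r in PLATE_ROWS),
        )

    @classmethod
    def secondary_default(cls) -> "ControlScheme":
        """Secondary tier: outer two rows/columns empty; controls in the
        three central columns 11-13 and in column 22."""
        excluded = set()
        for r in PLATE_ROWS:
            for c in range(1, N_COLS + 1):
                if r in "ABOP" or c in (1, 2, 23, 24):
                    excluded.add(format_well(r, c))
        return cls(
            tier="secondary",
            sample_columns=frozenset(range(3, 11)) | frozenset(range(14, 22)),
            control_columns=frozenset({11, 12, 13, 22}),
            excluded_wells=frozenset(excluded),
        )

    @classmethod
    def full_plate(cls, tier: str = "primary") -> "ControlScheme":
        """Whole-plate control layout (used by uniformity-assessment plates,
        which fill every well with NTC)."""
        return cls(tier=tier, sample_columns=frozenset(),
                   control_columns=frozenset(range(1, N_COLS + 1)))

    def to_dict(self) -> dict:
        return {
            "tier": self.tier,
            "sample_columns": sorted(self.sample_columns),
            "control_columns": sorted(self.control_columns),
            "excluded_wells": sorted(self.excluded_wells),
            "min_control_wells": self.min_control_wells,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ControlScheme":
        return cls(
            tier=d["tier"],
            sample_columns=frozenset(d["sample_columns"]),
            control_columns=frozenset(d["control_columns"]),
            excluded_wells=frozenset(d.get("excluded_wells", ())),
            min_control_wells=int(d.get("min_control_wells", 3)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ControlScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_DEFAULT_SCHEMES = {
    "primary": ControlScheme.primary_default,
    "secondary": ControlScheme.secondary_default,
    "tertiary": ControlScheme.full_plate,
}


@dataclass
class ScreenDataset:
    """A validated collection of well records for one screen tier.

    The backing store is a pandas DataFrame with one row per physical well
    replicate (columns :data:`FRAME_COLUMNS`, plus score columns once
    attached).  Row order is preserved through read/write round trips.
    """

    tier: str
    frame: pd.DataFrame
    scheme: ControlScheme
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in FRAME_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def plates(self) -> list[str]:
        return list(pd.unique(self.frame["plate_id"]))

    def plate(self, plate_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["plate_id"] == plate_id]
        if sub.empty:
            raise KeyError(f"no such plate: {plate_id!r}")
        return sub

    def samples(self) -> pd.DataFrame:
        return self.frame[self.frame["well_anno"] == SAMPLE]

    def records(self) -> Iterator[WellRecord]:
        for row in self.frame.itertuples(index=False):
            eid = row.entrez_id
            yield WellRecord(
                plate_id=row.plate_id, well=row.well,
                gene_symbol=row.gene_symbol,
                entrez_id=None if pd.isna(eid) else int(eid),
                sirna_id=row.sirna_id, well_anno=row.well_anno,
                stimulated=bool(row.stimulated), stimulus=row.stimulus,
                r1=float(row.r1), r2=float(row.r2),
                replicate=int(row.replicate),
            )

    def equals(self, other: "ScreenDataset") -> bool:
        if self.tier != other.tier:
            return False
        a = self.frame[FRAME_COLUMNS].reset_index(drop=True)
        b = other.frame[FRAME_COLUMNS].reset_index(drop=True)
        if len(a) != len(b):
            return False
        for col in FRAME_COLUMNS:
            if col in ("r1", "r2"):
                if not np.allclose(a[col].astype(float), b[col].astype(float),
                                   rtol=1e-9, atol=0, equal_nan=True):
                    return False
            else:
                av, bv = a[col], b[col]
                if col == "entrez_id":
                    av = av.astype("Int64")
                    bv = bv.astype("Int64")
                if not av.equals(bv):
                    return False
        return True

    @classmethod
    def from_records(cls, tier: str, records: Iterable[WellRecord],
                     scheme: ControlScheme | None = None,
                     provenance: str = "") -> "ScreenDataset":
        rows = [dataclasses.asdict(r) for r in records]
        frame = pd.DataFrame(rows, columns=FRAME_COLUMNS)
        frame["entrez_id"] = frame["entrez_id"].astype("Int64")
        if scheme is None:
            scheme = _DEFAULT_SCHEMES[tier]()
        ds = cls(tier=tier, frame=frame, scheme=scheme, provenance=provenance)
        _check_unique(frame)
        return ds


def _check_unique(frame: pd.DataFrame) -> None:
    key = frame[["plate_id", "well", "replicate"]]
    dup = key.duplicated()
    if dup.any():
        first = frame[dup].iloc[0]
        raise IntegrityError(
            "duplicate (plate, well, replicate): "
            f"({first['plate_id']}, {first['well']}, {first['replicate']})")


# --------------------------------------------------------------------------
# deposit-schema reader / writer
# --------------------------------------------------------------------------

DEPOSIT_FIELDS = {
    "PlateID": "plate_id",
    "Well": "well",
    "GeneSymbol": "gene_symbol",
    "EntrezID": "entrez_id",
    "siRNAID": "sirna_id",
    "WellAnno": "well_anno",
}
_OPTIONAL_FIELDS = {
    "Replicate": "replicate",
    "Stimulated": "stimulated",
    "Stimulus": "stimulus",
    "Zscore": "zscore",
    "ActivityScore": "activity_score",
    "Outcome": "outcome",
}
_REP_READOUT_RE = re.compile(r"^Rep(\d+)R([12])$")

_MINUS_SIGNS = str.maketrans({"−": "-"})


def _to_float(value: str) -> float:
    s = str(value).strip().translate(_MINUS_SIGNS)
    if s == "" or s.lower() in ("na", "nan"):
        return float("nan")
    return float(s)


def _to_bool(value: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise RecordError(f"cannot parse boolean: {value!r}")


def read_screen_table(path: str | Path, tier: str,
                      schema: Mapping[str, str] | None = None,
                      scheme: ControlScheme | None = None) -> ScreenDataset:
    """Read a deposit-schema CSV into a validated :class:`ScreenDataset`.

    Parameters
    ----------
    path
        Delimited text file with a header row.  Minimal fields PlateID,
        Well, GeneSymbol, EntrezID, siRNAID and WellAnno are required, plus
        raw readout columns: either one ``Rep1R1``/``Rep1R2`` pair (one row
        per physical well; the layout of the primary-screen deposit) or
        several ``RepkR1``/``RepkR2`` pairs (one row per siRNA with
        replicates side by side; the secondary-screen deposit), in which
        case each row is expanded into one record per replicate.
    tier
        ``"primary"``, ``"secondary"`` or ``"tertiary"``.
    schema
        Optional mapping from deposit field names (e.g. ``"PlateID"``) to
        the actual column names in the file.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = dict(schema) if schema else {}

    def col(name: str) -> str:
        return rename.get(name, name)

    for name in DEPOSIT_FIELDS:
        if col(name) not in raw.columns:
            raise SchemaError(f"missing mandatory column: {name!r}")

    # locate replicate readout column pairs
    rep_cols: dict[int, dict[str, str]] = {}
    for c in raw.columns:
        m = _REP_READOUT_RE.match(c)
        if m:
            rep_cols.setdefault(int(m.group(1)), {})[f"r{m.group(2)}"] = c
    rep_cols = {k: v for k, v in rep_cols.items() if set(v) == {"r1", "r2"}}
    if not rep_cols:
        raise SchemaError("missing readout columns (expected RepkR1/RepkR2)")
    wide = len(rep_cols) > 1

    has_rep_col = col("Replicate") in raw.columns
    has_stim = col("Stimulated") in raw.columns
    has_stimulus = col("Stimulus") in raw.columns

    records: list[dict] = []
    for idx, row in enumerate(raw.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        r = raw.iloc[idx]
        try:
            wrow, wcol = parse_well(r[col("Well")])
            anno = normalize_anno(r[col("WellAnno")])
            entrez_raw = str(r[col("EntrezID")]).strip()
            entrez = int(float(entrez_raw)) if entrez_raw else None
            base = {
                "plate_id": str(r[col("PlateID")]).strip(),
                "well": format_well(wrow, wcol),
                "gene_symbol": str(r[col("GeneSymbol")]).strip(),
                "entrez_id": entrez,
                "sirna_id": str(r[col("siRNAID")]).strip(),
                "well_anno": anno,
            }
            if has_stim:
                stim = _to_bool(r[col("Stimulated")])
            else:
                stim = anno != SIRENILLA and anno != EMPTY
            if has_stimulus:
                skey = str(r[col("Stimulus")]).strip().lower()
                stimulus = _STIMULUS_LOOKUP.get(skey)
                if stimulus is None:
                    raise RecordError(f"unknown stimulus: {r[col('Stimulus')]!r}")
            else:
                stimulus = "LPS" if stim else "none"
            for k in sorted(rep_cols):
                rc = rep_cols[k]
                r1 = _to_float(r[rc["r1"]])
                r2 = _to_float(r[rc["r2"]])
                if wide:
                    rep = k
                elif has_rep_col:
                    rep = int(float(r[col("Replicate")]))
                else:
                    rep = 0  # assigned positionally below
                rec = dict(base, stimulated=stim, stimulus=stimulus,
                           r1=r1, r2=r2, replicate=rep)
                if anno == EMPTY:
                    records.append(rec)
                    continue
                if not np.isfinite(r1) or r1 < 0 or not np.isfinite(r2) or r2 < 0:
                    raise RecordError(
                        f"readout must be finite and >= 0 (got r1={r1}, r2={r2})")
                if anno == SAMPLE and not rec["sirna_id"]:
                    raise RecordError("sample well without siRNA id")
                records.append(rec)
        except RecordError as exc:
            raise RecordError(f"row {line_no}: {exc}") from None

    frame = pd.DataFrame(records, columns=FRAME_COLUMNS)
    frame["entrez_id"] = frame["entrez_id"].astype("Int64")

    if not wide and not has_rep_col:
        # positional replicate assignment: controls/empty wells are single
        # observations; sample wells are numbered in file order within each
        # (plate, siRNA) group -- the within-plate reformat order.
        frame["replicate"] = 1
        is_sample = frame["well_anno"] == SAMPLE
        grp = frame[is_sample].groupby(["plate_id", "sirna_id"], sort=False)
        frame.loc[is_sample, "replicate"] = (grp.cumcount() + 1).astype(int)

    # retain deposited score columns if present
    for dep_name in ("Zscore", "ActivityScore", "Outcome"):
        if col(dep_name) in raw.columns and not wide:
            frame[_OPTIONAL_FIELDS[dep_name]] = [
                _to_float(v) for v in raw[col(dep_name)]]

    _check_unique(frame)
    if scheme is None:
        scheme = _DEFAULT_SCHEMES[tier]()
    return ScreenDataset(tier=tier, frame=frame, scheme=scheme,
                         provenance=str(path))


def _fmt_float(x: float) -> str:
    if pd.isna(x):
        return ""
    return f"{float(x):.10g}"


def write_screen_table(dataset: ScreenDataset, path: str | Path,
                       include_scores: bool = False) -> Path:
    """Write a dataset as deposit-schema CSV (long dialect, one row per
    physical well replicate).  Column order is deterministic; minus signs
    are ASCII; floats use shortest round-trippable decimal (10 significant
    digits)."""
    frame = dataset.frame
    out = pd.DataFrame({
        "PlateID": frame["plate_id"].astype(str),
        "Well": frame["well"].astype(str),
        "GeneSymbol": frame["gene_symbol"].astype(str),
        "EntrezID": [("" if pd.isna(v) else str(int(v)))
                     for v in frame["entrez_id"]],
        "siRNAID": frame["sirna_id"].astype(str),
        "WellAnno": frame["well_anno"].astype(str),
        "Replicate": frame["replicate"].astype(int).astype(str),
        "Stimulated": np.where(frame["stimulated"].astype(bool),
                               "true", "false"),
        "Stimulus": frame["stimulus"].astype(str),
        "Rep1R1": [_fmt_float(v) for v in frame["r1"]],
        "Rep1R2": [_fmt_float(v) for v in frame["r2"]],
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = frame["r1"].astype(float) / frame["r2"].astype(float)
    ratio = ratio.where(np.isfinite(ratio))
    out["Rep1R1/R2"] = [_fmt_float(v) for v in ratio]
    if include_scores:
        for dep_name, canonical in (("Zscore", "zscore"),
                                    ("ActivityScore", "activity_score"),
                                    ("Outcome", "outcome")):
            if canonical in frame.columns:
                vals = frame[canonical]
                if dep_name in ("ActivityScore", "Outcome"):
                    out[dep_name] = [("" if pd.isna(v) else str(int(v)))
                                     for v in vals]
                else:
                    out[dep_name] = [_fmt_float(v) for v in vals]
    path = Path(path)
    out.to_csv(path, index=False, lineterminator="\n")
    return path


# --------------------------------------------------------------------------
# expression table
# --------------------------------------------------------------------------

CONDITIONS = ("noLPS", "LPS")


@dataclass
class ExpressionTable:
    """Gene-level microarray presence data for the two screen conditions
    (unstimulated, and 4 h LPS).  One row per gene; probes mapping to the
    same gene were collapsed by the minimum detection p-value per condition
    (most permissive "expressed" evidence) and maximum log2 signal."""

    frame: pd.DataFrame  # index: gene_symbol; columns p_noLPS, p_LPS, ...

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            if f"p_{cond}" not in self.frame.columns:
                raise ValidationError(
                    f"expression table missing condition {cond!r} "
                    "(both +/-LPS conditions required)")
            p = self.frame[f"p_{cond}"].astype(float)
            if ((p < 0) | (p > 1)).any():
                raise ValidationError("detection p-value outside [0, 1]")

    def __contains__(self, gene: str) -> bool:
        return gene in self.frame.index

    def detection_p(self, gene: str) -> tuple[float, float]:
        row = self.frame.loc[gene]
        return float(row["p_noLPS"]), float(row["p_LPS"])

    def is_expressed(self, gene: str, p_cut: float = 0.1) -> bool | None:
        """Expressed iff detection p < ``p_cut`` in at least one condition;
        ``None`` if the gene was not measured."""
        if gene not in self.frame.index:
            return None
        p_no, p_lps = self.detection_p(gene)
        return bool(p_no < p_cut or p_lps < p_cut)


_EXPR_COLUMNS = {
    "GeneSymbol": "gene_symbol",
    "DetectionPval_noLPS": "p_noLPS",
    "DetectionPval_LPS": "p_LPS",
}
_EXPR_SIGNAL = {
    "Log2Signal_noLPS": "log2_noLPS",
    "Log2Signal_LPS": "log2_LPS",
}


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a probe- or gene-level expression CSV and collapse to genes.

    Expected columns: ``GeneSymbol``, ``DetectionPval_noLPS``,
    ``DetectionPval_LPS`` and optionally ``ProbeID`` plus
    ``Log2Signal_noLPS``/``Log2Signal_LPS``.  Multiple probes per gene are
    collapsed by minimum detection p per condition and maximum signal.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for name in _EXPR_COLUMNS:
        if name not in raw.columns:
            raise SchemaError(f"missing mandatory column: {name!r}")
    df = pd.DataFrame({"gene_symbol": raw["GeneSymbol"].str.strip()})
    for src, dst in {**_EXPR_COLUMNS, **_EXPR_SIGNAL}.items():
        if src == "GeneSymbol" or src not in raw.columns:
            continue
        df[dst] = [_to_float(v) for v in raw[src]]
    for cond in CONDITIONS:
        p = df[f"p_{cond}"]
        bad = ~p.between(0.0, 1.0) | p.isna()
        if bad.any():
            raise ValidationError(
                f"detection p-value outside [0, 1] at row "
                f"{int(np.flatnonzero(bad)[0]) + 2}")
    agg = {f"p_{c}": "min" for c in CONDITIONS}
    agg.update({c: "max" for c in ("log2_noLPS", "log2_LPS")
                if c in df.columns})
    collapsed = df.groupby("gene_symbol", sort=True).agg(agg)
    return ExpressionTable(frame=collapsed)


def write_expression_table(table: ExpressionTable, path: str | Path) -> Path:
    out = pd.DataFrame({"GeneSymbol": table.frame.index})
    for src, dst in {**_EXPR_COLUMNS, **_EXPR_SIGNAL}.items():
        if src == "GeneSymbol" or dst not in table.frame.columns:
            continue
        out[src] = [_fmt_float(v) for v in table.frame[dst]]
    path = Path(path)
    out.to_csv(path, index=False, lineterminator="\n")
    return path


# --------------------------------------------------------------------------
# dataset validation
# --------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-based validation: one entry per invariant violation."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)

    def __str__(self) -> str:
        if self.ok:
            return "dataset conforms (no violations)"
        return "\n".join(f"- {v}" for v in self.violations)


def validate_dataset(dataset: ScreenDataset) -> ValidationReport:
    """Check layout conformity, replicate structure and control minimums.

    The report is empty iff the dataset conforms; violations never raise.
    """
    report = ValidationReport()
    frame = dataset.frame
    scheme = dataset.scheme

    # uniqueness
    dup = frame[["plate_id", "well", "replicate"]].duplicated()
    for _, row in frame[dup].iterrows():
        report.add(
            f"duplicate (plate, well, replicate): ({row['plate_id']}, "
            f"{row['well']}, {row['replicate']})")

    cols = frame["well"].map(lambda w: parse_well(w)[1])

    # layout conformity
    is_sample = frame["well_anno"] == SAMPLE
    is_control = frame["well_anno"].isin(CONTROL_ANNOS)
    bad_sample = is_sample & ~cols.isin(scheme.sample_columns)
    for _, row in frame[bad_sample].iterrows():
        report.add(
            f"sample well outside sample columns: {row['plate_id']}:"
            f"{row['well']}")
    if scheme.control_columns:
        bad_ctl = is_control & ~cols.isin(scheme.control_columns)
        for _, row in frame[bad_ctl].iterrows():
            report.add(
                f"control well outside control columns: {row['plate_id']}:"
                f"{row['well']} ({row['well_anno']})")
    in_excluded = frame["well"].isin(scheme.excluded_wells)
    bad_excl = in_excluded & (frame["well_anno"] != EMPTY)
    for _, row in frame[bad_excl].iterrows():
        report.add(
            f"non-empty well in excluded position: {row['plate_id']}:"
            f"{row['well']}")

    # readouts
    for ch in ("r1", "r2"):
        v = frame[ch].astype(float)
        bad = (~np.isfinite(v) | (v < 0)) & (frame["well_anno"] != EMPTY)
        for _, row in frame[bad].iterrows():
            report.add(
                f"non-finite or negative {ch}: {row['plate_id']}:{row['well']}")
    no_id = is_sample & (frame["sirna_id"].astype(str) == "")
    for _, row in frame[no_id].iterrows():
        report.add(f"sample well without siRNA id: {row['plate_id']}:"
                   f"{row['well']}")

    # replicate structure
    samples = frame[is_sample]
    if dataset.tier == "primary" and not samples.empty:
        per_pool = samples.groupby("sirna_id")
        for sid, grp in per_pool:
            n_plates = grp["plate_id"].nunique()
            if n_plates != 1:
                report.add(f"SMARTpool {sid} spread over {n_plates} plates")
            if len(grp) != 4:
                report.add(f"SMARTpool {sid}: replicate count {len(grp)} != 4")
    elif dataset.tier == "secondary" and not samples.empty:
        for (pid, sid), grp in samples.groupby(["plate_id", "sirna_id"]):
            reps = sorted(grp["replicate"])
            if len(reps) != len(set(reps)):
                report.add(f"siRNA {sid} duplicated within a replicate of "
                           f"plate {pid}")
            if len(reps) != 3:
                report.add(f"siRNA {sid}: {len(reps)} replicate plates != 3")
        for gene, grp in samples.groupby("gene_symbol"):
            n_sirnas = grp["sirna_id"].nunique()
            if n_sirnas != 6:
                report.add(f"gene {gene}: {n_sirnas} distinct siRNAs != 6")

    # control minimums, per plate ("at least 3 wells each")
    for pid, plate in frame.groupby("plate_id", sort=False):
        ctl = plate[plate["well_anno"].isin(CONTROL_ANNOS)]
        if ctl.empty:
            report.add(f"plate {pid}: no control wells")
            continue
        counts = ctl.groupby(["well_anno", "replicate"]).size()
        for (anno, rep), n in counts.items():
            if n < scheme.min_control_wells:
                report.add(
                    f"plate {pid} replicate {rep}: control {anno} has {n} "
                    f"wells, below the at-least-{scheme.min_control_wells}"
                    "-wells-each minimum")
    return report

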