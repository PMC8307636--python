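"""Domain types and on-disk artifact handling.

The package works on three kinds of inputs: a log-scale miRNA expression
matrix (miRNAs x samples, tab-separated), a sample annotation table linking
samples to patients and tissues (CSV), and a per-patient table of
environmental exposures, smoking history and benzo(a)pyrene-DNA adduct
(tetrol) levels (CSV).  Everything downstream consumes the validated types
defined here.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "Tissue",
    "Histotype",
    "ExpressionMatrix",
    "SampleAnnotation",
    "ExposureProfile",
    "AdductMeasurement",
    "DifferentialRecord",
    "DifferentialTable",
    "Signature",
    "AttributionReport",
    "ValidationError",
    "read_expression",
    "write_expression",
    "read_metadata",
    "validate_pairing",
    "write_report",
    "read_differential_table",
    "read_signature",
    "read_attribution_report",
    "read_literature_list",
    "read_geo_series_matrix",
]

# Tetrol method detection limits (instrument units, pg/mL); measurements at
# or below these are flagged as below-MDL but never zero-filled.
MDL_TETROL_I1 = 2.0
MDL_TETROL_II2 = 3.1


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates a structural invariant."""


class Scale(str, enum.Enum):
    RAW_LINEAR = "raw_linear"
    LOG2 = "log2"


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class Histotype(str, enum.Enum):
    SCLC = "SCLC"
    NSCLC = "NSCLC"
    UNKNOWN = "unknown"


@dataclass
class ExpressionMatrix:
    """miRNA x sample intensity matrix.

    ``values`` is a dense float array with one row per entry of
    ``mirna_ids`` and one column per entry of ``sample_ids``.  Probe-level
    replicates are allowed (duplicate miRNA ids) until
    :func:`envsig.preprocess.average_replicates` collapses them; sample ids
    must always be unique.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale = Scale.LOG2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not all(self.mirna_ids) or not all(self.sample_ids):
            raise ValidationError("empty identifier")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def has_replicates(self) -> bool:
        return len(set(self.mirna_ids)) != len(self.mirna_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_ids, columns=self.sample_ids)

    def subset_mirnas(self, mirnas: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given miRNAs, preserving row order of the matrix."""
        wanted = set(mirnas)
        idx = [i for i, m in enumerate(self.mirna_ids) if m in wanted]
        missing = wanted - set(self.mirna_ids)
        if missing:
            raise ValidationError(f"miRNAs not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            [self.mirna_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
            self.scale,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        idx = [pos[s] for s in samples]
        return ExpressionMatrix(
            list(self.mirna_ids), list(samples), self.values[:, idx], self.scale
        )


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    patient_id: str
    tissue: Tissue
    histotype: Histotype = Histotype.UNKNOWN


NEVER_SMOKER = "never"


@dataclass(frozen=True)
class ExposureProfile:
    """Questionnaire-derived exposure covariates for one patient.

    ``years_since_cessation`` is ``None`` for never-smokers; ``complete``
    is False when the questionnaire was unavailable, in which case the
    patient is excluded from attribution (never imputed).
    """

    patient_id: str
    passive_smoke_home: bool
    passive_smoke_work: bool
    vehicle_traffic_home: bool
    distance_etna_km: float
    radon_risk: bool
    years_since_cessation: float | None
    never_smoker: bool
    complete: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.distance_etna_km <= 1000.0):
            raise ValidationError(
                f"implausible Etna distance {self.distance_etna_km} km "
                f"for patient {self.patient_id}"
            )
        if self.years_since_cessation is not None and self.years_since_cessation < 0:
            raise ValidationError("negative years since cessation")


@dataclass(frozen=True)
class AdductMeasurement:
    """Benzo(a)pyrene tetrol levels in lymphocyte DNA (pg per ug DNA)."""

    patient_id: str
    tetrol_I1: float
    tetrol_II2: float
    total: float
    below_mdl_I1: bool = False
    below_mdl_II2: bool = False

    def __post_init__(self) -> None:
        if self.tetrol_I1 < 0 or self.tetrol_II2 < 0:
            raise ValidationError(f"negative tetrol level for {self.patient_id}")
        if abs(self.total - (self.tetrol_I1 + self.tetrol_II2)) > 1e-6:
            raise ValidationError(
                f"adduct total {self.total} != I1+II2 "
                f"{self.tetrol_I1 + self.tetrol_II2} for {self.patient_id}"
            )


@dataclass(frozen=True)
class DifferentialRecord:
    mirna_id: str
    log2fc: float
    t_stat: float
    p_value: float
    direction: str  # "up" | "down"
    selected: bool
    degenerate: bool = False


@dataclass
class DifferentialTable:
    records: list[DifferentialRecord]
    contrast: str = "tumor_vs_normal"

    def __post_init__(self) -> None:
        n_sel = sum(r.selected for r in self.records)
        if self.n_up + self.n_down != n_sel:
            raise ValidationError("selection counts inconsistent")

    @property
    def n_selected(self) -> int:
        return sum(r.selected for r in self.records)

    @property
    def n_up(self) -> int:
        return sum(r.selected and r.direction == "up" for r in self.records)

    @property
    def n_down(self) -> int:
        return sum(r.selected and r.direction == "down" for r in self.records)

    def selected_records(self) -> list[DifferentialRecord]:
        return [r for r in self.records if r.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna_id": [r.mirna_id for r in self.records],
                "log2fc": [r.log2fc for r in self.records],
                "t_stat": [r.t_stat for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "direction": [r.direction for r in self.records],
                "selected": [r.selected for r in self.records],
                "degenerate": [r.degenerate for r in self.records],
            }
        )


@dataclass
class Signature:
    """A named, directed miRNA set tied to one exposure (or cancer itself)."""

    name: str
    exposure_key: str
    members: frozenset[tuple[str, str]]  # (mirna_id, "up"|"down")
    provenance: str = "derived"  # derived | literature | merged

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def mirna_ids(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.members)

    def sorted_members(self) -> list[tuple[str, str]]:
        return sorted(self.members)


@dataclass
class AttributionReport:
    """Per-patient altered-miRNA counts and median-threshold attribution."""

    patient_ids: list[str]
    exposures: list[str]
    counts: np.ndarray  # patients x exposures, integer
    medians: np.ndarray  # per exposure
    above_median: np.ndarray  # boolean, patients x exposures
    n_above: dict[str, int]
    ranking: list[str]
    signature_sizes: dict[str, int] = field(default_factory=dict)
    tiebreak: str = "signature_size"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.above_median = np.asarray(self.above_median, dtype=bool)
        col_sums = self.above_median.sum(axis=0)
        for j, e in enumerate(self.exposures):
            if self.n_above[e] != int(col_sums[j]):
                raise ValidationError(f"n_above inconsistent for exposure {e}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale: Scale = Scale.LOG2) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (first column = miRNA id).

    Duplicate miRNA rows (replicate spots) are retained; duplicate sample
    headers and non-numeric cells are hard errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ValidationError(f"duplicate sample ids in header of {path}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    sample_ids = [str(c) for c in df.columns]
    mirna_ids = [str(i) for i in df.index]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=True)):
            for j, cell in enumerate(row[1:]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric cell at miRNA {mirna_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}: {cell!r}"
                    ) from None
        raise
    if np.isnan(values).any():
        raise ValidationError(f"missing cells in {path}")
    return ExpressionMatrix(mirna_ids, sample_ids, values, scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="miRNA_ID", float_format="%.10g")


def _parse_bool(cell: object) -> bool:
    s = str(cell).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    raise ValidationError(f"unparseable boolean cell: {cell!r}")


def _is_missing(cell: object) -> bool:
    return pd.isna(cell) or str(cell).strip() == ""


def read_metadata(
    samples_path: str | Path,
    exposures_path: str | Path,
    adducts_path: str | Path | None = None,
) -> tuple[list[SampleAnnotation], list[ExposureProfile], list[AdductMeasurement]]:
    """Read and cross-reference the CSV metadata tables.

    Exposure/adduct rows for patients absent from the sample table are
    dropped with a warning; pairing (one tumor + one normal per patient) is
    validated.  Any missing exposure answer marks the whole profile
    incomplete — attribution later ignores incomplete profiles rather than
    imputing.
    """
    import warnings

    samples_df = pd.read_csv(samples_path, dtype=str)
    required = {"sample_id", "patient_id", "tissue"}
    if not required.issubset(samples_df.columns):
        raise ValidationError(f"sample table missing columns {required - set(samples_df.columns)}")
    annotations = []
    for row in samples_df.itertuples(index=False):
        histotype = Histotype(getattr(row, "histotype", "unknown") or "unknown")
        annotations.append(
            SampleAnnotation(
                sample_id=str(row.sample_id),
                patient_id=str(row.patient_id),
                tissue=Tissue(str(row.tissue).lower()),
                histotype=histotype,
            )
        )
    validate_pairing(annotations)
    known_patients = {a.patient_id for a in annotations}

    exp_df = pd.read_csv(exposures_path, dtype=str)
    profiles = []
    exposure_cols = [
        "passive_smoke_home",
        "passive_smoke_work",
        "vehicle_traffic_home",
        "distance_etna_km",
        "radon_risk",
    ]
    for row in exp_df.itertuples(index=False):
        pid = str(row.patient_id)
        if pid not in known_patients:
            warnings.warn(f"exposure row for unknown patient {pid}; dropped", stacklevel=2)
            continue
        cells = {c: getattr(row, c, None) for c in exposure_cols}
        complete = not any(_is_missing(v) for v in cells.values())
        ysc_cell = getattr(row, "years_since_cessation", None)
        never = (not _is_missing(ysc_cell)) and str(ysc_cell).strip().lower() == NEVER_SMOKER
        profiles.append(
            ExposureProfile(
                patient_id=pid,
                passive_smoke_home=_parse_bool(cells["passive_smoke_home"]) if complete else False,
                passive_smoke_work=_parse_bool(cells["passive_smoke_work"]) if complete else False,
                vehicle_traffic_home=_parse_bool(cells["vehicle_traffic_home"]) if complete else False,
                distance_etna_km=float(cells["distance_etna_km"]) if complete else 0.0,
                radon_risk=_parse_bool(cells["radon_risk"]) if complete else False,
                years_since_cessation=(
                    None if never or _is_missing(ysc_cell) else float(ysc_cell)
                ),
                never_smoker=never,
                complete=complete,
            )
        )

    adducts: list[AdductMeasurement] = []
    if adducts_path is not None:
        add_df = pd.read_csv(adducts_path, dtype=str)
        for row in add_df.itertuples(index=False):
            pid = str(row.patient_id)
            if pid not in known_patients:
                warnings.warn(f"adduct row for unknown patient {pid}; dropped", stacklevel=2)
                continue
            i1 = float(row.tetrol_I1)
            ii2 = float(row.tetrol_II2)
            total = float(getattr(row, "total", i1 + ii2))
            adducts.append(
                AdductMeasurement(
                    patient_id=pid,
                    tetrol_I1=i1,
                    tetrol_II2=ii2,
                    total=total,
                    below_mdl_I1=i1 <= MDL_TETROL_I1,
                    below_mdl_II2=ii2 <= MDL_TETROL_II2,
                )
            )
    return annotations, profiles, adducts


def validate_pairing(annotations: Sequence[SampleAnnotation]) -> None:
    """Every patient must have exactly one tumor and one normal sample."""
    by_patient: dict[str, dict[Tissue, int]] = {}
    for a in annotations:
        by_patient.setdefault(a.patient_id, {Tissue.TUMOR: 0, Tissue.NORMAL: 0})
        by_patient[a.patient_id][a.tissue] += 1
    bad = [
        pid
        for pid, c in by_patient.items()
        if c[Tissue.TUMOR] != 1 or c[Tissue.NORMAL] != 1
    ]
    if bad:
        raise ValidationError(f"unpaired or multiply-sampled patients: {sorted(bad)}")


# ---------------------------------------------------------------------------
# report serialization (deterministic order, exact round-trip)
# ---------------------------------------------------------------------------


def write_report(obj, path: str | Path, format: str | None = None) -> None:
    """Write a result object as TSV or JSON (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "tsv"
    if format not in {"tsv", "json"}:
        raise ValueError(f"unknown format {format!r}")

    if isinstance(obj, DifferentialTable):
        if format == "tsv":
            df = obj.to_frame()
            df.insert(0, "contrast", obj.contrast)
            df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        else:
            payload = {
                "contrast": obj.contrast,
                "records": [dataclasses.asdict(r) for r in obj.records],
            }
            path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif isinstance(obj, Signature):
        payload = {
            "name": obj.name,
            "exposure_key": obj.exposure_key,
            "provenance": obj.provenance,
            "n": obj.n,
            "members": [list(m) for m in obj.sorted_members()],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif isinstance(obj, AttributionReport):
        if format == "tsv":
            df = pd.DataFrame(obj.counts, index=obj.patient_ids, columns=obj.exposures)
            df.to_csv(path, sep="\t", index_label="patient_id")
        else:
            payload = {
                "patient_ids": obj.patient_ids,
                "exposures": obj.exposures,
                "counts": obj.counts.tolist(),
                "medians": [float(m) for m in obj.medians],
                "above_median": obj.above_median.tolist(),
                "n_above": obj.n_above,
                "ranking": obj.ranking,
                "signature_sizes": obj.signature_sizes,
                "tiebreak": obj.tiebreak,
            }
            path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif isinstance(obj, pd.DataFrame):
        if format == "tsv":
            obj.to_csv(path, sep="\t", index=False, float_format="%.17g")
        else:
            path.write_text(obj.to_json(orient="records", indent=1))
    else:
        raise TypeError(f"no serializer for {type(obj).__name__}")


def read_differential_table(path: str | Path) -> DifferentialTable:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str})
    records = [
        DifferentialRecord(
            mirna_id=str(r.mirna_id),
            log2fc=float(r.log2fc),
            t_stat=float(r.t_stat),
            p_value=float(r.p_value),
            direction=str(r.direction),
            selected=bool(r.selected),
            degenerate=bool(getattr(r, "degenerate", False)),
        )
        for r in df.itertuples(index=False)
    ]
    contrast = str(df["contrast"].iloc[0]) if "contrast" in df.columns and len(df) else "tumor_vs_normal"
    return DifferentialTable(records, contrast=contrast)


def read_signature(path: str | Path) -> Signature:
    payload = json.loads(Path(path).read_text())
    return Signature(
        name=payload["name"],
        exposure_key=payload["exposure_key"],
        members=frozenset((m, d) for m, d in payload["members"]),
        provenance=payload["provenance"],
    )


def read_attribution_report(path: str | Path) -> AttributionReport:
    payload = json.loads(Path(path).read_text())
    return AttributionReport(
        patient_ids=payload["patient_ids"],
        exposures=payload["exposures"],
        counts=np.asarray(payload["counts"], dtype=int),
        medians=np.asarray(payload["medians"], dtype=float),
        above_median=np.asarray(payload["above_median"], dtype=bool),
        n_above={k: int(v) for k, v in payload["n_above"].items()},
        ranking=payload["ranking"],
        signature_sizes={k: int(v) for k, v in payload.get("signature_sizes", {}).items()},
        tiebreak=payload.get("tiebreak", "signature_size"),
    )


def read_literature_list(path: str | Path) -> list[str]:
    """One miRNA id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_geo_series_matrix(path: str | Path, scale: Scale = Scale.LOG2) -> ExpressionMatrix:
    """Import an uncompressed GEO series-matrix text file.

    Convenience entry point for re-running the pipeline on a deposited
    series (e.g. an Agilent miRNA array series): keeps only the block
    between the series-matrix table markers.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValidationError(f"{path} is not a series-matrix file") from None
    from io import StringIO

    table = "\n".join(lines[start + 1 : end])
    df = pd.read_csv(StringIO(table), sep="\t", index_col=0)
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)
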