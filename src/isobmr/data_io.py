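"""Reading, writing and validation of count matrices, sample annotations
and experimental designs.

Counts are stored genes-in-rows (the TempO-Seq convention). Orientation is
never guessed: callers that hold a samples-in-rows table pass
``transpose=True`` explicitly. Vehicle controls are identified solely by
``concentration_uM == 0``; the vehicle string (e.g. "0.1% DMSO") is
metadata, not a control flag. Concentrations are µM, times are hours,
both plain floats.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

ANNOTATION_COLUMNS = [
    "sample_id",
    "chemical",
    "concentration_uM",
    "time_h",
    "bio_rep",
    "tech_rep",
    "plate",
    "well",
]


class DataIOError(ValueError):
    """Malformed input table or annotation."""


@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes × samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataIOError("counts must be a 2-D genes × samples array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataIOError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            rounded = np.rint(as_int)
            bad = np.nonzero(~np.isclose(as_int, rounded, atol=0, rtol=0))
            if bad[0].size:
                g, s = bad[0][0], bad[1][0]
                raise DataIOError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {as_int[g, s]}"
                )
            self.counts = rounded.astype(np.int64)
        neg = np.nonzero(self.counts < 0)
        if neg[0].size:
            g, s = neg[0][0], neg[1][0]
            raise DataIOError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise DataIOError(f"duplicate {label} id: {x!r}")
                seen.add(x)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.nonzero(keep)[0]
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return CountMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleAnnotation:
    """One sequencing sample: its treatment cell and plate position."""

    sample_id: str
    chemical: str | None
    concentration: float  # µM; exactly 0 for vehicle controls
    time_h: float
    bio_rep: int
    tech_rep: int
    plate: str
    well: str

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DataIOError(
                f"sample {self.sample_id!r}: negative concentration "
                f"{self.concentration}"
            )
        if self.time_h <= 0:
            raise DataIOError(f"sample {self.sample_id!r}: time_h must be > 0")
        if self.concentration == 0 and self.chemical is not None:
            raise DataIOError(
                f"sample {self.sample_id!r}: vehicle control (concentration 0) "
                f"must have chemical = None, got {self.chemical!r}"
            )

    @property
    def is_control(self) -> bool:
        return self.concentration == 0


def _default_chemicals() -> list[str]:
    return [
        "aflatoxin B1",
        "benzo[a]pyrene",
        "cyclosporine A",
        "rotenone",
        "trichostatin A",
    ]


def dilution_series(top: float, factor: float, n: int = 8) -> list[float]:
    """Descending geometric dilution series starting at ``top``."""
    return [top / factor**i for i in range(n)]


@dataclass
class ExperimentDesign:
    """The concentration × time × replicate layout of the study.

    Defaults mirror the reference design: 5 chemicals, 8 concentrations at
    dilution factor 2.5 (top 50 µM, 10 µM for rotenone), exposure times
    {2, 6, 12, 24, 48} h, 3 biological × 3 technical replicates, 2 plates
    per time point each holding 4 of the 8 concentrations plus 6 vehicle
    controls.
    """

    chemicals: list[str] = field(default_factory=_default_chemicals)
    concentrations_per_chemical: dict[str, list[float]] = field(default_factory=dict)
    dilution_factor: float = 2.5
    time_points_h: list[float] = field(default_factory=lambda: [2.0, 6.0, 12.0, 24.0, 48.0])
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    n_controls_per_plate: int = 6
    n_plates_per_timepoint: int = 2

    def __post_init__(self) -> None:
        if not self.concentrations_per_chemical:
            self.concentrations_per_chemical = {
                chem: dilution_series(10.0 if chem == "rotenone" else 50.0, self.dilution_factor)
                for chem in self.chemicals
            }
        for chem, concs in self.concentrations_per_chemical.items():
            if len(concs) % self.n_plates_per_timepoint != 0:
                raise DataIOError(
                    f"{chem}: {len(concs)} concentrations do not split evenly "
                    f"over {self.n_plates_per_timepoint} plates"
                )
            for hi, lo in zip(concs, concs[1:]):
                if not np.isclose(hi / lo, self.dilution_factor, rtol=1e-9):
                    raise DataIOError(
                        f"{chem}: consecutive concentrations {hi}/{lo} do not "
                        f"match dilution factor {self.dilution_factor}"
                    )

    @property
    def n_concentrations(self) -> int:
        return len(next(iter(self.concentrations_per_chemical.values())))

    def total_samples(self) -> int:
        """Closed-form sample count of the full layout."""
        n_conc_per_plate = self.n_concentrations // self.n_plates_per_timepoint
        per_plate = (
            len(self.chemicals) * n_conc_per_plate * self.n_tech_reps
            + self.n_controls_per_plate
        )
        return (
            per_plate
            * self.n_plates_per_timepoint
            * len(self.time_points_h)
            * self.n_bio_reps
        )


# ---------------------------------------------------------------------------
# count matrix I/O


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_counts(
    path: str | Path,
    format: str = "delimited",
    transpose: bool = False,
) -> CountMatrix:
    """Read a count matrix.

    ``delimited``: gene ids in the first column, sample ids in the header,
    tab- or comma-separated. ``matrix-market``: coordinate triplets at
    ``path`` with sidecar id lists ``<stem>.genes.txt`` / ``<stem>.samples.txt``
    (one id per line, genes indexing rows).
    """
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"count file not found: {path}")
    if format == "delimited":
        df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise DataIOError(f"duplicate sample id in header: {dup!r}")
        cm = CountMatrix(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(),
        )
    elif format == "matrix-market":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.name.split(".")[0]
        genes = _read_id_list(path.parent / f"{stem}.genes.txt")
        samples = _read_id_list(path.parent / f"{stem}.samples.txt")
        cm = CountMatrix(genes, samples, np.asarray(mat))
    else:
        raise DataIOError(f"unknown count format: {format!r}")
    if transpose:
        cm = CountMatrix(cm.sample_ids, cm.gene_ids, cm.counts.T)
    return cm


def _read_id_list(path: Path) -> list[str]:
    if not path.exists():
        raise DataIOError(f"sidecar id list not found: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_counts(cm: CountMatrix, path: str | Path, format: str = "delimited") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        cm.to_frame().to_csv(path, sep=sep, index_label="gene_id")
    elif format == "matrix-market":
        # mmwrite emits a binary-safe ASCII stream; route through text handles
        buf = _io.BytesIO()
        scipy.io.mmwrite(buf, scipy.sparse.coo_matrix(cm.counts), field="integer")
        path.write_bytes(buf.getvalue())
        stem = path.name.split(".")[0]
        (path.parent / f"{stem}.genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        (path.parent / f"{stem}.samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise DataIOError(f"unknown count format: {format!r}")


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotation(path: str | Path) -> list[SampleAnnotation]:
    """Read the sample annotation table (see ANNOTATION_COLUMNS)."""
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataIOError(f"annotation missing required column(s): {missing}")
    return annotation_from_frame(df)


def annotation_from_frame(df: pd.DataFrame) -> list[SampleAnnotation]:
    records = []
    for row in df.itertuples(index=False):
        chem = getattr(row, "chemical")
        if pd.isna(chem) or chem == "":
            chem = None
        records.append(
            SampleAnnotation(
                sample_id=str(row.sample_id),
                chemical=chem,
                concentration=float(row.concentration_uM),
                time_h=float(row.time_h),
                bio_rep=int(row.bio_rep),
                tech_rep=int(row.tech_rep),
                plate=str(row.plate),
                well=str(row.well),
            )
        )
    return records


def annotation_to_frame(annotation: Sequence[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotation],
            "chemical": [a.chemical if a.chemical is not None else "" for a in annotation],
            "concentration_uM": [a.concentration for a in annotation],
            "time_h": [a.time_h for a in annotation],
            "bio_rep": [a.bio_rep for a in annotation],
            "tech_rep": [a.tech_rep for a in annotation],
            "plate": [a.plate for a in annotation],
            "well": [a.well for a in annotation],
        }
    )


def write_annotation(annotation: Sequence[SampleAnnotation], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    annotation_to_frame(annotation).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# design validation


@dataclass
class DesignReport:
    """Completeness report of an annotation against a design; never raises."""

    total_samples: int
    expected_samples: int
    cells: pd.DataFrame  # chemical, concentration_uM, time_h, bio_rep, n_tech, present
    missing_cells: pd.DataFrame
    controls_per_plate: pd.Series

    @property
    def complete(self) -> bool:
        return len(self.missing_cells) == 0 and self.total_samples == self.expected_samples


def validate_design(
    annotation: Sequence[SampleAnnotation], design: ExperimentDesign
) -> DesignReport:
    """Count samples and flag missing (chemical, concentration, time, bio_rep)
    cells relative to the design's full enumeration."""
    df = annotation_to_frame(annotation)
    treated = df[df["concentration_uM"] > 0]
    key = ["chemical", "concentration_uM", "time_h", "bio_rep"]
    observed = (
        treated.groupby(key, sort=False).size().rename("n_tech").reset_index()
        if len(treated)
        else pd.DataFrame(columns=key + ["n_tech"])
    )
    rows = []
    for chem in design.chemicals:
        for conc in design.concentrations_per_chemical[chem]:
            for t in design.time_points_h:
                for b in range(1, design.n_bio_reps + 1):
                    rows.append((chem, conc, t, b))
    cells = pd.DataFrame(rows, columns=key)
    cells = cells.merge(observed, on=key, how="left")
    cells["n_tech"] = cells["n_tech"].astype(float).fillna(0).astype(int)
    cells["present"] = cells["n_tech"] >= 1
    controls = df[df["concentration_uM"] == 0]
    per_plate = controls.groupby("plate").size() if len(controls) else pd.Series(dtype=int)
    return DesignReport(
        total_samples=len(df),
        expected_samples=design.total_samples(),
        cells=cells,
        missing_cells=cells[~cells["present"]].reset_index(drop=True),
        controls_per_plate=per_plate,
    )
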