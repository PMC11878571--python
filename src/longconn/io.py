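"""Reading, validating and addressing connectomes, parcellations and cohorts.

This module defines the on-disk contract for the whole pipeline:

* connectivity matrices — dense delimited numeric text (comma or whitespace)
  or MatrixMarket coordinate files, one square symmetric nonnegative matrix
  of streamline counts per subject per timepoint per parcellation scale,
  named ``<subject_id>_<timepoint>_scale<k>.<ext>``;
* parcellation metadata — TSV with columns
  ``parcel_id, name, hemisphere, lobe, structure_class``;
* cohort metadata — TSV with one row per subject-scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "Connectome",
    "ParcellationInfo",
    "SubjectRecord",
    "Cohort",
    "FormatError",
    "ValidationError",
    "DEFAULT_LOBES",
    "read_connectome",
    "write_connectome",
    "read_parcellation",
    "write_parcellation",
    "read_cohort",
]

log = logging.getLogger(__name__)

#: Default cortical lobe taxonomy: five lobes per hemisphere, ten in total.
DEFAULT_LOBES = ("frontal", "temporal", "parietal", "occipital", "insular-cingulate")

HEMISPHERES = ("left", "right", "midline")
STRUCTURE_CLASSES = (
    "cortical",
    "thalamic",
    "hippocampal",
    "brainstem",
    "other-subcortical",
)
TIMEPOINTS = ("control", "early", "late")

#: Asymmetry up to this relative Frobenius tolerance is repaired by averaging.
ASYMMETRY_TOL = 1e-6


class FormatError(ValueError):
    """File does not conform to the on-disk contract (shape, columns, dialect)."""


class ValidationError(ValueError):
    """Data is well-formed but violates a domain invariant."""


@dataclass(frozen=True)
class Connectome:
    """Square symmetric nonnegative weighted adjacency of streamline counts.

    The diagonal is zero: self-connections carry no meaning for the metrics
    implemented here and are discarded on read.
    """

    matrix: np.ndarray
    parcel_ids: tuple[str, ...]
    scale: int
    subject_id: str
    timepoint: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise FormatError(f"connectome matrix must be square, got {m.shape}")
        if len(self.parcel_ids) != m.shape[0]:
            raise FormatError(
                f"{len(self.parcel_ids)} parcel ids for a {m.shape[0]}-row matrix"
            )
        if not np.all(np.isfinite(m)):
            raise ValidationError("connectome contains non-finite entries")
        if np.any(m < 0):
            raise ValidationError("connectome contains negative weights")
        if not np.allclose(m, m.T, atol=1e-9, rtol=0.0):
            raise ValidationError("connectome matrix is not symmetric")
        if np.any(np.diag(m) != 0.0):
            raise ValidationError("connectome diagonal must be zero")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if not 1 <= int(self.scale) <= 5:
            raise ValidationError(f"scale must be in 1..5, got {self.scale}")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "parcel_ids", tuple(self.parcel_ids))

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ParcellationInfo:
    """Parcel → (hemisphere, lobe, structure class) lookup for one atlas scale.

    Invariants enforced on construction: exactly 7 thalamic parcels per
    hemisphere, 3 hippocampal parcels per hemisphere, 4 brainstem parcels,
    every cortical parcel mapped to exactly one lobe, and 10 (hemisphere,
    lobe) combinations across both hemispheres.
    """

    scale: int
    parcel_ids: tuple[str, ...]
    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    lobes: tuple[str | None, ...]
    structure_classes: tuple[str, ...]
    lobe_taxonomy: tuple[str, ...] = DEFAULT_LOBES

    def __post_init__(self) -> None:
        n = len(self.parcel_ids)
        for name, seq in (
            ("names", self.names),
            ("hemispheres", self.hemispheres),
            ("lobes", self.lobes),
            ("structure_classes", self.structure_classes),
        ):
            if len(seq) != n:
                raise FormatError(f"{name} has length {len(seq)}, expected {n}")
        for h in self.hemispheres:
            if h not in HEMISPHERES:
                raise ValidationError(f"unknown hemisphere label {h!r}")
        for s in self.structure_classes:
            if s not in STRUCTURE_CLASSES:
                raise ValidationError(f"unknown structure class {s!r}")
        for lobe, sc in zip(self.lobes, self.structure_classes):
            if sc == "cortical":
                if lobe is None:
                    raise ValidationError("cortical parcel without a lobe assignment")
                if lobe not in self.lobe_taxonomy:
                    raise ValidationError(f"unknown lobe label {lobe!r}")
        for hemi in ("left", "right"):
            n_thal = sum(
                1
                for h, s in zip(self.hemispheres, self.structure_classes)
                if h == hemi and s == "thalamic"
            )
            if n_thal != 7:
                raise ValidationError(
                    f"expected 7 thalamic parcels in {hemi} hemisphere, found {n_thal}"
                )
            n_hipp = sum(
                1
                for h, s in zip(self.hemispheres, self.structure_classes)
                if h == hemi and s == "hippocampal"
            )
            if n_hipp != 3:
                raise ValidationError(
                    f"expected 3 hippocampal parcels in {hemi} hemisphere, found {n_hipp}"
                )
        n_bs = sum(1 for s in self.structure_classes if s == "brainstem")
        if n_bs != 4:
            raise ValidationError(f"expected 4 brainstem parcels, found {n_bs}")
        cortical_lobe_pairs = {
            (h, l)
            for h, l, s in zip(self.hemispheres, self.lobes, self.structure_classes)
            if s == "cortical"
        }
        if len(cortical_lobe_pairs) != 10:
            raise ValidationError(
                f"expected 10 (hemisphere, lobe) combinations, found "
                f"{len(cortical_lobe_pairs)}"
            )

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def indices(
        self,
        structure_class: str | None = None,
        hemisphere: str | None = None,
        lobe: str | None = None,
    ) -> np.ndarray:
        """Integer indices of parcels matching every given filter."""
        mask = np.ones(self.n_parcels, dtype=bool)
        if structure_class is not None:
            mask &= np.asarray([s == structure_class for s in self.structure_classes])
        if hemisphere is not None:
            mask &= np.asarray([h == hemisphere for h in self.hemispheres])
        if lobe is not None:
            mask &= np.asarray([l == lobe for l in self.lobes])
        return np.flatnonzero(mask)

    def thalamic_indices(self, hemisphere: str) -> np.ndarray:
        return self.indices(structure_class="thalamic", hemisphere=hemisphere)


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and clinical labels for one subject.

    ``ages`` maps timepoint → age at scan in years. Controls have exactly one
    scan (timepoint ``control``); patients have exactly two (``early`` and
    ``late`` with age_early ≤ age_late) and a recorded affected lobe.
    """

    subject_id: str
    group: str
    ages: Mapping[str, float]
    sex: str
    histopathology: str | None = None
    seizure_free: bool | None = None
    affected_lobe: str | None = None
    affected_hemisphere: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValidationError(
                f"subject {self.subject_id}: unknown group {self.group!r}"
            )
        if self.sex not in ("male", "female"):
            raise ValidationError(f"subject {self.subject_id}: unknown sex {self.sex!r}")
        tps = set(self.ages)
        if self.group == "control":
            if tps != {"control"}:
                raise ValidationError(
                    f"control {self.subject_id} must have exactly one scan "
                    f"at timepoint 'control', got {sorted(tps)}"
                )
        else:
            if tps != {"early", "late"}:
                raise ValidationError(
                    f"patient {self.subject_id} must have exactly two scans "
                    f"(early, late), got {sorted(tps)}"
                )
            if self.ages["early"] > self.ages["late"]:
                raise ValidationError(
                    f"patient {self.subject_id}: age at early scan exceeds late"
                )
            if self.affected_lobe is None or self.affected_hemisphere is None:
                raise ValidationError(
                    f"patient {self.subject_id}: affected lobe/hemisphere required"
                )

    @property
    def timepoints(self) -> tuple[str, ...]:
        return ("control",) if self.group == "control" else ("early", "late")


@dataclass
class Cohort:
    """A set of subjects with their connectomes at one or more scales."""

    subjects: list[SubjectRecord]
    connectomes: dict[tuple[str, str, int], Connectome]
    parcellations: dict[int, ParcellationInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValidationError("no subjects in cohort")
        for subj in self.subjects:
            for tp in subj.timepoints:
                scales = {
                    sc for (sid, t, sc) in self.connectomes if sid == subj.subject_id and t == tp
                }
                for sc in scales:
                    conn = self.connectomes[(subj.subject_id, tp, sc)]
                    parc = self.parcellations.get(sc)
                    if parc is not None and conn.parcel_ids != parc.parcel_ids:
                        raise ValidationError(
                            f"{subj.subject_id}/{tp}/scale{sc}: parcel ordering "
                            "differs from the scale's parcellation"
                        )

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]

    @property
    def patients(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "patient"]

    def connectome(self, subject_id: str, timepoint: str, scale: int) -> Connectome:
        return self.connectomes[(subject_id, timepoint, scale)]

    def scales(self) -> tuple[int, ...]:
        return tuple(sorted({sc for (_, _, sc) in self.connectomes}))


def _load_matrix(path: Path) -> np.ndarray:
    if path.suffix == ".mtx":
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        return np.asarray(m, dtype=float)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        return np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse as delimited numeric text: {exc}")


def read_connectome(
    path: str | Path,
    parcellation: ParcellationInfo,
    *,
    subject_id: str | None = None,
    timepoint: str | None = None,
) -> Connectome:
    """Read and validate one connectivity matrix.

    Symmetry is repaired by averaging when the relative Frobenius asymmetry is
    at most ``ASYMMETRY_TOL`` (floating-point artifacts); anything larger is
    rejected. The diagonal is zeroed.

    Subject id and timepoint default to the ``<subject>_<timepoint>_scale<k>``
    pattern of the file name.
    """
    path = Path(path)
    m = _load_matrix(path)
    if m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: matrix is {m.shape}, not square")
    if m.shape[0] != parcellation.n_parcels:
        raise FormatError(
            f"{path}: {m.shape[0]} rows but parcellation scale "
            f"{parcellation.scale} has {parcellation.n_parcels} parcels"
        )
    if not np.all(np.isfinite(m)):
        raise ValidationError(f"{path}: non-finite entries")
    if np.any(m < 0):
        raise ValidationError(f"{path}: negative weights")
    denom = np.linalg.norm(m)
    asym = np.linalg.norm(m - m.T) / denom if denom > 0 else 0.0
    if asym > ASYMMETRY_TOL:
        raise ValidationError(
            f"{path}: relative asymmetry {asym:.3g} exceeds {ASYMMETRY_TOL:g}"
        )
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    if subject_id is None or timepoint is None:
        parts = path.stem.split("_")
        if len(parts) >= 3 and parts[-1].startswith("scale"):
            subject_id = subject_id or "_".join(parts[:-2])
            timepoint = timepoint or parts[-2]
        else:
            raise FormatError(
                f"{path}: cannot infer subject/timepoint from file name; "
                "expected <subject>_<timepoint>_scale<k>"
            )
    return Connectome(
        matrix=m,
        parcel_ids=parcellation.parcel_ids,
        scale=parcellation.scale,
        subject_id=subject_id,
        timepoint=timepoint,
    )


def write_connectome(conn: Connectome, path: str | Path) -> Path:
    """Write a connectome matrix; format chosen by suffix (.mtx or text)."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(conn.matrix))
    else:
        np.savetxt(path, conn.matrix, delimiter=",", fmt="%.17g")
    return path


def read_parcellation(path: str | Path, scale: int) -> ParcellationInfo:
    """Read a parcellation TSV and validate its invariants for ``scale``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"parcel_id", "name", "hemisphere", "lobe", "structure_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    lobes = [None if pd.isna(l) or l == "" else l for l in df["lobe"]]
    return ParcellationInfo(
        scale=scale,
        parcel_ids=tuple(df["parcel_id"]),
        names=tuple(df["name"]),
        hemispheres=tuple(df["hemisphere"]),
        lobes=tuple(lobes),
        structure_classes=tuple(df["structure_class"]),
    )


def write_parcellation(parc: ParcellationInfo, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "parcel_id": parc.parcel_ids,
            "name": parc.names,
            "hemisphere": parc.hemispheres,
            "lobe": ["" if l is None else l for l in parc.lobes],
            "structure_class": parc.structure_classes,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def _parse_bool(x: str) -> bool | None:
    if pd.isna(x) or x == "":
        return None
    return str(x).strip().lower() in ("1", "true", "yes")


def read_cohort(
    metadata_path: str | Path,
    matrix_dir: str | Path,
    scale: int,
    parcellation: ParcellationInfo,
) -> Cohort:
    """Load a cohort: metadata TSV plus one matrix file per subject-scan.

    Matrix files are looked up as ``<subject_id>_<timepoint>_scale<k>`` with
    extension ``.csv``, ``.txt`` or ``.mtx`` under ``matrix_dir``.
    """
    metadata_path = Path(metadata_path)
    matrix_dir = Path(matrix_dir)
    df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if df.empty:
        raise ValidationError(f"{metadata_path}: no subjects")
    subjects: list[SubjectRecord] = []
    connectomes: dict[tuple[str, str, int], Connectome] = {}
    for sid, rows in df.groupby("subject_id", sort=True):
        group = rows["group"].iloc[0]
        ages = {r["timepoint"]: float(r["age_at_scan"]) for _, r in rows.iterrows()}
        if len(ages) != len(rows):
            raise ValidationError(f"subject {sid}: duplicate timepoints")
        if group == "patient" and len(rows) != 2:
            raise ValidationError(
                f"patient {sid}: expected 2 scans, found {len(rows)}"
            )
        first = rows.iloc[0]
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                group=group,
                ages=ages,
                sex=first["sex"],
                histopathology=None if pd.isna(first.get("histopathology")) else first["histopathology"],
                seizure_free=_parse_bool(first.get("seizure_free")),
                affected_lobe=None if pd.isna(first.get("affected_lobe")) else first["affected_lobe"],
                affected_hemisphere=None if pd.isna(first.get("affected_hemisphere")) else first["affected_hemisphere"],
            )
        )
        for tp in ages:
            stem = f"{sid}_{tp}_scale{scale}"
            for ext in (".csv", ".txt", ".mtx"):
                candidate = matrix_dir / (stem + ext)
                if candidate.exists():
                    break
            else:
                raise IOError(
                    f"missing matrix file {stem}.{{csv,txt,mtx}} for subject {sid}"
                )
            connectomes[(str(sid), tp, scale)] = read_connectome(
                candidate, parcellation, subject_id=str(sid), timepoint=tp
            )
    cohort = Cohort(
        subjects=subjects,
        connectomes=connectomes,
        parcellations={scale: parcellation},
    )
    log.info(
        "loaded cohort: %d controls, %d patients, %d connectomes at scale %d",
        len(cohort.controls),
        len(cohort.patients),
        len(connectomes),
        scale,
    )
    return cohort
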