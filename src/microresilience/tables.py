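"""Core data model and file I/O for the perturbation-recovery pipeline.

The central object is the :class:`GenusCountTable` — a samples × genera
integer count matrix with per-sample annotations (subject, arm, visit).
Visits follow the two-arm antibiotic/supplementation design: a baseline
clinical investigation day (CID1), a post-antibiotic visit after wash-out
(CID2, start of supplementation), three supplementary visits at two-week
intervals (SuV1–SuV3) and the end-of-supplementation visit (CID3).

All tables read and write plain UTF-8 TSV; BIOM (1.0 JSON and 2.x HDF5)
count tables can optionally be read.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("microresilience")

__all__ = [
    "Arm",
    "Timepoint",
    "SampleRecord",
    "GenusCountTable",
    "LongOutcomeTable",
    "ValidationError",
    "FormatError",
    "read_count_table",
    "read_metadata",
    "write_metadata",
    "join_and_validate",
]


class ValidationError(ValueError):
    """A table violates a structural invariant (duplicates, unknown labels...)."""


class FormatError(ValueError):
    """A file cannot be parsed into a valid table."""


class Arm(enum.Enum):
    """Intervention arm: placebo (maltodextrin) or 2'-fucosyllactose."""

    PLACEBO = "placebo"
    FL2 = "2FL"

    @classmethod
    def parse(cls, label: str) -> "Arm":
        key = str(label).strip().lower().replace("'", "").replace("′", "")
        aliases = {
            "placebo": cls.PLACEBO,
            "pla": cls.PLACEBO,
            "2fl": cls.FL2,
            "2-fl": cls.FL2,
            "fl2": cls.FL2,
            "fl": cls.FL2,
        }
        if key not in aliases:
            raise ValidationError(
                f"unknown arm label {label!r}; allowed: placebo, 2FL"
            )
        return aliases[key]


class Timepoint(enum.Enum):
    """Ordered study visits.

    ``week`` is weeks since the start of supplementation (CID2 = 0).  CID1
    precedes the antibiotic perturbation and carries no supplementation
    week; models over the supplementation period use CID2..CID3 only.
    """

    CID1 = 0
    CID2 = 1
    SUV1 = 2
    SUV2 = 3
    SUV3 = 4
    CID3 = 5

    @classmethod
    def parse(cls, label: str) -> "Timepoint":
        key = str(label).strip().upper().replace("-", "")
        if key in cls.__members__:
            return cls[key]
        raise ValidationError(
            f"unknown timepoint label {label!r}; allowed: "
            + ", ".join(cls.__members__)
        )

    @property
    def week(self) -> float | None:
        """Weeks since the start of supplementation; None for CID1."""
        return {
            Timepoint.CID1: None,
            Timepoint.CID2: 0.0,
            Timepoint.SUV1: 2.0,
            Timepoint.SUV2: 4.0,
            Timepoint.SUV3: 6.0,
            Timepoint.CID3: 8.0,
        }[self]

    def __lt__(self, other: "Timepoint") -> bool:
        return self.value < other.value


#: Visits after the baseline sample, in study order.
POST_BASELINE = (
    Timepoint.CID2,
    Timepoint.SUV1,
    Timepoint.SUV2,
    Timepoint.SUV3,
    Timepoint.CID3,
)

#: Supplementation-period visits used in the eight-week models.
SUPPLEMENTATION_PERIOD = POST_BASELINE


@dataclass(frozen=True)
class SampleRecord:
    """Annotation for one sequenced sample."""

    sample_id: str
    subject_id: str
    arm: Arm
    timepoint: Timepoint

    @property
    def week(self) -> float | None:
        return self.timepoint.week


@dataclass
class GenusCountTable:
    """Samples × genera integer count matrix with sample annotations.

    ``counts`` is a DataFrame with sample IDs as the index and genus-level
    taxon labels as columns.  ``meta`` maps each sample ID to its
    :class:`SampleRecord`; samples without a record are only permitted
    before :func:`join_and_validate`.
    """

    counts: pd.DataFrame
    meta: dict[str, SampleRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon IDs: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.isnan(values.astype(float)).any():
            i, j = np.argwhere(np.isnan(values.astype(float)))[0]
            raise FormatError(
                f"non-numeric count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise FormatError(
                f"non-integer count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        if self.meta:
            pairs = [(r.subject_id, r.timepoint) for r in self.meta.values()]
            if len(pairs) != len(set(pairs)):
                raise ValidationError("duplicate (subject, timepoint) in metadata")

    # -- accessors ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def record(self, sample_id: str) -> SampleRecord:
        return self.meta[sample_id]

    def meta_frame(self) -> pd.DataFrame:
        """Sample annotations as a DataFrame aligned to the count rows."""
        rows = []
        for sid in self.sample_ids:
            rec = self.meta.get(sid)
            if rec is None:
                continue
            rows.append(
                dict(
                    sample_id=sid,
                    subject_id=rec.subject_id,
                    arm=rec.arm.value,
                    timepoint=rec.timepoint.name,
                    week=rec.week,
                )
            )
        return pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "arm", "timepoint", "week"]
        )

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class LongOutcomeTable:
    """Tidy (subject, arm, timepoint, variable, value) outcome records.

    Optional covariate columns carry the baseline BMI and the change of
    the variable during the antibiotic week (value at CID2 minus CID1),
    which enter the metabolic mixed models as fixed covariates.
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "arm", "timepoint", "variable", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        df = self.data.copy()
        df["arm"] = [a if isinstance(a, Arm) else Arm.parse(a) for a in df["arm"]]
        df["timepoint"] = [
            t if isinstance(t, Timepoint) else Timepoint.parse(t)
            for t in df["timepoint"]
        ]
        key = df[["subject_id", "timepoint", "variable"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValidationError(
                f"duplicate (subject, timepoint, variable): {key[key.duplicated()].iloc[0]}"
            )
        self.data = df.reset_index(drop=True)

    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique())

    def for_variable(self, name: str) -> pd.DataFrame:
        sub = self.data[self.data["variable"] == name].copy()
        if sub.empty:
            raise ValidationError(f"no records for variable {name!r}")
        return sub

    def with_vanco_delta(self) -> "LongOutcomeTable":
        """Attach the antibiotic-week change (CID2 − CID1) per subject/variable."""
        df = self.data.copy()
        wide = df.pivot_table(
            index=["subject_id", "variable"],
            columns="timepoint",
            values="value",
            aggfunc="first",
        )
        delta = {}
        for (subj, var), row in wide.iterrows():
            v1 = row.get(Timepoint.CID1, np.nan)
            v2 = row.get(Timepoint.CID2, np.nan)
            delta[(subj, var)] = v2 - v1
        df["vanco_delta_covariate"] = [
            delta.get((s, v), np.nan)
            for s, v in zip(df["subject_id"], df["variable"])
        ]
        return LongOutcomeTable(df)

    def to_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        df["arm"] = [a.value for a in df["arm"]]
        df["timepoint"] = [t.name for t in df["timepoint"]]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LongOutcomeTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df)


# ---------------------------------------------------------------------------
# readers


def read_count_table(path: str | Path, format: str = "tsv") -> GenusCountTable:
    """Read a samples × genera count table from TSV or BIOM.

    TSV dialect: UTF-8, tab-separated, first column ``sample_id``, header
    row of genus labels.  BIOM tables (orientation observations × samples)
    are transposed to samples × taxa on read.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        if path.stat().st_size == 0:
            raise FormatError(f"empty count table: {path}")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001 - rewrap as format error
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        df.index.name = None
        if df.empty and df.columns.empty:
            raise FormatError(f"empty count table: {path}")
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                sid = df.index[bad.argmax()]
                raise FormatError(
                    f"non-numeric count at sample {sid!r}, taxon {col!r}"
                )
        return GenusCountTable(df)
    if format == "biom":
        return _read_biom(path)
    raise ValidationError(f"unknown count-table format {format!r}")


def _read_biom(path: Path) -> GenusCountTable:
    """Minimal BIOM reader: 1.0 (JSON) and 2.x (HDF5, CSR/CSC) layouts."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        import h5py

        with h5py.File(path, "r") as f:
            obs_ids = [x.decode() for x in f["observation/ids"][:]]
            sample_ids = [x.decode() for x in f["sample/ids"][:]]
            grp = f["observation/matrix"]  # CSR over observations
            data = grp["data"][:]
            indices = grp["indices"][:]
            indptr = grp["indptr"][:]
        from scipy.sparse import csr_matrix

        mat = csr_matrix(
            (data, indices, indptr), shape=(len(obs_ids), len(sample_ids))
        ).toarray()
        df = pd.DataFrame(mat.T, index=sample_ids, columns=obs_ids)
        return GenusCountTable(df)
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(obs_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(mat.T, index=sample_ids, columns=obs_ids)
    return GenusCountTable(df)


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read per-sample annotations from TSV.

    Requires columns ``subject_id``, ``arm``, ``timepoint``; an optional
    ``sample_id`` column names the sequenced sample (defaults to
    ``<subject>_<timepoint>``).
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    required = {"subject_id", "arm", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    records: list[SampleRecord] = []
    seen: set[tuple[str, Timepoint]] = set()
    for _, row in df.iterrows():
        tp = Timepoint.parse(row["timepoint"])
        subj = str(row["subject_id"]).strip()
        key = (subj, tp)
        if key in seen:
            raise ValidationError(f"duplicate (subject, timepoint): {key}")
        seen.add(key)
        sid = (
            str(row["sample_id"]).strip()
            if "sample_id" in df.columns and pd.notna(row.get("sample_id"))
            else f"{subj}_{tp.name}"
        )
        records.append(SampleRecord(sid, subj, Arm.parse(row["arm"]), tp))
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        dict(
            sample_id=r.sample_id,
            subject_id=r.subject_id,
            arm=r.arm.value,
            timepoint=r.timepoint.name,
        )
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def join_and_validate(
    table: GenusCountTable, meta: Sequence[SampleRecord] | Mapping[str, SampleRecord]
) -> tuple[GenusCountTable, int]:
    """Attach metadata to a count table, dropping unannotated samples.

    Returns the joined table and the number of dropped samples.  Raises if
    the intersection is empty.  Idempotent: re-joining the result with the
    same records is a no-op.
    """
    if isinstance(meta, Mapping):
        by_sample = dict(meta)
    else:
        by_sample = {r.sample_id: r for r in meta}
    keep = [s for s in table.sample_ids if s in by_sample]
    dropped = table.n_samples - len(keep)
    if not keep:
        raise ValidationError("no samples with metadata — empty join")
    if dropped:
        logger.warning(
            "join_and_validate: dropped %d of %d samples without metadata",
            dropped,
            table.n_samples,
        )
    joined = GenusCountTable(
        table.counts.loc[keep].copy(), {s: by_sample[s] for s in keep}
    )
    return joined, dropped
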