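"""Long-format IDP measurement tables and per-IDP matrix extraction.

The canonical container is a tidy table of one measurement per row —
``(subject_id, session_label, idp_name, value)`` — with optional session
metadata (site, scanner manufacturer, model) and an IDP -> class map.
Every statistic in the package operates on a complete-case subject-by-session
matrix derived from this table via :meth:`IDPTable.extract_matrix`.

In a travelling-heads design a "session" is a scanning site (the same
subjects visit every site); in a test-retest design it is a visit at a single
site. Missing acquisitions (a scanner failure for one subject at one site)
are represented either by an absent row or by a NaN/empty value; both are
normalised to NaN on ingestion and handled by complete-case filtering at
matrix-extraction time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    InsufficientDataError,
    IntegrityError,
)

RECORD_COLUMNS = ["subject_id", "session_label", "idp_name", "value"]
SESSION_COLUMNS = ["session_label", "site_name", "manufacturer", "scanner_model"]

#: Complete-case matrices with fewer subjects than this are rejected: below
#: n = 3 the error term of the two-way decomposition has fewer than
#: (3-1)(k-1) degrees of freedom and every downstream test is meaningless.
MIN_SUBJECTS = 3


class Manufacturer(enum.Enum):
    SIEMENS = "SIEMENS"
    GE = "GE"
    NONE = "NONE"

    @classmethod
    def coerce(cls, value) -> "Manufacturer":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().upper())


@dataclass(frozen=True)
class SessionInfo:
    """Metadata for one session (site/visit): where and on what scanner."""

    session_label: str
    site_name: str = ""
    manufacturer: Manufacturer = Manufacturer.NONE
    scanner_model: str = ""


@dataclass(frozen=True)
class SubjectBySessionMatrix:
    """Complete-case n x k value matrix for a single phenotype.

    Row i / column j holds subject ``subject_ids[i]`` measured at session
    ``session_labels[j]``. Subjects with any missing value among the
    requested sessions have been dropped, so ``values`` has no NaNs.
    """

    values: np.ndarray
    subject_ids: tuple
    session_labels: tuple
    idp_name: str = ""
    complete_case: bool = True

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_sessions(self) -> int:
        return self.values.shape[1]


class IDPTable:
    """Validated long-format measurement table plus session/class metadata.

    Parameters
    ----------
    records
        DataFrame with columns ``subject_id, session_label, idp_name, value``.
        Non-finite values are treated as missing. At most one row per
        (subject, session, idp) triple.
    sessions
        Optional mapping/iterable of :class:`SessionInfo`. Sessions appearing
        in the records but not listed here are filled in with empty metadata.
    class_map
        Optional ``idp_name -> class_label`` mapping. IDPs without an entry
        fall into the class ``"unclassified"``.
    """

    def __init__(self, records: pd.DataFrame, sessions=None, class_map=None):
        records = records.copy()
        missing_cols = [c for c in RECORD_COLUMNS if c not in records.columns]
        if missing_cols:
            raise FormatError(f"record table lacks columns: {missing_cols}")
        records = records[RECORD_COLUMNS]
        for col in ("subject_id", "session_label", "idp_name"):
            records[col] = records[col].astype(str)
        records["value"] = pd.to_numeric(records["value"], errors="coerce")
        records.loc[~np.isfinite(records["value"].to_numpy()), "value"] = np.nan

        dup = records.duplicated(subset=["subject_id", "session_label", "idp_name"])
        if dup.any():
            first = records.loc[dup.idxmax(), ["subject_id", "session_label", "idp_name"]]
            raise IntegrityError(
                "duplicate (subject, session, idp) triple: "
                + ", ".join(first.astype(str))
            )

        self.records = records.reset_index(drop=True)

        if sessions is None:
            sessions = []
        if isinstance(sessions, dict):
            sessions = list(sessions.values())
        info = {s.session_label: s for s in sessions}
        for label in sorted(self.records["session_label"].unique()):
            info.setdefault(label, SessionInfo(session_label=label))
        self.sessions: dict[str, SessionInfo] = dict(sorted(info.items()))

        self.class_map: dict[str, str] = dict(class_map or {})

    # ------------------------------------------------------------------ I/O

    @classmethod
    def read(cls, path, fmt=None, sessions_path=None, class_map_path=None) -> "IDPTable":
        """Read a measurement table (TSV or CSV) with optional sidecars.

        ``fmt`` is ``"tsv"`` or ``"csv"``; inferred from the file suffix when
        omitted. Empty fields and the tokens NA/NaN in the value column are
        read as missing.
        """
        sep = _resolve_sep(path, fmt)
        try:
            records = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - pandas error detail
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if not set(RECORD_COLUMNS) <= set(records.columns):
            raise FormatError(
                f"{path}: header must name {RECORD_COLUMNS}, got {list(records.columns)}"
            )
        records["value"] = records["value"].replace(
            {"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan}
        )

        sessions = None
        if sessions_path is not None:
            meta = pd.read_csv(sessions_path, sep=_resolve_sep(sessions_path, fmt), dtype=str)
            if not set(SESSION_COLUMNS) <= set(meta.columns):
                raise FormatError(
                    f"{sessions_path}: header must name {SESSION_COLUMNS}"
                )
            sessions = [
                SessionInfo(
                    session_label=row.session_label,
                    site_name=row.site_name,
                    manufacturer=Manufacturer.coerce(row.manufacturer),
                    scanner_model=row.scanner_model,
                )
                for row in meta.itertuples()
            ]

        class_map = None
        if class_map_path is not None:
            cmap = pd.read_csv(class_map_path, sep=_resolve_sep(class_map_path, fmt), dtype=str)
            if not {"idp_name", "class_label"} <= set(cmap.columns):
                raise FormatError(f"{class_map_path}: header must name idp_name, class_label")
            class_map = dict(zip(cmap["idp_name"], cmap["class_label"]))

        return cls(records, sessions=sessions, class_map=class_map)

    def write(self, path, fmt=None) -> None:
        """Write the records at full precision; missing values as empty fields."""
        sep = _resolve_sep(path, fmt)
        out = self.records.copy()
        out["value"] = out["value"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        out.to_csv(path, sep=sep, index=False)

    def write_sessions(self, path, fmt=None) -> None:
        sep = _resolve_sep(path, fmt)
        rows = [
            {
                "session_label": s.session_label,
                "site_name": s.site_name,
                "manufacturer": s.manufacturer.value,
                "scanner_model": s.scanner_model,
            }
            for s in self.sessions.values()
        ]
        pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, sep=sep, index=False)

    def write_class_map(self, path, fmt=None) -> None:
        sep = _resolve_sep(path, fmt)
        pd.DataFrame(
            sorted(self.class_map.items()), columns=["idp_name", "class_label"]
        ).to_csv(path, sep=sep, index=False)

    # ----------------------------------------------------------- accessors

    @property
    def idp_names(self) -> list[str]:
        return sorted(self.records["idp_name"].unique())

    @property
    def session_labels(self) -> list[str]:
        return sorted(self.sessions)

    def class_of(self, idp_name: str) -> str:
        return self.class_map.get(idp_name, "unclassified")

    def n_missing(self) -> int:
        return int(self.records["value"].isna().sum())

    # ---------------------------------------------------------- operations

    def extract_matrix(self, idp_name: str, sessions=None) -> SubjectBySessionMatrix:
        """Complete-case subject-by-session matrix for one phenotype.

        Subjects with any missing value among the requested sessions are
        dropped. Subject and session ordering is lexicographic, so the
        result is invariant to the record order of the input table.

        Raises
        ------
        InsufficientDataError
            If fewer than :data:`MIN_SUBJECTS` subjects survive.
        """
        if sessions is None:
            sessions = self.session_labels
        sessions = sorted(sessions)
        if not sessions:
            raise ConfigurationError("empty session subset")
        sub = self.records[self.records["idp_name"] == idp_name]
        if sub.empty:
            raise KeyError(f"unknown IDP {idp_name!r}")
        wide = sub.pivot(index="subject_id", columns="session_label", values="value")
        for s in sessions:
            if s not in wide.columns:
                wide[s] = np.nan
        wide = wide[sessions].sort_index()
        complete = wide.dropna()
        if len(complete) < MIN_SUBJECTS:
            raise InsufficientDataError(
                f"{idp_name}: only {len(complete)} complete subjects over "
                f"sessions {sessions} (minimum {MIN_SUBJECTS})",
                n_complete=len(complete),
            )
        return SubjectBySessionMatrix(
            values=complete.to_numpy(dtype=float),
            subject_ids=tuple(complete.index),
            session_labels=tuple(sessions),
            idp_name=idp_name,
            complete_case=len(complete) < len(wide.dropna(how="all")),
        )

    def subset_sessions(self, manufacturer) -> list[str]:
        """Session labels for one scanner manufacturer.

        ``Manufacturer.NONE`` (or the string "none"/"all") returns every
        session — the all-sites analysis. Raises
        :class:`~idprel.errors.ConfigurationError` when no session matches.
        """
        if isinstance(manufacturer, str) and manufacturer.lower() == "all":
            return self.session_labels
        manufacturer = Manufacturer.coerce(manufacturer)
        if manufacturer is Manufacturer.NONE:
            return self.session_labels
        labels = [
            s.session_label
            for s in self.sessions.values()
            if s.manufacturer is manufacturer
        ]
        if not labels:
            raise ConfigurationError(
                f"no session with manufacturer {manufacturer.value}"
            )
        return sorted(labels)


def _resolve_sep(path, fmt) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("tsv", "csv"):
            raise FormatError(f"unknown format {fmt!r}")
        return "\t" if fmt == "tsv" else ","
    suffix = str(path).rsplit(".", 1)[-1].lower()
    return "," if suffix == "csv" else "\t"


def read_idp_table(path, fmt=None, sessions_path=None, class_map_path=None) -> IDPTable:
    """Functional alias for :meth:`IDPTable.read`."""
    return IDPTable.read(
        path, fmt=fmt, sessions_path=sessions_path, class_map_path=class_map_path
    )
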