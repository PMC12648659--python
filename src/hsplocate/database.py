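"""CAS-indexed solvent HSP database.

A database is a flat CSV (UTF-8, comma-separated) with header

    cas,name,synonyms,smiles,dD,dP,dH

``synonyms`` packs alternative names with ``;``. Extra columns (boiling
point, price...) are carried through verbatim but never interpreted.
Records resolve by CAS number or, case-insensitively, by name or synonym.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pandas as pd

from .core import HspVector, NegativeComponentWarning
from .errors import (
    AmbiguousSolventError,
    DataValidationError,
    SchemaError,
    SolventNotFoundError,
)

__all__ = [
    "SolventRecord",
    "SolventDatabase",
    "Issue",
    "load_database",
    "write_database",
    "validate_database",
]

REQUIRED_COLUMNS = ("cas", "name", "dD", "dP", "dH")
_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


@dataclass(frozen=True)
class Issue:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    record: str  # CAS or a line reference
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.record}: {self.message}"


@dataclass(frozen=True)
class SolventRecord:
    """One database entry: CAS registry number, names, optional SMILES, HSPs."""

    cas: str
    name: str
    hsp: HspVector
    synonyms: Tuple[str, ...] = ()
    smiles: Optional[str] = None
    extras: Tuple[Tuple[str, str], ...] = field(default_factory=tuple)

    def keys(self) -> Tuple[str, ...]:
        """All strings under which this record can be looked up."""
        return (self.cas, self.name) + self.synonyms


def cas_checksum_ok(cas: str) -> bool:
    """CAS registry check digit: weighted digit sum mod 10."""
    digits = cas.replace("-", "")
    body, check = digits[:-1], int(digits[-1])
    total = sum(int(d) * w for w, d in enumerate(reversed(body), start=1))
    return total % 10 == check


class SolventDatabase:
    """An in-memory, validated collection of :class:`SolventRecord`.

    With ``strict=True`` (default) duplicate CAS numbers or name/synonym
    collisions between different records raise :class:`DataValidationError`
    at construction; with ``strict=False`` collisions are kept and surface
    as :class:`AmbiguousSolventError` on lookup.
    """

    def __init__(self, records: Iterable[SolventRecord], strict: bool = True):
        self.records: List[SolventRecord] = list(records)
        self._by_cas: Dict[str, SolventRecord] = {}
        self._by_name: Dict[str, List[SolventRecord]] = {}
        issues: List[Issue] = []
        for rec in self.records:
            if rec.cas in self._by_cas:
                issues.append(Issue("error", rec.cas, "duplicate CAS number"))
            else:
                self._by_cas[rec.cas] = rec
            for key in (rec.name,) + rec.synonyms:
                bucket = self._by_name.setdefault(key.strip().lower(), [])
                if rec not in bucket:
                    bucket.append(rec)
        if strict:
            for key, bucket in self._by_name.items():
                if len(bucket) > 1:
                    cass = ", ".join(r.cas for r in bucket)
                    issues.append(
                        Issue("error", key, f"name/synonym resolves to multiple records ({cass})")
                    )
            if issues:
                raise DataValidationError(issues)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolventRecord]:
        return iter(self.records)

    def __contains__(self, key: str) -> bool:
        try:
            self.get(key)
            return True
        except (SolventNotFoundError, AmbiguousSolventError):
            return False

    def get(self, key: str) -> SolventRecord:
        """Resolve ``key`` (CAS, name or synonym; names case-insensitive)."""
        k = str(key).strip()
        if k in self._by_cas:
            return self._by_cas[k]
        bucket = self._by_name.get(k.lower(), [])
        if len(bucket) == 1:
            return bucket[0]
        if len(bucket) > 1:
            raise AmbiguousSolventError(k, bucket)
        raise SolventNotFoundError(k)


def get_solvent(db: SolventDatabase, key: str) -> SolventRecord:
    """Functional alias for :meth:`SolventDatabase.get`."""
    return db.get(key)


def load_database(path) -> SolventDatabase:
    """Read and validate a solvent CSV (dialect in the module docstring).

    Raises :class:`SchemaError` for a missing required column and
    :class:`DataValidationError` (with 1-based line numbers; line 1 is the
    header) for unparseable numerics, negative components, empty names or
    duplicate CAS values.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"database file {path} is missing required column {col!r}")

    known = {"cas", "name", "synonyms", "smiles", "dD", "dP", "dH"}
    extra_cols = [c for c in df.columns if c not in known]

    records: List[SolventRecord] = []
    issues: List[Issue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rowd = dict(zip(df.columns, row))
        cas = rowd["cas"].strip()
        name = rowd["name"].strip()
        if not name:
            issues.append(Issue("error", f"line {line}", "empty solvent name"))
            continue
        comps = {}
        bad = False
        for col in ("dD", "dP", "dH"):
            try:
                comps[col] = float(rowd[col])
            except (TypeError, ValueError):
                issues.append(
                    Issue("error", f"line {line}", f"unparseable numeric {col}={rowd[col]!r}")
                )
                bad = True
        if bad:
            continue
        if min(comps.values()) < 0:
            issues.append(Issue("error", f"line {line}", f"negative HSP component in {comps}"))
            continue
        synonyms = tuple(
            s.strip() for s in rowd.get("synonyms", "").split(";") if s.strip()
        )
        smiles = rowd.get("smiles", "").strip() or None
        extras = tuple((c, rowd[c]) for c in extra_cols)
        records.append(
            SolventRecord(
                cas=cas, name=name, hsp=HspVector(comps["dD"], comps["dP"], comps["dH"]),
                synonyms=synonyms, smiles=smiles, extras=extras,
            )
        )
    if issues:
        raise DataValidationError(issues)
    return SolventDatabase(records)


def write_database(db: SolventDatabase, path) -> None:
    """Write ``db`` back to the flat CSV dialect; numerics round-trip exactly."""
    extra_cols: List[str] = []
    for rec in db:
        for col, _ in rec.extras:
            if col not in extra_cols:
                extra_cols.append(col)
    rows = []
    for rec in db:
        row = {
            "cas": rec.cas,
            "name": rec.name,
            "synonyms": ";".join(rec.synonyms),
            "smiles": rec.smiles or "",
            "dD": rec.hsp.dD,
            "dP": rec.hsp.dP,
            "dH": rec.hsp.dH,
        }
        row.update({c: "" for c in extra_cols})
        row.update(dict(rec.extras))
        rows.append(row)
    cols = ["cas", "name", "synonyms", "smiles", "dD", "dP", "dH"] + extra_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def validate_database(db: SolventDatabase) -> List[Issue]:
    """Report invariant violations without raising.

    Errors: negative HSP components, empty names, duplicate CAS.
    Warnings: malformed CAS pattern, failing CAS checksum, unparseable
    SMILES (only checked when RDKit is importable).
    """
    issues: List[Issue] = []
    seen_cas: Dict[str, int] = {}
    try:  # structure validation is best-effort
        from rdkit import Chem  # type: ignore
        from rdkit import RDLogger  # type: ignore

        RDLogger.DisableLog("rdApp.*")
    except ImportError:  # pragma: no cover - rdkit is optional
        Chem = None

    for rec in db:
        ref = rec.cas or rec.name
        seen_cas[rec.cas] = seen_cas.get(rec.cas, 0) + 1
        if not rec.name:
            issues.append(Issue("error", ref, "empty solvent name"))
        h = rec.hsp
        if min(h.dD, h.dP, h.dH) < 0:
            issues.append(Issue("error", ref, f"negative HSP component ({h.dD}, {h.dP}, {h.dH})"))
        if not _CAS_RE.match(rec.cas):
            issues.append(Issue("warning", ref, f"malformed CAS number {rec.cas!r}"))
        elif not cas_checksum_ok(rec.cas):
            issues.append(Issue("warning", ref, f"CAS checksum fails for {rec.cas!r}"))
        if rec.smiles and Chem is not None:
            if Chem.MolFromSmiles(rec.smiles) is None:
                issues.append(Issue("warning", ref, f"unparseable SMILES {rec.smiles!r}"))
    for cas, count in seen_cas.items():
        if count > 1:
            issues.append(Issue("error", cas, f"CAS appears {count} times"))
    return issues


def record_from_values(cas: str, name: str, dD: float, dP: float, dH: float, **kw) -> SolventRecord:
    """Convenience constructor used by tests and synthetic panels."""
    with warnings.catch_warnings():
        warnings.simplefilter("always", NegativeComponentWarning)
        return SolventRecord(cas=cas, name=name, hsp=HspVector(dD, dP, dH), **kw)
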