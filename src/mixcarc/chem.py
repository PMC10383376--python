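"""Single-chemical libraries.

Ingests CSV tables of single chemicals, validates and de-duplicates them,
maps source-specific group labels (MEG, IARC, JSOH, NTP, CPDB) onto binary
and three-class carcinogenicity targets, and synthesizes seeded libraries of
small valid structures for testing and simulation.

Label semantics
---------------
``binary_label``: 1 = carcinogen, 0 = noncarcinogen.
``class_label``: 0 = noncarcinogen, 1 = possibly carcinogenic / not
classifiable, 2 = carcinogen or probable carcinogen.
``td50``: median toxic dose rate in mg/kg body weight/day — the chronic dose
inducing tumors in half of test animals (the CPDB potency unit).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    CapacityError,
    FormatError,
    MappingError,
    RowValidationError,
    SmilesError,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")


class Source(str, Enum):
    """Provenance of a single-chemical record."""

    MEG = "MEG"
    NTP = "NTP"
    IARC = "IARC"
    JSOH = "JSOH"
    CPDB = "CPDB"
    DCDB = "DCDB"
    LIT = "LIT"
    SYNTH = "SYNTH"


#: Sentinel returned by :func:`map_group_to_binary` for groups excluded from
#: the binary task (e.g. MEG Group D, "not classifiable").
EXCLUDED = "excluded"


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string, raising :class:`SmilesError` if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass
class ChemicalRecord:
    """One single chemical with its labels and optional dose annotations.

    Invariants are enforced at construction: the SMILES must parse, ``td50``
    and ``concentration`` must be positive when present, and binary/class
    labels must be mutually consistent (class 0 <-> binary 0, class 2 -> binary 1).
    """

    chem_id: str
    smiles: str
    source: Source
    source_group: str = ""
    binary_label: int | None = None
    class_label: int | None = None
    td50: float | None = None  # mg/kg body weight/day
    concentration: float | None = None  # mg/L
    canonical: str = field(init=False, repr=False)

    def __post_init__(self):
        self.source = Source(self.source)
        self.canonical = canonical_smiles(self.smiles)
        if self.binary_label is not None and self.binary_label not in (0, 1):
            raise ValueError(f"{self.chem_id}: binary_label must be 0 or 1")
        if self.class_label is not None and self.class_label not in (0, 1, 2):
            raise ValueError(f"{self.chem_id}: class_label must be 0, 1 or 2")
        if self.td50 is not None and not self.td50 > 0:
            raise ValueError(f"{self.chem_id}: td50 must be positive")
        if self.concentration is not None and not self.concentration > 0:
            raise ValueError(f"{self.chem_id}: concentration must be positive")
        if self.binary_label is not None and self.class_label is not None:
            if self.class_label == 0 and self.binary_label != 0:
                raise ValueError(f"{self.chem_id}: class 0 requires binary 0")
            if self.class_label == 2 and self.binary_label != 1:
                raise ValueError(f"{self.chem_id}: class 2 requires binary 1")
            if self.class_label != 0 and self.binary_label == 0 and self.class_label == 2:
                raise ValueError(f"{self.chem_id}: inconsistent labels")


_REQUIRED_COLUMNS = ("chem_id", "smiles", "source_group")
_OPTIONAL_FLOATS = ("td50", "concentration")


def read_chemical_table(path, source: Source | str | None = None) -> list[ChemicalRecord]:
    """Read a chemicals CSV into validated records, preserving row order.

    The file must be comma-separated UTF-8 with a header naming at least
    ``chem_id``, ``smiles`` and ``source_group``. A ``source`` column is used
    when present, otherwise the ``source`` argument applies to every row.
    Blank optional cells leave the field unset. The first invalid row raises
    :class:`RowValidationError` naming its (1-based, header excluded) index.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        if source is None and "source" not in header:
            raise FormatError("no 'source' column and no source argument given")

        records: list[ChemicalRecord] = []
        for i, row in enumerate(reader, start=1):
            kwargs = {
                "chem_id": row["chem_id"],
                "smiles": row["smiles"],
                "source": Source(row["source"]) if "source" in header and row.get("source") else Source(source),
                "source_group": row.get("source_group", "") or "",
            }
            for col in ("binary_label", "class_label"):
                val = (row.get(col) or "").strip()
                if val:
                    try:
                        kwargs[col] = int(val)
                    except ValueError as exc:
                        raise RowValidationError(i, f"{col}={val!r} is not an integer") from exc
            for col in _OPTIONAL_FLOATS:
                val = (row.get(col) or "").strip()
                if val:
                    try:
                        kwargs[col] = float(val)
                    except ValueError as exc:
                        raise RowValidationError(i, f"{col}={val!r} is not a number") from exc
            try:
                records.append(ChemicalRecord(**kwargs))
            except (SmilesError, ValueError) as exc:
                raise RowValidationError(i, str(exc)) from exc
    return records


def write_chemical_table(records: Sequence[ChemicalRecord], path) -> None:
    """Write records back out as a normalized chemicals CSV."""
    cols = ["chem_id", "smiles", "source", "source_group", "binary_label",
            "class_label", "td50", "concentration"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            writer.writerow([
                r.chem_id, r.smiles, r.source.value, r.source_group,
                "" if r.binary_label is None else r.binary_label,
                "" if r.class_label is None else r.class_label,
                "" if r.td50 is None else repr(r.td50),
                "" if r.concentration is None else repr(r.concentration),
            ])


# --- group-label mappings -------------------------------------------------
#
# MEG (TG 230) groups: A human carcinogen, B probable, C possible,
# D not classifiable, E no evidence. IARC monograph groups 1/2A/2B/3.
# JSOH groups 1/2A/2B. NTP "known" / "reasonably anticipated". CPDB rows are
# flagged carcinogenic (TD50-annotated) or noncarcinogenic.

_BINARY_MAP: dict[Source, dict[str, int | str]] = {
    Source.MEG: {"A": 1, "B": 1, "C": 1, "D": EXCLUDED, "E": 0},
    Source.CPDB: {"carcinogenic": 1, "noncarcinogenic": 0},
    Source.SYNTH: {"0": 0, "1": 1, "2": 1},
}

_CLASS_MAP: dict[Source, dict[str, int]] = {
    Source.MEG: {"A": 2, "B": 2, "C": 1, "D": 1, "E": 0},
    Source.NTP: {"known": 2, "reasonably_anticipated": 2},
    Source.IARC: {"1": 2, "2A": 2, "2B": 1, "3": 1},
    Source.JSOH: {"1": 2, "2A": 2, "2B": 1},
    Source.CPDB: {"carcinogenic": 2, "noncarcinogenic": 0},
    Source.SYNTH: {"0": 0, "1": 1, "2": 2},
}


def _lookup(table, source, group, task):
    source = Source(source)
    try:
        groups = table[source]
    except KeyError:
        raise MappingError(
            f"source {source.value} has no {task} mapping; "
            f"mapped sources: {', '.join(s.value for s in table)}"
        ) from None
    try:
        return groups[group]
    except KeyError:
        raise MappingError(
            f"unknown {source.value} group {group!r} for {task}; "
            f"valid labels: {', '.join(sorted(groups))}"
        ) from None


def map_group_to_binary(source: Source | str, group: str):
    """Map a published group label to the binary target (0, 1 or :data:`EXCLUDED`).

    MEG Groups A/B/C are carcinogens, Group E is the noncarcinogen class and
    Group D ("not classifiable") is excluded from the binary task entirely.
    """
    return _lookup(_BINARY_MAP, source, group, "binary")


def map_group_to_class(source: Source | str, group: str) -> int:
    """Map a published group label to the three-class target {0, 1, 2}."""
    return _lookup(_CLASS_MAP, source, group, "class")


def dedupe_and_resolve(
    records: Iterable[ChemicalRecord], log_path=None
) -> list[ChemicalRecord]:
    """Collapse duplicate structures and drop label-conflicting ones.

    Records are keyed by canonical SMILES (sources spell structures
    differently). Exact duplicates collapse onto the first occurrence, with
    unset optional fields filled in from later duplicates. Structures whose
    records disagree on the binary or the class label across sources are
    removed entirely — both sides of the conflict — and logged. Idempotent.
    """
    by_structure: dict[str, list[ChemicalRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.canonical not in by_structure:
            order.append(rec.canonical)
        by_structure.setdefault(rec.canonical, []).append(rec)

    kept: list[ChemicalRecord] = []
    removal_log: list[str] = []
    for key in order:
        group = by_structure[key]
        binaries = {r.binary_label for r in group if r.binary_label is not None}
        classes = {r.class_label for r in group if r.class_label is not None}
        if len(binaries) > 1 or len(classes) > 1:
            ids = ", ".join(r.chem_id for r in group)
            removal_log.append(f"conflict\t{key}\t{ids}")
            continue
        first = group[0]
        for other in group[1:]:
            removal_log.append(f"duplicate\t{key}\t{other.chem_id} -> {first.chem_id}")
            updates = {}
            for fld in ("binary_label", "class_label", "td50", "concentration"):
                if getattr(first, fld) is None and getattr(other, fld) is not None:
                    updates[fld] = getattr(other, fld)
            if updates:
                first = replace(first, **updates)
        kept.append(first)

    for line in removal_log:
        logger.info("dedupe: %s", line)
    if log_path is not None:
        with open(log_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(removal_log) + ("\n" if removal_log else ""))
    return kept


# --- synthetic library ----------------------------------------------------

def _structure_pool() -> list[str]:
    """Deterministic pool of small valid structures (canonical, unique).

    Branched alkanes, alcohols, amines, halides, nitriles, acids and simple
    substituted benzenes — structurally diverse enough to give distinct
    descriptor rows while staying trivially valid.
    """
    suffixes = ["", "O", "N", "Cl", "Br", "F", "C#N", "C(=O)O", "C(=O)N", "S"]
    candidates: list[str] = []
    for n in range(1, 13):
        chain = "C" * n
        for suf in suffixes:
            candidates.append(chain + suf)
    for n in range(0, 9):
        for suf in suffixes:
            candidates.append("c1ccccc1" + "C" * n + suf)
    for n in range(1, 9):
        for m in (1, 2):
            for suf in suffixes:
                candidates.append("CC(" + "C" * m + ")" + "C" * n + suf)

    seen: set[str] = set()
    pool: list[str] = []
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            pool.append(smi)
    return pool


#: TD50 sampling range for synthetic class-2 carcinogens, mg/kg/day,
#: log-uniform — spans typical CPDB potencies without extreme magnitudes.
TD50_RANGE = (1e-3, 1e3)
#: Exposure-concentration sampling range, mg/L, log-uniform.
CONCENTRATION_RANGE = (1e-2, 1e2)


def synth_library(
    n_class0: int, n_class1: int, n_class2: int, seed: int
) -> list[ChemicalRecord]:
    """Generate a seeded synthetic single-chemical library.

    Emulates the real curated libraries: valid unique structures, class
    labels 0/1/2 with consistent binary labels (classes 1 and 2 are treated
    as carcinogens), a log-uniform TD50 on ``TD50_RANGE`` for every class-2
    record, and a log-uniform exposure concentration for every record.
    Byte-identical output for a fixed seed.
    """
    import numpy as np

    if min(n_class0, n_class1, n_class2) < 0:
        raise ValueError("counts must be non-negative")
    total = n_class0 + n_class1 + n_class2
    pool = _structure_pool()
    if total > len(pool):
        raise CapacityError(
            f"requested {total} structures but the generator holds only {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=total, replace=False)]

    lo_t, hi_t = (math.log10(v) for v in TD50_RANGE)
    lo_c, hi_c = (math.log10(v) for v in CONCENTRATION_RANGE)
    records = []
    classes = [0] * n_class0 + [1] * n_class1 + [2] * n_class2
    for i, (smi, cls) in enumerate(zip(chosen, classes)):
        td50 = 10 ** rng.uniform(lo_t, hi_t) if cls == 2 else None
        conc = 10 ** rng.uniform(lo_c, hi_c)
        records.append(
            ChemicalRecord(
                chem_id=f"S{i:04d}",
                smiles=smi,
                source=Source.SYNTH,
                source_group=str(cls),
                binary_label=0 if cls == 0 else 1,
                class_label=cls,
                td50=td50,
                concentration=conc,
            )
        )
    return records
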