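"""Reading and writing of PSM tables and FASTA databases.

PSM tables are plain TSV with a header row. Column names are decoupled from
the engine that produced them through a :class:`PSMDialect` column map, so any
closed-search engine's export can be adapted with a flat key=value config
file. FASTA reading goes through :mod:`Bio.SeqIO`; writing wraps sequences
at 60 columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .exceptions import ConfigurationError, FastaError, PSMTableError
from .records import (
    DEFAULT_DECOY_PREFIX,
    DEFAULT_RANDOM_PREFIX,
    FastaEntry,
    PSMRecord,
    SpectrumKey,
    derive_is_modified,
    format_modifications,
    origin_from_accession,
    parse_modifications,
    validate_key_profile,
)

_TRUE = {"true", "1", "yes", "decoy", "t"}
_FALSE = {"false", "0", "no", "target", "f", ""}


def read_config(path: str | os.PathLike) -> dict[str, str]:
    """Read a flat ``key = value`` text config (``#`` starts a comment)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


@dataclass(frozen=True)
class PSMDialect:
    """Column mapping for a PSM table.

    ``file``, ``scan``, ``peptide`` and ``score`` are mandatory; the decoy
    flag comes from ``decoy`` (a boolean-ish column) and/or from the decoy
    accession prefix on ``proteins``. When both are available they must agree
    row by row. ``ptm_name`` names the search-specific PTM used to derive
    ``is_modified`` when no explicit column exists.
    """

    file: str = "file"
    scan: str = "scan"
    peptide: str = "peptide"
    score: str = "score"
    charge: str | None = "charge"
    decoy: str | None = "is_decoy"
    modified: str | None = "is_modified"
    modifications: str | None = "modifications"
    proteins: str | None = "proteins"
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    protein_sep: str = ";"
    ptm_name: str | None = None

    @classmethod
    def from_config(cls, path: str | os.PathLike) -> "PSMDialect":
        cfg = read_config(path)
        kwargs = {}
        for fld in ("file", "scan", "peptide", "score", "charge", "decoy", "modified",
                    "modifications", "proteins", "decoy_prefix", "protein_sep", "ptm_name"):
            if fld in cfg:
                kwargs[fld] = cfg[fld] or None
        return cls(**kwargs)


DEFAULT_DIALECT = PSMDialect()

#: Canonical column order of the neutral TSV dialect on write.
_CANONICAL_COLUMNS = ("file", "scan", "peptide", "modifications", "charge",
                      "score", "is_decoy", "is_modified", "proteins")


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise PSMTableError(f"row {row}: cannot interpret {value!r} in column {column!r} as a flag")


def read_psm_table(path: str | os.PathLike, dialect: PSMDialect | None = None) -> list[PSMRecord]:
    """Read one PSM per row from a TSV table under a column-mapping dialect."""
    dialect = dialect or DEFAULT_DIALECT
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise PSMTableError(f"{path}: empty file without a header") from exc

    for logical, column in (("file", dialect.file), ("scan", dialect.scan),
                            ("peptide", dialect.peptide), ("score", dialect.score)):
        if column not in df.columns:
            raise PSMTableError(
                f"{path}: mandatory column {column!r} (mapped from {logical!r}) is missing"
            )
    has_decoy_col = dialect.decoy is not None and dialect.decoy in df.columns
    has_proteins = dialect.proteins is not None and dialect.proteins in df.columns
    if not has_decoy_col and not has_proteins:
        raise PSMTableError(
            f"{path}: no decoy information: neither column {dialect.decoy!r} "
            f"nor protein accessions ({dialect.proteins!r}) are present"
        )

    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        try:
            peptide = row_map[dialect.peptide].strip()
            mods = ()
            if dialect.modifications and dialect.modifications in df.columns:
                mods = parse_modifications(row_map[dialect.modifications])
            charge = None
            if dialect.charge and dialect.charge in df.columns and row_map[dialect.charge].strip():
                charge = int(row_map[dialect.charge])
            proteins: tuple[str, ...] = ()
            if has_proteins:
                raw = row_map[dialect.proteins].strip()
                proteins = tuple(p for p in raw.split(dialect.protein_sep) if p) if raw else ()

            decoy_col = _parse_bool(row_map[dialect.decoy], dialect.decoy, i) if has_decoy_col else None
            decoy_prefix = None
            if proteins:
                decoy_prefix = all(p.startswith(dialect.decoy_prefix) for p in proteins)
            if decoy_col is not None and decoy_prefix is not None and decoy_col != decoy_prefix:
                raise PSMTableError(
                    f"row {i}: decoy column says {decoy_col} but accession prefixes say "
                    f"{decoy_prefix}; the two sources must agree"
                )
            is_decoy = decoy_col if decoy_col is not None else bool(decoy_prefix)

            if dialect.modified and dialect.modified in df.columns:
                is_modified = _parse_bool(row_map[dialect.modified], dialect.modified, i)
            else:
                is_modified = derive_is_modified(mods, dialect.ptm_name)

            rec = PSMRecord(
                key=SpectrumKey(
                    file_name=row_map[dialect.file].strip(),
                    scan_number=int(row_map[dialect.scan]),
                    charge=charge,
                    peptide=None,  # filled after mods are known
                ),
                peptide=peptide,
                modifications=mods,
                charge=charge,
                score=float(row_map[dialect.score]),
                is_decoy=is_decoy,
                is_modified=is_modified,
                proteins=proteins,
            )
            rec = replace(rec, key=replace(rec.key, peptide=rec.annotated_peptide))
            rec.validate()
        except PSMTableError:
            raise
        except (ValueError, KeyError) as exc:
            raise PSMTableError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str | os.PathLike) -> None:
    """Write records as the neutral TSV dialect; lossless round-trip with read."""
    rows = []
    for r in records:
        rows.append({
            "file": r.key.file_name,
            "scan": r.key.scan_number,
            "peptide": r.peptide,
            "modifications": format_modifications(r.modifications, r.peptide),
            "charge": "" if r.charge is None else r.charge,
            "score": repr(r.score),
            "is_decoy": str(r.is_decoy).lower(),
            "is_modified": str(r.is_modified).lower(),
            "proteins": ";".join(r.proteins),
        })
    df = pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_fasta(
    path: str | os.PathLike,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    random_prefix: str = DEFAULT_RANDOM_PREFIX,
) -> list[FastaEntry]:
    """Read a FASTA file; origin is inferred from accession prefixes."""
    entries: list[FastaEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        desc = rec.description[len(rec.id):].strip() \
            if rec.description.startswith(rec.id) else rec.description
        sequence = str(rec.seq)
        if not sequence:
            raise FastaError(f"{path}: entry {accession!r} has an empty sequence")
        entries.append(FastaEntry(
            accession=accession,
            description=desc,
            sequence=sequence.upper(),
            origin=origin_from_accession(accession, decoy_prefix, random_prefix),
        ))
    return entries


def write_fasta(entries: Iterable[FastaEntry], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for e in entries:
            header = f">{e.accession} {e.description}".rstrip()
            fh.write(header + "\n")
            for start in range(0, len(e.sequence), width):
                fh.write(e.sequence[start:start + width] + "\n")


def intersect_psms(
    a: Sequence[PSMRecord],
    b: Sequence[PSMRecord],
    key_profile: Sequence[str],
) -> tuple[set, set, set]:
    """Partition two PSM sets into core and unique keys under a key profile.

    Returns ``(core, unique_a, unique_b)`` as sets of projected key tuples.
    The profile is an explicit subset of ``(file, scan, charge, peptide)``;
    which fields participate in identity is always carried by the caller.
    """
    validate_key_profile(key_profile)
    keys_a = {r.key.project(key_profile) for r in a}
    keys_b = {r.key.project(key_profile) for r in b}
    core = keys_a & keys_b
    return core, keys_a - core, keys_b - core
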