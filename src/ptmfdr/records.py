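"""Core record types: spectrum keys, peptide-spectrum matches, FASTA entries.

A PSM (peptide-spectrum match) is one scored assignment of a peptide sequence
to one MS/MS spectrum. Records carry the target/decoy flag used for FDR
estimation and a ``is_modified`` flag marking the search-specific PTM
(methionine oxidation and fixed modifications such as carbamidomethylation do
not count as "modified" for grouping purposes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, Union

from .exceptions import ConfigurationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

N_TERM = "N-term"
C_TERM = "C-term"

DEFAULT_DECOY_PREFIX = "DECOY_"
DEFAULT_RANDOM_PREFIX = "RND_"

#: Modifications that never count towards ``is_modified`` grouping.
BACKGROUND_MODS = frozenset({"oxidation", "carbamidomethyl"})

#: Key fields, in canonical order, that may participate in PSM identity.
KEY_FIELDS = ("file", "scan", "charge", "peptide")

#: Primary key used for core/unique partitions of search-space experiments
#: (file name, scan number, modified peptide sequence).
SIZING_KEY_PROFILE = ("file", "scan", "peptide")

#: Primary key used when intersecting two search regimes or engines
#: (file name, scan number, charge, modified peptide sequence).
FULL_KEY_PROFILE = ("file", "scan", "charge", "peptide")


class Origin(str, Enum):
    """Provenance of a FASTA entry within a built search database."""

    REAL = "real"
    RANDOM = "random"
    DECOY = "decoy"
    RANDOM_DECOY = "random_decoy"


def origin_from_accession(
    accession: str,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    random_prefix: str = DEFAULT_RANDOM_PREFIX,
) -> Origin:
    """Infer entry origin from its accession prefix alone."""
    if accession.startswith(decoy_prefix):
        rest = accession[len(decoy_prefix):]
        if rest.startswith(random_prefix):
            return Origin.RANDOM_DECOY
        return Origin.DECOY
    if accession.startswith(random_prefix):
        return Origin.RANDOM
    return Origin.REAL


@dataclass(frozen=True)
class Modification:
    """One modification on a peptide.

    ``position`` is a 1-based residue index or a terminus marker
    (:data:`N_TERM` / :data:`C_TERM`); ``mass_delta`` is in Da.
    """

    position: Union[int, str]
    name: str
    mass_delta: float

    def __post_init__(self) -> None:
        if isinstance(self.position, int):
            if self.position < 1:
                raise ValueError(f"modification position must be >= 1, got {self.position}")
        elif self.position not in (N_TERM, C_TERM):
            raise ValueError(f"invalid terminus marker {self.position!r}")


_MOD_TOKEN_RE = re.compile(
    r"^(?:(?P<residue>[A-Z])(?P<pos>\d+)|(?P<term>N-term|C-term))"
    r"\[(?P<name>[^\[\]+\-]+)(?P<delta>[+-]\d+(?:\.\d+)?)\]$"
)


def parse_modification_token(token: str) -> Modification:
    """Parse one ``residue+position[name+delta]`` token, e.g. ``S7[phospho+79.9663]``."""
    m = _MOD_TOKEN_RE.match(token.strip())
    if m is None:
        raise ValueError(f"unparseable modification token {token!r}")
    position: Union[int, str]
    position = m.group("term") if m.group("term") else int(m.group("pos"))
    return Modification(position=position, name=m.group("name"), mass_delta=float(m.group("delta")))


def parse_modifications(text: str) -> tuple[Modification, ...]:
    """Parse a ``;``-joined modification annotation string; empty -> no mods."""
    text = text.strip()
    if not text:
        return ()
    return tuple(parse_modification_token(tok) for tok in text.split(";"))


def format_modification(mod: Modification, peptide: str) -> str:
    if isinstance(mod.position, int):
        if mod.position > len(peptide):
            raise ValueError(
                f"modification position {mod.position} beyond peptide of length {len(peptide)}"
            )
        site = f"{peptide[mod.position - 1]}{mod.position}"
    else:
        site = mod.position
    return f"{site}[{mod.name}{mod.mass_delta:+.6f}]".replace(".000000]", "]")


def format_modifications(mods: Sequence[Modification], peptide: str) -> str:
    return ";".join(format_modification(m, peptide) for m in mods)


@dataclass(frozen=True)
class SpectrumKey:
    """Spectrum-level primary key of a PSM.

    Which fields participate in equality is not fixed here: callers project
    the key through an explicit key profile (a subset of :data:`KEY_FIELDS`).
    ``peptide`` is the *annotated* peptide string (sequence plus inline
    modification tokens), so two charge states or two proteoforms of the same
    scan stay distinct under profiles that include it.
    """

    file_name: str
    scan_number: int
    charge: int | None = None
    peptide: str | None = None

    def __post_init__(self) -> None:
        if not self.file_name:
            raise ValueError("file_name must be non-empty")
        if self.scan_number < 0:
            raise ValueError("scan_number must be >= 0")
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be a positive integer")

    def project(self, profile: Sequence[str]) -> tuple:
        """Project to a hashable tuple under ``profile`` (subset of KEY_FIELDS)."""
        validate_key_profile(profile)
        values = {
            "file": self.file_name,
            "scan": self.scan_number,
            "charge": self.charge,
            "peptide": self.peptide,
        }
        return tuple(values[f] for f in KEY_FIELDS if f in profile)


def validate_key_profile(profile: Sequence[str]) -> None:
    if not profile:
        raise ConfigurationError("key profile must name at least one field")
    bad = set(profile) - set(KEY_FIELDS)
    if bad:
        raise ConfigurationError(f"unknown key fields {sorted(bad)}; valid: {KEY_FIELDS}")


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match."""

    key: SpectrumKey
    peptide: str
    modifications: tuple[Modification, ...]
    charge: int | None
    score: float
    is_decoy: bool
    is_modified: bool
    proteins: tuple[str, ...] = ()

    def validate(self) -> None:
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValueError(f"peptide {self.peptide!r} contains non-standard residues")
        for mod in self.modifications:
            if isinstance(mod.position, int) and mod.position > len(self.peptide):
                raise ValueError(
                    f"modification at {mod.position} beyond peptide {self.peptide!r}"
                )
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be positive")

    @property
    def annotated_peptide(self) -> str:
        """Peptide string with inline modification tokens; the modified-peptide identity."""
        if not self.modifications:
            return self.peptide
        return f"{self.peptide}|{format_modifications(self.modifications, self.peptide)}"


def derive_is_modified(mods: Iterable[Modification], ptm_name: str | None = None) -> bool:
    """Whether a modification set carries the search-specific PTM.

    With ``ptm_name`` given, only that PTM counts; otherwise any modification
    outside the background set (oxidation, carbamidomethyl) counts.
    """
    if ptm_name is not None:
        return any(m.name == ptm_name for m in mods)
    return any(m.name not in BACKGROUND_MODS for m in mods)


@dataclass(frozen=True)
class FastaEntry:
    """One protein database entry with its provenance tag."""

    accession: str
    description: str
    sequence: str
    origin: Origin = Origin.REAL

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"entry {self.accession!r} has an empty sequence")
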