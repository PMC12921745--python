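"""Reduced PTM-specific search database construction.

For each PTM, the search database holds only the proteins annotated with
that PTM (from UniProt flat-style and dbPTM-style annotation sources, plus
user-supplied lists), padded with 5000 random "entrapment" protein sequences
and their 5000 reverses, so that decoy statistics stay well populated even
when few real proteins carry the modification. Random sequences match the
proteome's amino-acid composition and empirical length distribution; decoys
are full-sequence reverses. Random-protein hits are stripped from results
only *after* the FDR threshold has been determined.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .fdr import separate_fdr_curve
from .curves import rank_psms
from .records import (
    AMINO_ACIDS,
    DEFAULT_DECOY_PREFIX,
    DEFAULT_RANDOM_PREFIX,
    FastaEntry,
    Origin,
    PSMRecord,
    SIZING_KEY_PROFILE,
    origin_from_accession,
)


@dataclass(frozen=True)
class PTMSpec:
    """One post-translational modification: name, residues it targets, mass delta (Da)."""

    name: str
    target_residues: frozenset[str]
    mass_delta: float

    def __post_init__(self) -> None:
        if not self.target_residues:
            raise ValueError(f"PTM {self.name!r} must target at least one residue")

    @classmethod
    def parse(cls, text: str) -> "PTMSpec":
        """Parse ``name@RESIDUES:delta``, e.g. ``phospho@STY:79.96633``."""
        m = re.match(r"^([\w\-]+)@([A-Z]+):([+-]?\d+(?:\.\d+)?)$", text.strip())
        if m is None:
            raise ConfigurationError(f"cannot parse PTM spec {text!r} (want name@RES:delta)")
        return cls(name=m.group(1), target_residues=frozenset(m.group(2)),
                   mass_delta=float(m.group(3)))


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated modification site on a protein."""

    accession: str
    position: int
    residue: str | None
    ptm_name: str
    source: str = "custom"
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"annotation position must be >= 1, got {self.position}")


class ParseReport(list):
    """List of :class:`AnnotationRecord` with parse bookkeeping attached."""

    def __init__(self, records: Iterable[AnnotationRecord] = (),
                 n_features: int = 0, n_skipped: int = 0) -> None:
        super().__init__(records)
        self.n_features = n_features
        self.n_skipped = n_skipped


#: UniProt MOD_RES feature descriptions -> (normalized PTM name, residue, mass delta).
PTM_VOCABULARY: dict[str, tuple[str, str, float]] = {
    "Phosphoserine": ("phospho", "S", 79.96633),
    "Phosphothreonine": ("phospho", "T", 79.96633),
    "Phosphotyrosine": ("phospho", "Y", 79.96633),
    "N-acetylalanine": ("acetyl", "A", 42.01057),
    "N-acetylmethionine": ("acetyl", "M", 42.01057),
    "N-acetylserine": ("acetyl", "S", 42.01057),
    "N-acetylthreonine": ("acetyl", "T", 42.01057),
    "N6-acetyllysine": ("acetyl", "K", 42.01057),
    "N6-methyllysine": ("methyl", "K", 14.01565),
    "N6,N6-dimethyllysine": ("dimethyl", "K", 28.03130),
    "N6,N6,N6-trimethyllysine": ("trimethyl", "K", 42.04695),
    "Omega-N-methylarginine": ("methyl", "R", 14.01565),
    "Asymmetric dimethylarginine": ("dimethyl", "R", 28.03130),
    "Symmetric dimethylarginine": ("dimethyl", "R", 28.03130),
    "Citrulline": ("citrulline", "R", 0.98402),
    "Deamidated asparagine": ("deamidated", "N", 0.98402),
    "Deamidated glutamine": ("deamidated", "Q", 0.98402),
}

#: dbPTM modification-type names -> normalized PTM name.
DBPTM_VOCABULARY: dict[str, str] = {
    "Phosphorylation": "phospho",
    "Acetylation": "acetyl",
    "Methylation": "methyl",
    "Ubiquitination": "ubiquitin",
    "Citrullination": "citrulline",
    "Deamidation": "deamidated",
    "Sumoylation": "sumo",
}


def parse_uniprot_ptm_annotations(path) -> ParseReport:
    """Parse modified-residue features from UniProt flat-style text.

    Recognizes ``AC`` accession lines and ``FT   MOD_RES`` features with a
    following ``/note="..."`` line (single-line old-style features are also
    accepted). Feature descriptions are normalized through
    :data:`PTM_VOCABULARY`; unmapped descriptions are kept with their raw
    name, flagged ``mapped=False``. Malformed features are skipped with a
    warning and counted in the report.
    """
    records: list[AnnotationRecord] = []
    n_features = n_skipped = 0
    accession: str | None = None
    pending_pos: int | None = None

    def close_feature(note: str | None) -> None:
        nonlocal n_skipped, pending_pos
        if pending_pos is None:
            return
        pos = pending_pos
        pending_pos = None
        if note is None or accession is None:
            n_skipped += 1
            warnings.warn(f"skipping MOD_RES at {accession}:{pos}: no /note", stacklevel=3)
            return
        entry = PTM_VOCABULARY.get(note)
        if entry is None:
            records.append(AnnotationRecord(accession=accession, position=pos,
                                            residue=None, ptm_name=note,
                                            source="uniprot", mapped=False))
        else:
            name, residue, _ = entry
            records.append(AnnotationRecord(accession=accession, position=pos,
                                            residue=residue, ptm_name=name,
                                            source="uniprot"))

    for raw in Path(path).read_text().splitlines():
        if raw.startswith("AC"):
            close_feature(None)
            parts = raw[2:].strip().rstrip(";").split(";")
            accession = parts[0].strip() if parts and parts[0].strip() else accession
        elif raw.startswith("FT"):
            body = raw[2:].strip()
            if body.startswith("MOD_RES"):
                close_feature(None)
                n_features += 1
                rest = body[len("MOD_RES"):].strip()
                fields = rest.split(None, 1)
                try:
                    pending_pos = int(fields[0])
                except (IndexError, ValueError):
                    n_skipped += 1
                    warnings.warn(f"malformed MOD_RES line {raw!r}", stacklevel=2)
                    continue
                # old single-line style: position then free-text description
                if len(fields) > 1 and fields[1].strip():
                    close_feature(fields[1].strip().rstrip("."))
            elif body.startswith("/note=") and pending_pos is not None:
                note = body[len("/note="):].strip().strip('"').rstrip(".")
                close_feature(note)
    close_feature(None)
    return ParseReport(records, n_features=n_features, n_skipped=n_skipped)


def parse_dbptm_table(path, columns: Mapping[str, int] | None = None) -> ParseReport:
    """Parse a dbPTM-style headerless TSV.

    Default column layout (0-based): entry name, accession, position,
    modification type, evidence, sequence window; the site residue is taken
    from the centre of the window when present. Unknown modification types
    are kept with the raw name, flagged unmapped; rows with position < 1 are
    rejected with their row index.
    """
    cols = {"accession": 1, "position": 2, "type": 3, "window": 5}
    if columns:
        cols.update(columns)
    records: list[AnnotationRecord] = []
    n_skipped = 0
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    for i, line in enumerate(lines):
        fields = line.rstrip("\n").split("\t")
        try:
            accession = fields[cols["accession"]].strip()
            position = int(fields[cols["position"]])
            raw_type = fields[cols["type"]].strip()
            if position < 1 or not accession:
                raise ValueError("position < 1" if not accession else f"position {position} < 1")
        except (IndexError, ValueError) as exc:
            n_skipped += 1
            warnings.warn(f"dbPTM row {i} rejected: {exc}", stacklevel=2)
            continue
        residue = None
        widx = cols.get("window")
        if widx is not None and widx < len(fields):
            window = fields[widx].strip()
            if window:
                residue = window[len(window) // 2].upper()
        name = DBPTM_VOCABULARY.get(raw_type)
        records.append(AnnotationRecord(
            accession=accession, position=position, residue=residue,
            ptm_name=name if name is not None else raw_type,
            source="dbptm", mapped=name is not None,
        ))
    return ParseReport(records, n_features=len(lines), n_skipped=n_skipped)


def select_ptm_proteins(
    annotations: Sequence[AnnotationRecord],
    ptm: PTMSpec,
    identified: Sequence[str],
    extra: Sequence[str] = (),
    sequences: Mapping[str, str] | None = None,
) -> list[str]:
    """Accessions to include in the PTM-specific database.

    An identified protein qualifies when it carries at least one annotation
    of this PTM on one of its target residues. Annotations with an unknown
    site residue are resolved against ``sequences`` when given, otherwise
    skipped. Proteins on the ``extra`` custom list are always included.
    Result is de-duplicated and sorted.
    """
    identified_set = set(identified)
    chosen: set[str] = set()
    for ann in annotations:
        if ann.ptm_name != ptm.name or ann.accession not in identified_set:
            continue
        residue = ann.residue
        if residue is None and sequences is not None:
            seq = sequences.get(ann.accession, "")
            if 1 <= ann.position <= len(seq):
                residue = seq[ann.position - 1]
        if residue is not None and residue in ptm.target_residues:
            chosen.add(ann.accession)
    chosen.update(extra)
    if not chosen:
        warnings.warn(
            f"no proteins selected for PTM {ptm.name!r}; the database will "
            "contain only random sequences", stacklevel=2,
        )
    return sorted(chosen)


def aa_composition(entries: Sequence[FastaEntry]) -> np.ndarray:
    """Amino-acid frequency vector (order :data:`AMINO_ACIDS`) of a proteome."""
    counts = np.zeros(len(AMINO_ACIDS))
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for e in entries:
        for ch in e.sequence:
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("proteome contains no standard residues")
    return counts / total


def proteome_lengths(entries: Sequence[FastaEntry]) -> np.ndarray:
    return np.array([len(e.sequence) for e in entries], dtype=int)


def generate_random_proteins(
    n: int,
    composition: np.ndarray | Sequence[float],
    length_sampler: np.ndarray | Sequence[int] | Callable,
    seed: int,
    prefix: str = DEFAULT_RANDOM_PREFIX,
) -> list[FastaEntry]:
    """Generate ``n`` random protein sequences, deterministic under ``seed``.

    Lengths are resampled from an empirical length pool (or drawn from a
    callable ``length_sampler(rng, n)``); residues are i.i.d. from
    ``composition`` over the 20 standard amino acids.
    """
    composition = np.asarray(composition, dtype=float)
    if composition.shape != (len(AMINO_ACIDS),):
        raise ValueError(f"composition must have {len(AMINO_ACIDS)} entries")
    if abs(composition.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition sums to {composition.sum()!r}, not 1")
    rng = np.random.default_rng(seed)
    if callable(length_sampler):
        lengths = np.asarray(length_sampler(rng, n), dtype=int)
    else:
        pool = np.asarray(length_sampler, dtype=int)
        lengths = rng.choice(pool, size=n) if n else np.array([], dtype=int)
    alphabet = np.array(list(AMINO_ACIDS))
    entries = []
    for i in range(n):
        seq = "".join(rng.choice(alphabet, size=int(lengths[i]), p=composition))
        entries.append(FastaEntry(
            accession=f"{prefix}{i:05d}", description="random entrapment protein",
            sequence=seq, origin=Origin.RANDOM,
        ))
    return entries


def reverse_decoy(entry: FastaEntry, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> FastaEntry:
    """Full-sequence reversal decoy; accession gets the decoy prefix."""
    origin = Origin.RANDOM_DECOY if entry.origin is Origin.RANDOM else Origin.DECOY
    return FastaEntry(
        accession=f"{decoy_prefix}{entry.accession}",
        description=entry.description,
        sequence=entry.sequence[::-1],
        origin=origin,
    )


@dataclass
class DatabaseSpec:
    """Recipe for one PTM-specific search database."""

    ptm: PTMSpec
    annotated_accessions: Sequence[str]
    n_random: int = 5000
    random_seed: int = 0
    decoy_mode: str = "reverse"
    composition: np.ndarray | None = None      # default: proteome frequencies
    length_pool: np.ndarray | None = None      # default: proteome lengths
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    random_prefix: str = DEFAULT_RANDOM_PREFIX

    def __post_init__(self) -> None:
        if self.n_random < 0:
            raise ValueError("n_random must be >= 0")
        if self.decoy_mode != "reverse":
            raise ConfigurationError(f"unsupported decoy mode {self.decoy_mode!r}")


def build_ptm_fasta(spec: DatabaseSpec, proteome: Sequence[FastaEntry]) -> list[FastaEntry]:
    """Assemble the PTM database: annotated reals + randoms + their reverses + real decoys.

    The reversed randoms are the reverses of the generated forwards (mirroring
    the target/decoy construction), and every real entry gets one reversal
    decoy. Deterministic for a fixed spec (including seed).
    """
    by_acc = {e.accession: e for e in proteome}
    missing = [a for a in spec.annotated_accessions if a not in by_acc]
    if missing:
        raise ConfigurationError(
            f"accessions not found in the proteome: {', '.join(sorted(missing))}"
        )
    real = [by_acc[a] for a in spec.annotated_accessions]
    composition = spec.composition if spec.composition is not None else aa_composition(proteome)
    length_pool = spec.length_pool if spec.length_pool is not None else proteome_lengths(proteome)
    randoms = generate_random_proteins(spec.n_random, composition, length_pool,
                                       seed=spec.random_seed, prefix=spec.random_prefix)
    random_decoys = [reverse_decoy(e, spec.decoy_prefix) for e in randoms]
    real_decoys = [reverse_decoy(e, spec.decoy_prefix) for e in real]
    return real + randoms + random_decoys + real_decoys


def build_manifest(entries: Sequence[FastaEntry], spec: DatabaseSpec) -> pd.DataFrame:
    """Counts by origin plus the seed and a composition hash, for provenance."""
    counts: dict[str, int] = {o.value: 0 for o in Origin}
    for e in entries:
        counts[e.origin.value] += 1
    composition = spec.composition
    comp_hash = ""
    if composition is not None:
        comp_hash = hashlib.md5(np.asarray(composition, dtype=float).tobytes()).hexdigest()[:12]
    rows = [{"key": f"n_{k}", "value": v} for k, v in counts.items()]
    rows += [{"key": "ptm", "value": spec.ptm.name},
             {"key": "n_random", "value": spec.n_random},
             {"key": "seed", "value": spec.random_seed},
             {"key": "composition_md5", "value": comp_hash}]
    return pd.DataFrame(rows)


def strip_random_hits(
    records: Sequence[PSMRecord],
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    random_prefix: str = DEFAULT_RANDOM_PREFIX,
) -> list[PSMRecord]:
    """Drop PSMs whose *every* protein assignment is a random (entrapment) entry.

    Applied only after the FDR threshold has been determined; it never
    recomputes the threshold. Idempotent. PSMs with no protein assignment
    are kept.
    """
    kept = []
    for r in records:
        origins = [origin_from_accession(p, decoy_prefix, random_prefix) for p in r.proteins]
        if origins and all(o in (Origin.RANDOM, Origin.RANDOM_DECOY) for o in origins):
            continue
        kept.append(r)
    return kept


@dataclass
class SearchSpaceResult:
    """Per-database-size q-value summaries and the core/unique PSM partition."""

    summary: pd.DataFrame
    core: set
    unique: dict[str, set]


def search_space_experiment(
    psm_tables: Mapping[str, Sequence[PSMRecord]],
    sizes: Sequence[str] | None = None,
    q_threshold: float = 0.05,
    key_profile: Sequence[str] = SIZING_KEY_PROFILE,
) -> SearchSpaceResult:
    """Harness for the database-size experiment.

    For each labelled result table (one per database size) the modified-PSM
    q-value distribution is summarized (quartiles and mean over target PSMs)
    and PSMs are filtered at q <= ``q_threshold``. Surviving target PSMs are
    partitioned into a core set (keys present in every search) and per-size
    unique sets (keys present in exactly that search), under the
    (file, scan, modified peptide) key profile by default.
    """
    if sizes is not None:
        missing = [s for s in sizes if s not in psm_tables]
        if missing:
            raise ConfigurationError(f"no PSM table for size label(s): {missing}")
        psm_tables = {s: psm_tables[s] for s in sizes}

    rows = []
    surviving_keys: dict[str, set] = {}
    for label, records in psm_tables.items():
        ranked = rank_psms(list(records))
        sep = separate_fdr_curve(ranked)
        target = ~sep.is_decoy
        q_t = sep.q[target]
        idx_t = sep.indices[target]
        pass_mask = q_t <= q_threshold
        surviving_keys[label] = {
            ranked.records[i].key.project(key_profile)
            for i in idx_t[pass_mask]
        }
        rows.append({
            "size": label,
            "n_modified_targets": int(target.sum()),
            "q_mean": float(np.nanmean(q_t)) if q_t.size else np.nan,
            "q25": float(np.nanpercentile(q_t, 25)) if q_t.size else np.nan,
            "q50": float(np.nanpercentile(q_t, 50)) if q_t.size else np.nan,
            "q75": float(np.nanpercentile(q_t, 75)) if q_t.size else np.nan,
            "n_pass": int(pass_mask.sum()),
        })

    labels = list(surviving_keys)
    core = set.intersection(*surviving_keys.values()) if surviving_keys else set()
    unique = {}
    for label in labels:
        others = set().union(*(surviving_keys[o] for o in labels if o != label)) \
            if len(labels) > 1 else set()
        unique[label] = surviving_keys[label] - others
    return SearchSpaceResult(summary=pd.DataFrame(rows), core=core, unique=unique)
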