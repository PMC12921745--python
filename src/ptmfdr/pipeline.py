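"""Orchestration: per-PTM transferred FDR, random stripping, reports.

Each PTM is processed independently against the same standard-search
unmodified background: merge, rank, fit the group-specific FDR at the
configured level, strip PSMs mapping only to random (entrapment) proteins,
and emit machine-readable tables — per-PTM accepted PSMs, a combined table,
per-PTM summary counts, a modification-site table, and protein coverage
before/after adding the modified peptides.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .database import strip_random_hits
from .exceptions import ConfigurationError, GammaEstimationError, FitError
from .fdr import TransferredFDR, TransferredFDRResults
from .io import PSMDialect, read_config, read_psm_table, write_psm_table
from .records import (
    BACKGROUND_MODS,
    FastaEntry,
    PSMRecord,
    SIZING_KEY_PROFILE,
)

#: Modifications excluded from site tables: the fixed cysteine
#: carbamidomethylation and variable methionine oxidation.
EXCLUDED_SITE_MODS = frozenset(BACKGROUND_MODS)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (parsable from flat key=value text)."""

    standard_table: str
    ptm_tables: dict[str, str]
    alpha: float = 0.01
    fdr_method: str = "spline_transferred"
    sigma_cutoff: float = 0.01
    smoothing_sigma: float | None = None
    n_interior_knots: int = 3
    key_profile: tuple[str, ...] = SIZING_KEY_PROFILE
    output_dir: str = "ptmfdr_out"
    seed: int = 0
    exclude_standard_keys: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fdr_method not in ("spline_transferred", "linear_transferred", "separate"):
            raise ConfigurationError(f"unknown fdr_method {self.fdr_method!r}")
        if not self.ptm_tables:
            raise ConfigurationError("at least one ptm_table.<name> entry is required")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        cfg = read_config(path)
        base = Path(path).parent
        ptm_tables = {k.split(".", 1)[1]: str(base / v)
                      for k, v in cfg.items() if k.startswith("ptm_table.")}
        kwargs: dict = {"ptm_tables": ptm_tables}
        if "standard_table" in cfg:
            kwargs["standard_table"] = str(base / cfg["standard_table"])
        else:
            raise ConfigurationError(f"{path}: standard_table is required")
        for key, cast in (("alpha", float), ("sigma_cutoff", float),
                          ("smoothing_sigma", float), ("n_interior_knots", int),
                          ("seed", int)):
            if key in cfg:
                kwargs[key] = cast(cfg[key])
        if "fdr_method" in cfg:
            kwargs["fdr_method"] = cfg["fdr_method"]
        if "key_profile" in cfg:
            kwargs["key_profile"] = tuple(f.strip() for f in cfg["key_profile"].split(","))
        if "output_dir" in cfg:
            kwargs["output_dir"] = str(base / cfg["output_dir"])
        if "exclude_standard_keys" in cfg:
            kwargs["exclude_standard_keys"] = cfg["exclude_standard_keys"].lower() in ("true", "1", "yes")
        return cls(**kwargs)


@dataclass
class CoverageResult:
    """Sequence coverage of one protein by a peptide set."""

    percent: float
    covered: int
    length: int
    missing: list[str] = field(default_factory=list)


def compute_coverage(protein: FastaEntry | str, peptides: Sequence[str]) -> CoverageResult:
    """Percent of residues covered by >= 1 exact occurrence of any peptide.

    Every occurrence of every peptide marks its residues; overlaps count
    once (union, not sum). Peptides must be plain sequences (modifications
    stripped); peptides absent from the protein contribute nothing and are
    listed in ``missing``.
    """
    sequence = protein.sequence if isinstance(protein, FastaEntry) else protein
    mask = np.zeros(len(sequence), dtype=bool)
    missing = []
    for pep in peptides:
        found = False
        start = sequence.find(pep)
        while start != -1:
            found = True
            mask[start:start + len(pep)] = True
            start = sequence.find(pep, start + 1)
        if not found:
            missing.append(pep)
    covered = int(mask.sum())
    percent = 100.0 * covered / len(sequence) if len(sequence) else 0.0
    return CoverageResult(percent=percent, covered=covered, length=len(sequence),
                          missing=missing)


def coverage_table(
    proteins: Sequence[FastaEntry],
    base_peptides: Mapping[str, Sequence[str]],
    modified_peptides: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Coverage per protein before and after adding modified peptides."""
    rows = []
    for prot in proteins:
        base = list(base_peptides.get(prot.accession, ()))
        extra = list(modified_peptides.get(prot.accession, ()))
        before = compute_coverage(prot, base)
        after = compute_coverage(prot, base + extra)
        rows.append({
            "accession": prot.accession, "length": len(prot.sequence),
            "coverage_before": before.percent, "coverage_after": after.percent,
            "n_missing_peptides": len(after.missing),
        })
    return pd.DataFrame(rows)


@dataclass
class PTMSummary:
    """Accepted-PSM counts for one PTM."""

    ptm_name: str
    n_psms_accepted: int
    n_peptides: int
    n_proteins: int
    threshold_rank: float | None
    r_squared: float | None
    rmse: float | None


def summarize_ptm_counts(
    accepted: Mapping[str, Sequence[PSMRecord]],
    results: Mapping[str, TransferredFDRResults] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-PTM PSM/peptide/protein counts and the modification-site table.

    Site rows aggregate supporting PSMs per (accession, residue, position,
    PTM); positions are peptide-relative (1-based within the peptide).
    Carbamidomethylation and methionine oxidation never enter the site
    table. Counts are invariant to input row order.
    """
    summary_rows = []
    site_counts: dict[tuple, int] = {}
    for ptm_name in sorted(accepted):
        records = list(accepted[ptm_name])
        peptides = {r.annotated_peptide for r in records}
        proteins = {p for r in records for p in r.proteins}
        res = results.get(ptm_name) if results else None
        m = res.gamma_model if res is not None else None
        summary_rows.append({
            "ptm_name": ptm_name,
            "n_psms_accepted": len(records),
            "n_peptides": len(peptides),
            "n_proteins": len(proteins),
            "threshold_rank": res.threshold_rank if res is not None else None,
            "r_squared": m.r_squared if m is not None else None,
            "rmse": m.rmse if m is not None else None,
        })
        for r in records:
            for mod in r.modifications:
                if mod.name in EXCLUDED_SITE_MODS:
                    continue
                residue = (r.peptide[mod.position - 1]
                           if isinstance(mod.position, int) else "")
                for acc in (r.proteins or ("",)):
                    key = (acc, residue, mod.position, mod.name)
                    site_counts[key] = site_counts.get(key, 0) + 1
    site_rows = [
        {"accession": acc, "residue": res_, "position": pos, "ptm_name": name,
         "n_psms": n}
        for (acc, res_, pos, name), n in sorted(site_counts.items(), key=str)
    ]
    summary = pd.DataFrame(summary_rows, columns=[
        "ptm_name", "n_psms_accepted", "n_peptides", "n_proteins",
        "threshold_rank", "r_squared", "rmse"])
    sites = pd.DataFrame(site_rows, columns=[
        "accession", "residue", "position", "ptm_name", "n_psms"])
    return summary, sites


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    sites: pd.DataFrame
    accepted: dict[str, list[PSMRecord]]
    results: dict[str, TransferredFDRResults]
    output_paths: dict[str, Path]


def run_ptm_fdr_pipeline(config: RunConfig, dialect: PSMDialect | None = None) -> PipelineResult:
    """Run per-PTM group-specific FDR and write all report tables.

    Every PTM is filtered independently against the same standard-search
    unmodified background (no cross-PTM multiplicity correction beyond the
    per-group FDR). A PTM with zero modified targets, or too few decoys for
    a stable gamma estimate, yields a zero summary row with a warning and
    the run continues.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    standard = read_psm_table(config.standard_table, dialect)
    background = [r for r in standard if not r.is_modified]

    accepted: dict[str, list[PSMRecord]] = {}
    results: dict[str, TransferredFDRResults] = {}
    paths: dict[str, Path] = {}
    for ptm_name in sorted(config.ptm_tables):
        table = read_psm_table(config.ptm_tables[ptm_name], dialect)
        modified = [r for r in table if r.is_modified]
        if config.exclude_standard_keys:
            seen = {r.key.project(("file", "scan")) for r in standard}
            modified = [r for r in modified
                        if r.key.project(("file", "scan")) not in seen]
        if not any(r.is_modified and not r.is_decoy for r in modified):
            warnings.warn(f"PTM {ptm_name!r}: no modified target PSMs; skipping",
                          stacklevel=2)
            accepted[ptm_name] = []
            continue
        model = TransferredFDR(
            background + modified,
            method=config.fdr_method, alpha=config.alpha,
            sigma_cutoff=config.sigma_cutoff,
            smoothing_sigma=config.smoothing_sigma,
            n_interior_knots=config.n_interior_knots,
        )
        try:
            res = model.fit()
        except (GammaEstimationError, FitError) as exc:
            warnings.warn(f"PTM {ptm_name!r}: {exc}; reporting zero acceptances",
                          stacklevel=2)
            accepted[ptm_name] = []
            continue
        results[ptm_name] = res
        kept = strip_random_hits(res.accepted_records())
        accepted[ptm_name] = kept
        for kind, p in res.to_tables(out, prefix=ptm_name).items():
            paths[f"{ptm_name}_{kind}"] = p
        write_psm_table(kept, out / f"{ptm_name}_accepted.tsv")
        paths[f"{ptm_name}_accepted"] = out / f"{ptm_name}_accepted.tsv"

    # combined accepted table: union over PTMs under the key profile
    combined: list[PSMRecord] = []
    seen_keys = set()
    for ptm_name in sorted(accepted):
        for r in accepted[ptm_name]:
            k = (ptm_name,) + r.key.project(config.key_profile)
            if k not in seen_keys:
                seen_keys.add(k)
                combined.append(r)
    write_psm_table(combined, out / "combined_accepted.tsv")
    paths["combined"] = out / "combined_accepted.tsv"

    summary, sites = summarize_ptm_counts(accepted, results)
    summary.to_csv(out / "ptm_summary.csv", index=False)
    sites.to_csv(out / "ptm_sites.csv", index=False)
    paths["summary"] = out / "ptm_summary.csv"
    paths["sites"] = out / "ptm_sites.csv"
    return PipelineResult(summary=summary, sites=sites, accepted=accepted,
                          results=results, output_paths=paths)
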