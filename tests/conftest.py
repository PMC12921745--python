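"""Shared fixtures: programmatic record factories and tiny text fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from ptmfdr.records import Modification, PSMRecord, SpectrumKey


def make_psm(
    scan: int,
    score: float,
    *,
    file_name: str = "run1.mgf",
    peptide: str = "PEPTIDEK",
    mods: tuple = (),
    charge: int = 2,
    is_decoy: bool = False,
    is_modified: bool | None = None,
    proteins: tuple = ("P00001",),
) -> PSMRecord:
    if is_modified is None:
        is_modified = bool(mods)
    rec = PSMRecord(
        key=SpectrumKey(file_name=file_name, scan_number=scan, charge=charge),
        peptide=peptide, modifications=tuple(mods), charge=charge, score=score,
        is_decoy=is_decoy, is_modified=is_modified, proteins=tuple(proteins),
    )
    from dataclasses import replace
    return replace(rec, key=replace(rec.key, peptide=rec.annotated_peptide))


@pytest.fixture
def psm_factory():
    return make_psm


def random_psm_set(rng: np.random.Generator, n: int = 200,
                   frac_decoy: float = 0.3, frac_mod: float = 0.3) -> list[PSMRecord]:
    """Unstructured random PSMs for oracle-equivalence and property tests."""
    records = []
    for i in range(n):
        is_decoy = rng.random() < frac_decoy
        is_mod = rng.random() < frac_mod
        mods = (Modification(3, "phospho", 79.96633),) if is_mod else ()
        records.append(make_psm(
            scan=i + 1, score=float(rng.normal(20, 5)),
            peptide="AKSPTIDER", mods=mods, is_decoy=is_decoy,
            proteins=("DECOY_P1",) if is_decoy else ("P1",),
        ))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_psm_table(tmp_path):
    """3-row TSV fixture, one decoy row."""
    path = tmp_path / "small.tsv"
    path.write_text(
        "file\tscan\tpeptide\tmodifications\tcharge\tscore\tis_decoy\tis_modified\tproteins\n"
        "r1.mgf\t10\tPEPTIDEK\t\t2\t21.5\tfalse\tfalse\tP11111\n"
        "r1.mgf\t11\tSAMPLESEQK\tS7[phospho+79.9663]\t2\t18.0\tfalse\ttrue\tP22222\n"
        "r1.mgf\t12\tKEDITPEP\t\t3\t9.1\ttrue\tfalse\tDECOY_P11111\n"
    )
    return path


UNIPROT_FIXTURE = """\
ID   TEST1_HUMAN             Reviewed;         220 AA.
AC   P10001; Q99999;
FT   MOD_RES         15
FT                   /note="Phosphoserine"
FT   MOD_RES         42
FT                   /note="N6-acetyllysine"
SQ   SEQUENCE   220 AA;
ID   TEST2_HUMAN             Reviewed;         180 AA.
AC   P10002;
FT   MOD_RES         7
FT                   /note="Phosphothreonine"
SQ   SEQUENCE   180 AA;
"""


@pytest.fixture
def uniprot_fixture(tmp_path):
    path = tmp_path / "annotations.txt"
    path.write_text(UNIPROT_FIXTURE)
    return path


DBPTM_FIXTURE = (
    "TEST1_HUMAN\tP10001\t15\tPhosphorylation\t12345\tAAAAAASAAAAAA\n"
    "TEST1_HUMAN\tP10001\t42\tAcetylation\t12345\tAAAAAAKAAAAAA\n"
    "TEST2_HUMAN\tP10002\t7\tPhosphorylation\t12345\tAAAAAATAAAAAA\n"
    "TEST3_HUMAN\tP10003\t99\tPhosphorylation\t12345\tAAAAAASAAAAAA\n"
    "TEST4_HUMAN\tP10004\t3\tGlycation\t12345\tAAAAAAKAAAAAA\n"
)


@pytest.fixture
def dbptm_fixture(tmp_path):
    path = tmp_path / "dbptm.tsv"
    path.write_text(DBPTM_FIXTURE)
    return path
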