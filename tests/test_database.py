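"""Annotation parsing, random-protein generation, database assembly."""

import numpy as np
import pytest
from scipy import stats

from ptmfdr.database import (
    DatabaseSpec,
    PTMSpec,
    aa_composition,
    build_manifest,
    build_ptm_fasta,
    generate_random_proteins,
    parse_dbptm_table,
    parse_uniprot_ptm_annotations,
    reverse_decoy,
    search_space_experiment,
    select_ptm_proteins,
    strip_random_hits,
)
from ptmfdr.exceptions import ConfigurationError
from ptmfdr.io import write_fasta
from ptmfdr.records import AMINO_ACIDS, FastaEntry, Modification, Origin

from conftest import make_psm

PHOSPHO = PTMSpec("phospho", frozenset("STY"), 79.96633)
ACETYL_K = PTMSpec("acetyl", frozenset("K"), 42.01057)


class TestUniprotParsing:
    def test_three_features_parsed(self, uniprot_fixture):
        report = parse_uniprot_ptm_annotations(uniprot_fixture)
        assert len(report) == 3 and report.n_features == 3

    def test_vocabulary_normalization(self, uniprot_fixture):
        report = parse_uniprot_ptm_annotations(uniprot_fixture)
        first = report[0]
        assert (first.accession, first.position, first.residue, first.ptm_name) \
            == ("P10001", 15, "S", "phospho")

    def test_zero_feature_file(self, tmp_path):
        path = tmp_path / "nofeat.txt"
        path.write_text("ID   X\nAC   P1;\nSQ   SEQUENCE\n")
        report = parse_uniprot_ptm_annotations(path)
        assert list(report) == [] and report.n_features == 0

    def test_malformed_feature_skipped_with_warning(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("AC   P1;\nFT   MOD_RES         notanumber\n"
                        "FT   MOD_RES         5\nFT                   /note=\"Phosphoserine\"\n")
        with pytest.warns(UserWarning, match="malformed"):
            report = parse_uniprot_ptm_annotations(path)
        assert len(report) == 1 and report.n_skipped == 1

    def test_unknown_note_kept_unmapped(self, tmp_path):
        path = tmp_path / "odd.txt"
        path.write_text("AC   P1;\nFT   MOD_RES         9\n"
                        "FT                   /note=\"Exotic modification\"\n")
        report = parse_uniprot_ptm_annotations(path)
        assert len(report) == 1 and not report[0].mapped


class TestDbptmParsing:
    def test_five_rows(self, dbptm_fixture):
        report = parse_dbptm_table(dbptm_fixture)
        assert len(report) == 5
        assert all(r.source == "dbptm" for r in report)

    def test_residue_from_window_centre(self, dbptm_fixture):
        report = parse_dbptm_table(dbptm_fixture)
        assert report[0].residue == "S" and report[2].residue == "T"

    def test_unknown_type_flagged(self, dbptm_fixture):
        report = parse_dbptm_table(dbptm_fixture)
        glyc = [r for r in report if r.ptm_name == "Glycation"]
        assert len(glyc) == 1 and not glyc[0].mapped

    def test_position_zero_rejected_with_row_index(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("X\tP1\t0\tPhosphorylation\t1\tAAASAAA\n")
        with pytest.warns(UserWarning, match="row 0"):
            report = parse_dbptm_table(path)
        assert len(report) == 0 and report.n_skipped == 1


class TestSelection:
    def test_annotated_subset_selected(self, uniprot_fixture, dbptm_fixture):
        anns = list(parse_uniprot_ptm_annotations(uniprot_fixture)) \
            + list(parse_dbptm_table(dbptm_fixture))
        identified = [f"P1000{i}" for i in range(10)]
        chosen = select_ptm_proteins(anns, PHOSPHO, identified)
        assert chosen == ["P10001", "P10002", "P10003"]

    def test_duplicate_annotations_deduplicated(self, uniprot_fixture, dbptm_fixture):
        # P10001 phospho-S15 appears in both sources; one accession results
        anns = list(parse_uniprot_ptm_annotations(uniprot_fixture)) \
            + list(parse_dbptm_table(dbptm_fixture))
        chosen = select_ptm_proteins(anns, PHOSPHO, ["P10001"])
        assert chosen == ["P10001"]

    def test_custom_list_overrides_annotation(self, uniprot_fixture):
        anns = list(parse_uniprot_ptm_annotations(uniprot_fixture))
        with pytest.warns(UserWarning):
            base = select_ptm_proteins(anns, PHOSPHO, [])
        assert base == []
        chosen = select_ptm_proteins(anns, PHOSPHO, [], extra=["P99999"])
        assert chosen == ["P99999"]

    def test_wrong_residue_excluded(self, uniprot_fixture):
        anns = list(parse_uniprot_ptm_annotations(uniprot_fixture))
        # acetyl on K42 of P10001 does not qualify it for acetyl@A
        acetyl_a = PTMSpec("acetyl", frozenset("A"), 42.01057)
        with pytest.warns(UserWarning):
            assert select_ptm_proteins(anns, acetyl_a, ["P10001"]) == []


class TestRandomProteins:
    UNIFORM = np.full(20, 0.05)

    def test_zero_is_empty(self):
        assert generate_random_proteins(0, self.UNIFORM, [100], seed=1) == []

    def test_seed_determinism(self):
        a = generate_random_proteins(20, self.UNIFORM, [50, 80, 120], seed=7)
        b = generate_random_proteins(20, self.UNIFORM, [50, 80, 120], seed=7)
        assert a == b
        c = generate_random_proteins(20, self.UNIFORM, [50, 80, 120], seed=8)
        assert a != c

    def test_composition_within_binomial_bounds(self):
        entries = generate_random_proteins(500, self.UNIFORM, [200], seed=3)
        counts = np.zeros(20)
        for e in entries:
            for ch in e.sequence:
                counts[AMINO_ACIDS.index(ch)] += 1
        n = counts.sum()
        p = counts / n
        sd = np.sqrt(0.05 * 0.95 / n)
        assert np.all(np.abs(p - 0.05) < 4 * sd)

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError, match="sums"):
            generate_random_proteins(1, np.full(20, 0.06), [10], seed=0)

    def test_lengths_resampled_from_pool(self):
        entries = generate_random_proteins(50, self.UNIFORM, [33, 44], seed=5)
        assert {len(e.sequence) for e in entries} <= {33, 44}


class TestReverseDecoy:
    def test_sequence_reversed(self):
        e = FastaEntry("P1", "x", "PEPTIDE")
        d = reverse_decoy(e)
        assert d.sequence == "EDITPEP"
        assert d.accession == "DECOY_P1" and d.origin is Origin.DECOY

    def test_involution(self):
        e = FastaEntry("P1", "x", "MKVAQL")
        assert reverse_decoy(reverse_decoy(e)).sequence == e.sequence

    def test_palindrome_changes_accession_only(self):
        e = FastaEntry("P1", "x", "ABCBA")
        d = reverse_decoy(e)
        assert d.sequence == e.sequence and d.accession != e.accession

    def test_random_origin_maps_to_random_decoy(self):
        e = FastaEntry("RND_00001", "x", "AAACCC", origin=Origin.RANDOM)
        assert reverse_decoy(e).origin is Origin.RANDOM_DECOY


def toy_proteome(n=10, seed=0):
    rng = np.random.default_rng(seed)
    return [FastaEntry(f"P{i:05d}", f"toy protein {i}",
                       "".join(rng.choice(list(AMINO_ACIDS), size=120)))
            for i in range(n)]


class TestBuildDatabase:
    def test_counts_by_block(self):
        proteome = toy_proteome()
        spec = DatabaseSpec(ptm=PHOSPHO, annotated_accessions=[e.accession for e in proteome[:4]],
                            n_random=50, random_seed=1)
        db = build_ptm_fasta(spec, proteome)
        assert len(db) == 4 + 50 + 50 + 4
        origins = [e.origin for e in db]
        assert origins.count(Origin.REAL) == 4
        assert origins.count(Origin.RANDOM) == 50
        assert origins.count(Origin.RANDOM_DECOY) == 50
        assert origins.count(Origin.DECOY) == 4

    def test_random_reverses_pair_with_forwards(self):
        proteome = toy_proteome()
        spec = DatabaseSpec(ptm=PHOSPHO, annotated_accessions=[], n_random=10, random_seed=2)
        db = build_ptm_fasta(spec, proteome)
        fwd = {e.accession: e for e in db if e.origin is Origin.RANDOM}
        rev = [e for e in db if e.origin is Origin.RANDOM_DECOY]
        assert len(rev) == len(fwd)
        for r in rev:
            assert r.sequence == fwd[r.accession.removeprefix("DECOY_")].sequence[::-1]

    def test_every_real_entry_has_one_decoy(self):
        proteome = toy_proteome()
        spec = DatabaseSpec(ptm=PHOSPHO, annotated_accessions=[e.accession for e in proteome],
                            n_random=0, random_seed=0)
        db = build_ptm_fasta(spec, proteome)
        reals = [e for e in db if e.origin is Origin.REAL]
        decoys = {e.accession for e in db if e.origin is Origin.DECOY}
        assert decoys == {f"DECOY_{e.accession}" for e in reals}

    def test_rebuild_same_seed_identical_bytes(self, tmp_path):
        proteome = toy_proteome()
        spec = DatabaseSpec(ptm=PHOSPHO, annotated_accessions=["P00000"],
                            n_random=25, random_seed=9)
        for name in ("a.fasta", "b.fasta"):
            write_fasta(build_ptm_fasta(spec, proteome), tmp_path / name)
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_unresolvable_accession_listed(self):
        spec = DatabaseSpec(ptm=PHOSPHO, annotated_accessions=["MISSING1"], n_random=0)
        with pytest.raises(ConfigurationError, match="MISSING1"):
            build_ptm_fasta(spec, toy_proteome())

    def test_manifest_counts(self):
        proteome = toy_proteome()
        spec = DatabaseSpec(ptm=PHOSPHO, annotated_accessions=["P00000"], n_random=5,
                            random_seed=4)
        db = build_ptm_fasta(spec, proteome)
        manifest = build_manifest(db, spec)
        vals = dict(zip(manifest["key"], manifest["value"]))
        assert vals["n_real"] == 1 and vals["n_random"] == 5 and vals["seed"] == 4


class TestStripRandomHits:
    def test_random_only_removed_mixed_kept(self):
        recs = [
            make_psm(1, 10.0, proteins=("RND_00001",)),
            make_psm(2, 11.0, proteins=("P1", "RND_00002")),
            make_psm(3, 12.0, proteins=("DECOY_RND_00003",)),
            make_psm(4, 13.0, proteins=("P2",)),
        ]
        kept = strip_random_hits(recs)
        assert [r.key.scan_number for r in kept] == [2, 4]

    def test_idempotent(self):
        recs = [make_psm(1, 1.0, proteins=("RND_1",)), make_psm(2, 2.0)]
        once = strip_random_hits(recs)
        assert strip_random_hits(once) == once

    def test_acceptance_counts_differ_only_by_random_only(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(20):
            kind = rng.integers(3)
            prot = ("RND_%d" % i,) if kind == 0 else \
                   ("P%d" % i, "RND_%d" % i) if kind == 1 else ("P%d" % i,)
            recs.append(make_psm(i, float(i), proteins=prot))
        kept = strip_random_hits(recs)
        randoms_only = [r for r in recs
                        if all(p.startswith("RND_") for p in r.proteins)]
        assert len(recs) - len(kept) == len(randoms_only)


class TestSearchSpaceExperiment:
    def _table(self, rng, n=200, extra_decoys=0):
        recs = []
        for i in range(n):
            dec = i % 5 == 0
            recs.append(make_psm(
                i, float(rng.normal(25 if not dec else 15, 4)),
                mods=(Modification(1, "phospho", 79.96633),),
                peptide="SPEPTIDEK", is_decoy=dec,
                proteins=("DECOY_P1",) if dec else ("P1",)))
        for j in range(extra_decoys):
            recs.append(make_psm(
                n + j, float(rng.normal(22, 4)),
                mods=(Modification(1, "phospho", 79.96633),),
                peptide="SPEPTIDEK", is_decoy=True, proteins=("DECOY_P2",)))
        return recs

    def test_identical_tables_identical_summaries(self, rng):
        t = self._table(rng)
        res = search_space_experiment({"a": t, "b": list(t)})
        row_a = res.summary.set_index("size").loc["a"]
        row_b = res.summary.set_index("size").loc["b"]
        assert row_a.equals(row_b)
        assert res.unique["a"] == set() and res.unique["b"] == set()

    def test_inflated_decoy_rate_raises_mean_q(self, rng):
        base = self._table(rng, n=300)
        noisy = self._table(np.random.default_rng(1), n=300, extra_decoys=90)
        res = search_space_experiment({"clean": base, "noisy": noisy})
        s = res.summary.set_index("size")
        assert s.loc["noisy", "q_mean"] > s.loc["clean", "q_mean"]

    def test_survivor_count_on_hand_fixture(self):
        # 9 targets and 1 decoy ranked by score; the decoy is 3rd-best, so
        # targets above it have q = 0 and those below carry q = 1/T_k > 0.05
        scores = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        recs = [make_psm(i, float(s),
                         mods=(Modification(1, "phospho", 79.96633),),
                         peptide="SPEPTIDEK", is_decoy=(s == 80),
                         proteins=("DECOY_P1",) if s == 80 else ("P1",))
                for i, s in enumerate(scores)]
        res = search_space_experiment({"only": recs}, q_threshold=0.05)
        # q at 90,100 is 0; at 80 and below q = 1/{targets above} >= 1/9 > 0.05
        assert res.summary.loc[0, "n_pass"] == 2

    def test_missing_size_label_rejected(self, rng):
        with pytest.raises(ConfigurationError, match="5000"):
            search_space_experiment({"a": self._table(rng)}, sizes=["a", "5000"])


class TestComposition:
    def test_aa_composition_normalizes(self):
        entries = [FastaEntry("P1", "", "AAAA"), FastaEntry("P2", "", "CC")]
        comp = aa_composition(entries)
        assert comp[AMINO_ACIDS.index("A")] == pytest.approx(4 / 6)
        assert comp.sum() == pytest.approx(1.0)

    def test_goodness_of_fit_not_rejected(self):
        proteome = toy_proteome(n=30, seed=2)
        comp = aa_composition(proteome)
        entries = generate_random_proteins(300, comp, proteome_lengths_of(proteome), seed=6)
        counts = np.zeros(20)
        for e in entries:
            for ch in e.sequence:
                counts[AMINO_ACIDS.index(ch)] += 1
        chi2 = stats.chisquare(counts, f_exp=comp * counts.sum())
        assert chi2.pvalue > 0.001


def proteome_lengths_of(proteome):
    return np.array([len(e.sequence) for e in proteome])
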