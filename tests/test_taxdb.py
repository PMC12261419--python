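"""Affiliation parsing, archive construction, and rank-fallback resolution."""

import random
import zipfile

import pytest

from taxocycle.taxdb import (
    AffiliationError,
    DatabaseError,
    Rank,
    TaxonIndexEntry,
    TaxonomicAffiliation,
    create_db,
    load_index,
    load_taxon_record,
    parse_affiliations,
    resolve_affiliation,
    summarize_database,
    summarize_index,
)

from conftest import make_taxon_folder


def write_affiliations(path, rows, header=True):
    lines = ["observation_name\ttaxonomic_affiliation"] if header else []
    lines += rows
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParseAffiliations:
    def test_positional_ranks_left_aligned(self, tmp_path):
        path = write_affiliations(
            tmp_path / "aff.tsv", ["ASV_1\tBacteria;Bacillota;Clostridia"]
        )
        (aff,) = parse_affiliations(path)
        assert aff.observation_id == "ASV_1"
        assert len(aff.lineage) == 3
        assert aff.most_specific == (Rank.CLASS, "Clostridia")

    def test_right_alignment_anchors_species(self, tmp_path):
        path = write_affiliations(
            tmp_path / "aff.tsv", ["ASV_1\tHalanaerobium;Halanaerobium congolense"]
        )
        (aff,) = parse_affiliations(path, align="right")
        assert aff.lineage == (
            (Rank.GENUS, "Halanaerobium"),
            (Rank.SPECIES, "Halanaerobium congolense"),
        )

    def test_whitespace_trimmed(self, tmp_path):
        path = write_affiliations(tmp_path / "aff.tsv", ["ASV_1\t Bacteria ; Bacillota "])
        (aff,) = parse_affiliations(path)
        assert [n for _r, n in aff.lineage] == ["Bacteria", "Bacillota"]

    def test_empty_lineage_reports_line_number(self, tmp_path):
        path = write_affiliations(tmp_path / "aff.tsv", ["ASV_2\t"])
        with pytest.raises(AffiliationError, match="empty lineage at line 2"):
            parse_affiliations(path)

    def test_duplicate_observation_id_named(self, tmp_path):
        rows = ["A\tBacteria", "B\tArchaea", "A\tBacteria;Bacillota"]
        path = write_affiliations(tmp_path / "aff.tsv", rows)
        with pytest.raises(AffiliationError, match="'A'"):
            parse_affiliations(path)

    def test_headerless_mode(self, tmp_path):
        path = write_affiliations(tmp_path / "aff.tsv", ["X\tBacteria"], header=False)
        assert parse_affiliations(path, header=False)[0].observation_id == "X"


class TestCreateDb:
    def _three_taxa(self, tmp_path, counts=(7, 5, 2)):
        src = tmp_path / "input"
        for name, count in zip(("Alpha", "Beta", "Gamma"), counts):
            make_taxon_folder(
                src, name, "genus", count,
                [(f"{name}_c1", "MKVLA", [f"{name}_p1"], ["label"])],
            )
        return src

    def test_threshold_includes_and_logs_exclusions(self, tmp_path):
        src = self._three_taxa(tmp_path)
        archive, excluded = create_db(src, tmp_path / "db.zip", min_proteomes=5)
        index = load_index(archive)
        assert {e.taxon_name for e in index} == {"Alpha", "Beta"}
        assert excluded == ["Gamma"]

    def test_threshold_monotonicity(self, tmp_path):
        src = self._three_taxa(tmp_path, counts=(9, 6, 3))
        sizes = []
        for k, threshold in enumerate((1, 5, 7, 10)):
            archive, _ = create_db(src, tmp_path / f"db{k}.zip", min_proteomes=threshold)
            sizes.append(len(load_index(archive)))
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_input_errors(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(DatabaseError, match="no taxa found"):
            create_db(tmp_path / "empty", tmp_path / "db.zip")

    def test_annotation_id_mismatch_names_taxon_and_id(self, tmp_path):
        src = tmp_path / "input"
        folder = make_taxon_folder(src, "Alpha", "genus", 8, [("c1", "MKV", ["p1"], [])])
        (folder / "annotations.tsv").write_text(
            "cluster_id\tprotein_members\tannotation_labels\nGHOST\tp1\t\n"
        )
        with pytest.raises(DatabaseError, match="Alpha.*GHOST"):
            create_db(src, tmp_path / "db.zip")

    def test_round_trip_preserves_everything(self, tmp_path):
        src = tmp_path / "input"
        clusters = [
            ("c1", "MKVLAWFE", ["p1", "p2"], ["kinase"]),
            ("c2", "GGHHII", ["p3"], []),
            ("c3", "ACDEFGHIKL", ["p4", "p5", "p6"], ["oxidase", "membrane"]),
            ("c4", "WWYY", ["p7"], ["decoy"]),
        ]
        make_taxon_folder(src, "Alpha", "genus", 8, clusters)
        archive, _ = create_db(src, tmp_path / "db.zip")
        (entry,) = load_index(archive)
        record = load_taxon_record(archive, entry)
        assert len(record.clusters) == 4
        by_id = {c.cluster_id: c for c in record.clusters}
        for cid, seq, members, labels in clusters:
            assert by_id[cid].consensus_sequence == seq
            assert by_id[cid].member_protein_ids == tuple(members)
            assert by_id[cid].annotations == tuple(labels)

    def test_byte_determinism(self, tmp_path):
        src = self._three_taxa(tmp_path)
        a, _ = create_db(src, tmp_path / "a.zip")
        b, _ = create_db(src, tmp_path / "b.zip")
        assert a.read_bytes() == b.read_bytes()


class TestLoadTaxonRecord:
    def test_missing_member_names_it(self, tmp_path):
        src = tmp_path / "input"
        make_taxon_folder(src, "Alpha", "genus", 8, [("c1", "MKV", ["p1"], [])])
        archive, _ = create_db(src, tmp_path / "db.zip")
        bogus = TaxonIndexEntry("Alpha", Rank.GENUS, 8, "proteomes/ghost.faa", "annotations/Alpha.tsv")
        with pytest.raises(DatabaseError, match="ghost.faa"):
            load_taxon_record(archive, bogus)

    def test_empty_annotation_file(self, tmp_path):
        src = tmp_path / "input"
        folder = make_taxon_folder(src, "Alpha", "genus", 8, [("c1", "MKV", ["p1"], [])])
        (folder / "annotations.tsv").write_text("")
        archive, _ = create_db(src, tmp_path / "db.zip")
        (entry,) = load_index(archive)
        record = load_taxon_record(archive, entry)
        assert [c.cluster_id for c in record.clusters] == ["c1"]
        assert record.clusters[0].annotations == ()

    def test_unknown_annotation_row_kept_with_warning(self, tmp_path, caplog):
        src = tmp_path / "input"
        make_taxon_folder(src, "Alpha", "genus", 8, [("c1", "MKV", ["p1"], [])])
        archive, _ = create_db(src, tmp_path / "db.zip")
        # inject an extra annotation row post-hoc (create_db would reject it)
        with zipfile.ZipFile(archive) as zf:
            names = {n: zf.read(n) for n in zf.namelist()}
        names["annotations/Alpha.tsv"] += b"EXTRA\tp9\tlabel\n"
        with zipfile.ZipFile(archive, "w") as zf:
            for n, payload in names.items():
                zf.writestr(n, payload)
        (entry,) = load_index(archive)
        record = load_taxon_record(archive, entry)
        extra = {c.cluster_id: c for c in record.clusters}["EXTRA"]
        assert extra.member_protein_ids == ()
        assert extra.consensus_sequence == ""


class TestResolution:
    index = [
        TaxonIndexEntry("Halanaerobium", Rank.GENUS, 12),
        TaxonIndexEntry("Halanaerobiaceae", Rank.FAMILY, 30),
        TaxonIndexEntry("Clostridia", Rank.CLASS, 100),
    ]

    def _aff(self, *pairs):
        return TaxonomicAffiliation("obs", tuple((Rank(r), n) for r, n in pairs))

    def test_most_specific_rank_wins(self):
        aff = self._aff(
            ("family", "Halanaerobiaceae"),
            ("genus", "Halanaerobium"),
            ("species", "Halanaerobium congolense"),
        )
        result = resolve_affiliation(aff, self.index)
        assert result.status == "resolved"
        assert result.matched_rank == Rank.GENUS
        assert result.matched_taxon.taxon_name == "Halanaerobium"

    def test_species_match_short_circuits(self):
        index = self.index + [TaxonIndexEntry("Halanaerobium congolense", Rank.SPECIES, 6)]
        aff = self._aff(("genus", "Halanaerobium"), ("species", "Halanaerobium congolense"))
        result = resolve_affiliation(aff, index)
        assert result.matched_rank == Rank.SPECIES

    def test_unresolved_is_normal(self):
        aff = self._aff(("genus", "Nobody"))
        result = resolve_affiliation(aff, self.index)
        assert result.status == "unresolved"
        assert result.matched_taxon is None and result.matched_rank is None

    def test_name_rank_pair_disambiguates_homonyms(self):
        index = [TaxonIndexEntry("Ambi", Rank.FAMILY, 9)]
        aff = self._aff(("family", "Other"), ("genus", "Ambi"))
        assert resolve_affiliation(aff, index).status == "unresolved"

    def test_fallback_matches_brute_force_scan(self):
        """DP-free oracle: most specific lineage element present in the index."""
        rng = random.Random(42)
        names = [f"T{i}" for i in range(8)]
        for _ in range(100):
            lineage = tuple(
                (rank, rng.choice(names))
                for rank in (Rank.KINGDOM, Rank.PHYLUM, Rank.CLASS, Rank.ORDER)
            )
            aff = TaxonomicAffiliation("obs", lineage)
            index = [
                TaxonIndexEntry(rng.choice(names), rng.choice(list(Rank)), 7)
                for _ in range(6)
            ]
            keys = {(e.taxon_name, e.rank) for e in index}
            matches = [(r, n) for r, n in lineage if (n, r) in keys]
            expected = matches[-1][0] if matches else None
            result = resolve_affiliation(aff, index)
            assert result.matched_rank == expected
            shuffled = index[:]
            rng.shuffle(shuffled)
            assert resolve_affiliation(aff, shuffled) == result


class TestSummaries:
    def test_per_rank_rows_and_total(self):
        entries = [
            TaxonIndexEntry("S1", Rank.SPECIES, 6),
            TaxonIndexEntry("S2", Rank.SPECIES, 9),
            TaxonIndexEntry("G1", Rank.GENUS, 12),
        ]
        df = summarize_index(entries)
        by_rank = df.set_index("rank")
        assert by_rank.loc["species", "included_taxa"] == 2
        assert by_rank.loc["genus", "included_taxa"] == 1
        assert by_rank.loc["total", "included_taxa"] == 3
        assert by_rank.loc["total", "proteomes"] == 27

    def test_empty_index(self):
        df = summarize_index([])
        assert list(df["rank"]) == ["total"]
        assert df.iloc[0]["included_taxa"] == 0

    def test_archive_summary_matches_index(self, community_bundle):
        df = summarize_database(community_bundle.archive)
        total = df.set_index("rank").loc["total", "included_taxa"]
        assert total == len(load_index(community_bundle.archive))
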