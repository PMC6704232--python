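"""Pipeline orchestration: mode semantics, zoning, reports and determinism."""

import json

import numpy as np
import pytest

from rnaikit import (
    NucleotideSequence,
    RunParams,
    TranscriptDatabase,
    export_report,
    run_design_mode,
    run_offtarget_mode,
)
from rnaikit.design_pipeline import DesignReport, ZONE_GREEN, ZONE_RED
from rnaikit.synthetic_constructs import generate_window_construct, random_sequence

from conftest import brute_force_hits, make_db
from rnaikit.sirna_enumeration import enumerate_sirnas


@pytest.fixture(scope="module")
def target():
    return random_sequence(500, np.random.default_rng(101), "target")


@pytest.fixture(scope="module")
def small_target():
    return random_sequence(200, np.random.default_rng(202), "target")


class TestOfftargetMode:
    def test_self_trigger_gives_480_sense_hits(self, target):
        report = run_offtarget_mode(target, make_db(target))
        sense = report.hits[report.hits.orientation == "sense-match"]
        assert len(sense) == 480
        row = report.per_transcript.iloc[0]
        assert row.transcript_id == "target"
        assert row.total_hits >= 480

    def test_unrelated_transcript_absent_from_summary(self, target):
        other = random_sequence(300, np.random.default_rng(7), "other")
        report = run_offtarget_mode(target, make_db(target, other))
        assert "other" not in set(report.per_transcript.transcript_id)

    def test_paralog_counts_match_brute_force(self, target):
        rng = np.random.default_rng(11)
        # ~85%-identical paralog: mutate 15% of positions
        residues = list(target.residues)
        positions = rng.choice(500, size=75, replace=False)
        for p in positions:
            residues[p] = rng.choice([b for b in "ACGU" if b != residues[p]])
        paralog = NucleotideSequence("paralog", "".join(residues))
        db = make_db(target, paralog)
        report = run_offtarget_mode(target, db)
        oracle = brute_force_hits(enumerate_sirnas(target, 21), db, 0)
        expected = sum(1 for o in oracle if o[1] == "paralog")
        row = report.per_transcript.set_index("transcript_id").loc["paralog"]
        assert row.total_hits == expected

    def test_never_computes_accessibility(self, target):
        report = run_offtarget_mode(target, make_db(target))
        assert report.profiles == {}
        assert report.hits.site_lap.isna().all()

    def test_short_trigger_gives_empty_report_with_warning(self, target):
        short = NucleotideSequence("short", "ACGUACGUACGU")
        report = run_offtarget_mode(short, make_db(target))
        assert report.warnings
        assert len(report.hits) == 0
        assert (report.positions.total_hits == 0).all()


class TestDesignMode:
    def test_unknown_main_target_rejected(self, target):
        with pytest.raises(KeyError, match="nope"):
            run_design_mode(target, make_db(target), ["nope"])

    def test_counts_ordering_and_zone_invariant(self, small_target):
        report = run_design_mode(small_target, make_db(small_target), ["target"])
        pos = report.positions
        assert (pos.he_hits <= pos.hs_hits).all()
        assert (pos.hs_hits <= pos.total_hits).all()
        assert set(pos.zone) <= {ZONE_GREEN, ZONE_RED}
        # sole transcript is the main target: nothing can be red
        assert (pos.zone == ZONE_GREEN).all()

    def test_shared_block_paints_red_zone(self, small_target):
        rng = np.random.default_rng(17)
        other = random_sequence(200, rng, "other")
        # transcript sharing trigger positions 0..99
        other = NucleotideSequence(
            "other", small_target.residues[:100] + other.residues[100:]
        )
        report = run_design_mode(
            small_target, make_db(small_target, other), ["target"]
        )
        pos = report.positions.set_index("position")
        hs_off = report.hits[
            (report.hits.transcript_id == "other") & report.hits.hs_pass
        ]
        covered = np.zeros(200, dtype=bool)
        for row in hs_off.itertuples(index=False):
            covered[row.sirna_start - 1 : row.sirna_start - 1 + 21] = True
        expected = np.where(covered, ZONE_RED, ZONE_GREEN)
        assert list(pos.zone) == list(expected)
        assert (pos.zone == ZONE_RED).any()

    def test_recommended_region_tracks_he_rich_window(self, target):
        backbone = random_sequence(500, np.random.default_rng(23), "backbone")
        trigger = generate_window_construct(target, 400, 100, backbone)
        report = run_design_mode(trigger, make_db(target), ["target"])
        he = report.hits[report.hits.he_pass]
        assert len(he) >= 1, "fixture must contain HE-passing siRNAs"
        # matched block = copied window plus any chance-matching flank
        block_start = 400
        while block_start > 0 and trigger.residues[block_start - 1] == target.residues[block_start - 1]:
            block_start -= 1
        assert (he.sirna_start >= block_start + 1).all()
        region = report.recommended_region
        assert region is not None
        assert region["start"] >= block_start + 1 - (100 - 21)
        assert region["he_count"] == len(
            he[(he.sirna_start >= region["start"]) & (he.sirna_start + 21 - 1 <= region["end"])]
        )

    def test_no_he_sirnas_means_no_recommendation(self, small_target):
        report = run_design_mode(
            small_target,
            make_db(small_target),
            ["target"],
            RunParams(dmfe_threshold=50.0),  # unattainable margin
        )
        assert not report.hits.he_pass.any()
        assert report.recommended_region is None
        assert (report.positions.zone == ZONE_GREEN).all()

    def test_per_transcript_totals_split_by_orientation(self, small_target):
        report = run_design_mode(small_target, make_db(small_target), ["target"])
        by_orientation = report.hits.groupby("orientation").size().sum()
        assert by_orientation == report.per_transcript.total_hits.sum()


class TestExportAndDeterminism:
    def test_export_writes_all_artifacts(self, small_target, tmp_path):
        report = run_design_mode(small_target, make_db(small_target), ["target"])
        files = export_report(report, tmp_path / "out")
        names = {f.name for f in files}
        assert {
            "hits.tsv",
            "positions.tsv",
            "transcripts.tsv",
            "summary.json",
            "report.png",
            "accessibility_target.tsv",
        } <= names
        hits_lines = (tmp_path / "out" / "hits.tsv").read_text().splitlines()
        assert len(hits_lines) == len(report.hits) + 1

    def test_empty_report_exports_headers_only(self, target, tmp_path):
        short = NucleotideSequence("short", "ACGUACGUACGU")
        report = run_offtarget_mode(short, make_db(target))
        export_report(report, tmp_path / "empty")
        lines = (tmp_path / "empty" / "hits.tsv").read_text().splitlines()
        assert len(lines) == 1  # header only

    def test_json_summary_round_trips_to_equal_report(self, small_target, tmp_path):
        report = run_design_mode(small_target, make_db(small_target), ["target"])
        export_report(report, tmp_path / "rt")
        payload = json.loads((tmp_path / "rt" / "summary.json").read_text())
        assert DesignReport.from_dict(payload) == report

    def test_identical_inputs_give_byte_identical_reports(self, small_target, tmp_path):
        db = make_db(small_target)
        for d in ("a", "b"):
            export_report(
                run_design_mode(small_target, db, ["target"]), tmp_path / d
            )
        for name in ("hits.tsv", "positions.tsv", "transcripts.tsv", "summary.json",
                     "accessibility_target.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name
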