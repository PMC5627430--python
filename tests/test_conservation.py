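"""Conservation calls, aggregation and non-homolog classification."""

import random

import pytest

from ascoflux import (
    AlignmentHit,
    ConservationThresholds,
    best_hit_per_query,
    call_conservation,
    classify_nonhomologs,
    make_hit_table,
    parse_hits,
    summarize,
)
from ascoflux.conservation import parse_query_lengths, parse_subsystem_map
from ascoflux.synth import HitTableSpec


def _hit(query="Q1", subject="S|p1", strain="S", pident=80.0, length=100,
         evalue=1e-50, bitscore=200.0, qlen=100):
    return AlignmentHit(query, subject, strain, pident, length, evalue, bitscore, qlen)


HITS_FIXTURE = (
    "Q0001\tS|p1\t85.0\t100\t10\t2\t1\t100\t1\t100\t1e-50\t250.0\n"
    "Q0002\tS|p2\t45.0\t60\t30\t1\t1\t60\t1\t60\t1e-08\t90.0\n"
    "Q0003\tS|p3\t30.0\t30\t20\t1\t1\t30\t5\t35\t1e-03\t35.0\n"
)


def test_parse_hits_maps_columns_positionally(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(HITS_FIXTURE)
    lengths = {"Q0001": 100, "Q0002": 100, "Q0003": 100}
    hits = parse_hits(path, lengths, strain="S")
    assert len(hits) == 3
    assert hits[0].percent_identity == 85.0
    assert hits[1].e_value == 1e-8
    assert hits[2].alignment_length == 30
    assert all(h.subject_strain == "S" for h in hits)


def test_parse_hits_empty_file(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert parse_hits(path, {}, strain="S") == []


def test_parse_hits_bad_evalue_reports_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(HITS_FIXTURE.replace("1e-08", "not-a-number"))
    with pytest.raises(ValueError, match=":2"):
        parse_hits(path, {"Q0001": 100, "Q0002": 100, "Q0003": 100}, strain="S")


def test_parse_hits_unknown_query_named(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(HITS_FIXTURE)
    with pytest.raises(KeyError, match="Q0002"):
        parse_hits(path, {"Q0001": 100, "Q0003": 100}, strain="S")


def test_best_hit_lowest_evalue_with_tie_breaks():
    hits = [
        _hit(evalue=1e-3, bitscore=50.0, subject="S|late"),
        _hit(evalue=1e-10, bitscore=80.0, subject="S|best"),
        # e-value tie resolved by bit score, then subject id
        _hit(query="Q2", evalue=1e-5, bitscore=90.0, subject="S|lo"),
        _hit(query="Q2", evalue=1e-5, bitscore=120.0, subject="S|hi"),
        _hit(query="Q3", evalue=1e-5, bitscore=100.0, subject="S|b"),
        _hit(query="Q3", evalue=1e-5, bitscore=100.0, subject="S|a"),
    ]
    best = best_hit_per_query(hits, "S")
    assert best["Q1"].subject_id == "S|best"
    assert best["Q2"].subject_id == "S|hi"
    assert best["Q3"].subject_id == "S|a"
    assert "Q4" not in best
    # order independence
    assert best_hit_per_query(list(reversed(hits)), "S") == best


def test_threshold_boundary_semantics():
    """Identity and coverage inclusive at the threshold, e-value strict."""
    thresholds = ConservationThresholds()
    at_boundary = _hit(pident=40.0, length=50, qlen=100, evalue=1e-6)
    assert thresholds.passes(at_boundary)
    assert not thresholds.passes(_hit(pident=39.9, length=50, qlen=100, evalue=1e-6))
    assert not thresholds.passes(_hit(pident=40.0, length=49, qlen=100, evalue=1e-6))
    assert not thresholds.passes(_hit(pident=40.0, length=50, qlen=100, evalue=1e-5))


def test_queries_without_hits_are_not_conserved():
    best = {"Q1": _hit()}
    calls = call_conservation(best, {"Q1": 100, "Q2": 100}, strain="S")
    by_query = {c.query_id: c for c in calls}
    assert by_query["Q1"].conserved
    assert not by_query["Q2"].conserved and by_query["Q2"].best_hit is None


def test_planted_fraction_recovered_exactly(tmp_path):
    spec = HitTableSpec(n_queries=200, strains=("sA",), planted_fraction=(("sA", 0.75),))
    paths = make_hit_table(spec, tmp_path)
    lengths = parse_query_lengths(paths["query_lengths"])
    hits = parse_hits(paths["sA"], lengths, strain="sA")
    best = best_hit_per_query(hits, "sA")
    calls = call_conservation(best, lengths, strain="sA")
    summary = summarize(calls, parse_subsystem_map(paths["subsystem_map"]))
    assert summary.per_strain_fraction["sA"] == 0.75
    assert summary.n_queries == 200


@pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 1.0)])
def test_planted_extremes(tmp_path, fraction, expected):
    spec = HitTableSpec(n_queries=40, strains=("sA",), planted_fraction=(("sA", fraction),))
    paths = make_hit_table(spec, tmp_path)
    lengths = parse_query_lengths(paths["query_lengths"])
    calls = call_conservation(
        best_hit_per_query(parse_hits(paths["sA"], lengths, "sA"), "sA"), lengths, "sA"
    )
    assert sum(c.conserved for c in calls) / len(calls) == expected


def test_summarize_hand_computed_two_by_two():
    """4 queries x 2 subsystems x 2 strains with hand-set calls."""
    from ascoflux import ConservationCall

    submap = {"Q0": "ss0", "Q1": "ss0", "Q2": "ss1", "Q3": "ss1"}
    calls = [
        ConservationCall("Q0", "sA", True), ConservationCall("Q1", "sA", True),
        ConservationCall("Q2", "sA", True), ConservationCall("Q3", "sA", False),
        ConservationCall("Q0", "sB", False), ConservationCall("Q1", "sB", False),
        ConservationCall("Q2", "sB", True), ConservationCall("Q3", "sB", True),
    ]
    summary = summarize(calls, submap)
    assert summary.per_subsystem_matrix[("sA", "ss0")] == 1.0
    assert summary.per_subsystem_matrix[("sA", "ss1")] == 0.5
    assert summary.per_subsystem_matrix[("sB", "ss0")] == 0.0
    assert summary.per_subsystem_matrix[("sB", "ss1")] == 1.0
    assert summary.per_strain_fraction["sA"] == 0.75
    assert summary.per_strain_fraction["sB"] == 0.5
    frame = summary.to_long_frame()
    assert list(frame.columns) == ["strain", "subsystem", "fraction"]
    assert len(frame) == 4


def test_per_strain_is_weighted_mean_of_subsystem_cells():
    """Independent recomputation from raw calls on random fixtures."""
    rng = random.Random(7)
    from ascoflux import ConservationCall

    for _ in range(20):
        n = rng.randint(10, 60)
        submap = {f"Q{i}": f"ss{rng.randrange(3)}" for i in range(n)}
        calls = [ConservationCall(f"Q{i}", "sX", rng.random() < 0.6) for i in range(n)]
        summary = summarize(calls, submap)
        weighted = 0.0
        for (strain, subsystem), fraction in summary.per_subsystem_matrix.items():
            n_sub = sum(1 for q in submap if submap[q] == subsystem)
            weighted += fraction * n_sub / n
        assert summary.per_strain_fraction["sX"] == pytest.approx(weighted, abs=1e-12)
        # permutation invariance in call order
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert summarize(shuffled, submap).per_strain_fraction == summary.per_strain_fraction


def test_tightening_thresholds_never_raises_fractions(tmp_path):
    """Monotonicity under threshold tightening on randomized tables."""
    rng = random.Random(11)
    for trial in range(20):
        hits = [
            _hit(
                query=f"Q{i}",
                subject=f"S|p{i}",
                pident=rng.uniform(20, 100),
                length=rng.randint(30, 100),
                evalue=10 ** rng.uniform(-60, -1),
                qlen=100,
            )
            for i in range(30)
        ]
        lengths = {f"Q{i}": 100 for i in range(30)}
        best = best_hit_per_query(hits, "S")
        loose = ConservationThresholds(40.0, 0.5, 1e-5)
        for tighter in (
            ConservationThresholds(50.0, 0.5, 1e-5),
            ConservationThresholds(40.0, 0.7, 1e-5),
            ConservationThresholds(40.0, 0.5, 1e-8),
        ):
            n_loose = sum(c.conserved for c in call_conservation(best, lengths, "S", loose))
            n_tight = sum(c.conserved for c in call_conservation(best, lengths, "S", tighter))
            assert n_tight <= n_loose


def test_classify_nonhomologs_planted_census():
    """1166 queries, 146 non-homologous of which 95 isozyme-rescued and 15
    annotation-similar, leaves 36 absent; classes partition the queries."""
    from ascoflux import ConservationCall

    n_total, n_nonhom, n_iso, n_annot = 1166, 146, 95, 15
    calls = [
        ConservationCall(f"Q{i:04d}", "S14", conserved=(i >= n_nonhom))
        for i in range(n_total)
    ]
    reaction_enzyme_map = {}
    for i in range(n_iso):  # pair each rescued query with one conserved isozyme
        reaction_enzyme_map[f"rxn{i}"] = [f"Q{i:04d}", f"Q{n_nonhom + i:04d}"]
    annotation = {f"Q{i:04d}": True for i in range(n_iso, n_iso + n_annot)}
    counts = classify_nonhomologs(calls, reaction_enzyme_map, annotation)
    assert counts == {
        "homolog": n_total - n_nonhom,
        "isozyme_rescued": n_iso,
        "annotation_similar": n_annot,
        "absent": n_nonhom - n_iso - n_annot,
    }
    assert counts["absent"] == 36
    assert sum(counts.values()) == n_total


def test_classify_all_conserved():
    from ascoflux import ConservationCall

    calls = [ConservationCall(f"Q{i}", "S", True) for i in range(5)]
    counts = classify_nonhomologs(calls, {}, {})
    assert counts == {"homolog": 5, "isozyme_rescued": 0, "annotation_similar": 0, "absent": 0}


def test_isozyme_rescue_definition():
    from ascoflux import ConservationCall

    calls = [ConservationCall("QA", "S", False), ConservationCall("QB", "S", True)]
    counts = classify_nonhomologs(calls, {"rxn1": ["QA", "QB"]}, {})
    assert counts["isozyme_rescued"] == 1 and counts["homolog"] == 1
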