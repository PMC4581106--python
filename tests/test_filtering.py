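from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerkit.filtering import (
    REASON_CODES,
    filter_round1,
    filter_round2,
    remove_clusters,
    run_filter_pipeline,
)
from markerkit.model import FilterConfig, SampleCall, Transcript, VariantSite


def make_site(pos=500, tid="t1", **kw):
    defaults = dict(
        qual=100.0, fs=1.0, qd=20.0, mq0_fraction=0.0, total_depth=150,
        samples={
            "axillaris": SampleCall(gt=(0, 0), dp=50, ad=(50, 0)),
            "exserta": SampleCall(gt=(1, 1), dp=50, ad=(0, 50)),
            "integrifolia": SampleCall(gt=(0, 1), dp=50, ad=(25, 25)),
        },
    )
    defaults.update(kw)
    return VariantSite(transcript_id=tid, pos=pos, ref="A", alts=("G",), **defaults)


TRANSCRIPT = Transcript("t1", "ACGT" * 250, orf_start=101, orf_end=800,
                        boundary_positions=[600])
INDEX = {"t1": TRANSCRIPT}


@pytest.mark.parametrize(
    "kw,reason",
    [
        ({"fs": 75.0}, "STRAND_BIAS"),
        ({"fs": 60.0}, None),  # threshold is strictly greater-than
        ({"mq0_fraction": 0.2}, "MQ0"),
        ({"qd": 1.5}, "LOW_QD"),
        ({"qual": 10.5}, "LOW_QUAL"),
        ({"total_depth": 10}, "LOW_DEPTH"),
        ({}, None),
        # absent annotations pass their filters
        ({"fs": None, "qd": None, "qual": None, "total_depth": None}, None),
    ],
)
def test_round1_threshold_rules(kw, reason):
    verdicts = filter_round1([make_site(**kw)])
    if reason is None:
        assert verdicts[0].passed
    else:
        assert verdicts[0].reasons == [reason]


def test_round1_low_maf_uses_pooled_read_counts():
    samples = {
        "axillaris": SampleCall(gt=(0, 0), dp=100, ad=(100, 0)),
        "exserta": SampleCall(gt=(0, 0), dp=100, ad=(100, 0)),
        "integrifolia": SampleCall(gt=(0, 0), dp=100, ad=(99, 1)),
    }
    v = filter_round1([make_site(samples=samples)])
    assert v[0].reasons == ["LOW_MAF"]  # pooled minor = 1/300 < 0.01


def test_round1_requires_sorted_input():
    with pytest.raises(ValueError, match="sorted"):
        filter_round1([make_site(pos=500), make_site(pos=100)])


@pytest.mark.parametrize(
    "positions,failing",
    [
        ((100, 150, 199), {0, 1, 2}),  # span 100, inclusive rule: all fail
        ((100, 150, 201), set()),      # span 102
        ((100, 150), set()),           # below cluster size
    ],
)
def test_remove_clusters_examples(positions, failing):
    sites = [make_site(pos=p) for p in positions]
    assert remove_clusters(sites) == failing


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(st.integers(min_value=1, max_value=900), min_size=0, max_size=40),
)
def test_remove_clusters_matches_all_triples_brute_force(positions):
    """Sliding-window cluster detection agrees with exhaustive triple enumeration."""
    positions = sorted(set(positions))
    sites = [make_site(pos=p) for p in positions]
    got = remove_clusters(sites, size=3, window_bp=100)
    brute = set()
    for triple in combinations(range(len(sites)), 3):
        span = positions[triple[-1]] - positions[triple[0]] + 1
        if span <= 100:
            brute.update(triple)
    assert got == brute


@pytest.mark.parametrize(
    "pos,expect_edge",
    [(30, True), (31, False), (970, False), (971, True), (1, True), (1000, True)],
)
def test_round2_edge_rule(pos, expect_edge):
    v = filter_round2([make_site(pos=pos)], INDEX)
    assert ("EDGE" in v[0].reasons) is expect_edge


def test_round2_boundary_rule():
    near = filter_round2([make_site(pos=570)], INDEX)  # |570-600| = 30 <= 30
    far = filter_round2([make_site(pos=569)], INDEX)
    assert "BOUNDARY" in near[0].reasons
    assert "BOUNDARY" not in far[0].reasons


def test_round2_deep_genotypes_strictly_greater_than_10():
    samples = {
        "axillaris": SampleCall(gt=(0, 0), dp=50, ad=(50, 0)),
        "exserta": SampleCall(gt=(1, 1), dp=9, ad=(0, 9)),
        "integrifolia": SampleCall(gt=(1, 1), dp=8, ad=(0, 8)),
    }
    v = filter_round2([make_site(samples=samples)], INDEX)
    assert "INSUFFICIENT_DEEP_GENOTYPES" in v[0].reasons
    samples["exserta"] = SampleCall(gt=(1, 1), dp=11, ad=(0, 11))
    v = filter_round2([make_site(samples=samples)], INDEX)
    assert "INSUFFICIENT_DEEP_GENOTYPES" not in v[0].reasons


def test_round2_reference_heterozygote_excluded():
    samples = {
        "axillaris": SampleCall(gt=(0, 1), dp=50, ad=(25, 25)),
        "exserta": SampleCall(gt=(1, 1), dp=50, ad=(0, 50)),
        "integrifolia": SampleCall(gt=(0, 0), dp=50, ad=(50, 0)),
    }
    v = filter_round2([make_site(samples=samples)], INDEX)
    assert v[0].reasons == ["REF_HET"]


def test_round2_unknown_transcript_names_it():
    with pytest.raises(KeyError, match="t99"):
        filter_round2([make_site(tid="t99")], INDEX)


def test_pipeline_empty_input():
    passing, verdicts, report = run_filter_pipeline([], INDEX)
    assert passing == [] and verdicts == []
    assert report.n_input == 0 and all(c == 0 for c in report.reason_counts.values())


def test_pipeline_verdict_completeness_and_idempotence(small_panel):
    sites = small_panel.sites
    index = small_panel.transcript_index
    passing, verdicts, report = run_filter_pipeline(sites, index)
    assert len(verdicts) == len(sites)
    assert all(set(v.reasons) <= set(REASON_CODES) for v in verdicts)
    # idempotence: the passing set survives a rerun untouched
    passing2, _, report2 = run_filter_pipeline(passing, index)
    assert len(passing2) == len(passing)
    assert report2.n_passed == report2.n_input


def test_relaxing_a_threshold_never_shrinks_the_passing_set(small_panel):
    sites = small_panel.sites
    index = small_panel.transcript_index
    strict = run_filter_pipeline(sites, index, FilterConfig())[2].n_passed
    for relaxed in (
        FilterConfig(max_fs=1e9),
        FilterConfig(min_qual=0),
        FilterConfig(edge_exclusion_bp=0),
        FilterConfig(cluster_window_bp=0),
        FilterConfig(min_deep_genotypes=0),
    ):
        assert run_filter_pipeline(sites, index, relaxed)[2].n_passed >= strict


def test_planted_violations_recovered_exactly(small_panel):
    """Each planted filter violation fails for exactly its truth reasons."""
    truth = {
        (t.transcript_id, t.pos): set(t.reasons) for t in small_panel.truth_snps
    }
    _, verdicts, _ = run_filter_pipeline(
        small_panel.sites, small_panel.transcript_index
    )
    for v in verdicts:
        assert set(v.reasons) == truth[(v.site.transcript_id, v.site.pos)]
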