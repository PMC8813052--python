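import numpy as np
import pytest

from idrkit.disorder_segmentation import (
    DisorderSegment,
    DisorderTrack,
    percentile_of,
    read_scores_tsv,
    segment_track,
    segments_to_tsv,
    smooth_track,
    summarize_proteome,
    surrogate_disorder_scores,
    write_scores_tsv,
)
from idrkit.sequence_io import ProteinRecord


def brute_smooth(scores, window):
    left = (window - 1) // 2
    right = window // 2
    out = []
    for i in range(len(scores)):
        lo = max(0, i - left)
        hi = min(len(scores), i + right + 1)
        out.append(sum(scores[lo:hi]) / (hi - lo))
    return out


def test_track_validation():
    with pytest.raises(ValueError):
        DisorderTrack("x", (0.2, 1.4))
    with pytest.raises(ValueError):
        DisorderTrack("x", ())


def test_smooth_constant_unchanged():
    track = DisorderTrack("x", (0.7,) * 40)
    assert smooth_track(track).scores == pytest.approx(track.scores, abs=1e-12)


def test_smooth_impulse_mass_conserved_interior():
    scores = [0.0] * 60
    scores[30] = 1.0
    smoothed = smooth_track(DisorderTrack("x", tuple(scores)), 20)
    # away from edges every covering window has full size, so total mass is 1
    assert sum(smoothed.scores) == pytest.approx(1.0, abs=1e-9)
    assert sum(1 for s in smoothed.scores if s > 0) <= 20


def test_smooth_matches_brute_force():
    rng = np.random.default_rng(0)
    scores = tuple(float(x) for x in rng.uniform(0, 1, 57))
    for window in (1, 2, 7, 20, 57):
        smoothed = smooth_track(DisorderTrack("x", scores), window)
        assert np.allclose(smoothed.scores, brute_smooth(scores, window), atol=1e-12)


def test_smooth_step_is_monotone():
    track = DisorderTrack("x", tuple([0.0] * 30 + [1.0] * 30))
    smoothed = smooth_track(track, 20)
    assert all(a <= b + 1e-12 for a, b in zip(smoothed.scores, smoothed.scores[1:]))


def test_smooth_window_exceeding_length_warns():
    with pytest.warns(UserWarning, match="exceeds"):
        smoothed = smooth_track(DisorderTrack("x", (0.2, 0.8)), 20)
    assert smoothed.scores == pytest.approx((0.5, 0.5))


def _record(n, seed=0):
    rng = np.random.default_rng(seed)
    return ProteinRecord(f"p{n}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n)))


def test_segment_all_disordered():
    record = _record(300)
    track = DisorderTrack(record.id, (1.0,) * 300)
    segments = segment_track(record, track, min_length=100)
    assert len(segments) == 1
    seg = segments[0]
    assert (seg.region.start, seg.region.end, seg.region.label) == (1, 300, "disordered")


def test_segment_two_blocks_boundary_near_truth():
    record = _record(250)
    raw = DisorderTrack(record.id, tuple([1.0] * 150 + [0.0] * 100))
    smoothed = smooth_track(raw, 20)
    segments = segment_track(record, smoothed, min_length=80)
    labels = [s.region.label for s in segments]
    assert labels == ["disordered", "ordered"]
    boundary = segments[0].region.end
    assert abs(boundary - 150) <= 10  # within the smoothing half-window


def test_segment_below_min_length_dropped():
    record = _record(50)
    track = DisorderTrack(record.id, (0.4,) * 50)
    assert segment_track(record, track, min_length=100) == []


def test_segment_length_mismatch():
    record = _record(50)
    with pytest.raises(ValueError):
        segment_track(record, DisorderTrack(record.id, (0.5,) * 49), min_length=10)


def test_segments_conserve_residues_before_filtering():
    record = _record(400, seed=3)
    rng = np.random.default_rng(4)
    track = DisorderTrack(record.id, tuple(float(x) for x in rng.uniform(0, 1, 400)))
    segments = segment_track(record, track, min_length=1)
    covered = []
    for s in segments:
        covered.extend(range(s.region.start, s.region.end + 1))
    # min_length=1 drops only runs of length 1; emitted segments never overlap
    assert len(covered) == len(set(covered))
    spans = [(s.region.start, s.region.end) for s in segments]
    assert spans == sorted(spans)


def _segment(pid, start, end, label, complexity, hydropathy, liv, seq_seed=0):
    length = end - start + 1
    record = _record(length, seed=seq_seed)
    from idrkit import composition_metrics as cm

    return DisorderSegment(
        region=__import__("idrkit.sequence_io", fromlist=["Region"]).Region(pid, start, end, label),
        mean_score=0.5,
        composition=cm.aa_composition(record),
        hydropathy=hydropathy,
        complexity=complexity,
        fraction_liv=liv,
    )


def test_summarize_single_segment():
    seg = _segment("p", 1, 200, "disordered", 2.5, -1.0, 0.1)
    summary = summarize_proteome([seg])
    assert summary.per_class["disordered"]["count_gt_complexity_cutoff"] == 1
    assert summary.per_class["ordered"]["segment_count"] == 0
    assert summary.per_class["ordered"]["complexity"]["median"] is None


def test_summarize_respects_both_cutoffs():
    segs = [
        _segment("p", 1, 120, "ordered", 2.9, -0.5, 0.2),  # >100 but not >150
        _segment("p", 200, 400, "ordered", 2.8, -0.6, 0.25),  # both
    ]
    summary = summarize_proteome(segs)
    assert summary.per_class["ordered"]["count_gt_complexity_cutoff"] == 1
    assert summary.per_class["ordered"]["count_gt_feature_cutoff"] == 2


def test_summarize_all_short_is_empty():
    segs = [_segment("p", 1, 90, "ordered", 2.9, -0.5, 0.2)]
    summary = summarize_proteome(segs)
    for label in ("ordered", "disordered"):
        assert summary.per_class[label]["count_gt_feature_cutoff"] == 0


def test_summarize_mean_composition_residue_weighted():
    a = _segment("p", 1, 150, "disordered", 2.5, -1.0, 0.1, seq_seed=1)
    b = _segment("p", 200, 500, "disordered", 2.4, -1.1, 0.12, seq_seed=2)
    summary = summarize_proteome([a, b])
    mean_comp = summary.per_class["disordered"]["mean_composition"]
    weights = np.array([a.region.length, b.region.length], dtype=float)
    expected = (
        a.composition.as_vector() * weights[0] + b.composition.as_vector() * weights[1]
    ) / weights.sum()
    from idrkit.sequence_io import AMINO_ACIDS

    assert np.allclose([mean_comp[x] for x in AMINO_ACIDS], expected)


def test_synthetic_summary_orders_complexity_medians():
    from idrkit.synthetic_data import SyntheticProteomeConfig, generate_proteome

    config = SyntheticProteomeConfig(n_proteins=30, seed=7)
    records, tracks, _ = generate_proteome(config)
    segments = []
    for record, track in zip(records, tracks):
        segments.extend(segment_track(record, smooth_track(track), min_length=100))
    summary = summarize_proteome(segments)
    med_o = summary.per_class["ordered"]["complexity"]["median"]
    med_d = summary.per_class["disordered"]["complexity"]["median"]
    assert med_o > med_d


def test_percentile_of():
    dist = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert percentile_of(10.0, dist) == 100.0
    assert percentile_of(0.0, dist) == 0.0
    assert percentile_of(3.0, dist) == 60.0  # ties counted as <=
    with pytest.raises(ValueError):
        percentile_of(1.0, [])


def test_surrogate_limits():
    poly_k = surrogate_disorder_scores(ProteinRecord("k", "K" * 50))
    poly_i = surrogate_disorder_scores(ProteinRecord("i", "I" * 50))
    assert np.mean(poly_k.scores) > 0.9
    assert np.mean(poly_i.scores) < 0.1


def test_surrogate_wt_mostly_disordered(wt):
    assert np.mean(surrogate_disorder_scores(wt).scores) > 0.5


def test_surrogate_deterministic(wt):
    assert surrogate_disorder_scores(wt) == surrogate_disorder_scores(wt)


def test_scores_tsv_roundtrip(tmp_path):
    tracks = [
        DisorderTrack("a", (0.1, 0.9, 0.5)),
        DisorderTrack("b", (1.0, 0.0)),
    ]
    path = tmp_path / "scores.tsv"
    write_scores_tsv(tracks, path)
    loaded = read_scores_tsv(path)
    for track in tracks:
        assert loaded[track.protein_id].scores == pytest.approx(track.scores)


def test_scores_tsv_two_column(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("1\t0.25\n2\t0.75\n")
    loaded = read_scores_tsv(path, protein_id="p")
    assert loaded["p"].scores == (0.25, 0.75)
    with pytest.raises(ValueError):
        read_scores_tsv(path)  # needs an explicit protein id


def test_scores_tsv_noncontiguous_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("p\t1\t0.5\np\t3\t0.5\n")
    with pytest.raises(ValueError, match="contiguous"):
        read_scores_tsv(path)


def test_segments_tsv_format():
    seg = _segment("prot", 5, 160, "ordered", 2.9, -0.4, 0.3)
    text = segments_to_tsv([seg])
    lines = text.strip().splitlines()
    assert lines[0].startswith("protein_id\tstart\tend\tlabel")
    assert lines[1].split("\t")[:4] == ["prot", "5", "160", "ordered"]


def test_boundary_recovery_on_noisy_blocks():
    from idrkit.synthetic_data import SyntheticProteomeConfig, generate_proteome

    config = SyntheticProteomeConfig(n_proteins=20, noise_sd=0.05, seed=1)
    records, tracks, truth = generate_proteome(config)
    recovered = 0
    total = 0
    for record, track in zip(records, tracks):
        segments = segment_track(record, smooth_track(track), min_length=40)
        disordered = set()
        for s in segments:
            if s.region.label == "disordered":
                disordered.update(range(s.region.start, s.region.end + 1))
        for region in (r for r in truth if r.protein_id == record.id and r.label == "disordered"):
            for i in range(region.start, region.end + 1):
                total += 1
                recovered += i in disordered
    assert recovered / total >= 0.95
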