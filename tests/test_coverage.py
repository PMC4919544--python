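import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromaquant import (
    AlignmentRecord,
    CoverageTrack,
    WindowSpec,
    difference_track,
    extend_and_pile,
    mapq_filter,
    mean_profile,
    replicate_pearson,
    rpm_normalize,
    tss_window_matrix,
)
from chromaquant.annotation import Gene, GeneAnnotation
from chromaquant.coverage import window_bounds

from conftest import random_records


# ------------------------------------------------------------------ mapq_filter


def test_mapq_filter_keeps_all_above():
    recs = [AlignmentRecord("c", i, i + 50, "+", mapq=60, read_id=str(i)) for i in range(5)]
    assert mapq_filter(recs, 13) == recs


@pytest.mark.parametrize("mapq,kept", [(12, False), (13, True), (14, True)])
def test_mapq_filter_boundary_inclusive_at_13(mapq, kept):
    rec = AlignmentRecord("c", 0, 50, "+", mapq=mapq, read_id="r")
    assert (mapq_filter([rec], 13) == [rec]) is kept


def test_mapq_filter_zero_is_identity(rng):
    recs = random_records(rng, {"c": 10_000}, 50)
    assert mapq_filter(recs, 0) == recs


def test_mapq_filter_rejects_negative_threshold():
    with pytest.raises(ValueError):
        mapq_filter([], -1)


# -------------------------------------------------------------- extend_and_pile


def test_single_plus_read_extension():
    track = extend_and_pile(
        [AlignmentRecord("c", 100, 150, "+", read_id="r")], {"c": 500}, extension=148
    )
    v = track.values["c"]
    assert np.all(v[100:248] == 1.0)
    assert v[99] == 0.0 and v[248] == 0.0
    assert v.sum() == 148.0


def test_single_minus_read_extends_leftward_from_end():
    track = extend_and_pile(
        [AlignmentRecord("c", 300, 350, "-", read_id="r")], {"c": 500}, extension=148
    )
    v = track.values["c"]
    # covers [350-148, 350)
    assert np.all(v[202:350] == 1.0)
    assert v[201] == 0.0 and v[350] == 0.0


def test_empty_input_gives_zero_track():
    track = extend_and_pile([], {"c": 100})
    assert np.all(track.values["c"] == 0.0)
    assert track.total_reads == 0


def brute_force_pile(records, chrom_sizes, extension):
    """Independent per-base overlap counter."""
    cov = {c: np.zeros(size) for c, size in chrom_sizes.items()}
    for r in records:
        if r.strand == "+":
            s, e = r.start, r.start + extension
        else:
            s, e = r.end - extension, r.end
        for b in range(max(s, 0), min(e, chrom_sizes[r.chrom])):
            cov[r.chrom][b] += 1.0
    return cov


def test_pile_matches_brute_force_oracle(rng):
    sizes = {"cA": 3_000, "cB": 2_000}
    # short chromosome + long extension forces edge clipping on both sides
    recs = random_records(rng, sizes, 1_000, read_len=50)
    track = extend_and_pile(recs, sizes, extension=148)
    oracle = brute_force_pile(recs, sizes, 148)
    for c in sizes:
        assert np.array_equal(track.values[c], oracle[c])


def test_pile_mass_conservation(rng):
    sizes = {"c": 1_000}
    recs = random_records(rng, sizes, 200, read_len=50)
    track = extend_and_pile(recs, sizes, extension=148)
    expected = 0
    for r in recs:
        s, e = (r.start, r.start + 148) if r.strand == "+" else (r.end - 148, r.end)
        expected += min(e, 1_000) - max(s, 0)
    assert track.values["c"].sum() == expected


def test_pile_binning_averages_per_base(rng):
    sizes = {"c": 1_050}
    recs = random_records(rng, sizes, 100)
    per_base = extend_and_pile(recs, sizes, extension=148, bin_size=1)
    binned = extend_and_pile(recs, sizes, extension=148, bin_size=100)
    for i in range(10):
        assert binned.values["c"][i] == pytest.approx(
            per_base.values["c"][i * 100 : (i + 1) * 100].mean()
        )
    # partial last bin: 50 bases
    assert binned.values["c"][10] == pytest.approx(per_base.values["c"][1000:].mean())


def test_pile_rejects_out_of_bounds_record_by_name():
    bad = AlignmentRecord("c", 90, 140, "+", read_id="offender")
    with pytest.raises(ValueError, match="offender"):
        extend_and_pile([bad], {"c": 100})


def test_pile_rejects_unknown_chromosome():
    with pytest.raises(ValueError, match="unknown"):
        extend_and_pile([AlignmentRecord("nope", 0, 50, "+", read_id="r")], {"c": 100})


# --------------------------------------------------------------- rpm_normalize


def _track(values, total_reads, normalization="raw"):
    return CoverageTrack(
        values={"c": np.asarray(values, dtype=float)},
        chrom_sizes={"c": len(values)},
        normalization=normalization,
        total_reads=total_reads,
    )


def test_rpm_identity_at_one_million():
    t = rpm_normalize(_track([1.0, 2.0, 3.0], 10**6))
    assert np.array_equal(t.values["c"], [1.0, 2.0, 3.0])
    assert t.normalization == "rpm"


def test_rpm_two_million_halves():
    t = rpm_normalize(_track([4.0], 2 * 10**6))
    assert t.values["c"][0] == 2.0


def test_rpm_linearity(rng):
    vals = rng.random(50)
    t = rpm_normalize(_track(vals, 12_345))
    assert np.allclose(t.values["c"], vals * 1e6 / 12_345)


def test_rpm_zero_reads_errors():
    with pytest.raises(ValueError):
        rpm_normalize(_track([1.0], 0))


# ------------------------------------------------------------- difference_track


def test_difference_of_identical_is_zero(rng):
    a = rpm_normalize(_track(rng.random(20), 100))
    assert np.all(difference_track(a, a).values["c"] == 0.0)


def test_difference_antisymmetry(rng):
    a = rpm_normalize(_track(rng.random(20), 100))
    b = rpm_normalize(_track(rng.random(20), 150))
    d1 = difference_track(a, b).values["c"]
    d2 = difference_track(b, a).values["c"]
    assert np.array_equal(d1, -d2)


def test_difference_requires_matching_normalization(rng):
    a = rpm_normalize(_track(rng.random(20), 100))
    b = _track(rng.random(20), 100)
    with pytest.raises(ValueError):
        difference_track(a, b)


def test_difference_requires_matching_bins(rng):
    a = rpm_normalize(_track(rng.random(20), 100))
    b = rpm_normalize(_track(rng.random(30), 100))
    with pytest.raises(ValueError):
        difference_track(a, b)


# ------------------------------------------------------------ replicate_pearson


def test_pearson_identical_tracks():
    a = _track([1.0, 5.0, 3.0, 2.0], 10)
    assert replicate_pearson(a, a) == pytest.approx(1.0)


def test_pearson_negative_affine():
    a = _track([1.0, 5.0, 3.0, 2.0], 10)
    b = _track([-1.0 + 7, -5.0 + 7, -3.0 + 7, -2.0 + 7], 10)
    assert replicate_pearson(a, b) == pytest.approx(-1.0)


def test_pearson_matches_textbook_formula(rng):
    x, y = rng.random(100), rng.random(100)
    a, b = _track(x, 10), _track(y, 10)
    # independent direct formula
    xm, ym = x - x.mean(), y - y.mean()
    expected = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
    assert abs(replicate_pearson(a, b) - expected) < 1e-12


def test_pearson_zero_variance_errors():
    a = _track([2.0, 2.0, 2.0], 10)
    b = _track([1.0, 2.0, 3.0], 10)
    with pytest.raises(ValueError):
        replicate_pearson(a, b)


# ------------------------------------------------------------ tss_window_matrix


def test_window_spec_defaults_give_80_windows():
    assert WindowSpec().n_windows == 80


def test_window_spec_validates_divisibility():
    with pytest.raises(ValueError):
        WindowSpec(span=800, width=30)


def test_tss_matrix_has_80_windows(ann20, rng):
    recs = random_records(rng, ann20.chrom_sizes, 500)
    track = extend_and_pile(recs, ann20.chrom_sizes)
    m = tss_window_matrix(track, ann20)
    assert m.values.shape == (20, 80)


def test_isolated_gene_has_no_masked_windows(rng):
    ann = GeneAnnotation(
        [Gene("lone", "c", 5_000, 6_000, "+")], chrom_sizes={"c": 20_000}
    )
    track = extend_and_pile(random_records(rng, {"c": 20_000}, 200), {"c": 20_000})
    m = tss_window_matrix(track, ann)
    assert not m.mask.any()


def test_strand_reflection_oracle(rng):
    """A - strand gene row equals the + strand row on the mirrored genome."""
    size = 10_000
    vals = rng.random(size)
    tss_fwd = 4_321
    ann_fwd = GeneAnnotation(
        [Gene("g", "c", tss_fwd, tss_fwd + 500, "+")], chrom_sizes={"c": size}
    )
    fwd_track = CoverageTrack({"c": vals}, {"c": size})
    row_fwd = tss_window_matrix(fwd_track, ann_fwd).row("g")

    # mirror: base x -> size-1-x ; the gene becomes - strand with tss reflected
    tss_rev = size - 1 - tss_fwd
    ann_rev = GeneAnnotation(
        [Gene("g", "c", tss_rev - 499, tss_rev + 1, "-")], chrom_sizes={"c": size}
    )
    rev_track = CoverageTrack({"c": vals[::-1].copy()}, {"c": size})
    row_rev = tss_window_matrix(rev_track, ann_rev).row("g")
    assert np.allclose(row_fwd, row_rev, equal_nan=True)


def test_neighbour_masking_matches_interval_oracle(ann_tight, rng):
    track = extend_and_pile(
        random_records(rng, ann_tight.chrom_sizes, 300), ann_tight.chrom_sizes
    )
    m = tss_window_matrix(track, ann_tight)
    spec = m.window_spec
    genes = list(ann_tight)
    for gi, g in enumerate(genes):
        size = ann_tight.chrom_sizes[g.chrom]
        for wi, (ws, we) in enumerate(window_bounds(g.tss, g.strand, spec)):
            # exhaustive interval overlap check against every other gene
            expected = (ws < 0 or we > size) or any(
                o.chrom == g.chrom
                and o.gene_id != g.gene_id
                and max(ws, o.start) < min(we, o.end)
                for o in genes
            )
            assert m.mask[gi, wi] == expected
    assert m.mask.any()  # the tight genome must actually trigger masking


def test_edge_windows_masked_not_error(rng):
    ann = GeneAnnotation(
        [Gene("edge", "c", 100, 700, "+")], chrom_sizes={"c": 5_000}
    )
    track = extend_and_pile(random_records(rng, {"c": 5_000}, 100), {"c": 5_000})
    m = tss_window_matrix(track, ann)
    # TSS at 100: windows reaching below base 0 must be masked
    assert m.mask[0, : (800 - 100) // 20].all()
    assert not m.mask[0, 40:].any()


# ----------------------------------------------------------------- mean_profile


def test_mean_profile_single_gene_is_row(ann20, rng):
    track = extend_and_pile(random_records(rng, ann20.chrom_sizes, 500), ann20.chrom_sizes)
    m = tss_window_matrix(track, ann20)
    gid = ann20.gene_ids[0]
    assert np.allclose(mean_profile(m, [gid]), m.row(gid), equal_nan=True)


def test_mean_profile_symmetry():
    from chromaquant.coverage import TSSMatrix

    spec = WindowSpec()
    v = np.random.default_rng(0).random((1, 80))
    vals = np.vstack([v, -v])
    m = TSSMatrix(["a", "b"], vals, np.zeros_like(vals, dtype=bool), spec)
    assert np.allclose(mean_profile(m, ["a", "b"]), 0.0)


def test_mean_profile_matches_loop_oracle(ann20, rng):
    track = extend_and_pile(random_records(rng, ann20.chrom_sizes, 800), ann20.chrom_sizes)
    m = tss_window_matrix(track, ann20)
    genes = ann20.gene_ids
    prof = mean_profile(m, genes)
    for w in range(80):
        vals = [m.row(g)[w] for g in genes if not np.isnan(m.row(g)[w])]
        if vals:
            expected = sum(vals) / len(vals)
            assert abs(prof[w] - expected) < 1e-12
        else:
            assert np.isnan(prof[w])


def test_mean_profile_empty_set_errors(ann20, rng):
    track = extend_and_pile(random_records(rng, ann20.chrom_sizes, 100), ann20.chrom_sizes)
    m = tss_window_matrix(track, ann20)
    with pytest.raises(ValueError):
        mean_profile(m, [])


# -------------------------------------------------------------------- property


@settings(max_examples=25, deadline=None)
@given(total=st.integers(min_value=1, max_value=10**7))
def test_rpm_is_invertible(total):
    vals = np.array([0.0, 1.0, 7.5])
    t = rpm_normalize(_track(vals, total))
    assert np.allclose(t.values["c"] * total / 1e6, vals)
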