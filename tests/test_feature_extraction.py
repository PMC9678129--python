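"""Peak-list ingestion, ppm alignment, missingness filter, knn imputation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from milkspot.feature_extraction import (
    FeatureMatrix,
    PeakList,
    align_features,
    filter_missing,
    fuse_polarities,
    knn_impute,
    load_peak_list,
    threshold_peaks,
)


def _pl(sample_id, mz, intensity, polarity="positive"):
    return PeakList(sample_id, polarity, np.asarray(mz, float),
                    np.asarray(intensity, float))


# ---------------------------------------------------------------------------
# loading


def test_load_peak_list_sorts_and_tolerates_header(tmp_path):
    path = tmp_path / "s1.csv"
    path.write_text("mz,intensity\n100.1,2e5\n90.0,3e5\n")
    pl = load_peak_list(path, "s1", "positive")
    np.testing.assert_array_equal(pl.mz, [90.0, 100.1])
    np.testing.assert_array_equal(pl.intensity, [3e5, 2e5])


def test_load_peak_list_empty_and_malformed(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.warns(UserWarning, match="no peaks"):
        pl = load_peak_list(empty, "s", "positive")
    assert len(pl) == 0

    bad = tmp_path / "bad.csv"
    bad.write_text("100.0,1e5\nabc,1\n")
    with pytest.raises(ValueError, match="bad.csv:2"):
        load_peak_list(bad, "s", "positive")


def test_peak_list_validation():
    with pytest.raises(ValueError):
        _pl("s", [-1.0], [10.0])
    with pytest.raises(ValueError):
        _pl("s", [100.0], [-5.0])
    with pytest.raises(ValueError):
        PeakList("s", "middle", np.array([1.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# thresholding


def test_threshold_strictly_above():
    pl = _pl("s", [200.0, 300.0], [99_999.0, 100_001.0])
    kept = threshold_peaks(pl, 100_000.0)
    np.testing.assert_array_equal(kept.mz, [300.0])
    boundary = _pl("s", [200.0], [100_000.0])
    assert len(threshold_peaks(boundary, 100_000.0)) == 0
    assert len(threshold_peaks(_pl("s", [], []))) == 0
    all_above = _pl("s", [1.0, 2.0], [2e5, 3e5])
    np.testing.assert_array_equal(threshold_peaks(all_above).mz, [1.0, 2.0])


# ---------------------------------------------------------------------------
# alignment


def test_align_single_shared_feature():
    pls = [_pl(f"s{i}", [500.0], [1e6]) for i in range(3)]
    fm = align_features(pls)
    assert fm.n_features == 1
    assert fm.features["centroid_mz"].iloc[0] == pytest.approx(500.0)
    assert not fm.missing_mask.any()


def test_align_splits_at_five_ppm():
    """500.0000 and 500.0010 (~2 ppm apart) cluster together; 500.0060
    (~12 ppm from the first, ~10 from the second) forms its own feature —
    matching single-linkage clustering at 5 ppm on these three values."""
    pls = [
        _pl("a", [500.0000], [1e6]),
        _pl("b", [500.0010], [1e6]),
        _pl("c", [500.0060], [1e6]),
    ]
    fm = align_features(pls, ppm_window=5.0)
    assert fm.n_features == 2
    first = fm.values[:, 0]
    assert not np.isnan(first[0]) and not np.isnan(first[1]) and np.isnan(first[2])
    assert np.isnan(fm.values[0, 1]) and not np.isnan(fm.values[2, 1])


def test_align_empty_and_errors():
    fm = align_features([_pl("a", [], []), _pl("b", [], [])])
    assert fm.n_features == 0
    with pytest.raises(ValueError, match="mixed polarities"):
        align_features([_pl("a", [1.0], [1.0]),
                        _pl("b", [1.0], [1.0], polarity="negative")])
    with pytest.raises(ValueError, match="duplicate"):
        align_features([_pl("a", [1.0], [1.0]), _pl("a", [2.0], [2.0])])


def test_align_keeps_most_intense_duplicate():
    pls = [_pl("a", [500.0000, 500.0005], [1e6, 5e6]), _pl("b", [500.0002], [2e6])]
    fm = align_features(pls)
    assert fm.n_features == 1
    assert fm.values[0, 0] == 5e6  # the stronger of sample a's two peaks


def test_align_members_within_window_of_centroid(study_small):
    """Every matrix cell must come from a peak within 5 ppm of its
    feature's centroid (checked by locating the contributing peak via its
    unique intensity; alignment applied before imputation)."""
    pos_lists = [
        threshold_peaks(pl)
        for pl in study_small["peak_lists"]
        if pl.polarity == "positive"
    ]
    fm = align_features(pos_lists)
    by_key = {(pl.sample_id, pl.polarity): pl for pl in pos_lists}
    centroids = fm.features["centroid_mz"].to_numpy()
    polarities = fm.features["polarity"].to_numpy()
    rng = np.random.default_rng(0)
    cols = rng.choice(fm.n_features, size=min(40, fm.n_features), replace=False)
    for j in cols:
        for i, sid in enumerate(fm.sample_ids):
            v = fm.values[i, j]
            if np.isnan(v):
                continue
            pl = by_key[(sid, polarities[j])]
            matches = pl.mz[np.isclose(pl.intensity, v)]
            assert matches.size >= 1
            ppm = np.abs(matches - centroids[j]) / centroids[j] * 1e6
            assert ppm.min() <= 5.0 + 1e-9


def test_align_recovers_feature_count_without_jitter():
    from milkspot.synthetic_data import StudyDesign, generate_study

    design = StudyDesign(
        n_features_per_polarity=40, ppm_jitter_sd=0.0, seed=8,
        missing_rate_fn_params={"max_rate": 0.0},
    )
    peak_lists, _, _ = generate_study(design, [])
    for polarity in ("positive", "negative"):
        fm = align_features([p for p in peak_lists if p.polarity == polarity])
        assert fm.n_features == 40


# ---------------------------------------------------------------------------
# missingness filter


def test_filter_missing_strict_boundary():
    """With 48 samples: 10 missing (20.8%) is removed, 9 (18.75%) kept,
    and exactly 20% (with 45 samples, 9 missing) is retained."""
    values = np.ones((48, 2))
    values[:10, 0] = np.nan
    values[:9, 1] = np.nan
    fm = FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(48)],
        features=pd.DataFrame(
            {"centroid_mz": [100.0, 200.0], "polarity": ["positive"] * 2}
        ),
        values=values,
    )
    kept = filter_missing(fm, 0.2)
    assert kept.n_features == 1
    assert kept.features["centroid_mz"].iloc[0] == 200.0

    values = np.ones((45, 1))
    values[:9, 0] = np.nan  # exactly 20%
    fm20 = FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(45)],
        features=pd.DataFrame({"centroid_mz": [1.0], "polarity": ["positive"]}),
        values=values,
    )
    assert filter_missing(fm20, 0.2).n_features == 1


def test_filter_missing_idempotent_and_noop(study_small):
    fm_raw = align_features(
        [p for p in study_small["peak_lists"] if p.polarity == "positive"]
    )
    once = filter_missing(fm_raw)
    twice = filter_missing(once)
    np.testing.assert_array_equal(once.values, twice.values)
    complete = knn_impute(once)
    np.testing.assert_array_equal(filter_missing(complete).values, complete.values)


# ---------------------------------------------------------------------------
# knn imputation


def _impute_oracle(values, k):
    """Exhaustive feature-wise knn imputation oracle."""
    out = values.copy()
    n, p = values.shape
    for s in range(n):
        for j in range(p):
            if not np.isnan(values[s, j]):
                continue
            cands = []
            for i in range(p):
                if i == j or np.isnan(values[s, i]):
                    continue
                mutual = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
                if not mutual.any():
                    continue
                d = np.sqrt(np.sum((values[mutual, i] - values[mutual, j]) ** 2))
                cands.append((d, i))
            if not cands:
                out[s, j] = np.nanmean(values[:, j])
                continue
            cands.sort()
            chosen = [i for _, i in cands[: min(k, len(cands))]]
            out[s, j] = np.mean([values[s, i] for i in chosen])
    return out


def _fm(values):
    values = np.asarray(values, float)
    p = values.shape[1]
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        features=pd.DataFrame(
            {"centroid_mz": np.arange(1.0, p + 1), "polarity": ["positive"] * p}
        ),
        values=values,
    )


def test_knn_impute_toy_matches_oracle():
    values = np.array(
        [
            [1.0, 1.1, 5.0, 1.05],
            [2.0, 2.1, 6.0, np.nan],
            [3.0, 3.1, 7.0, 3.02],
        ]
    )
    out = knn_impute(_fm(values), k=2)
    expected = _impute_oracle(values, 2)
    np.testing.assert_allclose(out.values, expected)
    # k=2 nearest features to column 3 are columns 0 and 1
    assert out.values[1, 3] == pytest.approx((2.0 + 2.1) / 2)


def test_knn_impute_matches_oracle_random_sweep():
    """Property sweep: all random matrices up to 6x6 with <=2 missing
    cells agree with the exhaustive oracle."""
    rng = np.random.default_rng(42)
    for n, p in itertools.product((3, 4, 6), (2, 4, 6)):
        for _ in range(8):
            values = rng.uniform(1, 10, size=(n, p))
            n_missing = rng.integers(1, 3)
            cells = rng.choice(n * p, size=n_missing, replace=False)
            for c in cells:
                values[c // p, c % p] = np.nan
            if np.isnan(values).all(axis=0).any():
                continue
            k = int(rng.integers(1, p + 1))
            out = knn_impute(_fm(values), k=k)
            np.testing.assert_allclose(
                out.values, _impute_oracle(values, k), err_msg=f"{n}x{p} k={k}"
            )


def test_knn_impute_contracts():
    complete = _fm(np.ones((3, 3)))
    assert knn_impute(complete) is complete  # unchanged fast path
    values = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    out = knn_impute(_fm(values), k=10)  # k exceeds feature count
    assert out.values[0, 2] == pytest.approx(1.5)  # mean of other features
    all_nan = np.ones((3, 2))
    all_nan[:, 1] = np.nan
    with pytest.raises(ValueError, match="no observed values"):
        knn_impute(_fm(all_nan))


# ---------------------------------------------------------------------------
# fusion


def test_fuse_polarities_concatenates():
    pos = _fm(np.ones((4, 3)))
    neg = _fm(np.full((4, 2), 2.0))
    neg.features["polarity"] = "negative"
    fused = fuse_polarities(pos, neg)
    assert fused.values.shape == (4, 5)
    assert list(fused.features["polarity"]) == ["positive"] * 3 + ["negative"] * 2

    empty_neg = _fm(np.empty((4, 0)))
    out = fuse_polarities(pos, empty_neg)
    np.testing.assert_array_equal(out.values, pos.values)


def test_fuse_polarities_errors_name_difference():
    pos = _fm(np.ones((3, 2)))
    neg = _fm(np.ones((3, 2)))
    neg.sample_ids = ["s0", "s1", "other"]
    with pytest.raises(ValueError, match="other"):
        fuse_polarities(pos, neg)
    reordered = _fm(np.ones((3, 2)))
    reordered.sample_ids = ["s1", "s0", "s2"]
    with pytest.raises(ValueError, match="order"):
        fuse_polarities(pos, reordered)
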