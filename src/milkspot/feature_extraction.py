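"""Peak-list ingestion, ppm alignment, missingness filtering and imputation.

Direct-infusion MS yields one composite peak list (m/z, intensity) per
sample per polarity.  This module turns a collection of such lists into a
samples x features matrix:

1. intensity thresholding (keep peaks strictly above 100 000 counts by
   default — instrument noise floor);
2. m/z alignment within a 5 ppm window: peaks from all samples are pooled,
   sorted, split at consecutive relative gaps larger than the window, and
   each block is refined against its intensity-weighted centroid so that
   every member lies within the window of the centroid;
3. features with more than 20% missing values across all samples are
   removed;
4. remaining gaps are filled by feature-wise k-nearest-neighbour
   imputation (k = 10), Troyanskaya-style: a missing cell is the mean of
   the k most similar features (Euclidean distance over mutually observed
   samples) that are observed for that sample;
5. the positive- and negative-mode matrices are concatenated column-wise
   (low-level data fusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "FeatureMatrix",
    "load_peak_list",
    "load_mzml",
    "threshold_peaks",
    "align_features",
    "filter_missing",
    "knn_impute",
    "fuse_polarities",
    "write_feature_matrix",
    "read_feature_matrix",
]

POLARITIES = ("positive", "negative")


@dataclass(frozen=True)
class PeakList:
    """One sample's (m/z, intensity) pairs for one polarity."""

    sample_id: str
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray
    day: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if mz.size and mz.min() <= 0:
            raise ValueError("m/z values must be strictly positive")
        if intensity.size and intensity.min() < 0:
            raise ValueError("intensities must be non-negative")
        if not np.all(np.diff(mz) >= 0):
            order = np.argsort(mz, kind="stable")
            mz, intensity = mz[order], intensity[order]
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class FeatureMatrix:
    """Samples x aligned-features intensity matrix.

    ``values`` holds NaN where a sample contributed no peak; ``features``
    has one row per column with ``centroid_mz`` and ``polarity``.
    """

    sample_ids: list[str]
    features: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.features)} features"
            )
        self.features = self.features.reset_index(drop=True)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{row.polarity[:3]}_{row.centroid_mz:.5f}"
            for row in self.features.itertuples(index=False)
        ]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureMatrix(
            sample_ids=list(sample_ids),
            features=self.features.copy(),
            values=self.values[idx],
        )


def load_peak_list(path, sample_id: str, polarity: str, day: int = 0) -> PeakList:
    """Read a two-column delimited text file (m/z, intensity).

    Accepts comma, tab or whitespace delimiters and an optional header
    row.  Malformed data rows raise ``ValueError`` naming the line number;
    an empty file gives an empty PeakList with a warning.
    """
    path = Path(path)
    mzs: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            for delim in (",", "\t", None):
                parts = line.split(delim)
                if len(parts) >= 2:
                    break
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            mzs.append(mz)
            intensities.append(inten)
    if not mzs:
        warnings.warn(f"{path}: no peaks found", stacklevel=2)
    return PeakList(
        sample_id=sample_id,
        polarity=polarity,
        mz=np.array(mzs),
        intensity=np.array(intensities),
        day=day,
    )


def load_mzml(
    path, sample_id: str, polarity: str, day: int = 0, ppm_window: float = 5.0
) -> PeakList:
    """Thin mzML reader: pool the centroided MS1 scans of one acquisition
    into a single averaged peak list.

    Centroids from all MS1 spectra are pooled, grouped by the same
    gap-split rule used for alignment, and each group is reduced to its
    intensity-weighted m/z and its summed intensity divided by the scan
    count (scan-averaged intensity).
    """
    from pyteomics import mzml as _mzml

    mz_all: list[np.ndarray] = []
    int_all: list[np.ndarray] = []
    n_scans = 0
    with _mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            n_scans += 1
            mz_all.append(np.asarray(spec["m/z array"], dtype=float))
            int_all.append(np.asarray(spec["intensity array"], dtype=float))
    if not mz_all:
        warnings.warn(f"{path}: no MS1 spectra", stacklevel=2)
        return PeakList(sample_id, polarity, np.empty(0), np.empty(0), day)
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    out_mz, out_int = [], []
    for start, stop in _gap_blocks(mz, ppm_window):
        block_i = inten[start:stop]
        block_m = mz[start:stop]
        w = block_i.sum()
        c = float((block_m * block_i).sum() / w) if w > 0 else float(block_m.mean())
        out_mz.append(c)
        out_int.append(block_i.sum() / n_scans)
    return PeakList(sample_id, polarity, np.array(out_mz), np.array(out_int), day)


def threshold_peaks(pl: PeakList, min_intensity: float = 100_000.0) -> PeakList:
    """Keep peaks with intensity strictly greater than ``min_intensity``."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    keep = pl.intensity > min_intensity
    return PeakList(pl.sample_id, pl.polarity, pl.mz[keep], pl.intensity[keep], pl.day)


def _gap_blocks(mz_sorted: np.ndarray, ppm_window: float):
    """Split a sorted m/z array where the gap to the previous value exceeds
    ``ppm_window`` ppm of the lower value; yields (start, stop) slices."""
    n = mz_sorted.size
    if n == 0:
        return
    gaps = np.diff(mz_sorted) / mz_sorted[:-1] * 1e6
    breaks = np.nonzero(gaps > ppm_window)[0] + 1
    start = 0
    for b in list(breaks) + [n]:
        yield start, b
        start = b


def _centroid(mz: np.ndarray, intensity: np.ndarray) -> float:
    w = intensity.sum()
    if w <= 0:
        return float(mz.mean())
    return float((mz * intensity).sum() / w)


def _refine_block(mz, intensity, sample_idx, ppm_window, out):
    """Recursively split a block until every member is within ppm_window of
    the block's intensity-weighted centroid."""
    c = _centroid(mz, intensity)
    dev = np.abs(mz - c) / c * 1e6
    if mz.size <= 1 or dev.max() <= ppm_window:
        out.append((mz, intensity, sample_idx))
        return
    # split at the largest internal relative gap
    gaps = np.diff(mz) / mz[:-1]
    cut = int(np.argmax(gaps)) + 1
    _refine_block(mz[:cut], intensity[:cut], sample_idx[:cut], ppm_window, out)
    _refine_block(mz[cut:], intensity[cut:], sample_idx[cut:], ppm_window, out)


def align_features(
    pls: Sequence[PeakList], ppm_window: float = 5.0
) -> FeatureMatrix:
    """Cluster peaks from all samples into features within a ppm window.

    Pooled peaks are sorted by m/z, split at consecutive gaps above the
    window, and blocks are recursively refined so every member peak lies
    within ``ppm_window`` ppm of the block's intensity-weighted centroid.
    When one sample contributes several peaks to a feature, the most
    intense is kept; centroids are then recomputed from the kept peaks.
    """
    if ppm_window <= 0:
        raise ValueError("ppm_window must be positive")
    if not pls:
        raise ValueError("no peak lists given")
    polarity = pls[0].polarity
    if any(pl.polarity != polarity for pl in pls):
        raise ValueError("mixed polarities passed to align_features")
    sample_ids = [pl.sample_id for pl in pls]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")

    mz = np.concatenate([pl.mz for pl in pls]) if pls else np.empty(0)
    intensity = np.concatenate([pl.intensity for pl in pls])
    sample_idx = np.concatenate(
        [np.full(len(pl), i, dtype=int) for i, pl in enumerate(pls)]
    )
    order = np.argsort(mz, kind="stable")
    mz, intensity, sample_idx = mz[order], intensity[order], sample_idx[order]

    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for start, stop in _gap_blocks(mz, ppm_window):
        _refine_block(
            mz[start:stop],
            intensity[start:stop],
            sample_idx[start:stop],
            ppm_window,
            blocks,
        )

    n = len(pls)
    centroids: list[float] = []
    columns: list[np.ndarray] = []
    for bmz, bint, bsi in blocks:
        col = np.full(n, np.nan)
        # per sample keep the most intense contribution
        best = np.full(n, -1.0)
        best_mz = np.full(n, np.nan)
        for m, i, s in zip(bmz, bint, bsi):
            if i > best[s]:
                best[s] = i
                best_mz[s] = m
                col[s] = i
        kept = best >= 0
        centroids.append(_centroid(best_mz[kept], best[kept]))
        columns.append(col)

    if columns:
        values = np.column_stack(columns)
        order = np.argsort(centroids, kind="stable")
        values = values[:, order]
        centroids = [centroids[i] for i in order]
    else:
        values = np.empty((n, 0))
    features = pd.DataFrame(
        {"centroid_mz": centroids, "polarity": [polarity] * len(centroids)}
    )
    return FeatureMatrix(sample_ids=sample_ids, features=features, values=values)


def filter_missing(fm: FeatureMatrix, max_missing_frac: float = 0.2) -> FeatureMatrix:
    """Drop features missing in strictly more than ``max_missing_frac`` of
    all samples (QCs included); column order preserved."""
    if not (0 <= max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = fm.missing_mask.mean(axis=0)
    keep = frac <= max_missing_frac
    return FeatureMatrix(
        sample_ids=list(fm.sample_ids),
        features=fm.features.loc[keep].reset_index(drop=True),
        values=fm.values[:, keep],
    )


def _feature_distances(values: np.ndarray):
    """Pairwise feature Euclidean distances over mutually observed samples.

    Returns (D, C): squared distances and mutual-observation counts, both
    features x features.  Computed on the transposed matrix (features are
    rows)."""
    X = values.T  # features x samples
    W = (~np.isnan(X)).astype(float)
    Z = np.nan_to_num(X)
    Z2 = Z * Z
    D2 = Z2 @ W.T + W @ Z2.T - 2.0 * (Z @ Z.T)
    np.maximum(D2, 0.0, out=D2)
    C = W @ W.T
    return np.sqrt(D2), C


def knn_impute(fm: FeatureMatrix, k: int = 10) -> FeatureMatrix:
    """Feature-wise k-nearest-neighbour imputation.

    A missing cell (sample s, feature j) becomes the unweighted mean over
    the k features nearest to j (Euclidean distance across mutually
    observed samples) among features observed at s; ties broken by feature
    order.  With fewer than k eligible neighbours all of them are used;
    with none, the feature's own observed mean.  A feature with no
    observed values at all is an error (it should have been filtered).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = fm.missing_mask
    if not mask.any():
        return fm
    observed_counts = (~mask).sum(axis=0)
    if (observed_counts == 0).any():
        bad = int(np.nonzero(observed_counts == 0)[0][0])
        raise ValueError(
            f"feature {bad} has no observed values; filter before imputing"
        )
    D, C = _feature_distances(fm.values)
    values = fm.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feature_means = np.nanmean(fm.values, axis=0)
    p = fm.n_features
    for s, j in zip(*np.nonzero(mask)):
        eligible = [
            i
            for i in range(p)
            if i != j and not mask[s, i] and C[j, i] > 0
        ]
        if not eligible:
            values[s, j] = feature_means[j]
            continue
        eligible.sort(key=lambda i: (D[j, i], i))
        chosen = eligible[: min(k, len(eligible))]
        values[s, j] = float(np.mean([fm.values[s, i] for i in chosen]))
    return FeatureMatrix(
        sample_ids=list(fm.sample_ids),
        features=fm.features.copy(),
        values=values,
    )


def fuse_polarities(pos: FeatureMatrix, neg: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of both polarities (low-level fusion)."""
    if pos.sample_ids != neg.sample_ids:
        only_pos = set(pos.sample_ids) - set(neg.sample_ids)
        only_neg = set(neg.sample_ids) - set(pos.sample_ids)
        detail = []
        if only_pos:
            detail.append(f"only in positive: {sorted(only_pos)}")
        if only_neg:
            detail.append(f"only in negative: {sorted(only_neg)}")
        if not detail:
            detail.append("sample order differs")
        raise ValueError("sample sets differ: " + "; ".join(detail))
    return FeatureMatrix(
        sample_ids=list(pos.sample_ids),
        features=pd.concat([pos.features, neg.features], ignore_index=True),
        values=np.hstack([pos.values, neg.values]),
    )


def write_feature_matrix(fm: FeatureMatrix, path, header_comment: str = "") -> None:
    """Write a feature matrix CSV with a two-row header (centroid m/z,
    polarity) and a companion ``<stem>_mask.csv`` missingness mask."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "centroid_mz,"
            + ",".join(f"{v:.6f}" for v in fm.features["centroid_mz"])
            + "\n"
        )
        fh.write("polarity," + ",".join(fm.features["polarity"]) + "\n")
        for sid, row in zip(fm.sample_ids, fm.values):
            fh.write(
                sid
                + ","
                + ",".join("" if np.isnan(v) else f"{v:.10g}" for v in row)
                + "\n"
            )
    mask_path = path.with_name(path.stem + "_mask.csv")
    pd.DataFrame(
        fm.missing_mask.astype(int), index=fm.sample_ids
    ).to_csv(mask_path, header=False)


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a matrix written by :func:`write_feature_matrix`."""
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if not l.startswith("#")]
    mz = [float(v) for v in lines[0].split(",")[1:]]
    pol = lines[1].split(",")[1:]
    sample_ids, rows = [], []
    for line in lines[2:]:
        parts = line.split(",")
        sample_ids.append(parts[0])
        rows.append([float(v) if v else np.nan for v in parts[1:]])
    return FeatureMatrix(
        sample_ids=sample_ids,
        features=pd.DataFrame({"centroid_mz": mz, "polarity": pol}),
        values=np.array(rows) if rows else np.empty((0, len(mz))),
    )
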