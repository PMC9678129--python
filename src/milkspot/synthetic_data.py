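"""Synthetic dried-milk-spot DIMS datasets with known ground truth.

Emulates the statistical structure of a two-arm dairy-cow lameness study:
10 lame and 11 healthy cows, milk spotted on cards and extracted on two
days (day 8 and day 16), each extract profiled by direct infusion in both
ionisation polarities together with pooled QC samples.  The generator
produces per-sample peak lists (m/z, intensity), a sample-metadata table
and a truth table of planted class effects, so that the whole downstream
pipeline — alignment, imputation, chemometrics, ML triangulation,
stability selection — can be exercised and checked against known truth.

Generative model (all randomness from one seeded ``numpy`` Generator):

* each polarity carries its own set of true feature m/z values drawn
  uniformly over the scan range and held fixed across samples;
* log intensities are Gaussian: per-feature baseline ~ N(mu0, feature_sd),
  plus a per-cow random effect, plus the planted class shift
  (ln 2 · log2 fold change, applied to lame cows) on effect features,
  plus residual noise N(0, log_sd) — i.e. log-normal intensities;
* second-day intensities decay by a global attenuation factor in (0, 1]
  modulated per feature (each metabolite degrades at its own rate during
  storage), reproducing the overall day-16 signal reduction while
  remaining visible after TIC normalisation;
* observed m/z jitters around truth by Normal(0, ppm_jitter_sd) ppm;
* QC samples are the day's mean biological profile times a small drift
  factor and multiplicative log-normal noise, so they sit centrally in
  scores space;
* dropout is missing-not-at-random: a peak is deleted with probability
  max_rate · sigmoid(−(log I − mid) / scale), monotone non-increasing in
  intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_extraction import PeakList

__all__ = [
    "StudyDesign",
    "EffectSpec",
    "TruthTable",
    "default_effects",
    "generate_study",
    "qc_drift_profile",
    "write_study",
    "pick_robust_features",
    "map_truth_to_matrix",
]


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of the emulated study design.

    Defaults follow the study being emulated: 10 lame + 11 control cows,
    extraction days 8 and 16 with a global day-16 attenuation, 3 pooled
    QCs per day (21 cows x 2 days + 3 QCs x 2 days = 48 observations),
    ~500 features per polarity over m/z 70-1050.
    """

    n_lame: int = 10
    n_control: int = 11
    extraction_days: tuple[int, ...] = (8, 16)
    n_qc_per_day: int = 3
    n_features_per_polarity: int = 500
    mz_range: tuple[float, float] = (70.0, 1050.0)
    day_attenuation: float = 0.7
    day_effect_feature_sd: float = 1.0
    ppm_jitter_sd: float = 1.0
    base_intensity_log_mean: float = 14.0
    base_intensity_log_sd: float = 0.35
    feature_log_sd: float = 1.0
    cow_log_sd: float = 0.3
    missing_rate_fn_params: dict = field(
        default_factory=lambda: {"max_rate": 0.25, "mid": 12.2, "scale": 1.0}
    )
    qc_noise_log_sd: float = 0.03
    qc_drift_amplitude: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lame < 1 or self.n_control < 1:
            raise ValueError("need at least one cow per class")
        if self.n_qc_per_day < 0:
            raise ValueError("n_qc_per_day must be >= 0")
        lo, hi = self.mz_range
        if not (0 < lo < hi):
            raise ValueError("mz_range must satisfy 0 < low < high")
        if not (0 < self.day_attenuation <= 1):
            raise ValueError("day_attenuation must be in (0, 1]")
        for name in (
            "ppm_jitter_sd",
            "base_intensity_log_mean",
            "base_intensity_log_sd",
            "feature_log_sd",
            "cow_log_sd",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def n_cows(self) -> int:
        return self.n_lame + self.n_control

    @property
    def n_samples(self) -> int:
        """Observations per polarity (cows + QCs, all days)."""
        return len(self.extraction_days) * (self.n_cows + self.n_qc_per_day)


@dataclass(frozen=True)
class EffectSpec:
    """A planted discriminative feature.

    ``feature_index`` is global over the concatenated positive-then-negative
    feature list; ``log2_fc`` is the magnitude of the class difference on
    the log2 scale, applied to lame cows with the given direction.
    """

    feature_index: int
    direction: str  # "up" (elevated in lame) or "down"
    log2_fc: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not math.isfinite(self.log2_fc) or self.log2_fc == 0:
            raise ValueError("log2_fc must be finite and non-zero")

    @property
    def signed_log2_fc(self) -> float:
        return self.log2_fc if self.direction == "up" else -self.log2_fc


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a generated dataset."""

    effects: tuple[EffectSpec, ...]
    seed: int
    # per-effect realized mean log2(lame) - mean log2(control), day-8 cows
    realized_log2_fc: tuple[float, ...]
    feature_mz: pd.DataFrame  # columns: feature_index, polarity, true_mz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_index": [e.feature_index for e in self.effects],
                "direction": [e.direction for e in self.effects],
                "log2_fc": [e.log2_fc for e in self.effects],
                "realized_log2_fc": list(self.realized_log2_fc),
            }
        )


def default_effects(
    design: StudyDesign,
    n_effects: int = 10,
    log2_fc: float = 1.5,
    seed: int | None = None,
) -> list[EffectSpec]:
    """Plant ``n_effects`` effects at |log2 FC| = ``log2_fc`` on random
    features (alternating direction), mirroring the ~dozen discriminative
    ions of the emulated study."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    total = 2 * design.n_features_per_polarity
    idx = rng.choice(total, size=n_effects, replace=False)
    return [
        EffectSpec(int(j), "up" if i % 2 == 0 else "down", log2_fc)
        for i, j in enumerate(np.sort(idx))
    ]


def qc_drift_profile(design: StudyDesign) -> np.ndarray:
    """Deterministic per-QC intensity scaling factors, near 1.

    A linear instrument-drift ramp across the QC injection sequence with
    half-range ``qc_drift_amplitude``; amplitude 0 gives exactly 1.
    """
    n = len(design.extraction_days) * design.n_qc_per_day
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.ones(1)
    return 1.0 + design.qc_drift_amplitude * np.linspace(-1.0, 1.0, n)


def _dropout_probability(log_intensity: np.ndarray, params: dict) -> np.ndarray:
    from scipy.special import expit

    max_rate = float(params.get("max_rate", 0.25))
    mid = float(params.get("mid", 12.2))
    scale = float(params.get("scale", 1.0))
    if not (0 <= max_rate <= 1) or scale <= 0:
        raise ValueError("invalid dropout parameters")
    return max_rate * expit(-(log_intensity - mid) / scale)


def generate_study(
    design: StudyDesign,
    effects: Sequence[EffectSpec] = (),
) -> tuple[list[PeakList], pd.DataFrame, TruthTable]:
    """Generate one full study: peak lists, metadata and ground truth.

    Returns one :class:`PeakList` per sample per polarity (positive lists
    first, in metadata order), a metadata table with one row per sample
    (columns: sample_id, cow_id, class, day, role), and the
    :class:`TruthTable`.  Identical designs and effects give byte-identical
    output.
    """
    total_features = 2 * design.n_features_per_polarity
    seen = set()
    for e in effects:
        if not (0 <= e.feature_index < total_features):
            raise ValueError(
                f"effect feature index {e.feature_index} out of range "
                f"[0, {total_features})"
            )
        if e.feature_index in seen:
            raise ValueError(f"duplicate effect index {e.feature_index}")
        seen.add(e.feature_index)

    rng = np.random.default_rng(design.seed)
    lo, hi = design.mz_range
    p = design.n_features_per_polarity
    true_mz = {
        "positive": np.sort(rng.uniform(lo, hi, size=p)),
        "negative": np.sort(rng.uniform(lo, hi, size=p)),
    }

    # fixed per-feature baselines and per-cow random effects
    baseline = design.base_intensity_log_mean + design.feature_log_sd * rng.standard_normal(total_features)
    cow_effect = design.cow_log_sd * rng.standard_normal(design.n_cows)
    # feature-specific storage degradation: each metabolite decays at its
    # own rate around the global attenuation, so the day effect is not a
    # pure per-sample scaling (which TIC normalisation would cancel)
    day_gamma = np.exp(
        design.day_effect_feature_sd * rng.standard_normal(total_features)
    )

    class_shift = np.zeros(total_features)
    for e in effects:
        class_shift[e.feature_index] = math.log(2.0) * e.signed_log2_fc

    cow_ids = [f"cow{i + 1:02d}" for i in range(design.n_cows)]
    cow_class = ["lame"] * design.n_lame + ["control"] * design.n_control

    meta_rows: list[dict] = []
    log_bio: dict[str, np.ndarray] = {}  # sample_id -> log intensities
    day_samples: dict[int, list[str]] = {d: [] for d in design.extraction_days}

    for day_pos, day in enumerate(design.extraction_days):
        atten = (
            0.0
            if day_pos == 0
            else math.log(design.day_attenuation) * day_pos * day_gamma
        )
        for ci, cow in enumerate(cow_ids):
            sid = f"d{day:02d}_{cow}"
            noise = design.base_intensity_log_sd * rng.standard_normal(total_features)
            shift = class_shift if cow_class[ci] == "lame" else 0.0
            log_bio[sid] = baseline + cow_effect[ci] + shift + atten + noise
            day_samples[day].append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cow_id": cow,
                    "class": cow_class[ci],
                    "day": day,
                    "role": "study",
                }
            )

    # realized effect sizes on day-8 (first-day) cow samples
    first_day = design.extraction_days[0]
    lame_ids = [
        f"d{first_day:02d}_{c}"
        for c, cl in zip(cow_ids, cow_class)
        if cl == "lame"
    ]
    ctrl_ids = [
        f"d{first_day:02d}_{c}"
        for c, cl in zip(cow_ids, cow_class)
        if cl == "control"
    ]
    realized = []
    for e in effects:
        j = e.feature_index
        m_lame = np.mean([log_bio[s][j] for s in lame_ids]) / math.log(2.0)
        m_ctrl = np.mean([log_bio[s][j] for s in ctrl_ids]) / math.log(2.0)
        realized.append(float(m_lame - m_ctrl))

    # QC samples: mean of the day's biological profiles (linear scale),
    # drift factor, multiplicative noise
    drift = qc_drift_profile(design)
    qc_log: dict[str, np.ndarray] = {}
    k = 0
    for day in design.extraction_days:
        profiles = np.exp(np.stack([log_bio[s] for s in day_samples[day]]))
        pooled = np.log(profiles.mean(axis=0))
        for q in range(design.n_qc_per_day):
            sid = f"d{day:02d}_qc{q + 1}"
            noise = design.qc_noise_log_sd * rng.standard_normal(total_features)
            qc_log[sid] = pooled + math.log(drift[k]) + noise
            k += 1
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cow_id": "",
                    "class": "",
                    "day": day,
                    "role": "qc",
                }
            )

    metadata = pd.DataFrame(meta_rows)
    metadata = metadata.sort_values(
        ["day", "role", "sample_id"], kind="stable"
    ).reset_index(drop=True)

    all_log = {**log_bio, **qc_log}
    peak_lists: list[PeakList] = []
    for polarity, offset in (("positive", 0), ("negative", p)):
        mz_true = true_mz[polarity]
        for sid in metadata["sample_id"]:
            logi = all_log[sid][offset : offset + p]
            intensity = np.exp(logi)
            jitter = rng.standard_normal(p) * design.ppm_jitter_sd * 1e-6
            mz_obs = mz_true * (1.0 + jitter)
            p_drop = _dropout_probability(logi, design.missing_rate_fn_params)
            keep = rng.uniform(size=p) >= p_drop
            order = np.argsort(mz_obs[keep], kind="stable")
            day = int(metadata.loc[metadata["sample_id"] == sid, "day"].iloc[0])
            peak_lists.append(
                PeakList(
                    sample_id=sid,
                    polarity=polarity,
                    mz=mz_obs[keep][order],
                    intensity=intensity[keep][order],
                    day=day,
                )
            )

    feature_mz = pd.DataFrame(
        {
            "feature_index": np.arange(total_features),
            "polarity": ["positive"] * p + ["negative"] * p,
            "true_mz": np.concatenate([true_mz["positive"], true_mz["negative"]]),
        }
    )
    truth = TruthTable(
        effects=tuple(effects),
        seed=design.seed,
        realized_log2_fc=tuple(realized),
        feature_mz=feature_mz,
    )
    return peak_lists, metadata, truth


def write_study(
    out_dir,
    peak_lists: Sequence[PeakList],
    metadata: pd.DataFrame,
    truth: TruthTable,
) -> None:
    """Persist a generated study as plain text: one 2-column (m/z,
    intensity) CSV per sample per polarity, plus metadata and truth CSVs."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    for pl in peak_lists:
        path = out / "peaks" / f"{pl.sample_id}_{pl.polarity}.csv"
        pd.DataFrame({"mz": pl.mz, "intensity": pl.intensity}).to_csv(
            path, index=False, float_format="%.10g"
        )
    metadata.to_csv(out / "metadata.csv", index=False)
    truth.to_frame().to_csv(out / "truth.csv", index=False, float_format="%.10g")
    truth.feature_mz.to_csv(
        out / "feature_mz.csv", index=False, float_format="%.10g"
    )


def pick_robust_features(
    design: StudyDesign,
    n: int,
    log_margin: float = 1.2,
    min_intensity: float = 100_000.0,
) -> np.ndarray:
    """Indices of features that will survive peak picking even when
    down-shifted.

    Generates the design once without effects and returns the first ``n``
    features (alternating polarity halves) whose lowest sample
    log-intensity clears ``log(min_intensity)`` by ``log_margin`` — room
    for a planted down-shift without the feature dropping below the
    picking threshold.  Useful when planting effects whose recovery is to
    be scored against ground truth.
    """
    peak_lists, metadata, _ = generate_study(design, [])
    p = design.n_features_per_polarity
    lo = math.log(min_intensity) + log_margin
    ok = np.ones(2 * p, dtype=bool)
    # reconstruct per-feature minima from the jitter-free association of
    # peaks to true m/z (features are per-polarity sorted unique m/z)
    mins = np.full(2 * p, np.inf)
    counts = np.zeros(2 * p, dtype=int)
    truemz = {}
    rng = np.random.default_rng(design.seed)
    lo_mz, hi_mz = design.mz_range
    truemz["positive"] = np.sort(rng.uniform(lo_mz, hi_mz, size=p))
    truemz["negative"] = np.sort(rng.uniform(lo_mz, hi_mz, size=p))
    for pl in peak_lists:
        offset = 0 if pl.polarity == "positive" else p
        ref = truemz[pl.polarity]
        idx = np.clip(np.searchsorted(ref, pl.mz), 0, p - 1)
        left = np.clip(idx - 1, 0, p - 1)
        idx = np.where(
            np.abs(ref[left] - pl.mz) < np.abs(ref[idx] - pl.mz), left, idx
        )
        for j, inten in zip(idx, pl.intensity):
            g = offset + j
            counts[g] += 1
            if math.log(inten) < mins[g]:
                mins[g] = math.log(inten)
    n_samples = design.n_samples
    ok = (counts == n_samples) & (mins >= lo)
    pools = [list(np.nonzero(ok[:p])[0]), list(np.nonzero(ok[p:])[0] + p)]
    chosen: list[int] = []
    for i in range(n):
        pool = [j for j in pools[i % 2] if j not in chosen] or [
            j for j in np.nonzero(ok)[0] if j not in chosen
        ]
        if not pool:
            raise ValueError("not enough robust features for this design")
        # spread picks across the m/z range
        chosen.append(int(pool[(i // 2 * len(pool)) // max(n, 1) % len(pool)]))
    return np.array(sorted(chosen))


def map_truth_to_matrix(truth: TruthTable, fm, ppm_tol: float = 5.0) -> np.ndarray:
    """Map generator feature indices to aligned-matrix columns.

    For every row of ``truth.feature_mz`` find the matrix column of the
    same polarity whose centroid lies within ``ppm_tol`` ppm of the true
    m/z (nearest wins); -1 where the feature did not survive extraction.
    """
    centroids = fm.features["centroid_mz"].to_numpy()
    polarities = fm.features["polarity"].to_numpy()
    out = np.full(len(truth.feature_mz), -1, dtype=int)
    for i, row in enumerate(truth.feature_mz.itertuples(index=False)):
        same = np.nonzero(polarities == row.polarity)[0]
        if same.size == 0:
            continue
        ppm = np.abs(centroids[same] - row.true_mz) / row.true_mz * 1e6
        j = int(np.argmin(ppm))
        if ppm[j] <= ppm_tol:
            out[i] = same[j]
    return out
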