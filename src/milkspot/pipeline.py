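"""End-to-end pipeline: simulate/ingest -> extract -> chemometrics -> ML
triangulation -> stability selection -> annotation -> candidate report.

Every stage's numeric settings live in :class:`PipelineConfig` (loadable
from YAML); defaults follow the analysis being reproduced: intensity
threshold 100 000, 5 ppm alignment window, >20% missingness filter,
knn k=10, OPLS-DA with 1 predictive + 1 orthogonal component, VIP > 1,
p < 0.05, q < 0.05, top-10 ML importance lists, stability selection with
500 bootstraps / 20 permutations / 50 permutation bootstraps, 5 ppm
annotation tolerance.  A run is fully determined by (config, seed): all
randomness flows from the global seed, and output tables are written
with a fixed float format plus the config hash in a header comment, so
identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import chemometrics as chem
from . import feature_extraction as fx
from . import ml_triangulation as ml
from . import stability_selection as stab
from . import synthetic_data as synth

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "summarize_selection"]

log = logging.getLogger("milkspot")


@dataclass
class PipelineConfig:
    """All tunable settings of one pipeline run."""

    # inputs; with simulate=True the study is generated instead
    simulate: bool = True
    peaks_dir: str | None = None
    metadata_path: str | None = None
    compounds_path: str | None = None
    out_dir: str = "milkspot_out"

    # synthetic study (only with simulate=True)
    design: dict = field(default_factory=dict)  # StudyDesign overrides
    n_effects: int = 10
    effect_log2_fc: float = 1.5

    # feature extraction
    intensity_threshold: float = 100_000.0
    ppm_window: float = 5.0
    max_missing_frac: float = 0.2
    knn_k: int = 10

    # chemometrics
    n_pca_components: int = 6
    n_orthogonal: int = 1
    n_perm_opls: int = 100
    vip_cut: float = 1.0
    p_cut: float = 0.05
    q_cut: float = 0.05

    # machine-learning triangulation
    top_k: int = 10
    ml_n_repeats: int = 20
    rf_trees: int = 500
    run_rfe: bool = True

    # stability selection
    stability_n_boot: int = 500
    stability_n_perm: int = 20
    stability_n_perm_boot: int = 50
    bootstrap_p_cut: float = 0.05

    # annotation
    tol_ppm: float = 5.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pca_components", "n_perm_opls", "top_k",
                     "ml_n_repeats", "rf_trees", "stability_n_boot",
                     "stability_n_perm", "stability_n_perm_boot", "knn_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("vip_cut", "p_cut", "q_cut", "bootstrap_p_cut"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.max_missing_frac <= 1):
            raise ValueError("max_missing_frac must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific settings (the output location does not
        affect results and is excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    config: PipelineConfig
    config_hash: str
    metadata: pd.DataFrame
    feature_matrix: fx.FeatureMatrix
    truth: synth.TruthTable | None
    pca_scores: pd.DataFrame
    pca_explained: np.ndarray
    opls: chem.OplsModel
    q2: float
    permutation: chem.PermutationResult
    univariate: chem.UnivariateResult
    discriminative: np.ndarray
    rfe_curves: dict[str, ml.RfeCurve]
    accuracies: dict[str, float]
    topk: dict[str, np.ndarray]
    triangulation: pd.DataFrame
    stability: dict[str, stab.StabilityResult]
    annotation_hits: pd.DataFrame
    candidates: pd.DataFrame


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index, float_format="%.10g")


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        design_kwargs = dict(config.design)
        design_kwargs.setdefault("seed", config.seed)
        design = synth.StudyDesign(**design_kwargs)
        effects = synth.default_effects(
            design, n_effects=config.n_effects,
            log2_fc=config.effect_log2_fc, seed=design.seed + 1,
        )
        peak_lists, metadata, truth = synth.generate_study(design, effects)
        return peak_lists, metadata, truth
    if config.metadata_path is None or config.peaks_dir is None:
        raise FileNotFoundError(
            "simulate is off and peaks_dir/metadata_path are not set"
        )
    meta_path = Path(config.metadata_path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    peaks_dir = Path(config.peaks_dir)
    if not peaks_dir.exists():
        raise FileNotFoundError(f"peaks directory not found: {peaks_dir}")
    metadata = pd.read_csv(meta_path, keep_default_na=False)
    peak_lists = []
    for row in metadata.itertuples(index=False):
        for polarity in fx.POLARITIES:
            path = peaks_dir / f"{row.sample_id}_{polarity}.csv"
            if not path.exists():
                raise FileNotFoundError(f"peak list not found: {path}")
            peak_lists.append(
                fx.load_peak_list(path, row.sample_id, polarity, day=int(row.day))
            )
    return peak_lists, metadata, None


def _stage_extract(config: PipelineConfig, peak_lists, metadata) -> fx.FeatureMatrix:
    sample_order = list(metadata["sample_id"])
    per_polarity = {}
    for polarity in fx.POLARITIES:
        pls = [pl for pl in peak_lists if pl.polarity == polarity]
        pls = [fx.threshold_peaks(pl, config.intensity_threshold) for pl in pls]
        by_id = {pl.sample_id: pl for pl in pls}
        pls = [by_id[s] for s in sample_order]
        fm = fx.align_features(pls, ppm_window=config.ppm_window)
        fm = fx.filter_missing(fm, config.max_missing_frac)
        fm = fx.knn_impute(fm, k=config.knn_k)
        per_polarity[polarity] = fm
    return fx.fuse_polarities(per_polarity["positive"], per_polarity["negative"])


def _first_day_cows(metadata: pd.DataFrame):
    first_day = int(metadata["day"].min())
    sel = (metadata["day"] == first_day) & (metadata["role"] == "study")
    sub = metadata.loc[sel]
    y = (sub["class"] == "lame").to_numpy().astype(int)
    return list(sub["sample_id"]), y


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow; every stage's tables are persisted under
    ``config.out_dir``.  Identical config + seed gives identical output."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    def _stage(name):
        log.info("stage %-12s t=%.1fs", name, time.time() - t0)

    try:
        _stage("inputs")
        peak_lists, metadata, truth = _load_inputs(config)
        if config.simulate:
            synth.write_study(out / "simulated", peak_lists, metadata, truth)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    try:
        _stage("extract")
        fm = _stage_extract(config, peak_lists, metadata)
        fx.write_feature_matrix(fm, out / "feature_matrix.csv",
                                header_comment=f"config_hash={chash}")
    except Exception as exc:
        raise RuntimeError(f"stage 'extract' failed: {exc}") from exc

    try:
        _stage("chemometrics")
        # PCA over all observations (QCs included)
        X_all = chem.preprocess(fm)
        scores, loadings, evr = chem.pca(X_all, config.n_pca_components)
        pca_scores = pd.DataFrame(
            scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
        )
        pca_scores.insert(0, "sample_id", fm.sample_ids)
        pca_scores = pca_scores.merge(metadata, on="sample_id")
        _write_csv(pca_scores, out / "pca_scores.csv", chash)

        # OPLS-DA on first-day cow samples only
        cow_ids, y = _first_day_cows(metadata)
        fm_cows = fm.subset_samples(cow_ids)
        X = chem.preprocess(fm_cows)
        opls = chem.fit_opls_da(X, y, n_orthogonal=config.n_orthogonal)
        # Q2/permutations on TIC+log data with fold-internal Pareto refit
        X_unscaled = chem.preprocess(
            fm_cows, chem.PreprocessSpec(pareto_scale=False)
        )
        q2 = chem.loocv_q2(X_unscaled, y, config.n_orthogonal, scale="pareto")
        perm = chem.permutation_test(
            X_unscaled, y, config.n_orthogonal,
            n_perm=config.n_perm_opls, seed=config.seed + 11, scale="pareto",
        )
        uni = chem.t_test_fdr(X, y)
        disc = chem.select_discriminative(
            opls, uni, config.vip_cut, config.p_cut, config.q_cut
        )
        feat_stats = fm.features.copy()
        feat_stats["vip"] = opls.vip
        feat_stats["splot_cov"] = opls.splot_cov
        feat_stats["splot_corr"] = opls.splot_corr
        feat_stats["t"] = uni.t_stat
        feat_stats["p"] = uni.p_value
        feat_stats["q"] = uni.q_value
        feat_stats["discriminative"] = False
        feat_stats.loc[disc, "discriminative"] = True
        _write_csv(feat_stats, out / "feature_stats.csv", chash)
        opls_scores = pd.DataFrame(
            {"sample_id": cow_ids, "y": y, "t_pred": opls.t}
        )
        for a in range(opls.n_orthogonal):
            opls_scores[f"t_orth{a+1}"] = opls.t_o[:, a]
        _write_csv(opls_scores, out / "opls_scores.csv", chash)
        model_summary = pd.DataFrame(
            [
                {
                    "R2X": opls.R2X,
                    "R2Y": opls.R2Y,
                    "Q2": q2,
                    "perm_p_R2Y": perm.p_r2y,
                    "perm_p_Q2": perm.p_q2,
                    "n_discriminative": int(disc.size),
                }
            ]
        )
        _write_csv(model_summary, out / "model_summary.csv", chash)
    except Exception as exc:
        raise RuntimeError(f"stage 'chemometrics' failed: {exc}") from exc

    try:
        _stage("ml")
        X_raw = fm_cows.values  # TIC/standardisation handled fold-wise
        rfe_curves: dict[str, ml.RfeCurve] = {}
        accuracies: dict[str, float] = {}
        topk: dict[str, np.ndarray] = {}
        for kind in ml.MODEL_KINDS:
            hp = {"n_estimators": config.rf_trees} if kind == "random_forest" else {}
            spec = ml.MlSpec(kind, hyperparameters=hp,
                             n_repeats=config.ml_n_repeats,
                             seed=config.seed + 21)
            if config.run_rfe:
                curve = ml.rfe(X_raw, y, spec)
                rfe_curves[kind] = curve
                accuracies[kind] = ml.loocv_accuracy(
                    X_raw, y, spec, feature_subset=curve.best_subset
                )
                _write_csv(curve.to_frame(), out / f"rfe_{kind}.csv", chash)
            else:
                accuracies[kind] = ml.loocv_accuracy(X_raw, y, spec)
            topk[kind] = ml.importance_topk(X_raw, y, spec, k=config.top_k)
            _write_csv(
                pd.DataFrame(
                    {
                        "rank": np.arange(1, topk[kind].size + 1),
                        "feature": topk[kind],
                        "centroid_mz": fm.features["centroid_mz"].to_numpy()[topk[kind]],
                        "polarity": fm.features["polarity"].to_numpy()[topk[kind]],
                    }
                ),
                out / f"topk_{kind}.csv",
                chash,
            )
        tri = ml.triangulate(disc, topk)
        _write_csv(tri, out / "triangulation.csv", chash)
        ml_summary = pd.DataFrame(
            [
                {
                    "model": kind,
                    "best_size": (rfe_curves[kind].best_size if kind in rfe_curves else np.nan),
                    "loocv_accuracy": accuracies[kind],
                }
                for kind in ml.MODEL_KINDS
            ]
        )
        _write_csv(ml_summary, out / "ml_summary.csv", chash)
    except Exception as exc:
        raise RuntimeError(f"stage 'ml' failed: {exc}") from exc

    try:
        _stage("stability")
        X_std = ml.standardize(X_raw)
        names = [
            f"{row.polarity[:3]}_{row.centroid_mz:.5f}"
            for row in fm.features.itertuples(index=False)
        ]
        stability: dict[str, stab.StabilityResult] = {}
        for penalty in ("elastic_net", "lasso", "mcp"):
            spec = stab.PenalisedSpec(penalty=penalty)
            stability[penalty] = stab.run_stability(
                X_std, y, spec,
                n_boot=config.stability_n_boot,
                n_perm=config.stability_n_perm,
                n_perm_boot=config.stability_n_perm_boot,
                seed=config.seed + 31,
                feature_names=names,
            )
            _write_csv(
                stability[penalty].to_frame(), out / f"stability_{penalty}.csv", chash
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'stability' failed: {exc}") from exc

    try:
        _stage("annotation")
        if config.compounds_path:
            compounds = ann.load_compound_table(config.compounds_path)
        else:
            compounds = ann.default_compound_table()
        stable_union = set()
        for res in stability.values():
            stable_union.update(stab.select_stable(res, config.bootstrap_p_cut))
        interest = sorted(set(disc.tolist()) | stable_union)
        hits = []
        for j in interest:
            mz = float(fm.features["centroid_mz"].iloc[j])
            pol = fm.features["polarity"].iloc[j]
            adducts = "default_pos" if pol == "positive" else "default_neg"
            for h in ann.annotate(mz, compounds, adducts, tol_ppm=config.tol_ppm):
                rec = dataclasses.asdict(h)
                rec["feature"] = j
                hits.append(rec)
        hits_df = pd.DataFrame(
            hits,
            columns=["feature", "measured_mz", "compound", "formula",
                     "monoisotopic_mass", "adduct", "theoretical_mz", "ppm_error"],
        )
        _write_csv(hits_df, out / "annotation.csv", chash)
    except Exception as exc:
        raise RuntimeError(f"stage 'annotation' failed: {exc}") from exc

    report = RunReport(
        config=config,
        config_hash=chash,
        metadata=metadata,
        feature_matrix=fm,
        truth=truth,
        pca_scores=pca_scores,
        pca_explained=evr,
        opls=opls,
        q2=q2,
        permutation=perm,
        univariate=uni,
        discriminative=disc,
        rfe_curves=rfe_curves,
        accuracies=accuracies,
        topk=topk,
        triangulation=tri,
        stability=stability,
        annotation_hits=hits_df,
        candidates=pd.DataFrame(),
    )
    report.candidates = summarize_selection(report)
    _write_csv(report.candidates, out / "candidates.csv", chash)
    _stage("done")
    return report


def summarize_selection(report: RunReport) -> pd.DataFrame:
    """Final candidate table: stability-selected features (default elastic
    net) ranked by (stability score, ML consensus count, VIP).

    The strongest-candidate flag marks the highest-stability feature that
    also ranks in the top 2 of every ML model's importance list; ties on
    stability break by consensus count, then VIP.  Empty when no feature
    passes all gates.
    """
    res = report.stability.get("elastic_net")
    if res is None or res.threshold is None:
        raise ValueError("stability stage incomplete")
    stable = stab.select_stable(res, report.config.bootstrap_p_cut)
    if stable.size == 0:
        df = pd.DataFrame(
            columns=["feature", "centroid_mz", "polarity", "stability_score",
                     "bootstrap_p", "consensus_count", "vip",
                     "in_conventional_set", "strongest_candidate"]
        )
        df.attrs["note"] = "no feature passed the stability and p-value gates"
        return df
    feats = report.feature_matrix.features
    tri = report.triangulation.set_index("feature") if len(report.triangulation) else None
    rows = []
    for j in stable:
        consensus = sum(int(j in set(map(int, tk))) for tk in report.topk.values())
        top2_all = all(
            int(j) in set(map(int, tk[:2])) for tk in report.topk.values()
        )
        rows.append(
            {
                "feature": int(j),
                "centroid_mz": float(feats["centroid_mz"].iloc[j]),
                "polarity": feats["polarity"].iloc[j],
                "stability_score": float(res.stability_score[j]),
                "bootstrap_p": float(res.bootstrap_p[j]),
                "consensus_count": consensus,
                "vip": float(report.opls.vip[j]),
                "in_conventional_set": bool(
                    tri is not None and int(j) in tri.index
                ),
                "_top2_all": top2_all,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["stability_score", "consensus_count", "vip"],
        ascending=False,
        kind="stable",
    ).reset_index(drop=True)
    df["strongest_candidate"] = False
    eligible = df.index[df["_top2_all"]]
    if len(eligible):
        df.loc[eligible[0], "strongest_candidate"] = True
    return df.drop(columns="_top2_all")
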