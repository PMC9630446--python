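"""End-to-end orchestration: stages, file layout, and the reproducible report.

Every stage reads its inputs from, and writes its outputs to, a run directory,
so any stage can be re-run in isolation and every number in the final report
traces to a serialized intermediate file:

    <outdir>/inputs/          variants.tsv alignment.fasta members.yaml [truth.json]
    <outdir>/validation.tsv   wild-type / range cross-checks
    <outdir>/cluster_scores.tsv
    <outdir>/labels.tsv       + neutral_band.json
    <outdir>/features.tsv
    <outdir>/spearman.tsv  stratification.json  pcr.json  tree.json  cv.json
    <outdir>/predictors.tsv  predictor_summary.json
    <outdir>/report.json  manifest.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as act
from . import cluster_scoring as cs
from . import features as feat
from . import stats_modeling as sm_
from . import synthetic as syn
from . import variant_io as vio

log = logging.getLogger("vusannot")

STAGES = ("simulate", "score", "classify", "features", "model", "evaluate", "report")

#: covariates entering the full regression tree (conservation, clustering,
#: stability and substitution-score parameters)
TREE_COVARIATES = ("fi_score", "pclust_score", "datoms", "blosum62", "ddg")
#: the significant phylogenetic + clustering + physico-chemical parameters on
#: which the reduced principal-components regression is run
PCR_COVARIATES = ("fi_score", "vc_score", "vs_score", "prox_ratio_each",
                  "prox_ratio_all", "pclust_score", "datoms", "blosum62", "ddg")
#: the two-parameter model validated by cross-validation
CV_COVARIATES = ("fi_score", "pclust_score")


@dataclass
class RunConfig:
    outdir: str = "vusannot_run"
    simulate: bool = True
    sim: syn.SimConfig | None = None
    variants_path: str | None = None
    alignment_path: str | None = None
    alignment_format: str = "fasta"
    members_path: str | None = None
    reference_id: str | None = None      # default: first alignment member
    window: int = 7
    lof_threshold: float = 0.5
    gof_sigma: float = 2.0
    primary_channel: str = "me0"
    pclust_threshold: float = 1.5
    alpha: float = 0.05
    min_node: int = 7
    n_perm: int = 9999
    var_threshold: float = 0.75
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = sm_.DEFAULT_SEED

    def __post_init__(self) -> None:
        if not self.simulate and not (self.variants_path and self.alignment_path
                                      and self.members_path):
            raise ValueError("provide input paths or enable simulation")
        if self.simulate and self.sim is None:
            self.sim = syn.SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("sim", None)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if sim is not None:
            cfg.sim = syn.SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def _inputs_dir(cfg: RunConfig) -> Path:
    return Path(cfg.outdir) / "inputs"


def _load_inputs(cfg: RunConfig) -> tuple[vio.VariantTable, vio.ParalogAlignment,
                                          dict[str, int]]:
    if cfg.simulate:
        d = _inputs_dir(cfg)
        vpath, apath, mpath, fmt = (d / "variants.tsv", d / "alignment.fasta",
                                    d / "members.yaml", "fasta")
    else:
        vpath, apath, mpath, fmt = (Path(cfg.variants_path),
                                    Path(cfg.alignment_path),
                                    Path(cfg.members_path), cfg.alignment_format)
    table = vio.read_variant_table(vpath)
    clades, offsets = vio.load_member_config(mpath)
    aln = vio.read_alignment(apath, fmt, clades=clades)
    return table, aln, offsets


def _cmap(cfg: RunConfig, aln: vio.ParalogAlignment,
          offsets: dict[str, int]) -> vio.CoordinateMap:
    ref = cfg.reference_id or aln.members[0]
    return vio.build_coordinate_map(aln, ref, offsets)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _key_cols(table: vio.VariantTable) -> pd.DataFrame:
    return table.df[["protein_id", "position", "wt_aa", "mut_aa"]]


def stage_simulate(cfg: RunConfig) -> None:
    bundle = syn.generate(cfg.sim)
    bundle.write(_inputs_dir(cfg))
    log.info("simulate: wrote %d variants for %d members",
             len(bundle.table), len(bundle.alignment.members))


def stage_score(cfg: RunConfig) -> None:
    table, aln, offsets = _load_inputs(cfg)
    out = Path(cfg.outdir)
    report = vio.validate_variants(table, aln, offsets)
    report.to_csv(out / "validation.tsv", sep="\t", index=False)
    n_flagged = int((report["flag"] != "ok").sum())
    if n_flagged:
        log.warning("score: %d variants flagged by validation", n_flagged)
    scores = cs.compute_cluster_scores(table, _cmap(cfg, aln, offsets), cfg.window)
    pd.concat([_key_cols(table), scores], axis=1).to_csv(
        out / "cluster_scores.tsv", sep="\t", index=False)
    log.info("score: %d variants, window +/-%d", len(table), cfg.window)


def stage_classify(cfg: RunConfig) -> None:
    table, _, _ = _load_inputs(cfg)
    table.require_columns(["activity_me0"], "classify")
    out = Path(cfg.outdir)
    labels, band = act.classify_table(table.df, cfg.lof_threshold, cfg.gof_sigma,
                                      cfg.primary_channel)
    pd.concat([_key_cols(table),
               table.df[[c for c in ("activity_me0", "activity_me1", "activity_sd")
                         if c in table.df.columns]],
               labels], axis=1).to_csv(out / "labels.tsv", sep="\t", index=False)
    _write_json(out / "neutral_band.json",
                {"mean": band.mean, "sd": band.sd, "n": band.n,
                 "gof_sigma": cfg.gof_sigma, "lof_threshold": cfg.lof_threshold,
                 "primary_channel": cfg.primary_channel})
    log.info("classify: %s", labels["label"].value_counts().to_dict())


def stage_features(cfg: RunConfig) -> None:
    table, aln, offsets = _load_inputs(cfg)
    out = Path(cfg.outdir)
    scores = pd.read_csv(out / "cluster_scores.tsv", sep="\t")
    scores.index = table.df.index
    cmap = _cmap(cfg, aln, offsets)
    conservation = feat.family_vs_clade(aln, table, cmap) if aln.clades else None
    ftab = feat.assemble_features(table, scores, conservation)
    ftab.to_csv(out / "features.tsv", sep="\t", index=False)
    n_incomplete = int((ftab["n_missing"] > 0).sum())
    if n_incomplete:
        log.warning("features: %d rows missing ingested covariates", n_incomplete)


def _modeling_frame(cfg: RunConfig) -> tuple[pd.DataFrame, np.ndarray]:
    out = Path(cfg.outdir)
    ftab = pd.read_csv(out / "features.tsv", sep="\t")
    labels = pd.read_csv(out / "labels.tsv", sep="\t")
    activity_col = f"activity_{cfg.primary_channel}"
    return ftab, labels[activity_col].to_numpy(dtype=float)


def stage_model(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    ftab, y = _modeling_frame(cfg)

    screen = sm_.spearman_screen(ftab[feat.MODELING_COVARIATES], y)
    screen.to_csv(out / "spearman.tsv", sep="\t", index=False)

    strat = cs.stratify_by_pclust(ftab["pclust_score"], y, cfg.pclust_threshold)
    strat_out = {"threshold": strat.threshold,
                 "n_low": int(len(strat.low_activities)),
                 "n_high": int(len(strat.high_activities)),
                 "mean_low": strat.mean_low, "mean_high": strat.mean_high,
                 "mean_difference": strat.mean_difference}
    if len(strat.low_activities) >= 2 and len(strat.high_activities) >= 2:
        tt = sm_.welch_t_test(strat.low_activities, strat.high_activities)
        strat_out["welch"] = {"t": tt.t, "df": tt.df, "p": tt.p}
    _write_json(out / "stratification.json", strat_out)

    complete = ftab[list(feat.MODELING_COVARIATES)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.warning("model: %d rows dropped from fits (missing covariates)",
                    n_dropped)
    # contribution assessment over all 14 parameters (the summed cluster
    # score is exactly collinear with its parts, hence the reduced rank)
    Xall = ftab.loc[complete, list(feat.MODELING_COVARIATES)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pcr_full = sm_.pc_regression(Xall, y[complete.to_numpy()],
                                     cfg.var_threshold)
    _write_json(out / "pcr_full.json",
                pcr_full.to_dict() | {"n_dropped": n_dropped})
    # the reported model: PCR restricted to the significant parameters (the
    # summed cluster score stays in, so the rank deficiency is expected here too)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pcr = sm_.pc_regression(ftab.loc[complete, list(PCR_COVARIATES)],
                                y[complete.to_numpy()], cfg.var_threshold)
    _write_json(out / "pcr.json", pcr.to_dict() | {"n_dropped": n_dropped})

    Xtree = ftab.loc[complete, list(TREE_COVARIATES)]
    ytree = y[complete.to_numpy()]
    tree = sm_.fit_tree(Xtree, ytree, cfg.alpha, cfg.min_node, cfg.n_perm, cfg.seed)
    train_pred = tree.predict(Xtree)
    tree_adj_r2 = sm_.actual_vs_predicted_r2(ytree, train_pred)
    (out / "tree.json").write_text(tree.to_json())
    _write_json(out / "tree_fit.json",
                {"adj_r2": tree_adj_r2,
                 "rmse": float(np.sqrt(np.mean((ytree - train_pred) ** 2))),
                 "split_covariates": tree.split_covariates(), "n": len(ytree)})

    cv = sm_.crossvalidate(ftab.loc[complete, list(CV_COVARIATES)], ytree,
                           k=cfg.cv_folds, repeats=cfg.cv_repeats, seed=cfg.seed,
                           alpha=cfg.alpha, min_node=cfg.min_node,
                           n_perm=cfg.n_perm, lof_activity=cfg.lof_threshold)
    _write_json(out / "cv.json", cv.to_dict() | {"covariates": list(CV_COVARIATES)})
    log.info("model: tree adj R2 %.3f, CV accuracy %.3f", tree_adj_r2, cv.accuracy)


def stage_evaluate(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    table, _, _ = _load_inputs(cfg)
    labels = pd.read_csv(out / "labels.tsv", sep="\t")
    ftab = pd.read_csv(out / "features.tsv", sep="\t")
    y = labels[f"activity_{cfg.primary_channel}"].to_numpy(dtype=float)
    is_lof = (labels["label"] == act.LOF).to_numpy()

    quad_frame = _key_cols(table).copy()
    summary: dict = {"programs": {}}
    for prog in sm_.PREDICTOR_RULES:
        if prog not in table.df.columns:
            summary["programs"][prog] = {"missing_column": True}
            continue
        ev = sm_.evaluate_predictor(table.df[prog], is_lof, prog)
        quad_frame[f"{prog}_quadrant"] = ev.quadrant.to_numpy()
        d = ev.to_dict()
        # single-score regression analog of the actual-vs-predicted panels
        scores = pd.to_numeric(table.df[prog], errors="coerce")
        okv = scores.notna().to_numpy()
        pred = _ols_predict(scores[okv].to_numpy(), y[okv])
        d["adj_r2"] = sm_.actual_vs_predicted_r2(y[okv], pred)
        summary["programs"][prog] = d
    quad_frame.to_csv(out / "predictors.tsv", sep="\t", index=False)

    # conservation contrast behind the false-positive excess: family vs clade
    # scores of PolyPhen-2 FP and TP positions, two-factor ANOVA
    if "polyphen2_quadrant" in quad_frame.columns and "family_cons" in ftab.columns:
        sel = quad_frame["polyphen2_quadrant"].isin(["FP", "TP"]).to_numpy()
        if sel.sum() >= 8:
            vals = np.concatenate([ftab.loc[sel, "family_cons"],
                                   ftab.loc[sel, "clade_cons"]])
            scope = ["family"] * int(sel.sum()) + ["clade"] * int(sel.sum())
            status = list(quad_frame.loc[sel, "polyphen2_quadrant"]) * 2
            try:
                summary["family_vs_clade_anova"] = {
                    k: {"F": v[0], "p": v[1]}
                    for k, v in sm_.two_way_anova(vals, scope, status).items()}
            except ValueError as exc:
                summary["family_vs_clade_anova"] = {"skipped": str(exc)}
    _write_json(out / "predictor_summary.json", summary)
    log.info("evaluate: %d programs assessed", len(summary["programs"]))


def _ols_predict(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ beta


def stage_report(cfg: RunConfig) -> dict:
    """Compile the run report strictly from serialized stage outputs."""
    out = Path(cfg.outdir)
    labels = pd.read_csv(out / "labels.tsv", sep="\t")
    counts = labels["label"].value_counts().to_dict()
    n = int(len(labels))
    report = {
        "n_variants": n,
        "label_counts": counts,
        "label_fractions_pct": {k: 100.0 * v / n for k, v in counts.items()},
        "neutral_band": json.loads((out / "neutral_band.json").read_text()),
        "stratification": json.loads((out / "stratification.json").read_text()),
        "pcr": {k: v for k, v in
                json.loads((out / "pcr.json").read_text()).items()
                if k not in ("loadings", "coefficients")},
        "pcr_full": {k: v for k, v in
                     json.loads((out / "pcr_full.json").read_text()).items()
                     if k not in ("loadings", "coefficients")},
        "tree": json.loads((out / "tree_fit.json").read_text()),
        "cv": json.loads((out / "cv.json").read_text()),
        "predictors": json.loads((out / "predictor_summary.json").read_text()),
        "spearman": pd.read_csv(out / "spearman.tsv", sep="\t")
                      .to_dict(orient="records"),
    }
    _write_json(out / "report.json", report)
    artifacts = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
    manifest = {"config": cfg.to_dict(),
                "files": {str(p.relative_to(out)): _sha256(p) for p in artifacts}}
    _write_json(out / "manifest.json", manifest)
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the requested stages (default: all applicable) in canonical order."""
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    todo = list(stages) if stages else [s for s in STAGES
                                        if s != "simulate" or cfg.simulate]
    funcs = {"simulate": stage_simulate, "score": stage_score,
             "classify": stage_classify, "features": stage_features,
             "model": stage_model, "evaluate": stage_evaluate,
             "report": stage_report}
    report: dict = {}
    for stage in STAGES:
        if stage not in todo:
            continue
        log.info("running stage %s", stage)
        try:
            result = funcs[stage](cfg)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        if stage == "report":
            report = result
    return report
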