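"""End-to-end pipeline: rank -> discretize -> cox/apc -> build-ahp -> score -> evaluate.

Each stage persists its artifact (ranking table, bin schemes, Cox table,
matrices with consistency reports, scorecard, metric reports) plus a
manifest carrying the config hash, seed and per-stage row counts — enough
to reproduce the run.  All randomness flows through the single seed in the
config; a rerun with an identical config produces identical metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import __version__
from .ahp import consistency_report
from .apc import fit_apc, period_adjust
from .cohort import GeneratorParams, generate_cohort, apc_grid
from .discretize import BinScheme, bin_assign, supervised_discretize
from .hierarchy import FactorHierarchy, default_hierarchy, hierarchy_from_weights
from .ranking import rank_features, select_features
from .scoring import (
    auc_score,
    build_scorecard,
    choose_threshold,
    evaluate,
    risk_score,
    run_baselines,
)
from .survival import cox_weight_seed, fit_cox

__all__ = ["PipelineConfig", "PipelineError", "read_cohort", "run_pipeline"]

log = logging.getLogger("autoahp")

MISSING_TOKEN = "NA"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs persist."""


@dataclass
class PipelineConfig:
    """Paths, seeds, thresholds and stage toggles of one pipeline run."""

    out_dir: str = "autoahp_run"
    cohort_csv: str | None = None  # None -> simulate
    hierarchy_path: str | None = None  # None -> default three-criteria tree
    n: int = 2000  # simulated cohort size when cohort_csv is None
    seed: int = 7
    split: tuple[int, int] = (2, 1)  # train : test
    cr_threshold: float = 0.10
    confidence: float = 0.95
    min_frac: float = 0.05
    keep_k: int = 23
    duration_col: str = "event_time"  # observed time: min(event time, follow-up end)
    event_col: str = "event"
    discretize_vars: tuple[str, ...] = ("age", "course_years")
    run_apc: bool = True
    run_baselines: bool = False
    target_event_rate: float = 0.15

    def __post_init__(self) -> None:
        a, b = self.split
        if a <= 0 or b <= 0:
            raise ValueError(f"split ratio must have two positive parts, got {self.split}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        d = yaml.safe_load(raw) if path.suffix in {".yaml", ".yml"} else json.loads(raw)
        if "split" in d:
            d["split"] = tuple(d["split"])
        if "discretize_vars" in d:
            d["discretize_vars"] = tuple(d["discretize_vars"])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV with typed columns (missing token ``NA``)."""
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=True)
    if df.empty:
        raise ValueError(f"cohort file {path} contains no rows")
    log.info("read %d rows x %d columns from %s", len(df), df.shape[1], path)
    return df


def _split(df: pd.DataFrame, y: np.ndarray, ratio: tuple[int, int], seed: int):
    test_frac = ratio[1] / (ratio[0] + ratio[1])
    idx_train, idx_test = train_test_split(
        np.arange(len(df)), test_size=test_frac, random_state=seed, stratify=y
    )
    return np.sort(idx_train), np.sort(idx_test)


def _leaf_design(df: pd.DataFrame, h: FactorHierarchy, bins: dict[str, BinScheme]) -> pd.DataFrame:
    cols = {}
    for leaf in h.leaves():
        v = leaf.variable or leaf.name
        if v not in df.columns:
            raise KeyError(f"leaf {leaf.name!r} references missing column {v!r}")
        x = df[v]
        if v in bins:
            x = pd.Series(bin_assign(bins[v], x.to_numpy()), index=df.index)
        cols[v] = pd.to_numeric(x)
    return pd.DataFrame(cols, index=df.index)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every enabled stage in order and return the artifact bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": [],
    }
    artifacts: dict = {"manifest": manifest}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as err:
            manifest["stages"].append({"stage": name, "status": "failed", "error": str(err)})
            _write_manifest(out, manifest)
            raise PipelineError(f"stage {name!r} failed: {err}") from err
        manifest["stages"].append({"stage": name, "status": "ok"})
        _write_manifest(out, manifest)
        return result

    # --- cohort -----------------------------------------------------------
    def _cohort():
        if cfg.cohort_csv:
            df = read_cohort(cfg.cohort_csv)
        else:
            params = GeneratorParams(
                n=cfg.n, seed=cfg.seed, target_event_rate=cfg.target_event_rate
            )
            df, truth = generate_cohort(params)
            df.to_csv(out / "cohort.csv", index=False)
            (out / "cohort_truth.json").write_text(json.dumps(truth, indent=2))
        manifest["rows"] = len(df)
        return df

    df = stage("cohort", _cohort)
    y = df[cfg.event_col].to_numpy().astype(int)
    t = df[cfg.duration_col].to_numpy(dtype=float)

    idx_train, idx_test = stage("split", lambda: _split(df, y, cfg.split, cfg.seed))
    train, test = df.iloc[idx_train], df.iloc[idx_test]
    y_train, y_test = y[idx_train], y[idx_test]
    manifest["rows_train"], manifest["rows_test"] = len(train), len(test)

    # --- hierarchy --------------------------------------------------------
    h = stage(
        "hierarchy",
        lambda: FactorHierarchy.load(cfg.hierarchy_path) if cfg.hierarchy_path else default_hierarchy(),
    )
    leaf_vars = [leaf.variable or leaf.name for leaf in h.leaves()]

    # --- discretization ---------------------------------------------------
    def _discretize():
        bins: dict[str, BinScheme] = {}
        for var in cfg.discretize_vars:
            if var not in train.columns:
                continue
            scheme = supervised_discretize(
                train[var].to_numpy(dtype=float), y_train,
                confidence=cfg.confidence, min_frac=cfg.min_frac, variable=var,
            )
            scheme.to_json(out / f"bins_{var}.json")
            bins[var] = scheme
        return bins

    bins = stage("discretize", _discretize)

    # --- feature ranking --------------------------------------------------
    def _rank():
        X = _leaf_design(train, h, bins)
        table = rank_features(X, y_train, seed=cfg.seed)
        table.to_csv(out / "ranking.csv")
        selected = select_features(table, keep_k=cfg.keep_k)
        return table, selected

    ranking, selected = stage("rank", _rank)

    # --- Cox weight seeding -----------------------------------------------
    def _cox():
        X = _leaf_design(train, h, bins)
        model = fit_cox(train[cfg.duration_col].to_numpy(dtype=float), y_train, X)
        model.to_csv(out / "cox.csv")
        return model

    cox = stage("cox", _cox)

    # --- APC --------------------------------------------------------------
    if cfg.run_apc and {"age", "period"} <= set(df.columns):
        def _apc():
            grid = apc_grid(df)
            grid.to_csv(out / "apc_grid.csv", index=False)
            model = fit_apc(grid)
            rates = np.log((grid["events"] + 0.5) / grid["exposure"])
            adjusted = period_adjust(rates.to_numpy(), grid["period"].to_numpy(), model)
            pd.DataFrame({
                "period": model.period_effects.index,
                "period_effect": model.period_effects.to_numpy(),
            }).to_csv(out / "apc_period_effects.csv", index=False)
            return {"model": model, "adjusted_log_rates": adjusted}

        apc = stage("apc", _apc)
    else:
        apc = None
        manifest["stages"].append({"stage": "apc", "status": "skipped"})

    # --- AHP construction ---------------------------------------------------
    def _build_ahp():
        seeds = cox_weight_seed(cox)
        weights = {v: float(seeds.get(v, 0.0)) for v in leaf_vars}
        hierarchy_from_weights(h, weights, quantize=True, repair=True)
        reports = {}
        for node in h.internal_nodes():
            rep = consistency_report(node.matrix)
            reports[node.name] = rep.as_dict()
            node.matrix.to_csv(out / f"matrix_{node.name}.csv")
        globals_, overall = h.synthesize_global_weights()
        reports["overall_combination"] = overall.as_dict()
        (out / "consistency.json").write_text(json.dumps(reports, indent=2))
        h.save(out / "hierarchy.json")
        return reports

    consistency = stage("build_ahp", _build_ahp)

    # --- scorecard & scoring ------------------------------------------------
    card = stage("scorecard", lambda: build_scorecard(h, train, y_train, bins=bins))
    scores_train = stage("score_train", lambda: risk_score(train, card, bins=bins))
    scores_test = stage("score_test", lambda: risk_score(test, card, bins=bins))
    card.threshold = choose_threshold(scores_train, y_train)
    card.to_json(out / "scorecard.json")

    # --- evaluation ---------------------------------------------------------
    def _evaluate():
        scores_full = np.empty(len(df))
        scores_full[idx_train], scores_full[idx_test] = scores_train, scores_test
        rows = {
            "train": evaluate(scores_train, y_train, card.threshold).as_dict(),
            "test": evaluate(scores_test, y_test, card.threshold).as_dict(),
            "full": evaluate(scores_full, y, card.threshold).as_dict(),
        }
        rep = pd.DataFrame(rows).T
        rep.index.name = "split"
        rep.to_csv(out / "metrics.csv")
        # single-feature AUCs: direction learned on train, measured on
        # test and on the full cohort (the composite-vs-single comparison)
        Xtr = _leaf_design(train, h, bins)
        Xall = _leaf_design(df, h, bins)
        feats = {}
        for v in Xall.columns:
            try:
                sign = 1.0 if auc_score(Xtr[v].to_numpy(dtype=float), y_train) >= 0.5 else -1.0
                feats[v] = {
                    "auc_test": auc_score(sign * Xall[v].to_numpy(dtype=float)[idx_test], y_test),
                    "auc_full": auc_score(sign * Xall[v].to_numpy(dtype=float), y),
                }
            except ValueError:
                continue
        tab = pd.DataFrame(feats).T
        tab.index.name = "feature"
        tab.to_csv(out / "feature_auc.csv")
        return {"metrics": rows, "feature_auc": feats}

    evaluation = stage("evaluate", _evaluate)

    # --- baselines ----------------------------------------------------------
    if cfg.run_baselines:
        def _baselines():
            Xtr = _leaf_design(train, h, bins)
            Xte = _leaf_design(test, h, bins)
            reports = run_baselines(Xtr, y_train, Xte, y_test, seed=cfg.seed)
            tab = pd.DataFrame({k: v.as_dict() for k, v in reports.items()}).T
            tab.index.name = "method"
            tab.to_csv(out / "baselines.csv")
            return {k: v.as_dict() for k, v in reports.items()}

        artifacts["baselines"] = stage("baselines", _baselines)
    else:
        manifest["stages"].append({"stage": "baselines", "status": "skipped"})

    _write_manifest(out, manifest)
    artifacts.update(
        cohort=df, train_index=idx_train, test_index=idx_test, hierarchy=h, bins=bins,
        ranking=ranking, selected=selected, cox=cox, apc=apc, consistency=consistency,
        scorecard=card, scores_train=scores_train, scores_test=scores_test,
        evaluation=evaluation,
    )
    return artifacts


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
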