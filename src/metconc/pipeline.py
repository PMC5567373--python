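"""End-to-end orchestration: network -> features -> selection -> model -> domain.

A :class:`RunConfig` (loadable from YAML/JSON) drives one reproducible
run; all stage outputs land in the run directory as TSV/JSON, together
with a manifest of seeds, input hashes and counts. Any stage failure
aborts with the stage name and a machine-readable error code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, features, network, selection, synthetic
from .features import FeatureMatrix
from .model import ConcentrationSVR, RidgeConfig, SVRConfig
from .selection import GAConfig

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

ERROR_CODES = {"config": 2, "data": 3, "numerical": 4}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code
        self.exit_code = ERROR_CODES.get(code, 1)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    output_dir: str = "run"
    # inputs: either a synthetic benchmark or explicit files
    synthetic: bool = True
    synthetic_config: dict = field(default_factory=dict)
    metabolite_table: str | None = None
    molecular_descriptors: str | None = None
    reactant_pairs: str | None = None
    pathway_membership: str | None = None
    organism_pathways: str | None = None
    # procedure
    seed: int = 0
    split_strategy: str = "random"  # or "non_overlap", or "both"
    n_train: int = 91
    sd_threshold: float = 0.001
    min_pathway_minority: int = 2
    ga: dict = field(default_factory=dict)
    selection_regressor: str = "svr"  # or "ridge" for desk-scale runs
    ridge_alpha: float = 1e-3
    svr: dict = field(default_factory=dict)
    grid: dict | None = None
    grid_scheme: str = "10fold"
    standardize: bool = False
    collapse_mpf: bool = True
    clogp_column: str = "ClogP"
    clogp_bin_width: float = 0.5
    plots: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", "config", f"unknown keys {sorted(unknown)} in {path}")
        return cls(**raw)

    def ga_config(self) -> GAConfig:
        return GAConfig(seed=self.seed, **self.ga)

    def regressor(self):
        if self.selection_regressor == "ridge":
            return RidgeConfig(alpha=self.ridge_alpha)
        if self.selection_regressor == "svr":
            return SVRConfig(**self.svr) if self.svr else SVRConfig()
        raise PipelineError("config", "config", f"unknown selection_regressor {self.selection_regressor!r}")


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic:
        scfg = synthetic.SyntheticConfig(seed=cfg.seed, **cfg.synthetic_config)
        dataset, molecular, nets, members, truth = synthetic.generate(scfg)
        org_pathways = truth.organism_pathways
        input_paths: list[str] = []
        return dataset, molecular, nets, members, org_pathways, input_paths
    for name in ("metabolite_table", "molecular_descriptors", "reactant_pairs", "pathway_membership", "organism_pathways"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise PipelineError("load", "config", f"input {name} missing or not found: {p}")
    dataset = dataio.read_metabolite_table(cfg.metabolite_table)
    molecular = FeatureMatrix.from_csv(cfg.molecular_descriptors)
    pairs = network.read_reactant_pairs(cfg.reactant_pairs)
    members = features.read_pathway_membership(cfg.pathway_membership)
    opw = pd.read_csv(cfg.organism_pathways, sep="\t", dtype=str, keep_default_na=False)
    org_pathways = {
        org: set(g["pathway_id"]) for org, g in opw.groupby("organism")
    }
    nets = {
        org: network.reconstruct_network(pairs, pws) for org, pws in org_pathways.items()
    }
    input_paths = [
        cfg.metabolite_table,
        cfg.molecular_descriptors,
        cfg.reactant_pairs,
        cfg.pathway_membership,
        cfg.organism_pathways,
    ]
    return dataset, molecular, nets, members, org_pathways, input_paths


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write every report into the run directory."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"output_dir": str(outdir)}

    try:
        dataset, molecular, nets, members, org_pathways, input_paths = _load_inputs(cfg)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", "data", str(exc)) from exc

    all_pathways = set().union(*org_pathways.values()) if org_pathways else set()

    # ---- features --------------------------------------------------------
    try:
        topo = {org: net.descriptors_for(sorted(net.nodes)) for org, net in nets.items()}
        fm = features.assemble(dataset, molecular, topo, members, all_pathways)
        pw_cols = [c for c in fm.column_names if fm.origin[c] == "pathway"]
        pv, dropped_pw = features.filter_near_constant_pathways(
            fm.subset(pw_cols), cfg.min_pathway_minority
        )
        fm = fm.subset([c for c in fm.column_names if fm.origin[c] != "pathway"]).join(pv)
        fm, filter_report = features.preprocess(fm, cfg.sd_threshold)
        if cfg.standardize:
            frame = (fm.frame - fm.frame.mean()) / fm.frame.std(ddof=1)
            fm = FeatureMatrix(frame, fm.origin.to_dict())
        fm.to_csv(outdir / "feature_matrix.csv")
        filter_report.to_json(outdir / "filter_report.json")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("features", "data", str(exc)) from exc

    # ---- split + selection + model, per requested strategy ---------------
    strategies = ["random", "non_overlap"] if cfg.split_strategy == "both" else [cfg.split_strategy]
    reports = {}
    for strategy in strategies:
        reports[strategy] = _run_strategy(cfg, strategy, dataset, fm, members, outdir)
    results["strategies"] = reports
    if len(strategies) == 2:
        cmp = pd.concat(
            [reports[s]["validation_frame"].assign(strategy=s) for s in strategies],
            ignore_index=True,
        )
        cmp.to_csv(outdir / "strategy_comparison.tsv", sep="\t", index=False, na_rep="NA")

    # ---- descriptive reports --------------------------------------------
    try:
        tert_frames = []
        for org, net in nets.items():
            try:
                t = network.tertile_cluster_report(dataset, net, org)
                t.insert(0, "organism", org)
                tert_frames.append(t)
            except ValueError:
                pass
        if tert_frames:
            pd.concat(tert_frames, ignore_index=True).to_csv(
                outdir / "tertile_report.tsv", sep="\t", index=False
            )
        if cfg.clogp_column in molecular.frame.columns:
            clogp = molecular.frame[cfg.clogp_column].to_dict()
            bins, r2 = features.clogp_bin_report(dataset, clogp, cfg.clogp_bin_width)
            bins["fit_r2"] = r2
            bins.to_csv(outdir / "clogp_bins.tsv", sep="\t", index=False, float_format="%.6g")
            # deviation table over the metabolites carried by the MPF descriptor
            primary = reports[strategies[0]]
            mpf_pathways = set(primary.get("mpf_pathways", ()))
            if mpf_pathways:
                mpf_members = sorted(
                    m for m, pws in members.items() if pws & mpf_pathways
                )
                if mpf_members:
                    table, summary = features.pathway_deviation_table(dataset, mpf_members, clogp)
                    table.to_csv(outdir / "pathway_deviation.tsv", sep="\t", index=False,
                                 na_rep="NA", float_format="%.6g")
                    with open(outdir / "pathway_deviation_summary.json", "w") as fh:
                        json.dump(summary, fh, indent=2)
                        fh.write("\n")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("report", "numerical", str(exc)) from exc

    # ---- manifest --------------------------------------------------------
    dataio.write_manifest(
        outdir / "manifest.json",
        inputs=input_paths,
        seeds={"seed": cfg.seed},
        counts={
            "n_records": len(dataset),
            "n_features": len(fm.column_names),
            "organisms": sorted(nets),
        },
        extra={"config": asdict(cfg)},
    )
    results["manifest"] = str(outdir / "manifest.json")
    return results


def _run_strategy(cfg, strategy, dataset, fm, members, outdir: Path) -> dict:
    tag = "" if cfg.split_strategy != "both" else f"_{strategy}"
    try:
        if strategy == "random":
            split = dataio.split_random(dataset, cfg.n_train, cfg.seed)
        elif strategy == "non_overlap":
            split = dataio.split_non_overlap(dataset, cfg.n_train, cfg.seed)
        else:
            raise PipelineError("split", "config", f"unknown split strategy {strategy!r}")
        train_keys = split.train.row_keys()
        test_keys = split.test.row_keys()
        y = split.neg_log_c()
        y_train = y.loc[train_keys].to_numpy()
        y_test = y.loc[test_keys].to_numpy()
        X_all = fm.frame
        fm_train = FeatureMatrix(X_all.loc[train_keys], fm.origin.to_dict())
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("split", "data", str(exc)) from exc

    try:
        subset, trace = selection.select_variables(
            fm_train, y_train, cfg.ga_config(), cfg.regressor()
        )
        mpf_pathways: set = set()
        if cfg.collapse_mpf:
            subset, fm_aug, mpf_pathways = _collapse_mpf(subset, fm, members)
            if fm_aug is not fm:
                fm_train = FeatureMatrix(fm_aug.frame.loc[train_keys], fm_aug.origin.to_dict())
                X_all = fm_aug.frame
                subset.fitness_rmse = selection.fitness_loo_rmse(
                    subset.member_names, fm_train, y_train, cfg.regressor()
                )
        selection.write_trace(trace, outdir / f"selection_trace{tag}.tsv")
        selection.write_subset(subset, outdir / f"selected_variables{tag}.txt")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("selection", "numerical", str(exc)) from exc

    try:
        model = ConcentrationSVR(
            y_train, fm_train.frame[subset.member_names], config=SVRConfig(**cfg.svr) if cfg.svr else None
        )
        if cfg.grid is not None:
            model = model.grid_search(grid=cfg.grid or None, scheme=cfg.grid_scheme, seed=cfg.seed)
        res = model.fit()
        X_test = X_all.loc[test_keys, subset.member_names]
        report = res.validate(X_test, y_test, seed=cfg.seed)
        report.to_tsv(outdir / f"validation_report{tag}.tsv")
        report.to_json(outdir / f"validation_report{tag}.json")
        res.save_json(outdir / f"model{tag}.json")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("model", "numerical", str(exc)) from exc

    try:
        ad = res.applicability_domain(X_test, y_test)
        ad["id"] = train_keys + test_keys
        ad.to_csv(outdir / f"leverage_report{tag}.tsv", sep="\t", index=False)
        if cfg.plots:
            from .domain import plot_williams

            plot_williams(ad, outdir / f"williams{tag}.png")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("domain", "numerical", str(exc)) from exc

    return {
        "subset": subset,
        "trace": trace,
        "mpf_pathways": mpf_pathways,
        "validation": report,
        "validation_frame": report.to_frame(),
        "leverage": ad,
        "model_path": str(outdir / f"model{tag}.json"),
    }


def _collapse_mpf(subset, fm, members):
    """Replace surviving pathway-origin columns by the single MPF column."""
    pw = [m for m in subset.member_names if fm.origin.get(m) == "pathway"]
    if not pw:
        return subset, fm, set()
    mpf = features.build_mpf(members, set(pw), fm.row_keys)
    frame = fm.frame.copy()
    frame["MPF"] = mpf
    fm_aug = FeatureMatrix(frame, {**fm.origin.to_dict(), "MPF": "mpf"})
    names = [m for m in subset.member_names if m not in pw] + ["MPF"]
    new = selection.VariableSubset(names, subset.fitness_rmse)
    return new, fm_aug, set(pw)
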