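"""End-to-end orchestration: simulate/ingest -> prep -> ecology -> lsvcmm
-> fpca -> networks -> contingency stats, with an INI config, per-stage
toggles and a manifest recording parameters, seeds and output hashes."""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contingency, ecology, fpca, networks, prep, simulate, tables
from .lsvcmm import LSVCMM, summarize_significance

STAGES = ("simulate", "prep", "ecology", "lsvcmm", "fpca", "networks", "stats")


@dataclass
class PipelineConfig:
    """All pipeline parameters; INI round-trip via parse()/write()."""

    # input: either a fixture directory (shared/taxonomy/metadata files) or
    # simulate=True to generate a cohort in-memory
    fixture_dir: str = ""
    simulate: bool = True
    seed: int = 0
    outdir: str = "longisal_out"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulate
    n_otus: int = 200
    depth_mean: float = 20000.0
    dropout_rate: float = 0.10
    sigma_b: float = 0.7
    sigma_e: float = 1.0
    zero_inflation: float = 0.3
    arm_scale: float = 1.0
    # prep
    rarefaction_depth: int = 9484
    prevalence_lsvcmm: float = 0.05
    prevalence_network: float = 0.10
    clr_on_rarefied: bool = False
    # ecology
    n_perm: int = 999
    # lsvcmm
    variant: str = "full"
    n_boot: int = 1000
    n_lambda: int = 20
    ebic_gamma: float = 0.5
    lambda_smooth_grid: tuple = (0.0, 0.3, 1.0, 3.0, 10.0)
    max_otus: int = 0  # 0 = all retained OTUs
    # fpca
    fpca_variance: float = 0.99
    cv_folds: int = 5
    # networks
    network_rank: str = "family"
    stars_beta: float = 0.05
    stars_subsamples: int = 20
    network_lambda_points: int = 15

    def validate(self) -> None:
        if not self.simulate:
            d = Path(self.fixture_dir)
            for name in ("cohort.shared", "cohort.cons.taxonomy", "cohort.metadata.tsv"):
                if not (d / name).exists():
                    raise FileNotFoundError(d / name)
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        for p in (self.prevalence_lsvcmm, self.prevalence_network):
            if not 0 <= p < 1:
                raise ValueError("prevalence thresholds must be in [0, 1)")
        if self.variant not in ("full", "genotype", "diagnosis"):
            raise ValueError("variant must be full|genotype|diagnosis")

    # -- INI round-trip ---------------------------------------------------

    def write(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["global"] = {
            "fixture_dir": self.fixture_dir,
            "simulate": str(self.simulate),
            "seed": str(self.seed),
            "outdir": self.outdir,
        }
        cp["stages"] = {s: str(v) for s, v in self.stages.items()}
        cp["simulate"] = {
            k: str(getattr(self, k))
            for k in (
                "n_otus",
                "depth_mean",
                "dropout_rate",
                "sigma_b",
                "sigma_e",
                "zero_inflation",
                "arm_scale",
            )
        }
        cp["prep"] = {
            k: str(getattr(self, k))
            for k in (
                "rarefaction_depth",
                "prevalence_lsvcmm",
                "prevalence_network",
                "clr_on_rarefied",
            )
        }
        cp["ecology"] = {"n_perm": str(self.n_perm)}
        cp["lsvcmm"] = {
            "variant": self.variant,
            "n_boot": str(self.n_boot),
            "n_lambda": str(self.n_lambda),
            "ebic_gamma": str(self.ebic_gamma),
            "lambda_smooth_grid": ",".join(str(v) for v in self.lambda_smooth_grid),
            "max_otus": str(self.max_otus),
        }
        cp["fpca"] = {
            "fpca_variance": str(self.fpca_variance),
            "cv_folds": str(self.cv_folds),
        }
        cp["networks"] = {
            "network_rank": self.network_rank,
            "stars_beta": str(self.stars_beta),
            "stars_subsamples": str(self.stars_subsamples),
            "network_lambda_points": str(self.network_lambda_points),
        }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def parse(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        g = cp["global"]
        cfg = cls(
            fixture_dir=g.get("fixture_dir", ""),
            simulate=g.getboolean("simulate", True),
            seed=g.getint("seed", 0),
            outdir=g.get("outdir", "longisal_out"),
        )
        if "stages" in cp:
            cfg.stages = {s: cp["stages"].getboolean(s, True) for s in STAGES}
        sec = cp["simulate"] if "simulate" in cp else {}
        if sec:
            cfg.n_otus = cp["simulate"].getint("n_otus", cfg.n_otus)
            cfg.depth_mean = cp["simulate"].getfloat("depth_mean", cfg.depth_mean)
            cfg.dropout_rate = cp["simulate"].getfloat("dropout_rate", cfg.dropout_rate)
            cfg.sigma_b = cp["simulate"].getfloat("sigma_b", cfg.sigma_b)
            cfg.sigma_e = cp["simulate"].getfloat("sigma_e", cfg.sigma_e)
            cfg.zero_inflation = cp["simulate"].getfloat(
                "zero_inflation", cfg.zero_inflation
            )
            cfg.arm_scale = cp["simulate"].getfloat("arm_scale", cfg.arm_scale)
        if "prep" in cp:
            cfg.rarefaction_depth = cp["prep"].getint(
                "rarefaction_depth", cfg.rarefaction_depth
            )
            cfg.prevalence_lsvcmm = cp["prep"].getfloat(
                "prevalence_lsvcmm", cfg.prevalence_lsvcmm
            )
            cfg.prevalence_network = cp["prep"].getfloat(
                "prevalence_network", cfg.prevalence_network
            )
            cfg.clr_on_rarefied = cp["prep"].getboolean(
                "clr_on_rarefied", cfg.clr_on_rarefied
            )
        if "ecology" in cp:
            cfg.n_perm = cp["ecology"].getint("n_perm", cfg.n_perm)
        if "lsvcmm" in cp:
            sec = cp["lsvcmm"]
            cfg.variant = sec.get("variant", cfg.variant)
            cfg.n_boot = sec.getint("n_boot", cfg.n_boot)
            cfg.n_lambda = sec.getint("n_lambda", cfg.n_lambda)
            cfg.ebic_gamma = sec.getfloat("ebic_gamma", cfg.ebic_gamma)
            grid = sec.get("lambda_smooth_grid", "")
            if grid:
                cfg.lambda_smooth_grid = tuple(float(v) for v in grid.split(","))
            cfg.max_otus = sec.getint("max_otus", cfg.max_otus)
        if "fpca" in cp:
            cfg.fpca_variance = cp["fpca"].getfloat("fpca_variance", cfg.fpca_variance)
            cfg.cv_folds = cp["fpca"].getint("cv_folds", cfg.cv_folds)
        if "networks" in cp:
            sec = cp["networks"]
            cfg.network_rank = sec.get("network_rank", cfg.network_rank)
            cfg.stars_beta = sec.getfloat("stars_beta", cfg.stars_beta)
            cfg.stars_subsamples = sec.getint("stars_subsamples", cfg.stars_subsamples)
            cfg.network_lambda_points = sec.getint(
                "network_lambda_points", cfg.network_lambda_points
            )
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest, stage, params, outputs):
    manifest["stages"][stage] = {
        "params": params,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }


def run_full_analysis(config: PipelineConfig, outdir=None) -> dict:
    """Execute all enabled stages; returns the manifest dict.

    A stage failure raises ``RuntimeError`` naming the stage; outputs
    written before the failure remain on disk.
    """
    config.validate()
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    table = None
    truth = None
    clr = None

    def run(stage, fn):
        nonlocal manifest
        if not config.stages.get(stage, True):
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- simulate / ingest -------------------------------------------------
    def _simulate():
        nonlocal table, truth
        if config.simulate:
            arms = {
                k: max(2, int(round(v * config.arm_scale)))
                for k, v in simulate.DEFAULT_ARMS.items()
            }
            design = simulate.StudyDesign(
                n_mice=arms,
                n_otus=config.n_otus,
                depth_mean=config.depth_mean,
                dropout_rate=config.dropout_rate,
                seed=config.seed,
            )
            tc = simulate.TruthConfig(
                sigma_b=config.sigma_b,
                sigma_e=config.sigma_e,
                zero_inflation=config.zero_inflation,
            )
            table, truth = simulate.generate_cohort(design, tc)
            paths = simulate.write_fixture(table, truth, out / "fixture")
            _record(manifest, "simulate", {"seed": config.seed}, paths.values())
        else:
            d = Path(config.fixture_dir)
            table = tables.read_table(
                d / "cohort.shared", d / "cohort.cons.taxonomy", d / "cohort.metadata.tsv"
            )
            _record(manifest, "simulate", {"ingested_from": str(d)}, [])

    run("simulate", _simulate)
    if table is None:
        _simulate()  # inputs are required even when the stage toggle is off

    # -- prep --------------------------------------------------------------
    rarefied = None

    def _prep():
        nonlocal clr, rarefied
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rarefied = prep.rarefy(table, config.rarefaction_depth, seed=config.seed + 11)
            source = rarefied if config.clr_on_rarefied else table
            clr = prep.clr_transform(source, config.prevalence_lsvcmm)
        paths = prep.write_clr(clr, out / "prep")
        _record(
            manifest,
            "prep",
            {
                "rarefaction_depth": config.rarefaction_depth,
                "prevalence": config.prevalence_lsvcmm,
                "clr_on_rarefied": config.clr_on_rarefied,
                "seed": config.seed + 11,
            },
            paths.values(),
        )

    run("prep", _prep)

    # -- ecology -----------------------------------------------------------
    def _ecology():
        src = rarefied if rarefied is not None and rarefied.n_samples else table
        meta = src.sample_meta
        base_ids = meta.index[meta["week"] == meta["week"].min()]
        base = src.counts.loc[base_ids]
        dm = ecology.theta_yc_matrix(base)
        dm.to_frame().to_csv(out / "thetayc_baseline.tsv", sep="\t")
        f_stat, p = ecology.amova(
            dm, meta.loc[base_ids, "genotype"], n_perm=config.n_perm, seed=config.seed + 21
        )
        div = {
            "amova_F": f_stat,
            "amova_p": p,
        }
        invsimp = base.apply(ecology.inverse_simpson, axis=1)
        rich = base.apply(ecology.observed_richness, axis=1)
        for name, vals in (("inverse_simpson", invsimp), ("richness", rich)):
            a = vals[meta.loc[base_ids, "genotype"] == "WT"]
            b = vals[meta.loc[base_ids, "genotype"] == "KO"]
            t, pt = ecology.diversity_t_test(a, b)
            div[f"{name}_t"] = t
            div[f"{name}_p"] = pt
        (out / "ecology.json").write_text(json.dumps(div, indent=2, sort_keys=True))
        _record(
            manifest,
            "ecology",
            {"n_perm": config.n_perm, "seed": config.seed + 21},
            [out / "ecology.json", out / "thetayc_baseline.tsv"],
        )

    run("ecology", _ecology)

    # -- lsvcmm ------------------------------------------------------------
    def _lsvcmm():
        otus = clr.retained_otus
        if config.max_otus:
            otus = otus[: config.max_otus]
        results = {}
        for otu in otus:
            model = LSVCMM.from_clr(clr, table.sample_meta, otu, config.variant)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit_ebic(
                    n_lambda=config.n_lambda,
                    lambda_smooth_grid=config.lambda_smooth_grid,
                    gamma=config.ebic_gamma,
                )
                bands = res.bootstrap_bands(
                    n_boot=config.n_boot, seed=config.seed + 31
                )
            results[otu] = (res, bands)
        sig_table, reported = summarize_significance(results)
        sig_table.to_csv(out / "lsvcmm_significance.tsv", sep="\t", index=False)
        (out / "lsvcmm_reported_otus.json").write_text(
            json.dumps({"reported": reported}, indent=2)
        )
        _record(
            manifest,
            "lsvcmm",
            {
                "variant": config.variant,
                "n_boot": config.n_boot,
                "n_lambda": config.n_lambda,
                "gamma": config.ebic_gamma,
                "seed": config.seed + 31,
            },
            [out / "lsvcmm_significance.tsv", out / "lsvcmm_reported_otus.json"],
        )

    run("lsvcmm", _lsvcmm)

    # -- fpca --------------------------------------------------------------
    def _fpca():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = fpca.build_trajectories(clr, table.sample_meta)
            models = fpca.fit_fpca(traj, config.fpca_variance)
            report = fpca.predict_diagnosis(
                traj,
                models=models,
                seed=config.seed + 41,
                folds=config.cv_folds,
                variance_threshold=config.fpca_variance,
            )
        report.group_mean_scores.to_csv(out / "fpca_group_scores.tsv", sep="\t", index=False)
        eig_rows = []
        score_rows = []
        for otu in traj.otus:
            res = models[otu]
            for k in range(res.n_components):
                eig_rows.append(
                    [otu, f"fPC{k + 1}", float(res.eigenvalues[k])]
                    + [float(v) for v in res.eigenfunctions[k]]
                )
                for mouse, s in zip(traj.mice, res.scores[:, k]):
                    score_rows.append((otu, f"fPC{k + 1}", mouse, float(s)))
        pd.DataFrame(
            eig_rows,
            columns=["otu", "component", "eigenvalue"]
            + [f"week_{w}" for w in traj.weeks],
        ).to_csv(out / "fpca_eigenfunctions.tsv", sep="\t", index=False)
        pd.DataFrame(
            score_rows, columns=["otu", "component", "mouse_id", "score"]
        ).to_csv(out / "fpca_scores.tsv", sep="\t", index=False)
        summary = {
            g: {
                "C": fit.C_selected,
                "predictive_otus": fit.predictive_otus,
                "cv_neg_log_loss": fit.cv_score,
            }
            for g, fit in report.per_genotype.items()
        }
        (out / "fpca_report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        _record(
            manifest,
            "fpca",
            {
                "variance": config.fpca_variance,
                "folds": config.cv_folds,
                "seed": config.seed + 41,
            },
            [
                out / "fpca_group_scores.tsv",
                out / "fpca_report.json",
                out / "fpca_eigenfunctions.tsv",
                out / "fpca_scores.tsv",
            ],
        )

    run("fpca", _fpca)

    # -- networks ----------------------------------------------------------
    def _networks():
        lams = networks.default_lambda_seq(config.network_lambda_points)
        nets = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for geno in ("WT", "KO"):
                for est in networks.build_period_networks(
                    table,
                    config.network_rank,
                    geno,
                    prevalence_min=config.prevalence_network,
                    lambda_seq=lams,
                    n_subsamples=config.stars_subsamples,
                    beta_threshold=config.stars_beta,
                    seed=config.seed + 51,
                ):
                    nets[(geno, est.period)] = est
        rows = [
            (a, b, s, g, p)
            for (g, p), est in nets.items()
            for a, b, s in est.edges
        ]
        pd.DataFrame(rows, columns=["node1", "node2", "sign", "genotype", "period"]).to_csv(
            out / "network_edges.tsv", sep="\t", index=False
        )
        outputs = [out / "network_edges.tsv"]
        if len(nets) >= 2:
            cmp = networks.compare_networks(nets)
            cmp.presence.to_csv(out / "network_presence.tsv", sep="\t")
            (out / "network_report.json").write_text(
                json.dumps(
                    {"class_counts": cmp.class_counts(), "classes": cmp.classes},
                    indent=2,
                    sort_keys=True,
                )
            )
            outputs += [out / "network_presence.tsv", out / "network_report.json"]
        _record(
            manifest,
            "networks",
            {
                "rank": config.network_rank,
                "beta": config.stars_beta,
                "subsamples": config.stars_subsamples,
                "seed": config.seed + 51,
            },
            outputs,
        )

    run("networks", _networks)

    # -- stats -------------------------------------------------------------
    def _stats():
        mice = table.sample_meta.drop_duplicates("mouse_id")
        tabs = {}
        for sex in sorted(mice["sex"].unique()):
            sub = mice[mice["sex"] == sex]
            tab = np.zeros((2, 2), dtype=int)
            for i, geno in enumerate(("WT", "KO")):
                for j, diag in enumerate(("ED/CIS", "OSCC")):
                    tab[i, j] = int(
                        ((sub["genotype"] == geno) & (sub["diagnosis"] == diag)).sum()
                    )
            tabs[sex] = tab
        res = contingency.contingency_tests(tabs)
        (out / "contingency.json").write_text(
            json.dumps(
                {
                    k: {"statistic": v.statistic, "p": v.p_value}
                    for k, v in res.items()
                },
                indent=2,
                sort_keys=True,
            )
        )
        _record(manifest, "stats", {}, [out / "contingency.json"])

    run("stats", _stats)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
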