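"""Scenario orchestration: simulate -> (PCs) -> scan -> GC report -> artifacts.

``run_scenario`` drives one full scenario and leaves a self-describing
output directory: the config actually used, the per-locus results table,
GC report(s) with QQ coordinates, optional QQ plots, and a JSON run
manifest listing every artifact.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import ScenarioConfig
from .errors import GxescanError
from .gcdiag import build_gc_report
from .io import (write_gc_report, write_genotype_tsv, write_pc_scores_tsv,
                 write_phenotype_tsv, write_results_tsv)
from .regress import genome_scan
from .sim import simulate_cohort
from .structure import compute_pcs

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    artifacts: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


class _Stage:
    """Context manager recording wall status per pipeline stage."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        status = "ok" if exc_type is None else f"failed: {exc}"
        self.manifest.stages[self.name] = {
            "status": status,
            "seconds": round(time.perf_counter() - self.t0, 3),
        }
        if exc_type is not None:
            logger.error("stage %s failed: %s", self.name, exc)
            raise GxescanError(f"[{self.name}] {exc}") from exc
        logger.info("stage %s ok (%.2fs)", self.name,
                    self.manifest.stages[self.name]["seconds"])


def run_scenario(config: ScenarioConfig | str | Path, outdir,
                 n_pcs: int = 0, interact_covariates: bool = False,
                 save_cohort: bool = False, plots: bool = True,
                 scenario_tag: str = "") -> RunManifest:
    """Run one simulation scenario end to end.

    With ``n_pcs > 0`` the scan is performed twice — unadjusted and with the
    top PCs of the genotype matrix as covariates — mirroring the side-by-side
    comparison used for stratified scenarios.
    """
    if not isinstance(config, ScenarioConfig):
        config = ScenarioConfig.from_yaml(config)
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           version=__version__)
    art = manifest.artifacts

    with _Stage(manifest, "simulate"):
        cohort = simulate_cohort(config)
    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    art["config"] = str(cfg_path)

    if save_cohort:
        with _Stage(manifest, "export_cohort"):
            gpath = outdir / "genotypes.tsv"
            ppath = outdir / "phenotypes.tsv"
            write_genotype_tsv(gpath, cohort.genotypes, cohort.locus_ids,
                               cohort.sample_ids)
            write_phenotype_tsv(ppath, cohort)
            art["genotypes"] = str(gpath)
            art["phenotypes"] = str(ppath)

    pcs = None
    if n_pcs > 0:
        with _Stage(manifest, "compute_pcs"):
            pcr = compute_pcs(cohort.genotypes, k=n_pcs)
            pcs = pcr.scores
            pc_path = outdir / "pc_scores.tsv"
            write_pc_scores_tsv(pc_path, pcs, cohort.sample_ids)
            art["pc_scores"] = str(pc_path)

    runs = [("", None)]
    if pcs is not None:
        runs.append(("_pcadj", pcs))
    for suffix, cov in runs:
        with _Stage(manifest, f"scan{suffix}"):
            scan = genome_scan(cohort, covariates=cov,
                               interact_covariates=interact_covariates,
                               scenario=scenario_tag or config.mean_model,
                               seed=config.seed)
            rpath = outdir / f"results{suffix}.tsv"
            write_results_tsv(rpath, scan)
            art[f"results{suffix}"] = str(rpath)
        with _Stage(manifest, f"gc_report{suffix}"):
            report = build_gc_report(scan)
            art.update({f"{k}{suffix}": v for k, v in
                        write_gc_report(outdir, report,
                                        prefix=f"gc{suffix}").items()})
        if plots:
            with _Stage(manifest, f"qq_plot{suffix}"):
                from .plots import qq_plot
                ppath = outdir / f"qq{suffix}.png"
                qq_plot(report, ppath,
                        title=f"{config.family}/{config.mean_model}{suffix}")
                art[f"qq_png{suffix}"] = str(ppath)

    mpath = outdir / "manifest.json"
    manifest.to_json(mpath)
    missing = [p for p in art.values() if not Path(p).exists()]
    if missing:
        raise GxescanError(f"manifest lists missing artifacts: {missing}")
    return manifest
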