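"""End-to-end orchestration: simulate/load -> phases -> sFC/dFC -> tests.

The pipeline runs the stages in their analysis order (filter, analytic
phase, static and dynamic connectivity, surrogate dynamics tests, group
inference), writes every stage artifact under the output directory, and
records a manifest with the configuration, a config hash and package
version so any output can be reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .dynamic_fc import dynamics_cohort
from .inference import DesignMatrix, metastability_multinomial, nbs
from .io import (
    read_cohort,
    read_panel,
    write_cohort,
    write_edge_matrix,
    write_json,
    write_panel,
    write_phase_panel,
)
from .signal_phase import analytic_phase, bandpass_filter
from .simulate import SimulationConfig, generate_cohort
from .static_fc import sfc_cohort
from .surrogates import (
    build_surrogate_ensemble,
    edge_dynamics_test,
    whole_brain_dynamics_curve,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("phasedyn")


@dataclass
class PipelineConfig:
    """Flat, explicit configuration for one pipeline run.

    Every stochastic stage has its own named seed; the file representation
    is a flat ``key = value`` text (TOML-compatible) with units spelled
    out in the key names.
    """

    output_dir: str = "phasedyn_out"
    panels_dir: str = ""  # empty: simulate a cohort instead of loading
    cohort_csv: str = ""
    band_low_hz: float = 0.04
    band_high_hz: float = 0.07
    trim: int = 10
    sfc_lambda: float = 0.1
    n_surrogates: int = 1000
    n_perm: int = 5000
    primary_p: float = 0.05
    reference_group: str = "SCI"
    sd_ddof: int = 1
    n_subjects_per_group: int = 26
    n_nodes: int = 26
    n_timepoints: int = 202
    tr_seconds: float = 2.638
    sim_seed: int = 11
    surrogate_seed: int = 7
    perm_seed: int = 13

    def to_file(self, path) -> Path:
        path = Path(path)
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            else:
                lines.append(f"{key} = {value!r}")
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str, subject: str = "-"):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage=%s subject=%s failed: %s", name, subject, exc)
                raise RuntimeError(
                    f"pipeline stage {name!r} failed for subject {subject}: {exc}"
                ) from exc
            log.info(
                "stage=%s subject=%s elapsed=%.2fs", name, subject,
                time.perf_counter() - self.t0,
            )
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig, write_surrogate_edges: bool = True) -> dict:
    """Execute the full analysis; returns the results bundle.

    Artifacts written under ``config.output_dir``: simulated panels (when
    no input directory is given), cohort table, phase panels, sFC and dFC
    edge matrices with the pair map, a metastability table, surrogate-test
    results and the group-inference JSON, plus ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    file_handler = logging.FileHandler(out / "pipeline.log")
    log.addHandler(file_handler)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }
    try:
        # ---- input panels ------------------------------------------------
        if config.panels_dir:
            with _stage("load"):
                panel_paths = sorted(Path(config.panels_dir).glob("*.tsv"))
                panels = [read_panel(p) for p in panel_paths]
                cohort = read_cohort(config.cohort_csv)
        else:
            with _stage("simulate"):
                sim = SimulationConfig(
                    n_subjects=config.n_subjects_per_group,
                    n_nodes=config.n_nodes,
                    n_timepoints=config.n_timepoints,
                    tr_seconds=config.tr_seconds,
                    trim=config.trim,
                )
                panels, cohort = generate_cohort(sim, spec_seed=config.sim_seed)
                for p in panels:
                    write_panel(p, out / "panels")
                write_cohort(cohort, out / "cohort.csv")
        manifest["stages"]["input"] = {
            "n_subjects": len(panels),
            "n_nodes": panels[0].n_nodes,
            "n_timepoints": panels[0].n_timepoints,
        }

        # ---- phases ------------------------------------------------------
        phase_panels = []
        for p in panels:
            with _stage("phase", p.subject_id):
                filtered = bandpass_filter(
                    p, config.band_low_hz, config.band_high_hz
                )
                pp = analytic_phase(filtered, trim=config.trim)
                write_phase_panel(pp, out / "phases")
                phase_panels.append(pp)
        manifest["stages"]["phase"] = {
            "usable_timepoints": phase_panels[0].n_timepoints,
            "trim": config.trim,
        }

        # ---- static FC (session-wide, on the unfiltered series) -----------
        with _stage("sfc"):
            sfc = sfc_cohort(panels, lam=config.sfc_lambda)
            write_edge_matrix(sfc, out / "sfc_edges.csv", out / "edge_pairs.csv")
        manifest["stages"]["sfc"] = {"n_edges": sfc.shape[1], "rows": sfc.shape[0]}

        # ---- dynamic FC ----------------------------------------------------
        with _stage("dfc"):
            states, dfc, summary = dynamics_cohort(phase_panels, ddof=config.sd_ddof)
            write_edge_matrix(dfc, out / "dfc_edges.csv")
            summary.to_csv(out / "metastability.csv")
        manifest["stages"]["dfc"] = {
            "n_edges": dfc.shape[1],
            "metastability_rows": summary.shape[0],
        }

        # ---- surrogate tests ----------------------------------------------
        with _stage("surrogates"):
            groups = cohort.table.set_index("subject_id")["group"]
            ref_ids = [
                p.subject_id
                for p in panels
                if groups.get(p.subject_id) == config.reference_group
            ]
            ens = build_surrogate_ensemble(
                panels,
                config.n_surrogates,
                seed=config.surrogate_seed,
                low_hz=config.band_low_hz,
                high_hz=config.band_high_hz,
                trim=config.trim,
                keep_edges_for=ref_ids,
                ddof=config.sd_ddof,
            )
            curve = whole_brain_dynamics_curve(
                summary["dfc_sum"].to_numpy(), ens.dfc_sums
            )
            edge_p = None
            if ens.dfc is not None:
                ref_dfc = dfc.loc[ens.kept_subject_ids].to_numpy()
                edge_p = edge_dynamics_test(ref_dfc, ens.dfc)
                if write_surrogate_edges:
                    edge_p.to_csv(out / "surrogate_edge_p.csv", index=False)
            write_json(
                {
                    "n_surrogates": config.n_surrogates,
                    "whole_brain": curve.to_dict(orient="list"),
                },
                out / "surrogate_results.json",
            )
        manifest["stages"]["surrogates"] = {"n_surrogates": config.n_surrogates}

        # ---- group inference ----------------------------------------------
        with _stage("inference"):
            design = DesignMatrix.from_cohort(
                cohort, reference=config.reference_group
            )
            fit = metastability_multinomial(
                summary["metastability"].to_numpy(), design
            )
            results_nbs = {}
            for name, mat in (("sfc", sfc), ("dfc", dfc)):
                res = nbs(
                    mat,
                    design,
                    primary_p=config.primary_p,
                    n_perm=config.n_perm,
                    seed=config.perm_seed,
                )
                results_nbs[name] = {
                    "threshold_f": res.threshold_f,
                    "components": res.components,
                    "node_f_sums": res.node_f_sums,
                    "status": res.status,
                }
            inference = {
                "multinomial": {
                    "reference": fit.reference,
                    "summary": fit.summary.reset_index().to_dict(orient="list"),
                    "pseudo_r2": fit.pseudo_r2,
                    "log_likelihood": fit.log_likelihood,
                },
                "nbs": results_nbs,
            }
            write_json(inference, out / "inference.json")
        manifest["stages"]["inference"] = {
            "nbs_components": {
                k: len(v["components"]) for k, v in results_nbs.items()
            }
        }

        write_json(manifest, out / "manifest.json")
        return {
            "manifest": manifest,
            "sfc": sfc,
            "dfc": dfc,
            "summary": summary,
            "whole_brain_curve": curve,
            "edge_dynamics": edge_p,
            "multinomial": fit,
            "nbs": results_nbs,
        }
    finally:
        log.removeHandler(file_handler)
        file_handler.close()
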