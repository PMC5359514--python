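"""Config-driven pipeline execution with on-disk artifacts.

Loads or generates the replicate CV matrices a config describes, runs the
analysis chain, and writes every intermediate table (parts, loadings, flags,
scores, lag matrices, per-replicate sequences) plus the consensus report and
a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .cv import CVDefinition, CVMatrix, evaluate_cvs
from .pipeline import PipelineResult, analyze_dataset
from .pka import default_cv_definitions
from .structures import read_structure, read_trajectory
from .synth import default_dataset

__all__ = ["run_pipeline", "load_input_matrices"]

log = logging.getLogger("cvevents")


def load_input_matrices(config: PipelineConfig) -> list[CVMatrix]:
    """Materialize the replicate CV matrices the config's input mode describes."""
    inp = config.input
    if inp.mode == "synthetic":
        ds = default_dataset(
            seed=config.seed,
            n_replicates=config.synthetic.n_replicates,
            T=config.synthetic.T,
            noise_scale=config.synthetic.noise_scale,
        )
        outdir = Path(config.outdir)
        ds.write(outdir / "synthetic")
        log.info(
            "stage=simulate replicates=%d T=%d cvs=%d",
            len(ds.replicates), ds.replicates[0].n_frames, len(ds.cv_ids),
        )
        return ds.replicates
    if inp.mode == "cv_tables":
        if not inp.cv_tables:
            raise ValueError("input.mode=cv_tables requires input.cv_tables paths")
        cvms = [CVMatrix.from_tsv(p) for p in inp.cv_tables]
        log.info("stage=load tables=%d", len(cvms))
        return cvms
    # trajectories mode
    if not inp.trajectories:
        raise ValueError("input.mode=trajectories requires input.trajectories entries")
    reference = read_structure(inp.reference) if inp.reference else None
    if inp.cv_definitions == "default_pka":
        defs = default_cv_definitions(reference)
    else:
        defs = [
            CVDefinition(
                id=d.id,
                kind=d.kind,
                selections=tuple(d.selections),
                reference=reference if d.kind in ("segment_rmsd", "helix_rotation") else None,
                params=dict(d.params),
                unit=d.unit,
            )
            for d in inp.cv_definitions
        ]
    cvms = []
    for entry in inp.trajectories:
        topo = read_structure(entry.topology)
        topo.title = entry.id
        traj = read_trajectory(topo, entry.trajectory)
        cvm = evaluate_cvs(traj, defs)
        cvm.trajectory_id = entry.id
        cvms.append(cvm)
        log.info("stage=compute-cvs trajectory=%s shape=%s", entry.id, cvm.values.shape)
    return cvms


def _write_tables(result: PipelineResult, outdir: Path) -> list[str]:
    written = []

    def emit(df: pd.DataFrame, name: str):
        path = outdir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        written.append(name)

    parts_rows, load_rows, flag_rows, lag_rows = [], [], [], []
    for rep in result.replicates:
        for pi, pa in enumerate(rep.parts):
            parts_rows.append(
                dict(
                    trajectory_id=rep.trajectory_id,
                    part_index=pi,
                    start_frame=pa.part.start_frame,
                    end_frame=pa.part.end_frame,
                )
            )
            if pa.model is None:
                continue
            for j, fid in enumerate([f"p{pi}f{k}" for k in range(pa.model.loadings.shape[1])]):
                for cv, loading in zip(pa.model.cv_ids, pa.model.loadings[:, j]):
                    load_rows.append(
                        dict(
                            trajectory_id=rep.trajectory_id,
                            part_index=pi,
                            factor_id=fid,
                            cv_id=cv,
                            loading=loading,
                        )
                    )
            for f in pa.flags:
                flag_rows.append(
                    dict(
                        trajectory_id=rep.trajectory_id,
                        part_index=pi,
                        factor_id=f"p{pi}f{f.factor_index}",
                        net_displacement_ratio=f.net_displacement_ratio,
                        trend_rho=f.trend_rho,
                        selected=f.selected,
                    )
                )
            if pa.lag_matrix is not None:
                lm = pa.lag_matrix
                for i in range(lm.n):
                    for j in range(i + 1, lm.n):
                        lag_rows.append(
                            dict(
                                trajectory_id=rep.trajectory_id,
                                part_index=pi,
                                factor_i=lm.factor_ids[i],
                                factor_j=lm.factor_ids[j],
                                lag=lm.lag[i, j],
                                peak_ccf=lm.peak_ccf[i, j],
                                significant=lm.significant[i, j],
                            )
                        )
    emit(pd.DataFrame(parts_rows), "parts.tsv")
    if load_rows:
        emit(pd.DataFrame(load_rows), "factor_loadings.tsv")
    if flag_rows:
        emit(pd.DataFrame(flag_rows), "factor_flags.tsv")
    if lag_rows:
        emit(pd.DataFrame(lag_rows), "lag_matrices.tsv")

    ev_rows = [
        dict(event=e, common_factor=result.events.common_factor.get(e, ""), cv_ids=",".join(sorted(cvs)))
        for e, cvs in sorted(result.events.events.items())
    ]
    ev_rows += [dict(event="(residual)", common_factor="", cv_ids=c) for c in result.events.residual_cvs]
    emit(pd.DataFrame(ev_rows), "events.tsv")
    return written


def run_pipeline(config: PipelineConfig, cvms: list[CVMatrix] | None = None) -> PipelineResult:
    """Execute the full pipeline for a config and write all artifacts.

    ``cvms`` overrides the config's input stage (used by the stage-wise CLI
    subcommands); otherwise the input mode decides where matrices come from.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cvms is None:
        cvms = load_input_matrices(config)
    params = config.params()
    result = analyze_dataset(cvms, params)
    log.info(
        "stage=analyze replicates=%d events=%d stages=%d",
        len(result.replicates), len(result.events.events), len(result.consensus.stages),
    )
    written = _write_tables(result, outdir)

    seq_lines = []
    for rep_id, groups in sorted(result.event_sequences.items()):
        rendered = " < ".join("{" + ",".join(sorted(g)) + "}" for g in groups)
        seq_lines.append(f"{rep_id}: {rendered}")
    (outdir / "sequences.txt").write_text("\n".join(seq_lines) + "\n")
    written.append("sequences.txt")

    (outdir / "consensus.txt").write_text(str(result.consensus) + "\n")
    (outdir / "consensus.json").write_text(json.dumps(result.consensus.to_dict(), indent=2))
    written += ["consensus.txt", "consensus.json"]

    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "outputs": sorted(written),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("stage=write outdir=%s files=%d", outdir, len(written) + 1)
    return result
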