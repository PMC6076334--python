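"""File-based orchestration of the imaging workflow.

``run_pipeline`` replays the acquisition workflow on directories of movies
instead of hardware: per-cell tracking (detection, fitting, linking,
filtering), the cell-success criterion (a recording counts only if some
spot was tracked for at least 1 s), per-cell statistics (MSD curves, step
diffusion coefficients, MSD at 66 ms), condition-level fits, and a
machine-readable run report.  Every stage appends a structured JSON line to
``run.log``; re-running with the same config and seed reproduces every
output table exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats, tracking
from .io import ImageStack, write_config

__all__ = ["RunConfig", "run_pipeline", "report"]


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    pixel_size: float = 0.1                 # um/px
    frame_interval: float = 0.033           # s
    corr_threshold: float = 0.25
    link_max_dist: float = 6.0              # px
    sigma_bounds: tuple[float, float] = (1.5, 2.5)
    max_lag: int = 15
    min_track_duration: float = 1.0         # s, cell-success criterion
    manifest: str | None = None             # CSV: file, ligand_nM[, inhibitor_nM]
    seed: int = 0


def _log(fh, stage: str, **fields) -> None:
    fh.write(json.dumps({"stage": stage, **fields}) + "\n")
    fh.flush()


def run_pipeline(config: RunConfig) -> Path:
    """Run tracking + statistics over every movie in the input directory.

    Each ``*.tif`` in ``input_dir`` is one cell's movie (a sibling
    ``<name>_mask.tif`` is used as its cell mask when present; mask files
    themselves are skipped as movies).  Outputs land in ``output_dir``:
    per-cell spot/trajectory CSVs, ``cells.csv`` with per-cell summaries,
    ``msd_curves.csv``, fit reports in ``fits.json``, the resolved config,
    and ``run.log``.  On a stage failure partial outputs are kept and the
    run is marked failed with the stage name.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_config(asdict(config) | {"sigma_bounds": f"{config.sigma_bounds[0]},"
                                   f"{config.sigma_bounds[1]}"},
                 out_dir / "config.txt")
    status = {"failed": False, "failed_stage": None}
    log_fh = open(out_dir / "run.log", "w")

    movies = sorted(p for p in in_dir.glob("*.tif")
                    if not p.stem.endswith("_mask"))
    if not movies:
        status.update(failed=True, failed_stage="input")
        _log(log_fh, "input", error=f"no movies found in {in_dir}")
        (out_dir / "status.json").write_text(json.dumps(status))
        log_fh.close()
        raise FileNotFoundError(f"no .tif movies in {in_dir}")

    manifest = None
    if config.manifest:
        manifest = pd.read_csv(config.manifest).set_index("file")

    cell_rows, msd_rows = [], []
    per_cell_traj: dict[str, list] = {}
    try:
        for path in movies:
            stack = ImageStack.load(path, pixel_size=config.pixel_size,
                                    frame_interval=config.frame_interval)
            mask_path = path.with_name(path.stem + "_mask.tif")
            mask = None
            if mask_path.exists():
                mask = ImageStack.load(mask_path).frames[0] > 0
            trajs, diag = tracking.track_movie(
                stack.frames, threshold=config.corr_threshold,
                max_dist=config.link_max_dist, cell_mask=mask,
                sigma_bounds=config.sigma_bounds)
            _log(log_fh, "track", file=path.name, **diag)
            tracking.trajectories_to_frame(trajs).to_csv(
                out_dir / f"{path.stem}_trajectories.csv", index=False)

            pos_um = [t.positions_um(config.pixel_size) for t in trajs]
            success = stats.cell_success(pos_um, dt=config.frame_interval,
                                         min_duration=config.min_track_duration)
            row = {"file": path.name, "success": success,
                   "n_trajectories": len(trajs)}
            if success:
                per_cell_traj[path.name] = trajs
                curve = stats.msd(pos_um, dt=config.frame_interval,
                                  max_lag=config.max_lag, cell_id=path.name)
                for lag, val, n in zip(curve.lags, curve.values, curve.n_pairs):
                    msd_rows.append({"file": path.name, "lag_s": lag,
                                     "msd_um2": val, "n_pairs": int(n)})
                d_mol = stats.step_diffusion(pos_um, dt=config.frame_interval)
                row["mean_D_um2_s"] = float(np.mean(d_mol)) if len(d_mol) else np.nan
                row["msd_66ms_um2"] = float(curve.values[1]) if config.max_lag >= 2 else np.nan
            if manifest is not None and path.name in manifest.index:
                for col in manifest.columns:
                    row[col] = manifest.loc[path.name, col]
            cell_rows.append(row)
            _log(log_fh, "cell", file=path.name, success=bool(success))

        cells = pd.DataFrame(cell_rows)
        cells.to_csv(out_dir / "cells.csv", index=False)
        pd.DataFrame(msd_rows).to_csv(out_dir / "msd_curves.csv", index=False)
        _log(log_fh, "summary", n_cells=len(cells),
             n_success=int(cells["success"].sum()))

        fits: dict = {}
        ok = cells[cells["success"]]
        if "ligand_nM" in ok.columns and ok["ligand_nM"].notna().any():
            table = ok.rename(columns={"msd_66ms_um2": "msd"})[
                ["ligand_nM", "msd"] + (["inhibitor_nM"] if "inhibitor_nM"
                                        in ok.columns else [])].dropna()
            if "inhibitor_nM" in table.columns and table["inhibitor_nM"].notna().any():
                fit = stats.fit_inhibition(table, seed=config.seed)
                fits["inhibition"] = {"ec50_nM": fit.ec50, "ic50_nM": fit.ic50,
                                      "msd_max": fit.msd_max, "msd_min": fit.msd_min,
                                      "error_model": fit.error_model}
            elif table["ligand_nM"].nunique() >= 3:
                fit = stats.fit_dose_response(table, seed=config.seed)
                fits["dose_response"] = {"ec50_nM": fit.ec50, "h": fit.h,
                                         "msd_max": fit.msd_max,
                                         "msd_min": fit.msd_min,
                                         "error_model": fit.error_model}
        if len(ok) >= 2:
            mat = (pd.DataFrame(msd_rows)
                   .pivot(index="file", columns="lag_s", values="msd_um2"))
            mat = mat.dropna()
            if len(mat) >= 2:
                cf = stats.fit_confined(mat.to_numpy(),
                                        lags=mat.columns.to_numpy(dtype=float),
                                        seed=config.seed)
                fits["confined"] = {"D_um2_s": cf.d, "C_um": cf.c,
                                    "error_model": cf.error_model,
                                    "logL_norm": cf.logl_norm,
                                    "logL_log": cf.logl_log}
        (out_dir / "fits.json").write_text(json.dumps(fits, indent=2))
        _log(log_fh, "fits", keys=list(fits))
    except Exception as exc:  # keep partial outputs, mark the failing stage
        status.update(failed=True, failed_stage="analysis", error=str(exc))
        (out_dir / "status.json").write_text(json.dumps(status))
        log_fh.close()
        raise
    (out_dir / "status.json").write_text(json.dumps(status))
    log_fh.close()
    return out_dir


def report(run_dir, make_plots: bool = True) -> Path:
    """Render a human-readable summary (markdown + optional plots)."""
    run_dir = Path(run_dir)
    lines = ["# Run report", ""]
    cells_path = run_dir / "cells.csv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path)
        lines += [f"Cells analyzed: {len(cells)}; "
                  f"successful recordings: {int(cells['success'].sum())}", ""]
        if "ligand_nM" in cells.columns:
            grp = (cells[cells["success"]]
                   .groupby("ligand_nM")["msd_66ms_um2"].agg(["mean", "std", "count"]))
            lines += ["## MSD(66 ms) by ligand concentration", "",
                      grp.to_markdown(), ""]
    else:
        lines.append("cells.csv: absent")
    fits_path = run_dir / "fits.json"
    if fits_path.exists():
        fits = json.loads(fits_path.read_text())
        lines += ["## Fits", "", "```json", json.dumps(fits, indent=2), "```", ""]
    else:
        lines.append("fits.json: absent")
    msd_path = run_dir / "msd_curves.csv"
    if msd_path.exists() and make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        curves = pd.read_csv(msd_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, sub in curves.groupby("file"):
            ax.plot(sub["lag_s"], sub["msd_um2"], alpha=0.4, lw=0.8)
        mean = curves.groupby("lag_s")["msd_um2"].mean()
        ax.plot(mean.index, mean.values, "k-", lw=2, label="mean over cells")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("MSD (um$^2$)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "msd_curves.png", dpi=120)
        plt.close(fig)
        lines.append("![MSD curves](msd_curves.png)")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
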