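"""Reproducible multi-run optimization campaigns and ensemble summaries.

A campaign runs many independent seeded Monte Carlo searches on one dataset
and one nucleobase target, writes per-run artifacts (trajectory, final
scale), and summarizes the ensemble: mean/SD of the number of moves to a
convergence threshold, the mean unit-rescaled final scale, and per-amino-acid
weight statistics at requested matching levels. Run i uses seed
``base_seed + i`` so a manifest fully determines the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dataset import Proteome
from .genetic_code import AMINO_ACIDS
from .mc import MCConfig, MCTrajectory, moves_to_threshold, run_mc, select_scale_at_level
from .profiles import NucleobaseTarget, ProfileCache
from .scales import AffinityScale, rescale_unit, write_scale

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Campaign:
    """Configuration of one multi-run optimization campaign."""

    target: NucleobaseTarget
    n_runs: int = 1000
    mc: MCConfig = field(default_factory=MCConfig)
    base_seed: int = 0
    threshold: float | None = None  # convergence level for moves-to-threshold
    dataset_path: str = ""
    output_dir: str = ""

    def run_config(self, i: int) -> MCConfig:
        if not 0 <= i < self.n_runs:
            raise ValueError(f"run index {i} outside [0, {self.n_runs})")
        return replace(self.mc, target=self.target, seed=self.base_seed + i)


@dataclass
class CampaignSummary:
    """Ensemble-level results of a campaign."""

    campaign: Campaign
    trajectories: list[MCTrajectory]
    per_run: pd.DataFrame  # run, seed, final_R, moves_to_threshold
    mean_final_scale: AffinityScale
    moves_mean: float | None
    moves_sd: float | None


def proteome_checksum(proteome: Proteome) -> str:
    """SHA-256 over all (id, cds, protein) triples; identifies a dataset exactly."""
    h = hashlib.sha256()
    for pair in proteome:
        h.update(f"{pair.id}\t{pair.cds}\t{pair.protein}\n".encode())
    return h.hexdigest()


def mean_scale(scales: Sequence[AffinityScale], target: str = "", meta: str = "") -> AffinityScale:
    """Elementwise mean of unit-rescaled scales, itself unit-rescaled."""
    if not scales:
        raise ValueError("no scales")
    mean_vec = np.stack([rescale_unit(s).vector for s in scales]).mean(axis=0)
    return rescale_unit(AffinityScale.from_vector(mean_vec, target=target, meta=meta))


def run_campaign(
    campaign: Campaign,
    source: Proteome | ProfileCache,
    write_artifacts: bool = True,
) -> CampaignSummary:
    """Execute all runs of a campaign and summarize the ensemble.

    With ``write_artifacts`` and a configured output directory, writes per-run
    trajectory TSVs and final-scale TSVs plus ``summary.tsv``, the mean final
    scale, and a JSON manifest (package version, config, dataset checksum).
    """
    cache = source if isinstance(source, ProfileCache) else ProfileCache(source)
    outdir = Path(campaign.output_dir) if (write_artifacts and campaign.output_dir) else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    trajectories: list[MCTrajectory] = []
    rows = []
    for i in range(campaign.n_runs):
        traj = run_mc(cache, campaign.run_config(i))
        trajectories.append(traj)
        moves = (
            moves_to_threshold(traj, campaign.threshold)
            if campaign.threshold is not None
            else None
        )
        rows.append(
            {
                "run": i,
                "seed": campaign.base_seed + i,
                "final_R": traj.final_R,
                "moves_to_threshold": moves,
            }
        )
        if outdir is not None:
            _write_trajectory(traj, outdir / f"run{i:04d}_trajectory.tsv")
            write_scale(traj.final_scale, outdir / f"run{i:04d}_scale.tsv")
        logger.info("run %d/%d: final <R> = %.4f", i + 1, campaign.n_runs, traj.final_R)
    per_run = pd.DataFrame(rows)
    final = mean_scale(
        [t.final_scale for t in trajectories],
        target=campaign.target.name,
        meta=f"campaign mean of {campaign.n_runs} runs",
    )
    moves = per_run["moves_to_threshold"].dropna()
    moves_mean = float(moves.mean()) if len(moves) else None
    moves_sd = float(moves.std(ddof=1)) if len(moves) > 1 else None
    summary = CampaignSummary(
        campaign=campaign,
        trajectories=trajectories,
        per_run=per_run,
        mean_final_scale=final,
        moves_mean=moves_mean,
        moves_sd=moves_sd,
    )
    if outdir is not None:
        per_run.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        write_scale(final, outdir / "mean_final_scale.tsv")
        manifest = {
            "package_version": __version__,
            "target": campaign.target.name,
            "n_runs": campaign.n_runs,
            "base_seed": campaign.base_seed,
            "threshold": campaign.threshold,
            "mc_config": {
                k: (v.name if isinstance(v, NucleobaseTarget) else v)
                for k, v in asdict(campaign.mc).items()
            },
            "dataset_path": campaign.dataset_path,
            "dataset_checksum": proteome_checksum(cache.proteome),
            "n_pairs": len(cache),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def _write_trajectory(traj: MCTrajectory, path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("step\tamplitude\tproposal_R\taccepted\tcurrent_R\n")
        for s in traj.states:
            handle.write(
                f"{s.step}\t{s.amplitude:.6g}\t{s.proposal_R:.8f}"
                f"\t{int(s.accepted)}\t{s.current_R:.8f}\n"
            )


def weight_statistics_at_levels(
    trajectories: Sequence[MCTrajectory],
    levels: Sequence[float],
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Per-amino-acid mean and SD of unit-rescaled weights at each matching level.

    For each level, one scale is selected per run (accepted <R> closest to
    the level, within tolerance), unit-rescaled, and summarized columnwise.
    Levels not reached by at least 2 runs are dropped; an error is raised if
    no level is represented at all.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    rows = []
    for level in levels:
        vectors = [
            s.vector
            for t in trajectories
            if (s := select_scale_at_level(t, level, tolerance)) is not None
        ]
        if len(vectors) < 2:
            continue
        W = np.stack(vectors)
        means = W.mean(axis=0)
        sds = W.std(axis=0, ddof=1)
        for j, aa in enumerate(AMINO_ACIDS):
            rows.append(
                {
                    "level": level,
                    "n_scales": len(vectors),
                    "aa": aa,
                    "mean": means[j],
                    "sd": sds[j],
                }
            )
    if not rows:
        raise ValueError("no requested level is represented in any trajectory")
    return pd.DataFrame(rows, columns=["level", "n_scales", "aa", "mean", "sd"])


def level_grid(best_R: float, spacing: float = 0.02) -> list[float]:
    """Matching-level grid from 0 down to the best <R> at fixed spacing."""
    n = int(np.floor(abs(best_R) / spacing))
    sign = -1.0 if best_R < 0 else 1.0
    return [round(sign * spacing * i, 10) for i in range(n + 1)]
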