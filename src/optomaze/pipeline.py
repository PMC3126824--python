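"""End-to-end experiment pipeline.

Mirrors the automated assay loop: render the stimulus movie, quantify its
image regularity (peak spectral power), map regularity to a behavioral
salience, simulate direction-balanced maze populations for each strain,
score Visual Responses, and run the statistical tests. Fully
deterministic for a fixed master seed.

Seed splitting: per-stage seeds are drawn from a ``numpy`` SeedSequence
spawned off the master seed in a fixed order (stimulus first, then one
child per strain), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import scoring, spectral, stats
from .io import ExperimentConfig, write_counts_csv
from .maze_sim import simulate_experiment
from .stimuli import render

__all__ = ["PipelineError", "salience_from_spectrum", "run_pipeline"]

logger = logging.getLogger(__name__)

# Peak power of a full-contrast (0..255 luminance) sinusoid is
# width * 127.5^2 / 4 under the |F|^2/width normalization; dividing by it
# puts salience on a dimensionless 0..~1 scale independent of screen width.
_FULL_CONTRAST_AMPLITUDE = 127.5


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def salience_from_spectrum(summary: spectral.SpectrumSummary) -> float:
    """Normalized image regularity: peak power relative to the peak power
    of a full-contrast sinusoid on the same screen."""
    width = 2 * (len(summary.mean_power) - 1)
    full = width * _FULL_CONTRAST_AMPLITUDE ** 2 / 4.0
    return float(summary.peak_power / full)


def run_pipeline(config: ExperimentConfig) -> Dict:
    """Run render → spectrum → simulate → score → test and return the report.

    When ``config.output_dir`` is set, writes ``counts.csv`` and
    ``report.json`` there; on any stage failure the partial outputs of
    this run are removed and a stage-tagged :class:`PipelineError` raised.
    """
    written: List[Path] = []
    outdir: Optional[Path] = Path(config.output_dir) if config.output_dir else None
    try:
        stage = "render"
        ss = np.random.SeedSequence(config.master_seed)
        children = ss.spawn(1 + len(config.strains))
        render_seed = int(children[0].generate_state(1)[0] % (2 ** 31))
        frames = render(config.stimulus, config.geometry, config.n_frames, render_seed)

        stage = "spectrum"
        summary = spectral.movie_spectrum(frames)
        salience = salience_from_spectrum(summary)

        stage = "simulate"
        all_records = {}
        for strain, child in zip(config.strains, children[1:]):
            seed = int(child.generate_state(1)[0] % (2 ** 31))
            all_records[strain.name] = simulate_experiment(
                strain, salience, config.n_mazes, config.n_flies_per_maze,
                config.loss_prob, seed)

        stage = "score"
        results = {name: scoring.pooled_vr(recs, strain=name)
                   for name, recs in all_records.items()}

        stage = "stats"
        alpha0 = config.alpha_levels.get("vs_zero", 0.01)
        alpha_s = config.alpha_levels.get("strain", 0.01)
        vs_zero = {name: stats.test_vs_zero(res.per_maze_vr, alpha0)
                   for name, res in results.items()}
        names = list(results)
        comparisons = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                key = f"{names[i]}_vs_{names[j]}"
                comparisons[key] = stats.compare_groups(
                    results[names[i]].per_maze_vr, results[names[j]].per_maze_vr,
                    alpha_s)

        report = {
            "master_seed": config.master_seed,
            "salience": salience,
            "peak_power": summary.peak_power,
            "peak_frequency": int(summary.peak_frequency),
            "strains": {
                name: {
                    "vr_mean": res.vr_mean,
                    "vr_sem": res.vr_sem,
                    "n_mazes": res.n_mazes,
                    "n_flies": res.n_flies,
                    "vs_zero": {"test": vs_zero[name].test_name,
                                "p": vs_zero[name].p_value,
                                "significant": vs_zero[name].significant},
                }
                for name, res in results.items()
            },
            "comparisons": {
                key: {"test": rep.test_name, "p": rep.p_value,
                      "significant": rep.significant}
                for key, rep in comparisons.items()
            },
        }

        if outdir is not None:
            stage = "write"
            outdir.mkdir(parents=True, exist_ok=True)
            counts_path = outdir / "counts.csv"
            flat = [r for recs in all_records.values() for r in recs]
            write_counts_csv(flat, counts_path)
            written.append(counts_path)
            report_path = outdir / "report.json"
            report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            written.append(report_path)
        return report
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:  # pragma: no cover
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"[{stage}] {exc}") from exc
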