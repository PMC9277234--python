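"""Shared run configuration for the numbered analysis drivers.

All drivers operate on one pipeline run directory under ``scratch/`` (large
intermediates live there); each copies its small summary tables into
``results/``. Stages are incremental: a driver re-executes only work whose
inputs changed, so the scripts can be run in order or individually.
"""

from pathlib import Path

from symbiopleio.config import RunConfig, SimConfig
from symbiopleio.pipeline import PipelineRunner

_ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = _ROOT / "scratch" / "analysis_run"
RESULTS = _ROOT / "results"


def runner() -> PipelineRunner:
    cfg = RunConfig(sim=SimConfig(seed=20260920))
    RESULTS.mkdir(exist_ok=True)
    return PipelineRunner(cfg, RUN_DIR)
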