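"""Shared plumbing for the numbered analysis scripts: one output directory,
one seed, one config."""

from pathlib import Path

from ctcpheno.config import AnalysisConfig

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 1


def config() -> AnalysisConfig:
    return AnalysisConfig(seed=SEED, outdir=OUTDIR)
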