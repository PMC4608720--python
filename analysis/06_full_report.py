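#!/usr/bin/env python
"""One-shot pipeline run: simulate → descriptors → fingerprint → modes →
cavity → report, with plots, under results/pipeline/."""

from pathlib import Path

from kinastate.pipeline import PipelineConfig, run_pipeline
from kinastate.synthetic import GeneratorConfig


def main() -> None:
    cfg = PipelineConfig(
        outdir="results/pipeline",
        seed=20240901,
        generator=GeneratorConfig(n_frames=2000),
        plots=True,
        log_level="INFO",
    )
    run_pipeline(cfg)
    print(Path("results/pipeline/summary.txt").read_text())


if __name__ == "__main__":
    main()
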