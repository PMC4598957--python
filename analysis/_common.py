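"""Shared configuration of the demo analysis: one synthetic study area."""

from pathlib import Path

from alpgraze.config import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
AREA_DIR = RESULTS / "area_demo"

SEED = 1


def demo_config() -> PipelineConfig:
    """A 48x48-cell (1.2 km square) area, 4 paddocks grazed 7.5 d each,
    3 collared animals tracked for 3 days with device dropouts."""
    return PipelineConfig(
        out_dir=AREA_DIR,
        nrows=48,
        ncols=48,
        n_paddocks=4,
        period_days=7.5,
        herd_lu=50.0,
        n_animals=3,
        track_hours=72.0,
        fail_rate_per_h=0.1,
        recover_rate_per_h=2.0,
        int_strategy="grid",
        seed=SEED,
    )
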