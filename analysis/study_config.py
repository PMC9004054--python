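"""Shared run configuration for the numbered analysis scripts.

The default emulates the wheat study: a 236-line panel with 3 repeated
checks, three environments, seven traits (five primary agronomic, two
physiological secondary) with heritabilities, scales and genetic
correlations patterned on the study's summary tables.  The ``demo`` profile
reduces marker count, chain length and replicate count so the full analysis
runs at desk scale; ``study-scale`` uses 27,466 markers, 2000/12,000 Gibbs
iterations and 100 cross-validation replicates.
"""

from pathlib import Path

from mtgs.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"


def study_config(seed: int = 1, profile: str = "demo") -> RunConfig:
    return RunConfig(
        out_dir=str(RESULTS),
        seed=seed,
        profile=profile,
        cv_primary_traits=("GY",),  # demo runs one primary trait end-to-end
    )
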