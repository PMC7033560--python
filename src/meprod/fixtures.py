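"""Small packaged datasets for docs, examples, and oracle tests.

Everything is generated programmatically (synthetic plexes with known ground
truth); nothing is shipped as data files.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .io import write_peptide_table
from .simulate import (
    build_ground_truth,
    scenario_preset,
    simulate_acquisition,
    write_ground_truth,
)


def make_fixtures(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write the worked-example fixture set (<=200 proteins).

    Two variants of the low dilution series are produced:

    ``noiseless/``
        Detection threshold 0, no interference, no reporter noise — the
        configuration under which the processing chain inverts the forward
        model exactly (oracle tests).
    ``default/``
        The standard noise calibration (CV 8%, 3% interference,
        auto-calibrated detection threshold).

    Returns a mapping of variant name to its directory.
    """
    out_dir = Path(out_dir)
    written: dict[str, Path] = {}
    for variant in ("noiseless", "default"):
        design, config = scenario_preset("dilution_low", seed)
        config = replace(config, n_proteins=150)
        if variant == "noiseless":
            config = replace(
                config,
                detection_threshold=0.0,
                interference_fraction=0.0,
                reporter_cv=0.0,
            )
        truth = build_ground_truth(config, design)
        records = simulate_acquisition(truth, design, config)
        target = out_dir / variant
        target.mkdir(parents=True, exist_ok=True)
        write_peptide_table(records, design, target / "peptides.tsv")
        design.save(target / "design.yaml")
        write_ground_truth(truth, design, target / "truth.tsv")
        written[variant] = target
    return written
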