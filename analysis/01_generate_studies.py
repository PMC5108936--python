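#!/usr/bin/env python
"""Generate the synthetic reading and writing studies.

Emulates the three laboratory designs: a large at-home reading study
(65 participants x 20 threads: 9 negative, 9 positive, 2 neutral, with
7-point Likert-quantized reports), a smaller lab reading study
(53 participants x 7 threads: 3/3/1), and a writing study (65 participants
x 4 posts with pre/post emotion reports and per-post sentiment scores).
All datasets are written under results/data/ with sidecar manifests.
"""

import sys
from pathlib import Path

from emodyn.params import reference_expression_coeffs, reference_params
from emodyn.synth import (
    ReadingStudyDesign,
    generate_reading_study,
    generate_writing_study,
    write_dataset,
)

SEED = 0
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = reference_params()
    coeffs = reference_expression_coeffs()

    home = ReadingStudyDesign(
        n_participants=65, thread_counts=(9, 9, 2), quantize=True, seed=SEED
    )
    lab = ReadingStudyDesign(
        n_participants=53, thread_counts=(3, 3, 1), quantize=True, seed=SEED + 1
    )
    for name, design in (("reading_home", home), ("reading_lab", lab)):
        df = generate_reading_study(design, params)
        write_dataset(df, OUT / f"{name}.csv", design.seed, design.to_dict())
        print(
            f"{name}: {df['participant_id'].nunique()} participants, "
            f"{len(df)} reading events "
            f"(mean duration {df['duration_min'].mean():.2f} min)"
        )

    writing = generate_writing_study(65, params, coeffs, seed=SEED + 2)
    write_dataset(writing, OUT / "writing_study.csv", SEED + 2, {"n_participants": 65})
    print(f"writing_study: {len(writing)} posts from 65 participants (4 tasks each)")
    print(f"datasets written to {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
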