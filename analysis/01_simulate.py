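#!/usr/bin/env python
"""Generate the three synthetic sample-type datasets used by the analysis.

Emulates the study design: 3 high-health (HHS) + 3 low-health (LHS)
farms, 2 pooled samples per farm per sample type, with genus inventories
sized like the post-filter tables of the motivating study (57 wall, 95
slat, 259 slurry genera). Ten genera per sample type carry a known
between-status shift of 2 between-sample SDs; the ground truth is written
next to each table so later stages can be scored against it.
"""

from pathlib import Path

import farmbiome as fb

RESULTS = Path(__file__).resolve().parent.parent / "results"
SAMPLE_TYPES = {"wall": 57, "slat": 95, "slurry": 259}
BASE_SEED = 20240703


def main() -> None:
    for i, (sample_type, n_genera) in enumerate(SAMPLE_TYPES.items()):
        config = fb.SimulationConfig(
            n_genera=n_genera,
            n_differential=10,
            effect_size=2.0,
            sample_type=sample_type,
            seed=BASE_SEED + i,
        )
        counts, meta, truth = fb.generate_dataset(config)
        out = RESULTS / "data" / sample_type
        paths = fb.write_dataset(counts, meta, truth, out)
        print(
            f"{sample_type}: {counts.shape[0]} samples x {counts.shape[1]} genera, "
            f"{len(truth.differential_genus_ids)} differential -> {out}"
        )
        for p in paths.values():
            print(f"  wrote {p.relative_to(RESULTS.parent)}")


if __name__ == "__main__":
    main()
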