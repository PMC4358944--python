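#!/usr/bin/env python
"""Generate one example of each synthetic input class and record its ground truth.

Writes a dual-channel confocal stack, a stained-section label map and a set of
western-blot lane profiles under results/simulated/, together with a CSV of
the ground-truth values each downstream analysis should recover.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from airwayquant.io import write_labelmap, write_stack
from airwayquant.synthetic import (
    BandSpec,
    ColocSimSpec,
    GelSimSpec,
    LaneSpec,
    SectionSimSpec,
    make_coloc_stack,
    make_gel,
    make_section_labelmap,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1


def main() -> None:
    truth_rows = []

    stack, masks, realized = make_coloc_stack(
        ColocSimSpec(true_coloc_fraction=0.6, seed=SEED)
    )
    write_stack(stack, OUT / "example_stack.tif")
    truth_rows.append(
        {"input": "dual_channel_stack", "quantity": "realized_coloc_fraction", "value": realized}
    )
    print(
        f"stack: {stack.shape} voxels, {masks['green'].sum()} green object voxels, "
        f"realized colocalized fraction {realized:.3f}"
    )

    labelmap, fractions = make_section_labelmap(SectionSimSpec(seed=SEED))
    write_labelmap(labelmap, OUT / "example_labelmap.tif")
    for k, v in fractions.items():
        truth_rows.append({"input": "section_labelmap", "quantity": k, "value": v})
    print(
        f"section: {labelmap.shape} px, gland fraction {fractions['gland_fraction']:.3f}, "
        f"positive-within-gland {fractions['positive_fraction']:.3f}"
    )

    gel = make_gel(
        GelSimSpec(
            lanes=(
                LaneSpec(
                    bands=(
                        BandSpec("75kDa", 90.0, 1.0),
                        BandSpec("65kDa", 180.0, 0.5),
                        BandSpec("beta-actin", 300.0, 1.0),
                    )
                ),
            ),
            seed=SEED,
        )
    )
    np.savetxt(OUT / "example_lane_profiles.csv", gel.profiles.T, delimiter=",")
    for _, row in gel.truth.iterrows():
        truth_rows.append(
            {"input": "gel_lane", "quantity": f"abundance_{row.label}", "value": row.abundance}
        )
    print(f"gel: {len(gel.profiles)} lane(s), bands {list(gel.truth.label)}")

    pd.DataFrame(truth_rows).to_csv(OUT / "ground_truth.csv", index=False)
    print(f"wrote inputs and ground truth under {OUT}")


if __name__ == "__main__":
    main()
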