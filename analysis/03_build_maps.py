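"""Project, mask, warp and interpolate: build the excitability maps.

MEP-positive pulses are projected to the subject mesh, masked to the
precentral band, warped to the template sphere-to-sphere, and spread to
MEP-weighted vertex maps by geodesic inverse-distance interpolation.
Maps are written as one long table (subject, condition, muscle,
vertex_id, mep).
"""

import pandas as pd

from common import CONFIG, results_dir
from tmsmap.pipeline import build_maps, simulate_cohort


def main() -> None:
    out = results_dir()
    cohort = simulate_cohort(CONFIG)
    mep_table = pd.read_csv(out / "mep_table.csv")
    maps, counters = build_maps(cohort, mep_table, CONFIG)

    rows = []
    for (sid, cond, muscle), emap in maps.items():
        for v, w in zip(emap.vertex_ids, emap.mep):
            rows.append(
                {"subject": sid, "intensity_condition": cond, "muscle": muscle,
                 "vertex_id": int(v), "mep": float(w)}
            )
    long = pd.DataFrame(rows)
    long.to_csv(out / "maps_long.csv", index=False)

    print(f"built {len(maps)} maps "
          f"({CONFIG.n_subjects} subjects x {CONFIG.n_intensities} conditions x 8 muscles)")
    print(f"stimulations inside mask: {counters['stims_in_mask']}, "
          f"outside: {counters['stims_out_of_mask']}, "
          f"MEP-positive retained: {counters['mep_positive']}")
    sizes = long.groupby(["subject", "intensity_condition", "muscle"]).size()
    print(f"map support: median {int(sizes.median())} vertices "
          f"(range {int(sizes.min())}-{int(sizes.max())})")
    print(f"wrote maps_long.csv ({len(long)} rows) -> {out}")


if __name__ == "__main__":
    main()
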