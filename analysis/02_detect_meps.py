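"""Filter every stimulation-locked EMG sweep and classify MEP / non-MEP.

Regenerates the cohort deterministically, runs the 30 Hz zero-phase
high-pass filter and the amplitude rules (peak-to-peak > 20 x baseline
SD, < 10 mV) on all traces, and writes the per-pulse MEP table.
"""

from common import CONFIG, results_dir
from tmsmap.pipeline import detect_cohort, simulate_cohort


def main() -> None:
    out = results_dir()
    cohort = simulate_cohort(CONFIG)
    mep_table = detect_cohort(cohort, CONFIG)
    mep_table.to_csv(out / "mep_table.csv", index=False)

    yield_by_muscle = mep_table.groupby("muscle").is_mep.mean().sort_values(ascending=False)
    print(f"classified {len(mep_table)} pulse x muscle traces")
    print("MEP yield per muscle (fraction of pulses accepted):")
    for muscle, frac in yield_by_muscle.items():
        print(f"  {muscle:4s} {frac:.3f}")
    reasons = mep_table[~mep_table.is_mep].reason.value_counts()
    print("rejections:", dict(reasons))
    print(f"wrote mep_table.csv -> {out}")


if __name__ == "__main__":
    main()
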