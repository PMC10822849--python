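#!/usr/bin/env python
"""Simulate a demonstration RF cohort with known ground truth.

Generates a 20-patient two-class cohort (5 nonresponders, 15 responders,
four image planes each) whose tumour cores differ in scatterer radius and
number density between classes, plus the reference-phantom frame every
later stage normalizes against.  The RF frames go to scratch/ (they are
large); the ground-truth manifest, the quantity later stages must recover,
goes to results/.
"""

from pathlib import Path

from qusresponse import CohortConfig, generate_cohort, save_cohort

SEED = 17

def main() -> None:
    Path("results").mkdir(exist_ok=True)
    Path("scratch").mkdir(exist_ok=True)
    config = CohortConfig(n_nr=5, n_rr=15, frames_per_patient=(4, 4))
    cohort = generate_cohort(config, seed=SEED)
    save_cohort(cohort, "scratch/demo_cohort.h5", "results/demo_cohort_manifest.csv")

    m = cohort.manifest()
    print(f"generated {len(cohort)} patients "
          f"({(m.label == 'NR').sum()} NR / {(m.label == 'RR').sum()} RR), "
          f"{int(m.n_frames.sum())} RF frames at seed {SEED}")
    print("per-class ground truth (core scatterers):")
    print(m.groupby("label")[["true_core_radius_um", "true_core_density_per_mm2"]]
          .mean().round(2).to_string())
    print("wrote scratch/demo_cohort.h5 and results/demo_cohort_manifest.csv")


if __name__ == "__main__":
    main()
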