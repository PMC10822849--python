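#!/usr/bin/env python
"""Extract frozen-backbone features for the demonstration cohort.

Renders every frame's spectral-slope (SS) map to a 224x224 image, pushes it
through the frozen convolutional backbone (7x7x2048 -> 100,352 values) and
averages across each patient's image planes.  The per-patient table is
cached for the classification step; a small summary goes to results/.
"""

import numpy as np

from qusresponse import load_cohort
from qusresponse.pipeline import cohort_feature_tables

def main() -> None:
    cohort = load_cohort("scratch/demo_cohort.h5")
    table = cohort_feature_tables(cohort, parameters=("SS",))["SS"]
    np.savez_compressed("scratch/demo_features_ss.npz",
                        X=table.X, y=table.y, patient_ids=table.patient_ids)
    nz = (table.X != 0).mean(axis=0)
    print(f"feature table: {table.X.shape[0]} patients x {table.X.shape[1]} features")
    print(f"features nonzero in >=90% of patients: {(nz >= 0.9).sum()}")
    summary = table.manifest()
    summary["mean_activation"] = table.X.mean(axis=1)
    summary.to_csv("results/demo_feature_summary.csv", index=False)
    print("wrote scratch/demo_features_ss.npz and results/demo_feature_summary.csv")


if __name__ == "__main__":
    main()
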