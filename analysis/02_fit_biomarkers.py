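"""Estimate the mathematical biomarkers from burden trajectories.

Fits (mu, Lambda) for every patient by least squares on log burden with the
patient's intrinsic growth rate alpha0 fixed, computes alpha1 from the
first-restaging observation, assigns the favorable/unfavorable prognostic
group (threshold 0.002 / day), and — because this cohort is synthetic —
reports how well the fits recover the generator's true parameters.
Writes results/biomarkers/biomarkers.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from icisurv.cohort import CohortSpec, generate_cohort
from icisurv.mechanistic import fit_biomarker_table

OUT = Path(__file__).resolve().parent.parent / "results" / "biomarkers"
SEED = 42


def main() -> None:
    cohort, burden, _ = generate_cohort(CohortSpec(n_patients=93, seed=SEED))
    alpha0 = dict(zip(cohort["patient_id"], cohort["alpha0"]))
    fits = fit_biomarker_table(burden, alpha0_by_patient=alpha0, seed=SEED)

    OUT.mkdir(parents=True, exist_ok=True)
    fits.to_csv(OUT / "biomarkers.csv", index=False)

    merged = fits.merge(cohort[["patient_id", "mu", "Lambda"]],
                        on="patient_id", suffixes=("_fit", "_true"))
    mu_err = np.abs(merged["mu_fit"] - merged["mu_true"])
    print(f"fitted {len(fits)} patients; median RSS {fits['rss'].median():.3g}")
    print(f"mu recovery: median abs error {mu_err.median():.4g} "
          f"(90th pct {mu_err.quantile(0.9):.4g}) under "
          f"{CohortSpec().noise_sigma:.0%} lognormal measurement noise")
    print("\nprognostic groups by alpha1 (favorable iff <= 0.002 / day):")
    print(fits["prognostic_group"].value_counts().to_string())


if __name__ == "__main__":
    main()
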