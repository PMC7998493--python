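"""Generate the demo cohort: 44 women x 3 visits, 17 antioxidant biomarkers.

Writes two CSVs under results/: the clean cohort, and a variant with two
injected aberrant subjects (one with 10x inflated within-subject spread
in uric acid, one with a +6 SD mean shift in beta-carotene) used by the
screening and sensitivity drivers.
"""

from pathlib import Path

from biovariation import (
    OutlierInjection,
    default_cohort_spec,
    generate_cohort,
    inject_outliers,
    write_cohort,
)
from biovariation.synthetic_cohort import spec_to_yaml

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

spec = default_cohort_spec(seed=42)
clean = generate_cohort(spec)
write_cohort(clean, RESULTS / "cohort.csv")
spec_to_yaml(spec, RESULTS / "cohort_spec.yaml")

spec.outliers = [
    OutlierInjection(subject=6, kind="variance_inflation", magnitude=10.0,
                     biomarker="uric_acid"),
    OutlierInjection(subject=17, kind="mean_shift", magnitude=6.0,
                     biomarker="beta_carotene"),
]
perturbed = inject_outliers(clean, spec)
write_cohort(perturbed, RESULTS / "cohort_outliers.csv")

print(f"cohort: {clean.n_subjects} subjects x {clean.n_visits} visits, "
      f"{len(clean.biomarkers)} biomarkers, {len(clean.covariates)} covariates")
print(f"wrote {RESULTS/'cohort.csv'} and {RESULTS/'cohort_outliers.csv'}")
print("injected: S007 uric_acid within-variance x10, "
      "S018 beta_carotene mean +6 SD")
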