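#!/usr/bin/env python
"""Simulate the three study cohorts and write them as plain-text tables.

Generates (seed 0) an autopsy cohort with one concentration matrix per
brain region, a preclinical serum cohort followed for conversion to
incident AD, and a prodromal CN/MCI/AD serum cohort, with AD-like effects
planted on four sphingolipid-analog metabolites. Ground-truth parameters go
to ``truth.yaml`` beside each cohort.
"""

from common import COHORT_DIR, CONFIG, PLANTED

from easead.io import write_cohort
from easead.synthetic import (
    generate_brain_cohort,
    generate_preclinical_cohort,
    generate_prodromal_cohort,
)


def main() -> None:
    synth = CONFIG.synthetic
    cohorts = {
        "brain": generate_brain_cohort(synth),
        "preclinical": generate_preclinical_cohort(synth),
        "prodromal": generate_prodromal_cohort(synth),
    }
    for name, cohort in cohorts.items():
        write_cohort(cohort, COHORT_DIR / name)

    brain = cohorts["brain"]
    precl = cohorts["preclinical"]
    print(f"wrote cohorts to {COHORT_DIR}")
    print(f"  brain: {len(brain.neuropath)} subjects × {len(brain.concentrations)} "
          f"regions, {synth.n_metabolites} metabolites")
    n_conv = int(precl.survival['event'].sum())
    print(f"  preclinical: {len(precl.survival)} subjects, {n_conv} converters, "
          f"{(precl.metadata['metso'] > 5).sum()} samples with Met-So > 5 μM")
    print(f"  prodromal: {len(cohorts['prodromal'].metadata)} subjects")
    print(f"  planted AD-like sphingolipid analogs: {', '.join(PLANTED)}")


if __name__ == "__main__":
    main()
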