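"""Shared fixtures.

The atrophy-study fixtures are session-scoped: building aligned cohorts
involves hundreds of registrations, and the specificity, agreement and
variance checks all inspect the same two pipeline runs.
"""

import numpy as np
import pytest

from gwtbss import evalsim, phantom, reference


@pytest.fixture(scope="session")
def template():
    return phantom.make_template(seed=0)


@pytest.fixture(scope="session")
def standard_template(template):
    return phantom.make_standard_template(template)


@pytest.fixture(scope="session")
def study():
    """Canonical study inputs: (template, std template, controls, targets)."""
    return evalsim.make_study_inputs(seed=0)


@pytest.fixture(scope="session")
def specificity_groups(study):
    tpl, std, controls, targets = study
    smoothed, warped, sigma, fields = evalsim.make_specificity_cohort(controls, targets)
    return smoothed, warped, sigma, fields


@pytest.fixture(scope="session")
def st_specificity(study, specificity_groups):
    tpl, std, controls, targets = study
    smoothed, warped, _, _ = specificity_groups
    return evalsim.run_specificity(smoothed, warped, "ST", tpl.tract_labels, std,
                                   seed=5, label_space_fa=tpl.fa_volume)


@pytest.fixture(scope="session")
def gw_specificity(study, specificity_groups):
    tpl, std, controls, targets = study
    smoothed, warped, _, _ = specificity_groups
    return evalsim.run_specificity(smoothed, warped, "GW", tpl.tract_labels, std,
                                   seed=5, label_space_fa=tpl.fa_volume)


@pytest.fixture(scope="session")
def ss_cohort(study, specificity_groups):
    tpl, std, controls, targets = study
    smoothed, warped, _, _ = specificity_groups
    cohort, _ = reference.build_cohort([*smoothed, *warped], std, "SS")
    return cohort


@pytest.fixture(scope="session")
def small_warped_pair(template):
    """(warped volume, true field) with a planted 2-voxel-amplitude field."""
    vol = template.fa_volume
    rng = np.random.default_rng(7)
    fld = phantom._random_smooth_field(vol.shape, vol.voxel_size, 4.0, 8.0, rng)
    from gwtbss import imgreg
    return imgreg.resample(vol, fld, boundary="extend"), fld
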