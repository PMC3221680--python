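"""Bundled example cohort, generated programmatically.

``load_example_cohort`` builds a synthetic (labelled as such) cohort shaped
like the study design: 79 patients, 43 with liver metastasis, 16 matched
primary/metastasis pairs over the 13 candidate loci, with three THBS1
measurements knocked out (one primary, two metastases, distinct patients) so
the paired enumeration yields 205 measurement pairs.
"""

from __future__ import annotations

import numpy as np

from .cohort import validate_metadata
from .simulate import Cohort, SyntheticConfig, generate_cohort

__all__ = ["load_example_cohort", "EXAMPLE_SEED"]

EXAMPLE_SEED = 20111121


def load_example_cohort(seed: int = EXAMPLE_SEED) -> Cohort:
    """Deterministic synthetic example cohort (see module docstring)."""
    cohort = generate_cohort(SyntheticConfig(seed=seed))
    data = cohort.matrix.data
    # knock out THBS1 in one primary and two metastases of distinct pairs
    data.loc["P001_P", "THBS1"] = np.nan
    data.loc["P002_M", "THBS1"] = np.nan
    data.loc["P003_M", "THBS1"] = np.nan
    validate_metadata(cohort.meta)
    return cohort
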