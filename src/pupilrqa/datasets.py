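"""Bundled cohort tables.

``load_observed_cohort`` returns the 26-subject feature table (age, Epworth
Sleepiness Scale, entropy, determinism, mean pupil percent change);
``load_simulated_cohort`` returns the 100-row Gaussian-copula expansion of
it. Both ship with the package so the population-level analysis is fully
reproducible offline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("pupilrqa.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_observed_cohort() -> pd.DataFrame:
    """26-subject observed cohort feature table."""
    return _load("cohort_observed.csv")


def load_simulated_cohort() -> pd.DataFrame:
    """100-row Gaussian-copula simulated cohort."""
    return _load("cohort_simulated.csv")
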