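import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ftmseda import FTMSDataset, GroupDefinition

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def build_dataset(values, samples, formulas=None, mass_ids=None,
                  masses=None, isotopes=None, encoded=True) -> FTMSDataset:
    """Construct a small dataset from literal values.

    ``values`` is a peaks x samples array with np.nan for missing cells (or
    0 if ``encoded`` is False); ``formulas`` is a list of formula strings or
    None per peak.
    """
    from ftmseda.formulas import ELEMENTS, parse_formula

    values = np.asarray(values, dtype=float)
    n_peaks = values.shape[0]
    if mass_ids is None:
        mass_ids = [f"m{i + 1}" for i in range(n_peaks)]
    peak = pd.DataFrame(values, index=pd.Index(mass_ids, name="Mass"),
                        columns=samples)
    mol = pd.DataFrame(index=peak.index)
    formulas = formulas if formulas is not None else [None] * n_peaks
    mol["Formula"] = [f if f else np.nan for f in formulas]
    for el in ELEMENTS:
        mol[el] = [float(parse_formula(f)[el]) if f else np.nan for f in formulas]
    if masses is not None:
        mol["Mass"] = masses
    if isotopes is not None:
        mol["Isotope"] = isotopes
    return FTMSDataset(peak, mol, data_scale="abundance", missing_code=0,
                       missing_encoded=encoded)


@pytest.fixture
def toy_ds() -> FTMSDataset:
    """Five peaks x four samples with familiar formulas."""
    values = [
        [10.0, 20.0, np.nan, np.nan],   # glucose: group A only
        [5.0, np.nan, 7.0, 8.0],
        [np.nan, np.nan, 3.0, 4.0],     # group B only
        [1.0, 2.0, 3.0, 4.0],           # everywhere
        [np.nan, 6.0, np.nan, 9.0],     # no formula
    ]
    return build_dataset(
        values,
        samples=["A_s1", "A_s2", "B_s1", "B_s2"],
        formulas=["C6H12O6", "C18H36O2", "C6H6", "C10H14N2", None],
        masses=[180.06339, 284.27153, 78.04695, 162.11570, 123.45678],
    )


@pytest.fixture
def toy_groups() -> GroupDefinition:
    return GroupDefinition({"A_s1": "A", "A_s2": "A", "B_s1": "B", "B_s2": "B"})
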