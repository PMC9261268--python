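"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from plastccs import SyntheticConfig, consolidate, generate_ccs_dataset
from plastccs.synthetic import generate_mock_descriptors

# ~30 real plastic-additive / plastic-related structures for backend tests
# (plasticizers, antioxidants, flame retardants, bisphenols, UV stabilizers).
PLASTIC_ADDITIVE_SMILES = {
    "triphenyl phosphate": "O=P(Oc1ccccc1)(Oc1ccccc1)Oc1ccccc1",
    "tri-n-butyl phosphate": "CCCCOP(=O)(OCCCC)OCCCC",
    "tris(2-chloroethyl) phosphate": "ClCCOP(=O)(OCCCl)OCCCl",
    "tris(2,4-ditert-butylphenyl) phosphate":
        "CC(C)(C)c1ccc(OP(=O)(Oc2ccc(C(C)(C)C)cc2C(C)(C)C)"
        "Oc2ccc(C(C)(C)C)cc2C(C)(C)C)c(C(C)(C)C)c1",
    "diethyl phthalate": "CCOC(=O)c1ccccc1C(=O)OCC",
    "dibutyl phthalate": "CCCCOC(=O)c1ccccc1C(=O)OCCCC",
    "bis(2-ethylhexyl) phthalate": "CCCCC(CC)COC(=O)c1ccccc1C(=O)OCC(CC)CCCC",
    "dimethyl phthalate": "COC(=O)c1ccccc1C(=O)OC",
    "benzyl butyl phthalate": "CCCCOC(=O)c1ccccc1C(=O)OCc1ccccc1",
    "bisphenol A": "CC(C)(c1ccc(O)cc1)c1ccc(O)cc1",
    "bisphenol S": "O=S(=O)(c1ccc(O)cc1)c1ccc(O)cc1",
    "bisphenol F": "C(c1ccc(O)cc1)c1ccc(O)cc1",
    "butylated hydroxytoluene": "Cc1cc(C(C)(C)C)c(O)c(C(C)(C)C)c1",
    "butylated hydroxyanisole": "COc1ccc(O)c(C(C)(C)C)c1",
    "2,4-di-tert-butylphenol": "CC(C)(C)c1ccc(O)c(C(C)(C)C)c1",
    "benzophenone": "O=C(c1ccccc1)c1ccccc1",
    "benzophenone-3": "COc1ccc(C(=O)c2ccccc2)c(O)c1",
    "octocrylene": "CCCCC(CC)COC(=O)C(=C(c1ccccc1)c1ccccc1)C#N",
    "atrazine": "CCNc1nc(Cl)nc(NC(C)C)n1",
    "diuron": "CN(C)C(=O)Nc1ccc(Cl)c(Cl)c1",
    "triclosan": "Oc1cc(Cl)ccc1Oc1ccc(Cl)cc1Cl",
    "caprolactam": "O=C1CCCCCN1",
    "laurolactam": "O=C1CCCCCCCCCCCN1",
    "erucamide": "CCCCCCCC/C=C\\CCCCCCCCCCCC(N)=O",
    "oleamide": "CCCCCCCC/C=C\\CCCCCCCC(N)=O",
    "stearamide": "CCCCCCCCCCCCCCCCCC(N)=O",
    "dicyclohexyl phthalate": "O=C(OC1CCCCC1)c1ccccc1C(=O)OC1CCCCC1",
    "triacetin": "CC(=O)OCC(OC(C)=O)COC(C)=O",
    "tributyl citrate": "CCCCOC(=O)CC(O)(CC(=O)OCCCC)C(=O)OCCCC",
    "irganox 1076 fragment (3,5-di-tert-butyl-4-hydroxyphenyl)":
        "CC(C)(C)c1cc(CCC(=O)OC)cc(C(C)(C)C)c1O",
    "tinuvin 327":
        "CC(C)(C)c1cc(C(C)(C)C)c(O)c(-n2nc3ccc(Cl)cc3n2)c1",
}


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_compounds=250, seed=11)


@pytest.fixture(scope="session")
def raw_records(small_config):
    return generate_ccs_dataset(small_config)


@pytest.fixture(scope="session")
def consolidated(raw_records):
    return consolidate(raw_records).records


@pytest.fixture(scope="session")
def mock_matrix(raw_records):
    return generate_mock_descriptors(raw_records, seed=11)


@pytest.fixture(scope="session")
def ccs_by_key(consolidated):
    return {c.inchikey: c.median_ccs for c in consolidated}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
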