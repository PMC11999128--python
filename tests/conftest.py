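import numpy as np
import pytest

from dmtransit import cohort as cohort_mod
from dmtransit import nlp

# The two worked-example consultation notes used throughout the NLP tests.
NOTE_POLYPHARMACY = (
    "67 YEAR OLD PATIENT WITH HBP ON HANDLING WITH INSULIN GLARGINE 52 UNITS "
    "AT NIGHT ASPART 12-12-12 ASA 100X1 OMEPRAZOLE 20X1 PREDNISOLONE 5X1 "
    "TESTOSTERONE 250 MG MONTH LOSARTAN+HYDROCHLOROTHIAZIDE 50+12.5X2 "
    "ROSUVASTATIN 20X1 IMMUNOSUPPRESSANTS CARBAMAZEPINE 200X1 CLOPIDOGREL "
    "75X1 MYCOPHENOLATE 360MGX3 METOPROLOL SUCCINATE 50X1 "
    "Empagliflozin+Metformin 12.5mg/850mg Tab 1 e/12h"
)
NOTE_NON_ADHERENT = (
    "Seventy-year-old patient with type II diabetes diagnostic. HbA1c on "
    "target, hypertension is not controlled due to a decrease in the "
    "enalapril dose. Special emphasis on adhering to the pharmacological "
    "treatment and on sticking to a healthy diet. General recommendations of "
    "a healthy lifestyle. Next appointment should be scheduled within 3 months."
)

EXPECTED_POLYPHARMACY_DRUGS = {
    "insulin glargine",
    "insulin aspart",
    "omeprazole",
    "testosterone",
    "losartan+hydrochlorothiazide",
    "rosuvastatin",
    "carbamazepine",
    "clopidogrel",
    "mycophenolate",
    "metoprolol succinate",
    "empagliflozin+metformin",
}


@pytest.fixture(scope="session")
def lexicon() -> nlp.Lexicon:
    return nlp.default_lexicon()


@pytest.fixture(scope="session")
def templates() -> dict:
    return cohort_mod.default_templates()


@pytest.fixture(scope="session")
def small_cohort():
    """200 patients, three years, default noise — shared read-only."""
    config = cohort_mod.CohortConfig(n_patients=200, seed=42)
    return cohort_mod.generate_cohort(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
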