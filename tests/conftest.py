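import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from wishdiet import load_index

# Published population mean intakes (g/day) with their direction-of-change
# labels, used to check the labelling rule end to end.
POPULATION_MEANS = {
    "whole_grains": (1.0, "Increase"),
    "vegetables": (222.5, "Increase"),
    "fruits": (56.7, "Increase"),
    "dairy": (3.3, "Increase"),
    "red_meat": (126.1, "Decrease"),
    "fish": (35.6, "Decrease"),
    "eggs": (25.1, "Decrease"),
    "poultry": (37.7, "Decrease"),
    "legumes": (61.1, "Increase"),
    "nuts": (2.3, "Increase"),
    "unsat_oils": (6.5, "Increase"),
    "sat_oils": (0.2, "Good"),
    "added_sugars": (1.1, "Good"),
}

#: A diet hitting every component's full-score region exactly.
FULL_SCORE_DIET = {
    "whole_grains": 125.0,
    "vegetables": 300.0,
    "fruits": 200.0,
    "dairy": 250.0,
    "red_meat": 0.0,
    "fish": 28.0,
    "eggs": 0.0,
    "poultry": 0.0,
    "legumes": 75.0,
    "nuts": 50.0,
    "unsat_oils": 40.0,
    "sat_oils": 0.0,
    "added_sugars": 0.0,
}


@pytest.fixture(scope="session")
def index():
    return load_index()
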