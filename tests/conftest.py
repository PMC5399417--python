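import csv

import pytest

from patdisc import Dataset, TargetSpec, read_table

# Six-record illustrative dataset of categorical patient data: five nominal
# predictors, a rare Bleeding = Yes target (prevalence 2/6), and four
# missing cells scattered over the predictors.
TABLE1_HEADER = ["Gender", "PCI History", "Hemoglobin", "Diabetes", "CRP", "Bleeding"]
TABLE1_ROWS = [
    ("Male", "Yes", "Abnormal", "No", "Abnormal", "Yes"),
    ("Female", "No", "Abnormal", "N/A", "Abnormal", "No"),
    ("Male", "No", "N/A", "No", "Normal", "No"),
    ("N/A", "Yes", "Normal", "No", "Normal", "No"),
    ("Female", "Yes", "N/A", "No", "Abnormal", "Yes"),
    ("Male", "No", "Normal", "No", "Normal", "No"),
]

CANDIDATE_ATTRS = ("PCI History", "Hemoglobin", "CRP")
CANDIDATE_VALUES = ("Yes", "Abnormal", "Abnormal")


def write_table1_csv(path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TABLE1_HEADER)
        w.writerows(TABLE1_ROWS)
    return path


@pytest.fixture(scope="session")
def table1(tmp_path_factory) -> Dataset:
    path = tmp_path_factory.mktemp("data") / "table1.csv"
    write_table1_csv(path)
    return read_table(path, format="csv", target_name="Bleeding")


@pytest.fixture(scope="session")
def bleeding() -> TargetSpec:
    return TargetSpec("Bleeding", "Yes")
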