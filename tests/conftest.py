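import pytest

from mirmeta import load_fixture

# Chip datasets whose cancer arm is adenocarcinoma; their case-arm total (350)
# equals the stated adenocarcinoma chip sample count. GSE51853 predominantly
# profiles the squamous subtype but appears in the adenocarcinoma dataset
# listing, so analyses are run with and without it.
LUAD_CHIP_KEYS = [
    "GSE19945", "GSE27486", "GSE29248", "GSE33045", "GSE40738",
    "GSE47525", "GSE48414", "GSE56036", "GSE93300",
]
GSE51853 = "GSE51853"


@pytest.fixture(scope="session")
def chips():
    return load_fixture("table5_chips")


@pytest.fixture(scope="session")
def chip_counts():
    return load_fixture("table5_counts")


@pytest.fixture(scope="session")
def groups():
    return {f"table{i}": load_fixture(f"table{i}_groups") for i in (1, 2, 3, 4)}


def by_variable(rows, variable, table_id=None):
    return [r for r in rows
            if r.variable == variable and (table_id is None or r.table_id == table_id)]
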