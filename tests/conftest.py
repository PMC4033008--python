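import pytest

import drugwelfare as dw

BASE_THRESHOLD = 100_000.0


@pytest.fixture(scope="session")
def basket_and_welfare():
    """The bundled published basket and its printed welfare column."""
    return dw.table2_fixture()


@pytest.fixture(scope="session")
def basket(basket_and_welfare):
    return basket_and_welfare[0]


@pytest.fixture(scope="session")
def welfare_column(basket_and_welfare):
    return basket_and_welfare[1]


@pytest.fixture(scope="session")
def populated_basket(basket, welfare_column):
    """Basket with users back-derived from the printed base-case welfare."""
    return dw.populate_users(basket, welfare_column, BASE_THRESHOLD)


@pytest.fixture(scope="session")
def bundled_tables():
    return dw.basket_io.load_bundled_adjustment_tables()
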