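import pandas as pd
import pytest

from fishplasma import catalog, fpm


@pytest.fixture(scope="session")
def fixture44():
    return catalog.load_fixture()


@pytest.fixture(scope="session")
def trout_screen(fixture44):
    """Full screen of the packaged table against rainbow trout."""
    ctx = fixture44.species["rainbow_trout"]
    rfu_by_api = {
        row["name"]: row["rfu_trout_max"]
        for _, row in fixture44.table.iterrows()
        if pd.notna(row["rfu_trout_max"])
    }
    results, errors = fpm.screen(fixture44.apis, ctx, rfu_by_api)
    assert not errors
    return {r.api_name: r for r in results}
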