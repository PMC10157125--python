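import pytest

from domiscore import (
    Assessment,
    load_packaged_grid,
    load_packaged_matrix,
)
from domiscore.grid import (
    CategoryDefinition,
    GridDefinition,
    VariableDefinition,
)

LEVELS = {i: f"level {i}" for i in range(4)}


def make_variable(vid, cat, pos, alert=None):
    return VariableDefinition(
        id=vid,
        label=vid.replace("_", " "),
        category_id=cat,
        position=pos,
        sources=["in_situ"],
        level_descriptions=LEVELS,
        alert_threshold=alert,
    )


def make_grid(category_sizes, version="test", alerts=None):
    """A minimal grid: category c0 has category_sizes[0] variables, etc.

    ``alerts`` maps variable id -> alert threshold.
    """
    alerts = alerts or {}
    cats, vars_, pos = [], [], 0
    for ci, size in enumerate(category_sizes):
        cid = f"c{ci}"
        vids = []
        for vi in range(size):
            pos += 1
            vid = f"c{ci}v{vi}"
            vids.append(vid)
            vars_.append(make_variable(vid, cid, pos, alerts.get(vid)))
        cats.append(CategoryDefinition(id=cid, label=cid, variable_ids=vids))
    return GridDefinition(version=version, categories=cats, variables=vars_)


def complete_assessment(grid, level=0, **kwargs):
    return Assessment(
        grid_version=grid.version,
        entries={vid: level for vid in grid.variable_ids},
        **kwargs,
    )


@pytest.fixture(scope="session")
def grid11():
    return load_packaged_grid("2020-11")


@pytest.fixture(scope="session")
def grid01():
    return load_packaged_grid("2020-01")


@pytest.fixture(scope="session")
def matrix11():
    return load_packaged_matrix()
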