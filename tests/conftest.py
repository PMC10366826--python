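import pytest

import nbsahp as nb


@pytest.fixture(scope="session")
def hierarchy():
    return nb.canonical_hierarchy()


@pytest.fixture(scope="session")
def allocation():
    return nb.published_allocation()


@pytest.fixture(scope="session")
def profiles():
    return {name: nb.bundled_profile(name) for name in ("pku", "mcad", "ch")}


def all_equal_rows(hierarchy, rid="r1"):
    """Survey records of one respondent answering every question 'equal'."""
    from nbsahp.hierarchy import ROOT

    rows = []
    for node, children in hierarchy.internal_nodes():
        if len(children) < 2:
            continue
        level = (
            "category" if node == ROOT
            else "subcategory" if "/" not in node
            else "criterion"
        )
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                rows.append({
                    "respondent_id": rid, "level": level, "matrix_id": node,
                    "item_a": children[i], "item_b": children[j],
                    "judgment": "equal", "direction": "none",
                })
    return rows


@pytest.fixture()
def equal_rows(hierarchy):
    return all_equal_rows(hierarchy)
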