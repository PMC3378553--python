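import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rabscreen as rs
from rabscreen.datasets import (load_pathway_reference, load_rab27_reference,
                                load_specificity_reference)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return rs.load_default_catalog()


@pytest.fixture(scope="session")
def platform(catalog):
    present = set(catalog.symbols) - rs.default_absent_genes()
    return rs.restrict_to_platform(catalog, present)


@pytest.fixture(scope="session")
def rab27_reference():
    return load_rab27_reference()


@pytest.fixture(scope="session")
def pathway_references():
    return {p: load_pathway_reference(p) for p in ("non_mutated", "mutated")}


@pytest.fixture(scope="session")
def specificity_reference():
    return load_specificity_reference()


@pytest.fixture
def tiny_matrix():
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 2.5, 3.5, 4.5],
         [8.0, 8.1, 8.2, 8.3]],
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
        columns=["s1", "s2", "s3", "s4"])


def reference_calls(ref: pd.DataFrame, group: str) -> pd.DataFrame:
    """Deregulation calls from a bundled reference FC/q table."""
    table = ref[[f"fc_{group}", f"q_{group}"]].copy()
    table.columns = ["fc", "q_percent"]
    return rs.call_deregulated(table, group=group)
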