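"""Shared fixtures: the synthetic six-species blowfly reference set and the
two published HRM amplicons anchored on it."""

from __future__ import annotations

import pytest

from hrmbarcode import (
    ResolutionThresholds,
    ThermoParams,
    amplicon_from_primers,
    blowfly_reference_model,
    build_decision_tree,
    greedy_panel,
    read_primer_table,
    resolvability_matrix,
    simulate_haplotypes,
    species_profiles,
    variable_columns,
)

MERGED_82 = frozenset({"Chrysomya_megacephala", "Chrysomya_albiceps"})
MERGED_124 = frozenset({"Lucilia_cuprina", "Lucilia_eximia"})


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams.default()


@pytest.fixture(scope="session")
def blowfly_set():
    return simulate_haplotypes(blowfly_reference_model())


@pytest.fixture(scope="session")
def blowfly_variants(blowfly_set):
    return variable_columns(blowfly_set)


@pytest.fixture(scope="session")
def hrm_primers():
    return {p.name: p for p in read_primer_table()}


@pytest.fixture(scope="session")
def table1_candidates(blowfly_set, blowfly_variants, hrm_primers):
    """The 82 bp and 124 bp amplicons anchored on the synthetic references."""
    return [
        amplicon_from_primers(hrm_primers[name], blowfly_set, blowfly_variants)
        for name in ("HRM_82", "HRM_124")
    ]


@pytest.fixture(scope="session")
def blowfly_profiles(table1_candidates, thermo):
    return {c.name: species_profiles(c, thermo) for c in table1_candidates}


@pytest.fixture(scope="session")
def blowfly_entries(table1_candidates, blowfly_profiles):
    return [
        (c, resolvability_matrix(blowfly_profiles[c.name], variants=c.contained_variants))
        for c in table1_candidates
    ]


@pytest.fixture(scope="session")
def blowfly_panel(blowfly_entries):
    return greedy_panel(blowfly_entries)


@pytest.fixture(scope="session")
def blowfly_tree(blowfly_panel, blowfly_profiles):
    return build_decision_tree(blowfly_panel, blowfly_profiles)
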