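"""Shared fixtures: the bundled study table and per-model effect helpers."""

from __future__ import annotations

import pytest

import snpmeta as sm


@pytest.fixture(scope="session")
def fixture_studies() -> list[sm.StudyRecord]:
    return sm.load_fixture()


@pytest.fixture(scope="session")
def by_id(fixture_studies):
    return {s.study_id: s for s in fixture_studies}


@pytest.fixture(scope="session")
def groups(fixture_studies):
    return sm.subgroup_members(fixture_studies)


def tables_for(studies, model: sm.GeneticModel) -> list[sm.ContrastTable]:
    return [
        sm.continuity_correct(sm.build_two_by_two(s.cases, s.controls, model, s.study_id))
        for s in studies
    ]


def effects_for(studies, model: sm.GeneticModel) -> list[sm.EffectEstimate]:
    return [sm.study_effect(t) for t in tables_for(studies, model)]
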