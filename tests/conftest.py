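from __future__ import annotations

import textwrap

import pytest

from obosyn.obo_io import parse_obo_text

HEARING_OBO = textwrap.dedent(
    """\
    format-version: 1.2

    [Term]
    id: HP:0000118
    name: Phenotypic abnormality

    [Term]
    id: HP:0000598
    name: Abnormality of the ear
    is_a: HP:0000118

    [Term]
    id: HP:0000365
    name: Hearing impairment
    synonym: "Hearing loss" EXACT []
    synonym: "Hearing defect" EXACT []
    synonym: "Congenital hearing loss" RELATED []
    is_a: HP:0000598

    [Term]
    id: HP:0000407
    name: Sensorineural hearing impairment
    synonym: "Sensorineural hearing loss" EXACT []
    is_a: HP:0000365

    [Term]
    id: HP:0001757
    name: High-tone sensorineural hearing impairment
    synonym: "High frequency sensorineural hearing loss" EXACT []
    is_a: HP:0000407
    """
)


@pytest.fixture
def hearing_model():
    """Mini hearing-impairment hierarchy: HP:0000365 with its redundant
    synonym "Congenital hearing loss" and two descendant terms."""
    return parse_obo_text(HEARING_OBO)


@pytest.fixture
def hearing_obo_text():
    return HEARING_OBO
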