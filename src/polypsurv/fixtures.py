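"""Bit-exact fixtures encoding the published evaluation tables.

``table2_fixture`` carries the group-level counts of the clinician-knowledge
evaluation (low scorers by clinician type and by gender, for the 7- and
12-scenario batteries).  ``table3_fixture`` reconstructs the 58 pilot-study
colonoscopy records from their published category counts.  Both are constants:
byte-identical across runs and platforms.

Where the publication gives only margins, the synthetic detail behind them is
generated deterministically (seed 0) subject to those margins and is labelled
synthetic; see :func:`table2_synthetic_scorecards`.

Note: in the published 7-scenario table the gender rows (6/13 + 3/6 = 9 low
scorers) do not sum to the printed total of 10, while the clinician-type rows
do.  The fixture stores both count tables exactly as printed; the synthetic
scorecards reproduce the clinician-type margins and the 10/19 total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import (
    ClinicianGroup,
    Direction,
    PilotExclusion,
    PilotRecord,
    Scorecard,
)
from .exact import ContingencyTable


@dataclass(frozen=True)
class Table2Fixture:
    """Printed low-scorer counts, rows = (group, n_low, n_not_low)."""

    clinician_type_7: ContingencyTable
    clinician_type_12: ContingencyTable
    gender_7: ContingencyTable
    gender_12: ContingencyTable


def table2_fixture() -> Table2Fixture:
    return Table2Fixture(
        clinician_type_7=ContingencyTable(
            (
                ("SURGEON", 2, 3),
                ("GASTROENTEROLOGIST", 2, 2),
                ("PCP", 3, 1),
                ("RESIDENT", 3, 3),
            )
        ),
        # surgeons were not given the 12-scenario battery: zero-total row,
        # dropped by .informative() before testing
        clinician_type_12=ContingencyTable(
            (
                ("SURGEON", 0, 0),
                ("GASTROENTEROLOGIST", 2, 2),
                ("PCP", 2, 2),
                ("RESIDENT", 1, 1),
            )
        ),
        gender_7=ContingencyTable((("MALE", 6, 7), ("FEMALE", 3, 3))),
        gender_12=ContingencyTable((("MALE", 3, 2), ("FEMALE", 2, 3))),
    )


def table2_synthetic_scorecards(battery: int = 7) -> list[Scorecard]:
    """Synthetic per-clinician scorecards consistent with the printed margins.

    Raw per-clinician answers were not published, so individual ``n_correct``
    values are drawn deterministically (seed 0) within the low-scorer /
    not-low-scorer band implied by the clinician-type margins.
    """
    if battery == 7:
        margins = [
            (ClinicianGroup.SURGEON, 2, 5),
            (ClinicianGroup.GASTROENTEROLOGIST, 2, 4),
            (ClinicianGroup.PCP, 3, 4),
            (ClinicianGroup.RESIDENT, 3, 6),
        ]
        n_scen, low_band, high_band = 7, (0, 3), (4, 6)
    elif battery == 12:
        margins = [
            (ClinicianGroup.GASTROENTEROLOGIST, 2, 4),
            (ClinicianGroup.PCP, 2, 4),
            (ClinicianGroup.RESIDENT, 1, 2),
        ]
        n_scen, low_band, high_band = 12, (3, 6), (7, 10)
    else:
        raise ValueError("battery must be 7 or 12")
    rng = np.random.default_rng(0)
    cards: list[Scorecard] = []
    for group, n_low, n_total in margins:
        for i in range(n_total):
            band = low_band if i < n_low else high_band
            cards.append(
                Scorecard(
                    clinician_id=f"{group.value.lower()}_{battery}_{i + 1}",
                    group=group,
                    n_correct=int(rng.integers(band[0], band[1] + 1)),
                    n_scenarios=n_scen,
                )
            )
    return cards


#: Colonoscopies completed per pilot endoscopist (four did 10, one 11, one 7).
PILOT_ENDOSCOPIST_COUNTS = (10, 10, 10, 10, 11, 7)


def table3_fixture() -> list[PilotRecord]:
    """The 58 pilot colonoscopy records, reconstructed from published counts.

    30 agreements; 16 countable discordances — split 11 shorter / 5 longer,
    the unique integer split of 16 whose shorter share rounds to the published
    70%, with "would have changed my recommendation" asked on 12 of them and
    answered yes exactly twice; 4 incorrect-tool-use records (stated agreement
    contradicted by chart review); 6 age-driven no-follow-up records; 2 other
    not-applicable (hereditary syndrome / anal cancer).  Records are dealt
    round-robin to the six endoscopists' published colonoscopy counts.
    """
    protos: list[dict] = []
    protos += [dict(stated_agreement=True, chart_review_agreement=True)] * 30
    for i in range(11):
        protos.append(
            dict(
                stated_agreement=False,
                chart_review_agreement=False,
                direction=Direction.SHORTER,
                would_change=(True if i < 2 else False),
            )
        )
    for i in range(5):
        protos.append(
            dict(
                stated_agreement=False,
                chart_review_agreement=False,
                direction=Direction.LONGER,
                would_change=(False if i < 1 else None),
            )
        )
    protos += [
        dict(
            stated_agreement=True,
            chart_review_agreement=False,
            exclusion=PilotExclusion.INCORRECT_TOOL_USE,
        )
    ] * 4
    protos += [
        dict(stated_agreement=False, exclusion=PilotExclusion.AGE_NO_FOLLOWUP)
    ] * 6
    protos += [
        dict(stated_agreement=False, exclusion=PilotExclusion.NOT_APPLICABLE_OTHER)
    ] * 2

    capacity = list(PILOT_ENDOSCOPIST_COUNTS)
    records: list[PilotRecord] = []
    e = 0
    for proto in protos:
        while capacity[e % 6] == 0:
            e += 1
        capacity[e % 6] -= 1
        records.append(PilotRecord(endoscopist_id=f"E{e % 6 + 1}", **proto))
        e += 1
    assert len(records) == 58 and all(c == 0 for c in capacity)
    return records
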