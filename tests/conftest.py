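"""Shared fixtures: small synthetic cohorts and recordings."""

import dataclasses

import numpy as np
import pytest

from pdkin import synthetic as syn
from pdkin.mocap import CANONICAL_MARKERS, Recording


@pytest.fixture(scope="session")
def cohort6():
    """Six participants, half TD, half the PIGD participants freeze."""
    return syn.generate_cohort(6, td_fraction=0.5, fog_fraction_within_pigd=0.5,
                               seed=11)


@pytest.fixture(scope="session")
def td_participant(cohort6):
    return next(p for p in cohort6 if p.phenotype.subtype_label == "TD")


@pytest.fixture(scope="session")
def pigd_participant(cohort6):
    """A PIGD participant without freezing."""
    return next(p for p in cohort6
                if p.phenotype.subtype_label == "PIGD" and p.fog_score == 0)


@pytest.fixture(scope="session")
def pigd_freezer(cohort6):
    return next(p for p in cohort6 if p.fog_score > 0)


@pytest.fixture(scope="session")
def walk_recording(td_participant):
    rec, gt = syn.synthesize_session(td_participant, "walk_thru",
                                     duration=10.0, seed=2)
    return rec, gt


def noise_free(participant):
    """Copy of a participant whose sensor noise is switched off."""
    pp = dataclasses.replace(participant.phenotype, sensor_noise_sd=0.0)
    return syn.VirtualParticipant(participant.participant_id, pp,
                                  participant.fog_score)


@pytest.fixture()
def simple_recording():
    """A tiny hand-built recording (11 markers, constant geometry)."""
    n = 240
    data = np.zeros((n, len(CANONICAL_MARKERS), 3))
    for mi, name in enumerate(CANONICAL_MARKERS):
        data[:, mi, 1] = 100.0 - 5.0 * mi  # distinct heights
        data[:, mi, 0] = mi
    return Recording(data=data, sampling_rate=120.0,
                     marker_names=list(CANONICAL_MARKERS),
                     participant_id="PX", session_id="PX-s", session_type="walk_thru")
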