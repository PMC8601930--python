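from __future__ import annotations

import pytest

from armadiel.covariates import compute_camera_covariates
from armadiel.ingest import build_events, events_to_frame
from armadiel.summaries import summarize_sites
from armadiel.synthetic import SPECIES, fixed_counts_fixture


@pytest.fixture(scope="session")
def fixture_study():
    """The deterministic study whose counts reproduce the published design."""
    return fixed_counts_fixture()


@pytest.fixture(scope="session")
def fixture_events(fixture_study):
    events = build_events(fixture_study.photos, fixture_study.deployments, SPECIES)
    return events_to_frame(events)


@pytest.fixture(scope="session")
def fixture_covariates(fixture_study):
    return compute_camera_covariates(
        fixture_study.deployments,
        fixture_study.landcover,
        fixture_study.sound,
        forest_codes=[1.0],
        developed_codes=[2.0],
    )


@pytest.fixture(scope="session")
def fixture_site_table(fixture_events, fixture_study, fixture_covariates):
    return summarize_sites(fixture_events, fixture_study.deployments, fixture_covariates)
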