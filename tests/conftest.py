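"""Shared fixtures: one default synthetic campaign, built once per session.

The default scene is the package's standard study condition (400 segments,
60 sites, 10 days of 15-min bins, 4 sources + background, 10% noise); the
mobile/fixed-site samples drawn from it feed both the unit tests and the
acceptance experiments.
"""

import numpy as np
import pytest

import bcfuse as bf


@pytest.fixture(scope="session")
def scene():
    return bf.generate_truth(seed=1)


@pytest.fixture(scope="session")
def drive(scene):
    points = bf.sample_mobile(scene, seed=2)
    points = points.copy()
    points["segment_id"] = bf.snap_to_segments(points, scene.segments)
    return points


@pytest.fixture(scope="session")
def segment_map(scene, drive):
    passes = bf.drive_pass_means(drive)
    return bf.median_of_means(
        passes, segment_coords={s.segment_id: s.midpoint for s in scene.segments}
    )


@pytest.fixture(scope="session")
def sensor_matrix(scene):
    return bf.sample_sensor_matrix(scene, seed=3)


@pytest.fixture(scope="session")
def truth_map(scene):
    """Noiseless pollutant × location map over the full location set."""
    return bf.SegmentConcentrationMap(
        pollutants=scene.pollutants,
        locations=scene.location_ids,
        values=scene.map_truth(),
        visit_counts=np.zeros(len(scene.location_ids), dtype=int),
        coords=scene.location_coords,
    )


@pytest.fixture(scope="session")
def noiseless_sensor(scene):
    """Sensor matrix equal to the BC truth at the sites (no noise, no gaps)."""
    vals = scene.bc_truth[len(scene.segments):]
    return bf.SensorMatrix(
        sites=list(scene.sites["site_id"]),
        time_bins=scene.time_bins,
        bin_width=scene.config.bin_width,
        values=vals,
        observed_mask=np.ones(vals.shape, dtype=bool),
        imputed_fraction=np.zeros(vals.shape[0]),
    )
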