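"""Shared fixtures: hand-checkable training sets and a brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

from crpopf.cohort import (
    NON_PDAC,
    PDAC,
    Cohort,
    DiscretizedProfile,
    MarkerDefinition,
    PatientRecord,
)


@pytest.fixture
def eight_sample_fixture():
    """1 binary marker, 8 samples: counts {+: 3 low / 1 high, -: 1 low / 3 high}.

    Small enough that the fit, the posteriors and the re-substitution
    confusion matrix can be verified by hand arithmetic.
    """
    profiles = [
        DiscretizedProfile(("m",), (0,)),
        DiscretizedProfile(("m",), (0,)),
        DiscretizedProfile(("m",), (0,)),
        DiscretizedProfile(("m",), (1,)),
        DiscretizedProfile(("m",), (0,)),
        DiscretizedProfile(("m",), (1,)),
        DiscretizedProfile(("m",), (1,)),
        DiscretizedProfile(("m",), (1,)),
    ]
    labels = [True, True, True, True, False, False, False, False]
    return profiles, labels


def brute_force_predict(profiles, labels, query, alpha=0.0):
    """Independent oracle: tabulate the joint (cell, class) table explicitly
    and compare prior-weighted likelihoods directly, tie predicting positive."""
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    n_cells = 2 ** len(query.bins)
    count_pos = sum(1 for p, y in zip(profiles, labels) if y and p.bins == query.bins)
    count_neg = sum(
        1 for p, y in zip(profiles, labels) if not y and p.bins == query.bins
    )
    # prior(c) * P(cell|c) compared with a common positive multiplier
    # n * (n_pos + a*C) * (n_cells term) cleared, keeping arithmetic exact
    score_pos = n_pos * (count_pos + alpha) * (n_neg + alpha * n_cells)
    score_neg = n_neg * (count_neg + alpha) * (n_pos + alpha * n_cells)
    if score_pos == 0 and score_neg == 0:
        return n_pos >= n_neg
    return score_pos >= score_neg


def random_profiles(rng, n, k, marker_names=None):
    """Random discretized profiles and labels with both classes present."""
    names = tuple(marker_names or (f"m{i}" for i in range(k)))
    while True:
        bins = rng.integers(0, 2, size=(n, k))
        labels = rng.random(n) < rng.uniform(0.2, 0.8)
        if 0 < labels.sum() < n:
            break
    profiles = [DiscretizedProfile(names, tuple(int(b) for b in row)) for row in bins]
    return profiles, [bool(y) for y in labels]


def make_record(i, diagnosis=PDAC, mpd_index=0.25, bmi=22.0, cr_popf=False, **kw):
    """A fully-valued record with consistent derived markers."""
    thickness = 13.0
    defaults = dict(
        id=f"T{i:03d}",
        diagnosis=diagnosis,
        age=69.0,
        sex="male",
        height=1.6,
        weight=None if bmi is None else bmi * 1.6**2,
        bmi=bmi,
        vfa=90.0,
        albumin=4.0,
        lymphocytes=1540.0,
        pni=10 * 4.0 + 0.005 * 1540.0,
        parenchymal_thickness=thickness,
        mpd_size=mpd_index * thickness,
        mpd_index=mpd_index,
        diabetes=False,
        biliary_drainage=False,
        conut=0,
        sarcopenia=False,
        cr_popf=cr_popf,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


@pytest.fixture
def separating_cohort():
    """MPD index separates the outcome perfectly; all other markers constant."""
    records = []
    for i in range(10):
        records.append(make_record(i, mpd_index=0.2, cr_popf=True))
    for i in range(10, 24):
        records.append(make_record(i, mpd_index=0.5, cr_popf=False))
    return Cohort(tuple(records))
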