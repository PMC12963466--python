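"""Simulated observers.

A reader study is emulated by giving each observer a small set of fixed
traits plus per-measurement noise:

* ``edge_fraction`` — where within a window's gray-level ramp the
  observer perceives the stone border.  Only wide (WW > 0) windows use
  it: the perception threshold is ``lower_level + edge_fraction * width``,
  so the same trait spread translates into a much larger threshold
  spread — and hence size spread — in the 1120-HU-wide bone window than
  in the 400-HU soft-tissue window.  Half-value windows have an
  algorithmic threshold and ignore the trait entirely.
* ``roi_center_sd`` — jitter of the histogram-circle placement (mm),
  which perturbs the ROI mean (and barely the max) in the half-value
  modes.
* ``caliper_sd`` — caliper placement jitter (mm) added independently to
  each in-plane measurement.

Fixed traits generate between-observer variance and the jitters generate
residual variance, mapping directly onto the additive two-way
random-effects decomposition the agreement statistics assume.  All
randomness flows from named seeds via per-cell substreams, so a study
table regenerates bit-exactly from its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

import logging

from .errors import NotAStoneError
from .measure import Measurement, measure_stone
from .phantom import CohortMember, render_phantom

logger = logging.getLogger(__name__)

__all__ = ["ObserverProfile", "default_observers", "simulate_reading", "simulate_study"]


@dataclass(frozen=True)
class ObserverProfile:
    """Fixed behavioral traits of one simulated observer."""

    observer_id: str
    edge_fraction: float = 0.5
    caliper_sd: float = 0.0
    roi_center_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_fraction <= 1.0:
            raise ValueError("edge_fraction must be in [0, 1]")
        if self.caliper_sd < 0 or self.roi_center_sd < 0:
            raise ValueError("noise SDs must be >= 0")


#: Default five-observer panel.  The edge_fraction spread and jitter SDs are
#: calibration choices tuned so the simulated interreader variability ranks
#: the windows the way a heterogeneous human panel does (bone widest,
#: half-value MAX tightest); they are not measured behavioral data.
DEFAULT_OBSERVER_PARAMS = (
    ("obs1", 0.30),
    ("obs2", 0.45),
    ("obs3", 0.50),
    ("obs4", 0.55),
    ("obs5", 0.70),
)


def default_observers(
    caliper_sd: float = 0.10, roi_center_sd: float = 0.5
) -> list[ObserverProfile]:
    return [
        ObserverProfile(oid, ef, caliper_sd, roi_center_sd, seed=i)
        for i, (oid, ef) in enumerate(DEFAULT_OBSERVER_PARAMS)
    ]


def simulate_reading(
    vol,
    seed_point,
    window_mode: str,
    profile: ObserverProfile,
    rng: np.random.Generator,
    *,
    slab_thickness: float = 3.0,
    background_hu: float = 0.0,
    stone_id: str = "stone",
) -> Measurement:
    """One observer's measurement of one stone under one window setting.

    The ROI center is perturbed by N(0, roi_center_sd^2) in-plane, the
    perception threshold in wide windows follows the observer's
    edge_fraction, and independent caliper noise (truncated so diameters
    stay >= 0) is added to each in-plane diameter before the largest is
    retained.  With all noise at zero and a half-value mode this reduces
    exactly to the deterministic algorithm.
    """
    offset = (0.0, 0.0)
    if profile.roi_center_sd > 0:
        offset = tuple(rng.normal(0.0, profile.roi_center_sd, size=2))
    m = measure_stone(
        vol,
        seed_point,
        window_mode,
        edge_fraction=profile.edge_fraction,
        slab_thickness=slab_thickness,
        background_hu=background_hu,
        roi_center_offset=offset,
        stone_id=stone_id,
        observer_id=profile.observer_id,
    )
    if profile.caliper_sd > 0:
        noisy = tuple(
            max(0.0, d + rng.normal(0.0, profile.caliper_sd))
            for d in m.per_plane_diameter
        )
        largest = max(noisy)
        planes = ("axial", "coronal", "sagittal")
        m = replace(
            m,
            per_plane_diameter=noisy,
            largest_diameter=largest,
            plane_of_largest=planes[int(np.argmax(noisy))],
        )
    return m


def simulate_study(
    cohort: list[CohortMember],
    observers: list[ObserverProfile],
    window_modes: tuple[str, ...] = (
        "bone",
        "soft_tissue",
        "half_value_mean",
        "half_value_max",
    ),
    master_seed: int = 0,
    *,
    slab_thickness: float = 3.0,
    exclude: tuple[tuple[str, str], ...] = (),
) -> pd.DataFrame:
    """Simulate a full reader study and return a long-format table.

    One row per stone x observer x window (minus any
    ``(observer_id, window_mode)`` pairs in ``exclude``, which emulates
    observers whose readings in one window were lost).  Each phantom is
    rendered once — all observers read the same image, as in a real
    study — and every reading draws from its own substream keyed by
    ``(master_seed, stone index, observer seed, window index)``, so
    permuting loop order cannot change any value.

    A stone with no apparent supra-threshold region in any slab of the
    soft-tissue window — possible for small, low-attenuation stones under
    thick-slab partial volume — is logged and excluded, mirroring how an
    invisible stone would fall out of a reading session.  The exclusion
    is observer-independent, so per-window tables stay balanced.
    """
    if len(cohort) < 1 or len(observers) < 1:
        raise ValueError("cohort and observer list must be non-empty")
    excluded = set(exclude)
    rows = []
    for si, member in enumerate(cohort):
        vol, _ = render_phantom(member.spec)
        seed_point = tuple(
            int(round(member.spec.center[a] / member.spec.voxel_spacing[a]))
            for a in range(3)
        )
        try:
            measure_stone(
                vol, seed_point, "half_value_max", slab_thickness=slab_thickness
            )
        except NotAStoneError:
            logger.warning(
                "stone %s is not apparent in the soft-tissue window at "
                "%.1f mm slabs; excluded from the study table",
                member.stone_id,
                slab_thickness,
            )
            continue
        for obs in observers:
            for wi, wmode in enumerate(window_modes):
                if (obs.observer_id, wmode) in excluded:
                    continue
                rng = np.random.default_rng(
                    np.random.SeedSequence([master_seed, si, obs.seed, wi])
                )
                m = simulate_reading(
                    vol,
                    seed_point,
                    wmode,
                    obs,
                    rng,
                    slab_thickness=slab_thickness,
                    stone_id=member.stone_id,
                )
                rows.append(
                    {
                        "stone_id": m.stone_id,
                        "observer_id": m.observer_id,
                        "window": wmode,
                        "d_axial_mm": m.per_plane_diameter[0],
                        "d_coronal_mm": m.per_plane_diameter[1],
                        "d_sagittal_mm": m.per_plane_diameter[2],
                        "d_largest_mm": m.largest_diameter,
                        "roi_mean_hu": m.roi_mean_hu,
                        "roi_max_hu": m.roi_max_hu,
                        "plane_of_largest": m.plane_of_largest,
                        "true_d_mm": member.true_largest_diameter,
                        "passed": member.passed,
                    }
                )
    return pd.DataFrame(rows)
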