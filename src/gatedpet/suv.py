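"""Body-weight SUV conversion and the healthy-liver background-SUVmax threshold.

The segmentation threshold is individualized per exam: the SUVmax of the
*healthy* liver background is measured in spherical 20-30 cc regions of
interest, repeated until the measurements agree, and the tumour is defined
as every voxel with SUV strictly above that background SUVmax.

ROI repetition protocol:

* measure SUVmax in 3 ROIs; if the maximum pairwise difference is < 0.1 SUV,
  keep those 3;
* if the spread is between 0.1 and 0.2, add 2 further ROIs and use all 5;
* a final spread above 0.2 means the background is too heterogeneous for the
  protocol and the construction fails.

The retained SUVmax values are aggregated into the threshold tau by
arithmetic mean (the repetition rule exists to stabilise a noisy estimate,
which averaging does).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .geometry import BinaryMask, GridGeometry, SUVImage

__all__ = [
    "AcquisitionInfo",
    "BackgroundEstimate",
    "compute_suv_map",
    "sample_background_rois",
    "background_threshold",
    "estimate_threshold",
]

F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class AcquisitionInfo:
    """Injection metadata needed to convert activity concentration to SUV.

    Parameters
    ----------
    injected_activity_mbq:
        Activity at injection time, MBq.
    body_weight_kg:
        Patient body weight, kg.
    delay_min:
        Injection-to-scan uptake time, minutes (default 60, the standard
        FDG uptake period).
    half_life_min:
        Isotope half-life, minutes (default F-18).
    """

    injected_activity_mbq: float
    body_weight_kg: float
    delay_min: float = 60.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injected_activity_mbq", "body_weight_kg", "half_life_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delay_min < 0:
            raise ValueError("delay_min must be non-negative")

    @property
    def decayed_activity_bq(self) -> float:
        """Injected activity decayed to scan start, in Bq."""
        return self.injected_activity_mbq * 1e6 * 2.0 ** (-self.delay_min / self.half_life_min)

    @classmethod
    def from_file(cls, path) -> "AcquisitionInfo":
        """Load acquisition metadata from YAML or JSON.

        Recognised keys: activity_mbq, weight_kg, delay_min (optional),
        half_life_min (optional).
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {
            "injected_activity_mbq": float(raw["activity_mbq"]),
            "body_weight_kg": float(raw["weight_kg"]),
        }
        if "delay_min" in raw:
            kwargs["delay_min"] = float(raw["delay_min"])
        if "half_life_min" in raw:
            kwargs["half_life_min"] = float(raw["half_life_min"])
        return cls(**kwargs)


def compute_suv_map(activity: SUVImage | np.ndarray, acq: AcquisitionInfo,
                    geometry: GridGeometry | None = None) -> SUVImage:
    """Convert an activity-concentration image (Bq/mL) to body-weight SUV.

    SUV(v) = C(v) [Bq/mL] * body weight [g] / decay-corrected activity [Bq],
    with the decay factor 2^(-delay / half-life) applied to the injected
    activity. Body weight in grams divided by Bq gives the conventional
    g/mL-normalised dimensionless SUV.
    """
    if isinstance(activity, SUVImage):
        geometry = activity.geometry
        conc = activity.values
    else:
        if geometry is None:
            raise ValueError("geometry required when passing a bare array")
        conc = np.asarray(activity, dtype=np.float64)
    weight_g = acq.body_weight_kg * 1000.0
    suv = conc * weight_g / acq.decayed_activity_bq
    return SUVImage(geometry, suv)


@dataclass
class BackgroundEstimate:
    """Trace and result of the background-SUVmax threshold protocol."""

    roi_suvmax: list[float]
    threshold: float
    n_rois: int
    roi_volume_cc: float | None = None
    roi_centers_mm: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def spread(self) -> float:
        return float(max(self.roi_suvmax) - min(self.roi_suvmax))

    def to_dict(self) -> dict:
        return {
            "roi_suvmax": [float(v) for v in self.roi_suvmax],
            "spread": self.spread,
            "threshold": float(self.threshold),
            "n_rois": self.n_rois,
            "roi_volume_cc": self.roi_volume_cc,
            "roi_centers_mm": [list(c) for c in self.roi_centers_mm],
        }


class BackgroundProtocolError(RuntimeError):
    """Raised when the background ROI measurements disagree by more than 0.2 SUV."""


def _roi_radius_mm(roi_volume_cc: float) -> float:
    return (3.0 * roi_volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def sample_background_rois(
    img: SUVImage,
    liver_mask: BinaryMask,
    k: int,
    roi_volume_cc: float = 25.0,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 5000,
) -> tuple[list[float], list[tuple[float, float, float]]]:
    """Place ``k`` disjoint spherical ROIs inside the liver mask and return
    the SUVmax within each.

    The ROI volume must lie in the protocol's 20-30 cc window. Centres are
    drawn reproducibly from ``seed`` by rejection sampling: a candidate liver
    voxel is accepted when the sphere fits entirely inside the mask (checked
    via the mask's Euclidean distance transform) and does not overlap any
    previously placed ROI.

    Returns (suvmax per ROI, centre coordinates in mm).
    """
    if not 20.0 <= roi_volume_cc <= 30.0:
        raise ValueError(f"ROI volume must be within [20, 30] cc, got {roi_volume_cc}")
    liver_mask.check_compatible(img)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geo = img.geometry
    radius = _roi_radius_mm(roi_volume_cc)

    # distance (mm) from each liver voxel centre to the nearest outside voxel:
    # a sphere of radius r fits when this depth >= r.
    depth = ndimage.distance_transform_edt(liver_mask.values, sampling=geo.spacing)
    candidates = np.argwhere(depth >= radius)
    if len(candidates) == 0:
        raise ValueError(
            f"liver mask cannot contain a single {roi_volume_cc:.0f} cc ROI "
            f"(sphere radius {radius:.1f} mm)"
        )

    cx, cy, cz = geo.voxel_centers()
    centers: list[np.ndarray] = []
    suvmaxes: list[float] = []
    for i in range(k):
        placed = False
        for _ in range(max_attempts):
            idx = candidates[rng.integers(len(candidates))]
            c = np.array([cx[idx[0]], cy[idx[1]], cz[idx[2]]])
            if all(np.linalg.norm(c - p) >= 2 * radius for p in centers):
                centers.append(c)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place disjoint background ROI {i + 1} of {k} "
                f"inside the liver mask after {max_attempts} attempts"
            )
        dx = cx - centers[-1][0]
        dy = cy - centers[-1][1]
        dz = cz - centers[-1][2]
        inside = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
            <= radius**2
        )
        suvmaxes.append(float(img.values[inside].max()))
    return suvmaxes, [tuple(float(x) for x in c) for c in centers]


def background_threshold(
    initial_suvmax: Sequence[float],
    more_provider: Callable[[int], Sequence[float]] | None = None,
) -> BackgroundEstimate:
    """Apply the ROI repetition rule and aggregate the retained SUVmax values.

    ``initial_suvmax`` must hold exactly 3 values. If their spread lies in
    [0.1, 0.2], ``more_provider(2)`` is called for 2 additional measurements.
    A final spread above 0.2 raises :class:`BackgroundProtocolError`.
    """
    vals = [float(v) for v in initial_suvmax]
    if len(vals) != 3:
        raise ValueError(f"protocol starts from exactly 3 ROI values, got {len(vals)}")
    spread = max(vals) - min(vals)
    if spread < 0.1:
        retained = vals
    elif spread <= 0.2:
        if more_provider is None:
            raise ValueError(
                "spread in [0.1, 0.2] requires 2 additional ROI measurements "
                "but no provider was given"
            )
        extra = [float(v) for v in more_provider(2)]
        if len(extra) != 2:
            raise ValueError("provider must return exactly 2 additional values")
        retained = vals + extra
    else:
        raise BackgroundProtocolError(
            f"background ROI SUVmax spread {spread:.3f} exceeds 0.2; "
            "background too heterogeneous for the threshold protocol"
        )
    final_spread = max(retained) - min(retained)
    if final_spread > 0.2:
        raise BackgroundProtocolError(
            f"final ROI SUVmax spread {final_spread:.3f} exceeds 0.2"
        )
    tau = float(np.mean(retained))
    return BackgroundEstimate(roi_suvmax=retained, threshold=tau, n_rois=len(retained))


def estimate_threshold(
    img: SUVImage,
    liver_mask: BinaryMask,
    roi_volume_cc: float = 25.0,
    seed: int = 0,
    max_protocol_retries: int = 5,
) -> BackgroundEstimate:
    """Run the full protocol on one image: place 3 ROIs, extend to 5 on demand.

    ``img`` should be the gated phase matching the reference CT phase (or
    the non-gated exam for the non-gated workflow). ``liver_mask`` must cover
    only *healthy* liver. When a measurement set disagrees by more than
    0.2 SUV the whole set is discarded and re-measured in freshly drawn
    ROIs — the automated analogue of the clinician repeating the
    measurement — up to ``max_protocol_retries`` times before giving up.
    """
    rng = np.random.default_rng(seed)
    last_err: BackgroundProtocolError | None = None
    for _ in range(max_protocol_retries + 1):
        vals, centers = sample_background_rois(img, liver_mask, 3, roi_volume_cc, rng)
        all_centers = list(centers)

        def provider(n: int) -> list[float]:
            extra, c = sample_background_rois(img, liver_mask, n, roi_volume_cc, rng)
            all_centers.extend(c)
            return extra

        try:
            est = background_threshold(vals, provider)
        except BackgroundProtocolError as err:
            last_err = err
            continue
        est.roi_volume_cc = roi_volume_cc
        est.roi_centers_mm = all_centers[: est.n_rois]
        return est
    raise BackgroundProtocolError(
        f"background protocol failed {max_protocol_retries + 1} times: {last_err}"
    )
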