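"""Synthetic observer studies and phantom radiographs.

No raw observer data ship with scoliosis reliability studies, so this
module generates them: severity-stratified true Cobb angles, observer
measurements with per-method bias and Gaussian noise, and the full
factorial study table (curves × observers × rounds × methods).  It also
renders phantom radiographs — bright tilted vertebra rectangles on a
dark background with exact ground-truth endplate landmarks — for
end-to-end geometry testing.

The default design mirrors a standard absolute-reliability protocol:
35 curves in six severity strata (9 low 11–20°, 11 moderate 21–35°,
6 moderate-severe 36–40°, 4 severe 41–50°, 3 severe-very-severe
51–55°, 2 very severe ≥56°), 8 observers in two experience groups
(4 experts, 4 novices), 3 measurement rounds and 2 methods (software
and manual film reading) — 1680 measurements, 210 per observer.

Observer noise defaults are anchored to published intra-group mean
absolute round-to-round errors via the folded-normal closed form: the
mean absolute difference of two independent draws is
``2 * sigma / sqrt(pi)``, so ``sigma = MBE * sqrt(pi) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import (
    CurveAnnotation,
    MeasurementSession,
    TABLE_COLUMNS,
)
from .geometry import CAUDAL, CRANIAL, EndplateLine, Landmark, round_half_away
from .imaging import Radiograph

__all__ = [
    "SEVERITY_STRATA",
    "ObserverProfile",
    "StudyDesign",
    "VertebraSpec",
    "default_observers",
    "sample_true_curves",
    "simulate_study",
    "session_from_table",
    "endplate_pair_for_angle",
    "phantom_radiograph",
]

#: SOSORT-style severity strata: label -> (count, lower deg, upper deg).
#: The open-ended "very severe" class (>= 56 deg) is capped at 70 deg.
SEVERITY_STRATA: dict[str, tuple[int, float, float]] = {
    "low": (9, 11.0, 20.0),
    "moderate": (11, 21.0, 35.0),
    "moderate_severe": (6, 36.0, 40.0),
    "severe": (4, 41.0, 50.0),
    "severe_very_severe": (3, 51.0, 55.0),
    "very_severe": (2, 56.0, 70.0),
}

# sigma = MBE * sqrt(pi)/2 (folded normal), anchored per group x method
_SIGMA = math.sqrt(math.pi) / 2.0
_DEFAULT_NOISE = {
    ("expert", "software"): 1.71 * _SIGMA,
    ("novice", "software"): 1.90 * _SIGMA,
    ("expert", "manual"): 2.13 * _SIGMA,
    ("novice", "manual"): 2.50 * _SIGMA,
}


@dataclass(frozen=True)
class ObserverProfile:
    """One simulated rater: per-method systematic bias and noise SD."""

    observer_id: str
    group: str
    bias: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, sd in self.noise_sd.items():
            if not sd > 0:
                raise ValueError(f"noise_sd[{m}] must be > 0")


@dataclass(frozen=True)
class StudyDesign:
    """Study geometry: strata, rounds, methods and the master seed."""

    severity_counts: dict[str, int] = field(
        default_factory=lambda: {k: v[0] for k, v in SEVERITY_STRATA.items()}
    )
    n_rounds: int = 3
    methods: tuple[str, ...] = ("software", "manual")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, count in self.severity_counts.items():
            if name not in SEVERITY_STRATA:
                raise ValueError(f"unknown severity class {name!r}")
            if count < 0:
                raise ValueError(f"negative count for severity class {name!r}")

    @property
    def n_curves(self) -> int:
        return sum(self.severity_counts.values())


def default_observers() -> list[ObserverProfile]:
    """The default panel: 4 experts and 4 novices, zero bias, noise
    anchored to published group-level error magnitudes."""
    panel = []
    for group, prefix in (("expert", "E"), ("novice", "N")):
        for i in range(1, 5):
            panel.append(
                ObserverProfile(
                    observer_id=f"{prefix}{i}",
                    group=group,
                    bias={"software": 0.0, "manual": 0.0},
                    noise_sd={
                        "software": _DEFAULT_NOISE[(group, "software")],
                        "manual": _DEFAULT_NOISE[(group, "manual")],
                    },
                )
            )
    return panel


def sample_true_curves(
    design: StudyDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw latent true Cobb angles, uniform within each severity class.

    Returns a frame with columns ``curve_id``, ``severity``,
    ``true_angle`` (degrees, unrounded).  Curves are ordered by
    stratum, ids ``C01``, ``C02``, ...
    """
    records = []
    i = 0
    for name, (_, lo, hi) in SEVERITY_STRATA.items():
        count = design.severity_counts.get(name, 0)
        for angle in rng.uniform(lo, hi, size=count):
            i += 1
            records.append((f"C{i:02d}", name, float(angle)))
    return pd.DataFrame(records, columns=["curve_id", "severity", "true_angle"])


def simulate_study(
    true_curves: pd.DataFrame,
    observers: list[ObserverProfile],
    design: StudyDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate every measurement of the full factorial design.

    measurement = truth + bias(observer, method) + N(0, sd(observer,
    method)), rounded half-away-from-zero to 0.1° (the instrument
    scale).  Noise is independent across curves, observers, rounds and
    methods.  Returns a study table in the standard long format plus a
    ``true_angle`` column.
    """
    if not observers:
        raise ValueError("need at least one observer")
    rows = []
    for _, curve in true_curves.iterrows():
        for obs in observers:
            for method in design.methods:
                bias = obs.bias.get(method, 0.0)
                sd = obs.noise_sd.get(method)
                if sd is None:
                    raise ValueError(
                        f"observer {obs.observer_id} has no noise_sd for {method!r}"
                    )
                noise = rng.normal(0.0, sd, size=design.n_rounds)
                for rnd in range(1, design.n_rounds + 1):
                    value = curve["true_angle"] + bias + noise[rnd - 1]
                    rows.append(
                        (
                            curve["curve_id"], obs.observer_id, obs.group, method,
                            rnd, round_half_away(max(value, 0.0), 1), "", "",
                            curve["true_angle"],
                        )
                    )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS + ["true_angle"])


# ---------------------------------------------------------------------------
# landmark synthesis


def endplate_pair_for_angle(
    cobb_deg: float,
    centre: tuple[float, float] = (256.0, 256.0),
    separation: float = 200.0,
    width: float = 80.0,
) -> tuple[EndplateLine, EndplateLine]:
    """Construct a cranial/caudal endplate pair realising a Cobb angle.

    Tilts are split symmetrically (+cobb/2 cranial, -cobb/2 caudal), as
    in a balanced scoliotic curve.  Useful for generating sessions whose
    measured angle is known exactly.
    """
    cx, cy = centre
    half = width / 2.0

    def line(label: str, role: str, y0: float, tilt_deg: float) -> EndplateLine:
        t = math.radians(tilt_deg)
        dx, dy = math.cos(t) * half, math.sin(t) * half
        return EndplateLine(
            vertebra=label, role=role,
            p1=Landmark(cx - dx, y0 - dy), p2=Landmark(cx + dx, y0 + dy),
        )

    cranial = line("cranial", CRANIAL, cy - separation / 2.0, cobb_deg / 2.0)
    caudal = line("caudal", CAUDAL, cy + separation / 2.0, -cobb_deg / 2.0)
    return cranial, caudal


def session_from_table(
    table: pd.DataFrame,
    observer_id: str,
    method: str,
    round_no: int,
    radiograph_id: str = "SIM",
) -> MeasurementSession:
    """Reconstruct a measurement session from one observer-round slice.

    Software sessions get synthetic landmarks realising each recorded
    angle (so re-measuring them reproduces the table); manual sessions
    carry angle-only entries, as film readings do.
    """
    sub = table[
        (table["observer_id"] == observer_id)
        & (table["method"] == method)
        & (table["round"] == round_no)
    ]
    if not len(sub):
        raise ValueError(
            f"no rows for observer={observer_id!r} method={method!r} round={round_no}"
        )
    group = sub["group"].iloc[0]
    curves = []
    for _, row in sub.iterrows():
        if method == "manual":
            curves.append(
                CurveAnnotation(curve_id=row["curve_id"], cobb_deg=row["cobb_deg"])
            )
        else:
            cranial, caudal = endplate_pair_for_angle(row["cobb_deg"])
            curves.append(
                CurveAnnotation(
                    curve_id=row["curve_id"],
                    cranial_candidates=(cranial,),
                    caudal_candidates=(caudal,),
                )
            )
    return MeasurementSession(
        observer_id=observer_id, group=group, method=method,
        round=round_no, radiograph_id=radiograph_id, curves=tuple(curves),
    )


# ---------------------------------------------------------------------------
# phantom radiographs


@dataclass(frozen=True)
class VertebraSpec:
    """A rectangular phantom vertebra: centre (x, y), size, signed tilt."""

    label: str
    centre: tuple[float, float]
    width: float
    height: float
    tilt_deg: float


def _rect_corners(v: VertebraSpec) -> np.ndarray:
    """4x2 corner array (x, y): top-left, top-right, bottom-right,
    bottom-left of the tilted rectangle."""
    t = math.radians(v.tilt_deg)
    c, s = math.cos(t), math.sin(t)
    hw, hh = v.width / 2.0, v.height / 2.0
    local = np.array([(-hw, -hh), (hw, -hh), (hw, hh), (-hw, hh)])
    rot = local @ np.array([[c, s], [-s, c]])  # y-down rotation by tilt
    return rot + np.asarray(v.centre)


def phantom_radiograph(
    vertebrae: list[VertebraSpec],
    shape: tuple[int, int] = (512, 512),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    pixel_spacing: tuple[float, float] | None = (0.2, 0.2),
) -> tuple[Radiograph, dict[str, dict[str, EndplateLine]]]:
    """Render tilted vertebra rectangles and return exact landmarks.

    Returns the image (bright rectangles ~3000 on a dark ~0 background,
    16-bit range) and, per vertebra, the ground-truth superior and
    inferior endplate lines built from the rectangle's exact corners.
    Optional Gaussian noise emulates radiographic mottle.
    """
    from skimage.draw import polygon  # deferred: heavy import

    rows, cols = shape
    img = np.zeros((rows, cols), dtype=np.float64)
    landmarks: dict[str, dict[str, EndplateLine]] = {}
    for v in vertebrae:
        corners = _rect_corners(v)
        if (corners < -0.5).any() or (corners[:, 0] > cols - 0.5).any() or (
            corners[:, 1] > rows - 0.5
        ).any():
            raise ValueError(f"vertebra {v.label} extends outside the image")
        rr, cc = polygon(corners[:, 1], corners[:, 0], shape=shape)
        img[rr, cc] = 3000.0
        tl, tr, br, bl = (Landmark(float(x), float(y)) for x, y in corners)
        landmarks[v.label] = {
            "superior": EndplateLine(v.label, CRANIAL, tl, tr),
            "inferior": EndplateLine(v.label, CAUDAL, bl, br),
        }
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return (
        Radiograph(pixels=img, pixel_spacing=pixel_spacing, source_id="phantom"),
        landmarks,
    )
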