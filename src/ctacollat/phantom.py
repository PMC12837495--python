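"""Synthetic CTA-MIP-like phantom generator.

Produces 8-bit grayscale head phantoms that mimic the pixel-level
properties a windowed (0-450 HU) CTA maximum-intensity-projection slice
exhibits: a closed ring of maximum-intensity (255) cranium pixels, an
enclosed mid-intensity brain disc, zero-intensity background, and bright
curvilinear vessel strokes whose density differs between good- and
poor-collateral classes.  Every phantom carries exact ground-truth masks
so the segmentation pipeline and the classifier can be tested without
clinical data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

GOOD, POOR = "good", "poor"

__all__ = [
    "GOOD",
    "POOR",
    "PhantomSpec",
    "PhantomImage",
    "PatientRecord",
    "generate_phantom",
    "generate_cohort",
    "write_phantom",
    "write_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic head slice.

    Intensity layout follows the windowed-CTA convention: background 0,
    brain parenchyma in ``brain_intensity_range``, vessels strictly
    brighter than brain, and the cranium alone at the top value 255.
    """

    width: int = 256
    height: int = 256
    skull_radius: int = 110
    skull_thickness: int = 6
    brain_intensity_range: tuple[int, int] = (70, 110)
    vessel_intensity_range: tuple[int, int] = (160, 220)
    n_vessel_branches_good: int = 12
    n_vessel_branches_poor: int = 3
    calvarial_defect: bool = False
    defect_angle_deg: float = 5.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        b_lo, b_hi = self.brain_intensity_range
        v_lo, v_hi = self.vessel_intensity_range
        if not (0 <= b_lo <= b_hi <= 255 and 0 <= v_lo <= v_hi <= 255):
            raise ValueError("intensity ranges must lie within [0, 255]")
        if v_hi >= 255:
            raise ValueError(
                "vessel range maximum must be < 255 (255 is reserved for cranium)"
            )
        if b_hi >= v_lo:
            raise ValueError("brain range maximum must be below vessel range minimum")
        if self.skull_thickness < 1 or self.skull_radius <= self.skull_thickness:
            raise ValueError("skull ring must have positive interior radius")
        cx, cy = self.width / 2, self.height / 2
        if not self.calvarial_defect:
            if (
                self.skull_radius >= cx
                or self.skull_radius >= cy
            ):
                raise ValueError("skull ring must lie fully inside image bounds")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_vessel_branches_good < 0 or self.n_vessel_branches_poor < 0:
            raise ValueError("branch counts must be non-negative")


@dataclass(frozen=True)
class PhantomImage:
    """A generated phantom with its exact ground-truth masks."""

    image: np.ndarray  # uint8 (H, W)
    truth_brain: np.ndarray  # bool (H, W)
    truth_vessels: np.ndarray  # bool (H, W)
    label: str  # "good" | "poor"


@dataclass(frozen=True)
class PatientRecord:
    """Two-level input for the classifier.

    ``label`` is 1 for good (positive / non-poor) collateral, 0 for poor,
    matching the positive-class convention of the evaluation metrics.
    """

    patient_id: str
    ganglionic: np.ndarray
    supraganglionic: np.ndarray
    label: int
    meta: dict = field(default_factory=dict, compare=False)


def _disc(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _draw_vessels(
    rng: np.random.Generator,
    canvas: np.ndarray,
    allowed: np.ndarray,
    n_branches: int,
    centre: tuple[float, float],
    intensity_range: tuple[int, int],
) -> np.ndarray:
    """Draw ``n_branches`` jittered random-walk strokes inside ``allowed``.

    Each stroke starts near ``centre``, walks with correlated random
    headings, and stamps a 1-3 px-wide footprint of vessel-range
    intensities onto ``canvas``.  Returns the boolean footprint.
    """
    h, w = canvas.shape
    drawn = np.zeros((h, w), dtype=bool)
    cx, cy = centre
    v_lo, v_hi = intensity_range
    for _ in range(n_branches):
        x = cx + rng.normal(0, 6)
        y = cy + rng.normal(0, 6)
        heading = rng.uniform(0, 2 * np.pi)
        width_px = int(rng.integers(1, 4))  # 1-3 px
        n_steps = int(rng.integers(35, 75))
        half = (width_px - 1) / 2
        for _ in range(n_steps):
            heading += rng.normal(0, 0.35)
            x += np.cos(heading)
            y += np.sin(heading)
            xi, yi = int(round(x)), int(round(y))
            lo_y, hi_y = int(np.floor(yi - half)), int(np.ceil(yi + half))
            lo_x, hi_x = int(np.floor(xi - half)), int(np.ceil(xi + half))
            for py in range(lo_y, hi_y + 1):
                for px in range(lo_x, hi_x + 1):
                    if 0 <= py < h and 0 <= px < w and allowed[py, px]:
                        drawn[py, px] = True
                        canvas[py, px] = rng.integers(v_lo, v_hi + 1)
    return drawn


def generate_phantom(spec: PhantomSpec, label: str) -> PhantomImage:
    """Generate one phantom slice for the given collateral class.

    Good-collateral phantoms receive ``n_vessel_branches_good`` strokes in
    each hemisphere; poor-collateral phantoms keep that density in one
    hemisphere and drop to ``n_vessel_branches_poor`` in the other,
    mirroring the asymmetric deficit the classifier must detect.
    Deterministic: identical ``(spec, label)`` gives identical output.
    """
    spec.validate()
    if label not in (GOOD, POOR):
        raise ValueError(f"label must be {GOOD!r} or {POOR!r}, got {label!r}")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cx, cy = w / 2, h / 2
    r_out = float(spec.skull_radius)
    r_in = r_out - spec.skull_thickness

    ring = _disc(h, w, cx, cy, r_out) & ~_disc(h, w, cx, cy, r_in)
    if spec.calvarial_defect:
        yy, xx = np.mgrid[:h, :w]
        ang = np.degrees(np.arctan2(yy - cy, xx - cx))  # defect opens at angle 0 (east)
        half = spec.defect_angle_deg / 2
        ring &= ~((ang > -half) & (ang < half))

    truth_brain = _disc(h, w, cx, cy, r_in - 0.5) & ~ring

    # parenchyma sits comfortably inside its range (+-3 sigma) so the
    # histogram stays unimodal; clipping only catches rare outliers
    b_lo, b_hi = spec.brain_intensity_range
    img = np.zeros((h, w), dtype=float)
    brain_vals = rng.normal((b_lo + b_hi) / 2, (b_hi - b_lo) / 6, size=(h, w))
    if spec.noise_sd > 0:
        brain_vals += rng.normal(0, spec.noise_sd, size=(h, w))
    img[truth_brain] = np.clip(brain_vals[truth_brain], b_lo, b_hi)

    # vessels only well inside the brain so truth_vessels stays within truth_brain
    allowed = _disc(h, w, cx, cy, r_in - 4)
    n_left = spec.n_vessel_branches_good
    n_right = spec.n_vessel_branches_good if label == GOOD else spec.n_vessel_branches_poor
    truth_vessels = _draw_vessels(
        rng, img, allowed, n_left, (cx - r_in / 2.2, cy), spec.vessel_intensity_range
    )
    truth_vessels |= _draw_vessels(
        rng, img, allowed, n_right, (cx + r_in / 2.2, cy), spec.vessel_intensity_range
    )

    img[ring] = 255
    out = np.rint(img).astype(np.uint8)
    out[ring] = 255
    # clip guarantee: no non-skull pixel may reach 255
    out[~ring & (out == 255)] = 254
    return PhantomImage(
        image=out, truth_brain=truth_brain, truth_vessels=truth_vessels, label=label
    )


def generate_cohort(
    n_good: int,
    n_poor: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    defect_rate: float = 0.0,
) -> list[PatientRecord]:
    """Generate a cohort of two-level phantom patients.

    Each patient gets two phantom slices (ganglionic / supraganglionic
    stand-ins) from distinct sub-seeds.  ``defect_rate`` is the fraction
    of patients whose slices carry a calvarial defect.  Records store the
    raw grayscale phantom images; run the segmentation pipeline (or use
    the stored truth masks in ``meta``) to obtain classifier inputs.
    """
    if n_good < 0 or n_poor < 0:
        raise ValueError("cohort sizes must be non-negative")
    spec = spec if spec is not None else PhantomSpec()
    spec.validate()
    master = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    labels = [GOOD] * n_good + [POOR] * n_poor
    for i, lab in enumerate(labels):
        defect = bool(master.uniform() < defect_rate)
        sub = [int(master.integers(0, 2**31 - 1)) for _ in range(2)]
        slices = [
            generate_phantom(
                replace(spec, seed=s, calvarial_defect=defect or spec.calvarial_defect),
                lab,
            )
            for s in sub
        ]
        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                ganglionic=slices[0].image,
                supraganglionic=slices[1].image,
                label=1 if lab == GOOD else 0,
                meta={
                    "phantoms": slices,
                    "sub_seeds": sub,
                    "calvarial_defect": defect,
                },
            )
        )
    return records


def write_phantom(ph: PhantomImage, stem: Path) -> list[Path]:
    """Write image and truth masks as 8-bit grayscale BMP next to ``stem``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for suffix, arr in [
        ("", ph.image),
        ("_brain", ph.truth_brain.astype(np.uint8) * 255),
        ("_vessels", ph.truth_vessels.astype(np.uint8) * 255),
    ]:
        p = stem.with_name(stem.name + suffix + ".bmp")
        Image.fromarray(arr, mode="L").save(p)
        paths.append(p)
    return paths


def write_cohort(records: list[PatientRecord], outdir: Path) -> Path:
    """Write a cohort to ``outdir`` as BMPs plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "ganglionic", "supraganglionic", "label"])
        for rec in records:
            paths = []
            for level, arr in [
                ("gang", rec.ganglionic),
                ("supra", rec.supraganglionic),
            ]:
                p = outdir / f"{rec.patient_id}_{level}.bmp"
                Image.fromarray(np.asarray(arr, dtype=np.uint8), mode="L").save(p)
                paths.append(p.name)
            writer.writerow([rec.patient_id, *paths, rec.label])
    return manifest
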