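"""Metrically scaled stack assembly and DICOM export.

The actual abrasion of every grinding step is measured with a tactile length
gauge, so slice positions are the *cumulative sum of measured abrasions*
(starting at 0 for the first surface) rather than multiples of the nominal
step.  This module turns the measurement table into slice z-positions,
quantifies how far an equidistant assumption would have dislocated each
slice, assembles the aligned images into a 3D stack, and writes/reads the
stack as a DICOM secondary-capture series.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AbrasionLedger",
    "build_ledger",
    "ErrorReport",
    "error_report",
    "classify_propagation",
    "ReconstructedStack",
    "assemble_stack",
    "crop_stack",
    "write_dicom",
    "read_dicom_stack",
    "plot_error_report",
    "SLICE_THICKNESS_MM",
]

#: DICOM slice thickness: the lowest level expressible at three decimals,
#: respecting the two-dimensional character of a grinding surface.
SLICE_THICKNESS_MM = 0.001


@dataclass
class AbrasionLedger:
    """Per-step measured abrasion distances and the implied slice depths.

    ``z_um[0] == 0`` and ``z_um[i] = z_um[i-1] + measured_um[i-1]``; all
    measured abrasions are strictly positive.
    """

    nominal_um: float
    measured_um: np.ndarray
    z_um: np.ndarray

    def __post_init__(self) -> None:
        self.measured_um = np.asarray(self.measured_um, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.nominal_um <= 0:
            raise ValueError("nominal abrasion must be positive")
        if np.any(self.measured_um <= 0):
            raise ValueError("all measured abrasions must be positive")
        if len(self.z_um) != len(self.measured_um) + 1 or self.z_um[0] != 0:
            raise ValueError("z_um must be the cumulative sum starting at 0")
        if not np.allclose(np.diff(self.z_um), self.measured_um):
            raise ValueError("z_um inconsistent with measured abrasions")

    @property
    def n_slices(self) -> int:
        return len(self.z_um)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({
            "slice_index": np.arange(1, len(self.measured_um) + 1),
            "abrasion_um": self.measured_um,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, nominal_um: float = 100.0
                 ) -> "AbrasionLedger":
        import pandas as pd

        df = pd.read_csv(path)
        return build_ledger(df["abrasion_um"].to_numpy(), nominal_um=nominal_um)


def build_ledger(
    measured_um: np.ndarray, nominal_um: float = 100.0
) -> AbrasionLedger:
    """Ledger from per-step measurements; z as cumulative sums starting at 0."""
    measured = np.asarray(measured_um, dtype=float)
    z = np.concatenate([[0.0], np.cumsum(measured)])
    return AbrasionLedger(nominal_um=nominal_um, measured_um=measured, z_um=z)


# ---------------------------------------------------------------------------
# Error reporting
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Deviation of the measured grinding progress from equidistant abrasion.

    ``slice_error_um`` is the absolute per-step deviation |measured −
    nominal| (the signed values are kept alongside); ``accumulated_error_um``
    compares each slice's actual depth with its idealised depth ``i *
    nominal`` — an abstract dislocation that the measurement step corrects,
    reported to show what equidistant reconstruction would have done.
    ``max_accumulated_um`` keeps the sign of the extremal value.
    """

    nominal_um: float
    slice_error_um: np.ndarray
    signed_error_um: np.ndarray
    accumulated_error_um: np.ndarray
    max_accumulated_um: float
    abrasion_mean_um: float
    abrasion_sd_um: float
    error_mean_um: float
    error_sd_um: float
    propagation_type: int


def error_report(
    ledger: AbrasionLedger,
    drift_threshold_um: float = 1.0,
    monotone_fraction: float = 0.7,
) -> ErrorReport:
    """Per-step and accumulated abrasion errors plus the propagation type."""
    signed = ledger.measured_um - ledger.nominal_um
    abs_err = np.abs(signed)
    idx = np.arange(ledger.n_slices)
    accumulated = ledger.z_um - idx * ledger.nominal_um
    k = int(np.argmax(np.abs(accumulated)))
    ptype = classify_propagation(
        accumulated,
        drift_threshold_um=drift_threshold_um,
        monotone_fraction=monotone_fraction,
    ) if len(signed) >= 10 else 2
    return ErrorReport(
        nominal_um=ledger.nominal_um,
        slice_error_um=abs_err,
        signed_error_um=signed,
        accumulated_error_um=accumulated,
        max_accumulated_um=float(accumulated[k]),
        abrasion_mean_um=float(np.mean(ledger.measured_um))
        if len(signed) else 0.0,
        abrasion_sd_um=float(np.std(ledger.measured_um, ddof=1))
        if len(signed) > 1 else 0.0,
        error_mean_um=float(np.mean(abs_err)) if len(signed) else 0.0,
        error_sd_um=float(np.std(abs_err, ddof=1)) if len(signed) > 1 else 0.0,
        propagation_type=ptype,
    )


def classify_propagation(
    accumulated_error_um: np.ndarray,
    drift_threshold_um: float = 1.0,
    monotone_fraction: float = 0.7,
) -> int:
    """Classify the error propagation of a grinding series.

    Type 1: systematically excessive abrasion — the accumulated error trends
    away from zero (mean signed step error above ``drift_threshold_um`` and
    at least ``monotone_fraction`` of the steps increase the magnitude of
    the accumulated error).  Type 2: non-predictable progress with partial
    compensation (anything else, e.g. a zero-mean random walk).
    """
    acc = np.asarray(accumulated_error_um, dtype=float)
    if len(acc) < 11 or acc[0] != 0:
        raise ValueError("need accumulated errors for at least 10 steps, "
                         "starting at 0")
    steps = np.diff(acc)
    mean_step = float(np.mean(steps))
    growing = np.abs(acc[1:]) >= np.abs(acc[:-1])
    frac = float(np.mean(growing))
    if mean_step > drift_threshold_um and frac >= monotone_fraction:
        return 1
    return 2


# ---------------------------------------------------------------------------
# Stack assembly
# ---------------------------------------------------------------------------

@dataclass
class ReconstructedStack:
    """Aligned, metrically scaled image stack.

    ``images`` is a list of identically shaped 8-bit images; ``z_um`` the
    per-slice depth from the abrasion ledger; ``pixel_spacing_um_per_px`` the
    in-plane metric scale.  ``provenance`` carries whatever the producing
    step wants recorded (seed, config hash, transforms).
    """

    images: list[np.ndarray]
    pixel_spacing_um_per_px: float
    z_um: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        if len(self.images) != len(self.z_um):
            raise ValueError(
                f"{len(self.images)} images but {len(self.z_um)} z positions"
            )
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent image shapes: {shapes}")
        if self.pixel_spacing_um_per_px <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.images[0].shape

    def voxel_array(self) -> np.ndarray:
        """(n_slices, H, W[, C]) array view of the stack."""
        return np.stack(self.images)


def assemble_stack(
    aligned_images: list[np.ndarray],
    ledger: AbrasionLedger,
    pixel_spacing_um_per_px: float,
    provenance: dict | None = None,
) -> ReconstructedStack:
    """Locate each aligned slice at its measured depth."""
    if len(aligned_images) != ledger.n_slices:
        raise ValueError(
            f"{len(aligned_images)} images but ledger has "
            f"{ledger.n_slices} slices"
        )
    return ReconstructedStack(
        images=list(aligned_images),
        pixel_spacing_um_per_px=pixel_spacing_um_per_px,
        z_um=ledger.z_um.copy(),
        provenance=dict(provenance or {}),
    )


def crop_stack(
    stack: ReconstructedStack, bbox_px: tuple[int, int, int, int]
) -> ReconstructedStack:
    """Crop every slice to ``bbox_px = (x0, y0, width, height)``.

    Depths and pixel spacing are unchanged; the crop origin is recorded in
    the provenance.
    """
    x0, y0, bw, bh = bbox_px
    h, w = stack.shape[:2]
    if bw <= 0 or bh <= 0 or x0 < 0 or y0 < 0 or x0 + bw > w or y0 + bh > h:
        raise ValueError(f"bbox {bbox_px} outside image bounds {(w, h)}")
    prov = dict(stack.provenance)
    prov["crop_origin_px"] = (
        tuple(np.add(prov.get("crop_origin_px", (0, 0)), (x0, y0)))
    )
    return ReconstructedStack(
        images=[im[y0:y0 + bh, x0:x0 + bw] for im in stack.images],
        pixel_spacing_um_per_px=stack.pixel_spacing_um_per_px,
        z_um=stack.z_um.copy(),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _uid(seed: str) -> str:
    """Deterministic DICOM UID under the 2.25 (UUID-derived) root."""
    digest = hashlib.sha256(seed.encode()).hexdigest()
    return "2.25." + str(int(digest[:30], 16))


def write_dicom(
    stack: ReconstructedStack, out_dir: str | Path, uid_seed: int = 0
) -> list[Path]:
    """Write one secondary-capture DICOM file per slice.

    Pixel spacing (row and column) is the stack spacing converted to mm/px;
    slice thickness is fixed at 0.001 mm to respect the two-dimensional
    character of each grinding surface; slice position/location attributes
    carry the cumulative measured abrasion in mm.  All unique identifiers are
    derived deterministically from ``uid_seed``.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study_uid = _uid(f"study-{uid_seed}")
    series_uid = _uid(f"series-{uid_seed}")
    spacing_mm = stack.pixel_spacing_um_per_px / 1000.0

    paths: list[Path] = []
    for i, img in enumerate(stack.images):
        if img.dtype != np.uint8:
            raise ValueError("stack images must be 8-bit")
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = _uid(f"instance-{uid_seed}-{i}")
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.ConversionType = "SYN"
        ds.PatientName = "grindstack^phantom"
        ds.PatientID = f"GRINDSTACK-{uid_seed}"
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]  # axial identity
        z_mm = stack.z_um[i] / 1000.0
        ds.ImagePositionPatient = [0.0, 0.0, float(z_mm)]
        ds.SliceLocation = float(z_mm)
        ds.SliceThickness = SLICE_THICKNESS_MM
        ds.PixelSpacing = [spacing_mm, spacing_mm]

        if img.ndim == 3:
            ds.SamplesPerPixel = 3
            ds.PhotometricInterpretation = "RGB"
            ds.PlanarConfiguration = 0
        else:
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = img.shape[:2]
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelData = img.tobytes()

        p = out / f"slice_{i:04d}.dcm"
        pydicom.dcmwrite(p, ds, enforce_file_format=True)
        paths.append(p)
    return paths


def read_dicom_stack(in_dir: str | Path) -> ReconstructedStack:
    """Read a DICOM series back into a stack, ordered by slice location."""
    import pydicom

    paths = sorted(Path(in_dir).glob("*.dcm"))
    if not paths:
        raise FileNotFoundError(f"no .dcm files in {in_dir}")
    entries = []
    for p in paths:
        ds = pydicom.dcmread(p)
        spacing = float(ds.PixelSpacing[0]) * 1000.0
        if abs(float(ds.PixelSpacing[0]) - float(ds.PixelSpacing[1])) > 1e-12:
            raise ValueError(f"anisotropic pixel spacing in {p}")
        img = ds.pixel_array
        entries.append((float(ds.SliceLocation), spacing, img))
    entries.sort(key=lambda e: e[0])
    spacings = {round(e[1], 9) for e in entries}
    if len(spacings) > 1:
        raise ValueError(f"inconsistent pixel spacing across files: {spacings}")
    z_mm = np.array([e[0] for e in entries])
    return ReconstructedStack(
        images=[e[2] for e in entries],
        pixel_spacing_um_per_px=entries[0][1],
        z_um=(z_mm - z_mm[0]) * 1000.0,
    )


def plot_error_report(report: ErrorReport, out_path: str | Path) -> None:
    """Bar plot of per-step signed error with the accumulated-error line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    steps = np.arange(1, len(report.signed_error_um) + 1)
    ax.bar(steps, report.signed_error_um, color="tab:blue",
           label="slice error [µm]")
    ax.plot(np.arange(len(report.accumulated_error_um)),
            report.accumulated_error_um, color="tab:red",
            label="accumulated error [µm]")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("grinding step")
    ax.set_ylabel("deviation from nominal abrasion [µm]")
    ax.legend()
    ax.set_title(f"error propagation (type {report.propagation_type})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
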