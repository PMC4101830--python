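"""DAB immunostaining quantification on TMA spot images.

Brightfield immunohistochemistry reports antibody binding through the brown
DAB chromogen over a hematoxylin counterstain. Chromogen amount is linear in
optical density (OD), not in pixel intensity, so quantification proceeds as

1. transform 8-bit RGB to per-channel OD,
2. unmix the OD image into per-stain concentration planes with the
   Ruifrok-Johnston color-deconvolution inverse of the stain matrix,
3. summarize the DAB plane inside caller-provided tissue-class masks.

The continuous staining score is ``AvgOD * %Pos``: the mean DAB OD over all
region pixels multiplied by the percentage of region pixels at or above a
positivity threshold. For predominantly nuclear markers the unit of analysis
is the nucleus (``AvgNuclearOD * %PosNuclei``), and for the microvascular
marker a set of per-vessel morphometrics is reported instead.

Tissue classification, nucleus segmentation and vessel detection are *not*
performed here: label masks are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainVectors",
    "RegionMasks",
    "StainMetrics",
    "NuclearMetrics",
    "MicrovesselMetrics",
    "TISSUE_LABELS",
    "rgb_to_od",
    "od_to_intensity",
    "deconvolve",
    "region_metrics",
    "nuclear_metrics",
    "microvessel_metrics",
]

# tissue-class label encoding for RegionMasks.tissue_class
TISSUE_LABELS = {"glass": 0, "tumor_epithelium": 1, "stroma": 2}

DEFAULT_POSITIVITY_THRESHOLD = 0.15  # OD units


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class StainVectors:
    """Unit stain vectors in OD space (H-DAB basis).

    Defaults are the published Ruifrok-Johnston hematoxylin/DAB vectors;
    the residual axis is the normalized cross product, completing the basis.
    """

    hematoxylin: np.ndarray = field(
        default_factory=lambda: _unit([0.650, 0.704, 0.286])
    )
    dab: np.ndarray = field(default_factory=lambda: _unit([0.269, 0.568, 0.872]))
    residual: np.ndarray | None = None

    def __post_init__(self):
        self.hematoxylin = _unit(self.hematoxylin)
        self.dab = _unit(self.dab)
        if np.any(self.hematoxylin < 0) or np.any(self.dab < 0):
            raise ValueError("stain vectors must be non-negative")
        cross = np.cross(self.hematoxylin, self.dab)
        if np.linalg.norm(cross) < 1e-6:
            raise ValueError("hematoxylin and DAB vectors are collinear")
        if self.residual is None:
            self.residual = _unit(cross)
        else:
            self.residual = _unit(self.residual)

    @property
    def matrix(self) -> np.ndarray:
        """Rows = stains (hematoxylin, dab, residual), columns = RGB."""
        return np.stack([self.hematoxylin, self.dab, self.residual])


@dataclass
class RegionMasks:
    """Per-pixel label images accompanying an RGB spot.

    ``tissue_class`` uses :data:`TISSUE_LABELS`. ``nuclei`` and ``vessels``
    are optional positive-integer label images (0 = background); ``lumen``
    labels lumen pixels with their parent vessel id.
    """

    tissue_class: np.ndarray
    nuclei: np.ndarray | None = None
    vessels: np.ndarray | None = None
    lumen: np.ndarray | None = None

    def __post_init__(self):
        shape = self.tissue_class.shape
        for name in ("nuclei", "vessels", "lumen"):
            arr = getattr(self, name)
            if arr is not None:
                if arr.shape != shape:
                    raise ValueError(f"{name} mask shape {arr.shape} != {shape}")
                if arr.min() < 0:
                    raise ValueError(f"{name} ids must be non-negative")


@dataclass
class StainMetrics:
    avg_od: float
    pct_pos: float
    score: float
    n_pixels: int

    @property
    def missing(self) -> bool:
        return self.n_pixels == 0


@dataclass
class NuclearMetrics:
    avg_nuclear_od: float
    pct_pos_nuclei: float
    score: float
    n_nuclei: int

    @property
    def missing(self) -> bool:
        return self.n_nuclei == 0


@dataclass
class MicrovesselMetrics:
    avg_vessel_area: float
    avg_vessel_perimeter: float
    avg_lumen_area: float
    avg_vascular_area: float
    microvessel_density: float
    n_vessels: int


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an 8-bit RGB image.

    ``OD = -log10((I + 1) / 256)``; the +1 guard avoids log(0) at I=0 and
    makes a saturated white pixel (I=255) exactly OD 0. Strictly monotone
    decreasing in intensity.
    """
    rgb = np.asarray(rgb)
    if rgb.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit (uint8) RGB input, got dtype {rgb.dtype}; "
            "refusing to rescale silently"
        )
    return -np.log10((rgb.astype(float) + 1.0) / 256.0)


def od_to_intensity(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` with rounding to the 8-bit grid."""
    I = np.round(256.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0)
    return np.clip(I, 0, 255).astype(np.uint8)


def deconvolve(
    od_image: np.ndarray,
    vectors: StainVectors | None = None,
    cond_threshold: float = 1e6,
    clamp: bool = True,
):
    """Unmix an OD image into per-stain concentration planes.

    Solves ``od_pixel = M.T @ concentrations`` per pixel with ``M`` the
    stain matrix. Negative concentrations (noise outside the stain cone)
    are clamped to 0 unless ``clamp=False``. Returns
    ``(concentrations, reconstruction_rmse)`` where ``concentrations`` has
    shape ``(..., 3)`` ordered (hematoxylin, dab, residual).
    """
    vectors = vectors or StainVectors()
    M = vectors.matrix
    if np.linalg.cond(M) > cond_threshold:
        raise ValueError("stain matrix is near-singular; check stain vectors")
    inv = np.linalg.inv(M.T)
    od = np.asarray(od_image, dtype=float)
    conc = od @ inv.T
    recon = conc @ M
    rmse = float(np.sqrt(np.mean((recon - od) ** 2)))
    if clamp:
        conc = np.maximum(conc, 0.0)
    return conc, rmse


def region_metrics(
    dab_plane: np.ndarray,
    masks: RegionMasks,
    region: str = "tumor_epithelium",
    threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
) -> StainMetrics:
    """``AvgOD * %Pos`` over one tissue class.

    AvgOD is the mean DAB OD over *all* region pixels (positive and
    negative); %Pos is the percentage of region pixels with DAB OD at or
    above ``threshold``. An empty region yields a missing-flagged result
    (NaN metrics, ``n_pixels=0``), never silent zeros.
    """
    if region not in TISSUE_LABELS:
        raise KeyError(f"unknown region {region!r}; options {list(TISSUE_LABELS)}")
    sel = masks.tissue_class == TISSUE_LABELS[region]
    vals = np.asarray(dab_plane, dtype=float)[sel]
    if vals.size == 0:
        return StainMetrics(np.nan, np.nan, np.nan, 0)
    avg = float(vals.mean())
    pct = float(100.0 * np.mean(vals >= threshold))
    return StainMetrics(avg, pct, avg * pct, int(vals.size))


def nuclear_metrics(
    dab_plane: np.ndarray,
    masks: RegionMasks,
    threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
) -> NuclearMetrics:
    """``AvgNuclearOD * %PosNuclei`` with the nucleus as unit of analysis.

    Each nucleus is summarized by its mean DAB OD; a nucleus is positive
    iff that mean is at or above ``threshold``. No nuclei in the mask
    yields a missing-flagged result.
    """
    if masks.nuclei is None:
        raise ValueError("masks.nuclei is required for nuclear metrics")
    lab = masks.nuclei
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        return NuclearMetrics(np.nan, np.nan, np.nan, 0)
    dab = np.asarray(dab_plane, dtype=float)
    flat_lab = lab.ravel()
    sums = np.bincount(flat_lab, weights=dab.ravel())
    counts = np.bincount(flat_lab)
    means = sums[ids] / counts[ids]
    avg = float(means.mean())
    pct = float(100.0 * np.mean(means >= threshold))
    return NuclearMetrics(avg, pct, avg * pct, int(ids.size))


def _perimeter_4edges(binary: np.ndarray) -> int:
    """Boundary length as the count of 4-connected edge steps: pixel faces
    shared with background or the image border."""
    b = binary.astype(bool)
    pad = np.pad(b, 1, constant_values=False)
    per = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        per += int(np.sum(b & ~np.roll(pad, shift, axis=axis)[1:-1, 1:-1]))
    return per


def microvessel_metrics(
    masks: RegionMasks, tumor_area: float
) -> MicrovesselMetrics:
    """Per-vessel morphometrics from labeled vessel/lumen masks.

    Vessel labels are taken as filled components (lumen included in the
    vessel area); vascular area = vessel minus lumen. Density is vessels
    per unit tumor area. With zero vessels the averages are missing-flagged
    (NaN) and the density is 0.
    """
    if masks.vessels is None:
        raise ValueError("masks.vessels is required for microvessel metrics")
    if tumor_area <= 0:
        raise ValueError("tumor_area must be positive")
    lab = masks.vessels
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        return MicrovesselMetrics(np.nan, np.nan, np.nan, np.nan, 0.0, 0)
    lumen = masks.lumen if masks.lumen is not None else np.zeros_like(lab)
    areas, perims, lumens = [], [], []
    for vid in ids:
        vm = lab == vid
        areas.append(int(vm.sum()))
        perims.append(_perimeter_4edges(vm))
        lumens.append(int((lumen == vid).sum()))
    areas = np.array(areas, dtype=float)
    lumens = np.array(lumens, dtype=float)
    return MicrovesselMetrics(
        avg_vessel_area=float(areas.mean()),
        avg_vessel_perimeter=float(np.mean(perims)),
        avg_lumen_area=float(lumens.mean()),
        avg_vascular_area=float((areas - lumens).mean()),
        microvessel_density=float(ids.size / tumor_area),
        n_vessels=int(ids.size),
    )
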