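"""Threshold-based partition of the brain into transport subdomains.

Arteries and ventricles come from the pre-contrast T1 map; periarterial
spaces combine an early-time concentration threshold with voxel
proximity to arteries of the matching class.  Distances are Chebyshev
("voxels away") by default; Euclidean is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .relaxometry import ConcentrationSeries, T1Map
from .subdomains import LABEL_NAMES, Subdomain

__all__ = [
    "SegmentationThresholds",
    "ArteryMask",
    "SubdomainLabels",
    "segment_arteries",
    "segment_ventricles",
    "segment_pas",
    "compose_labels",
    "run_segmentation",
]


@dataclass
class SegmentationThresholds:
    artery_t1_max: float = 1200.0  # ms; subject range 1000-1400
    ventricle_t1_min: float = 3000.0  # ms
    pas_conc_min: float = 0.15  # mM
    pas_time: float = 20.0  # min
    surf_max_dist: int = 7  # voxels
    branch_max_dist: int = 3  # voxels
    metric: str = "chessboard"  # or "euclidean"

    def __post_init__(self) -> None:
        if self.artery_t1_max >= self.ventricle_t1_min:
            raise ValueError("artery T1 threshold must be below ventricle threshold")
        if self.surf_max_dist <= 0 or self.branch_max_dist <= 0:
            raise ValueError("distance bounds must be positive integers")
        if self.metric not in ("chessboard", "euclidean"):
            raise ValueError(f"unknown distance metric {self.metric!r}")


@dataclass
class ArteryMask:
    mask: np.ndarray  # bool
    classes: np.ndarray  # int8: 0 none, 1 surface, 2 branching
    unclassified_components: int = 0


@dataclass
class SubdomainLabels:
    """Per-voxel subdomain codes plus the thresholds that produced them."""

    values: np.ndarray  # int8
    provenance: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        labs, n = np.unique(self.values, return_counts=True)
        return {LABEL_NAMES[int(l)]: int(c) for l, c in zip(labs, n)}

    @property
    def brain_mask(self) -> np.ndarray:
        return self.values != int(Subdomain.BACKGROUND)


def _distance_to(mask: np.ndarray, metric: str) -> np.ndarray:
    if not mask.any():
        return np.full(mask.shape, np.inf)
    if metric == "chessboard":
        return ndimage.distance_transform_cdt(~mask, metric="chessboard").astype(float)
    return ndimage.distance_transform_edt(~mask)


def segment_arteries(
    t1: T1Map,
    thr: SegmentationThresholds,
    artery_class_map: np.ndarray,
    brain_mask: np.ndarray,
) -> ArteryMask:
    """Threshold T1 inside the brain; classify connected components.

    Classes come from the annotation map (1 = surface, 2 = branching):
    annotated voxels keep their per-voxel class; unannotated voxels of a
    connected component take the component's majority class.  Components
    with no annotated voxel at all stay unclassified and are counted.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    vals = np.where(t1.valid, t1.values, np.inf)
    mask = brain_mask & (vals < thr.artery_t1_max)
    if not mask.any():
        warnings.warn("no voxels below the artery T1 threshold; empty artery mask")
    elif mask.sum() == brain_mask.sum():
        warnings.warn("artery T1 threshold flags the whole brain; check thresholds")

    ann = np.asarray(artery_class_map, dtype=np.int8)
    classes = np.where(mask, ann, 0).astype(np.int8)
    comp, n_comp = ndimage.label(mask)
    unclassified = 0
    for c in range(1, n_comp + 1):
        sel = comp == c
        votes = classes[sel]
        votes = votes[votes > 0]
        if votes.size == 0:
            unclassified += 1
            continue
        fill = sel & (classes == 0)
        if fill.any():
            classes[fill] = np.int8(np.bincount(votes).argmax())
    return ArteryMask(mask=mask, classes=classes, unclassified_components=unclassified)


def segment_ventricles(
    t1: T1Map, thr: SegmentationThresholds, brain_mask: np.ndarray
) -> np.ndarray:
    vals = np.where(t1.valid, t1.values, -np.inf)
    return np.asarray(brain_mask, dtype=bool) & (vals > thr.ventricle_t1_min)


def segment_pas(
    conc: ConcentrationSeries,
    arteries: ArteryMask,
    thr: SegmentationThresholds,
    brain_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """PAS masks from early-time concentration and artery proximity.

    A voxel is PAS_Surf when its concentration at the frame nearest
    ``pas_time`` exceeds ``pas_conc_min`` and it lies within
    ``surf_max_dist`` of a surface-class artery voxel (PAS_Branch
    analogously); artery voxels are excluded and voxels qualifying for
    both classes go to PAS_Branch.
    """
    if arteries.mask.any() and arteries.unclassified_components > 0:
        raise ValueError(
            f"{arteries.unclassified_components} artery component(s) lack a "
            "surface/branching class annotation"
        )
    frame, used_time = conc.frame_at(thr.pas_time)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    hot = brain_mask & (frame > thr.pas_conc_min)

    d_surf = _distance_to(arteries.classes == 1, thr.metric)
    d_branch = _distance_to(arteries.classes == 2, thr.metric)
    pas_surf = hot & (d_surf <= thr.surf_max_dist) & ~arteries.mask
    pas_branch = hot & (d_branch <= thr.branch_max_dist) & ~arteries.mask
    pas_surf &= ~pas_branch  # tie-break
    info = {"pas_frame_time_min": used_time, "tie_break": "PAS_Branch"}
    return pas_surf, pas_branch, info


def compose_labels(
    brain_mask: np.ndarray,
    arteries: ArteryMask | np.ndarray,
    ventricle: np.ndarray,
    pas_surf: np.ndarray,
    pas_branch: np.ndarray,
    provenance: dict | None = None,
) -> SubdomainLabels:
    """Assemble masks with precedence Artery > Ventricle > PAS_Branch >
    PAS_Surf > BT; remaining in-brain voxels are BT."""
    artery_mask = arteries.mask if isinstance(arteries, ArteryMask) else np.asarray(arteries, bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    labels = np.zeros(brain_mask.shape, dtype=np.int8)
    labels[brain_mask] = int(Subdomain.BT)
    labels[brain_mask & pas_surf] = int(Subdomain.PAS_SURF)
    labels[brain_mask & pas_branch] = int(Subdomain.PAS_BRANCH)
    labels[brain_mask & ventricle] = int(Subdomain.VENTRICLE)
    labels[brain_mask & artery_mask] = int(Subdomain.ARTERY)
    out = SubdomainLabels(values=labels, provenance=provenance or {})
    out.provenance["voxel_counts"] = out.counts
    return out


def run_segmentation(
    t1: T1Map,
    conc: ConcentrationSeries,
    brain_mask: np.ndarray,
    artery_class_map: np.ndarray,
    thr: SegmentationThresholds | None = None,
) -> SubdomainLabels:
    """Full threshold segmentation: arteries, ventricles, PAS, composition."""
    thr = thr or SegmentationThresholds()
    arteries = segment_arteries(t1, thr, artery_class_map, brain_mask)
    ventricle = segment_ventricles(t1, thr, brain_mask)
    pas_surf, pas_branch, info = segment_pas(conc, arteries, thr, brain_mask)
    prov = {"thresholds": {k: getattr(thr, k) for k in vars(thr)}, **info}
    return compose_labels(brain_mask, arteries, ventricle, pas_surf, pas_branch, prov)
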